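"""Shared fixtures: one default synthetic dataset (seed 7) analysed once and
reused by the recovery, annotation, infection and integration tests."""

from __future__ import annotations

import numpy as np
import pytest

from damidkit import peaks as pk
from damidkit import windows as win
from damidkit.simulate import SimulationConfig, SyntheticDataset, simulate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_config) -> SyntheticDataset:
    return simulate_dataset(default_config)


def analyse_condition(dataset: SyntheticDataset, condition: str, max_fdr: float = 1e-2):
    """Count, score, call, FDR-attach and filter one condition in memory."""
    grid = win.build_windows(dataset.genome, dataset.config.window)
    treatment = win.count_reads(grid, dataset.reads[f"fusion_{condition}"])
    background = win.count_reads(grid, dataset.reads[f"dam_{condition}"])
    peaks, track = pk.call_and_summarize(treatment, background)
    estimates = pk.estimate_fdr(treatment, background)
    peaks = pk.attach_fdr(peaks, estimates)
    filtered = pk.filter_peaks(peaks, min_log2fc=3.0, max_fdr=max_fdr)
    return {
        "grid": grid,
        "treatment": treatment,
        "background": background,
        "track": track,
        "peaks": peaks,
        "filtered": filtered,
        "estimates": estimates,
    }


@pytest.fixture(scope="session")
def control_run(default_dataset):
    return analyse_condition(default_dataset, "control")


@pytest.fixture(scope="session")
def infected_run(default_dataset):
    return analyse_condition(default_dataset, "infected")


def peak_overlaps_site(peak, site) -> bool:
    return peak.chrom == site.chrom and peak.start < site.end and site.start < peak.end


@pytest.fixture(scope="session")
def annotated_control(default_dataset, control_run):
    from damidkit import annotate as ann

    return ann.annotate_peaks(control_run["filtered"], default_dataset.genes)
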