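"""Stage 3 — binding-site calls from runs of significant windows.

A binding site is a maximal run of >= 4 consecutive windows whose one-sided
enrichment p-value is below alpha; runs never cross chromosome boundaries.
Each peak is summarized by its span, the midpoint of its best window
(summit) and a fold change computed from summed counts over the run.

The false discovery rate is empirical: the identical pipeline is re-run
with treatment and background swapped, and FDR(threshold) is the ratio of
swapped-label to observed peak counts at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import WindowCountTrack
from .scoring import (
    DEFAULT_PSEUDOCOUNT,
    LogRatioTrack,
    score_tracks,
)

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_UNITS = 4
DEFAULT_MIN_LOG2FC = 3.0
CONTROL_MAX_FDR = 1e-4  # FDR < 0.01%
INFECTED_MAX_FDR = 1e-3  # FDR < 0.1%


@dataclass(frozen=True)
class PeakCall:
    """One called binding site: a run of significant windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    first_window: int  # global window index of the run start
    summit: int | None = None
    log2fc: float | None = None
    min_p: float | None = None
    fdr: float | None = None

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class FdrEstimate:
    """Empirical FDR at one (alpha, min log2FC) threshold pair."""

    alpha: float
    min_log2fc: float
    observed: int
    null: int

    @property
    def fdr(self) -> float | None:
        if self.observed == 0:
            return None
        return self.null / self.observed


def call_candidate_peaks(
    track: LogRatioTrack,
    alpha: float = DEFAULT_ALPHA,
    min_units: int = DEFAULT_MIN_UNITS,
) -> list[PeakCall]:
    """Maximal runs of >= min_units consecutive windows with p < alpha."""
    if track.pvalues is None:
        raise ValueError("track has no p-values; run window_pvalues first")
    peaks: list[PeakCall] = []
    grid = track.grid
    for chrom in grid.chrom_names:
        sl = grid.chrom_slice(chrom)
        sig = track.pvalues[sl] < alpha
        if not sig.any():
            continue
        # run boundaries from the padded sign changes of the mask
        padded = np.concatenate([[False], sig, [False]]).astype(np.int8)
        changes = np.flatnonzero(np.diff(padded))
        starts, stops = changes[::2], changes[1::2]
        length = grid.genome.length(chrom)
        for s, e in zip(starts, stops):
            if e - s < min_units:
                continue
            peaks.append(
                PeakCall(
                    chrom=chrom,
                    start=int(s) * grid.width,
                    end=min(int(e) * grid.width, length),
                    n_windows=int(e - s),
                    first_window=sl.start + int(s),
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def summarize_peak(
    peak: PeakCall,
    track: LogRatioTrack,
    treatment: WindowCountTrack,
    background: WindowCountTrack,
    factor: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PeakCall:
    """Fill summit (midpoint of the best window, leftmost on ties) and the
    peak log2 fold change log2((f*sum t + c)/(sum b + c))."""
    sl = slice(peak.first_window, peak.first_window + peak.n_windows)
    vals = track.values[sl]
    best = int(np.argmax(vals))  # argmax returns the leftmost maximum
    w_idx = peak.first_window + best
    _, ws, we = track.grid.window_bounds(w_idx)
    summit = (ws + we) // 2
    t_sum = float(treatment.counts[sl].sum())
    b_sum = float(background.counts[sl].sum())
    log2fc = float(np.log2(factor * t_sum + pseudocount) - np.log2(b_sum + pseudocount))
    min_p = float(track.pvalues[sl].min()) if track.pvalues is not None else None
    return replace(peak, summit=summit, log2fc=log2fc, min_p=min_p)


def summarize_peaks(
    peaks: list[PeakCall],
    track: LogRatioTrack,
    treatment: WindowCountTrack,
    background: WindowCountTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PeakCall]:
    return [
        summarize_peak(p, track, treatment, background, track.factor, pseudocount) for p in peaks
    ]


def call_and_summarize(
    treatment: WindowCountTrack,
    background: WindowCountTrack,
    alpha: float = DEFAULT_ALPHA,
    min_units: int = DEFAULT_MIN_UNITS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    n_floor: int = 100,
    normalization_target: float = 0.0,
) -> tuple[list[PeakCall], LogRatioTrack]:
    track = score_tracks(
        treatment,
        background,
        pseudocount=pseudocount,
        n_floor=n_floor,
        normalization_target=normalization_target,
    )
    peaks = call_candidate_peaks(track, alpha=alpha, min_units=min_units)
    return summarize_peaks(peaks, track, treatment, background, pseudocount), track


def estimate_fdr(
    treatment: WindowCountTrack,
    background: WindowCountTrack,
    thresholds: list[tuple[float, float]] | None = None,
    min_units: int = DEFAULT_MIN_UNITS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    n_floor: int = 100,
    normalization_target: float = 0.0,
) -> list[FdrEstimate]:
    """Label-swap empirical FDR over a grid of (alpha, min log2FC) pairs.

    The swapped run asks how many 'peaks' the Dam-only sample shows against
    the fusion sample under the identical procedure; with no true depletion
    signal this approximates the false-call count at each threshold.
    """
    if thresholds is None:
        thresholds = [(DEFAULT_ALPHA, fc) for fc in (0.0, 1.0, 2.0, 3.0)]
    estimates: list[FdrEstimate] = []
    kwargs = dict(
        min_units=min_units,
        pseudocount=pseudocount,
        n_floor=n_floor,
        normalization_target=normalization_target,
    )
    for alpha in sorted({a for a, _ in thresholds}):
        obs_peaks, _ = call_and_summarize(treatment, background, alpha=alpha, **kwargs)
        null_peaks, _ = call_and_summarize(background, treatment, alpha=alpha, **kwargs)
        for a, min_fc in thresholds:
            if a != alpha:
                continue
            n_obs = sum(1 for p in obs_peaks if p.log2fc > min_fc)
            n_null = sum(1 for p in null_peaks if p.log2fc > min_fc)
            estimates.append(FdrEstimate(alpha=a, min_log2fc=min_fc, observed=n_obs, null=n_null))
    return estimates


def attach_fdr(peaks: list[PeakCall], estimates: list[FdrEstimate]) -> list[PeakCall]:
    """Give each peak the FDR of the most stringent fold-change threshold it passes."""
    out: list[PeakCall] = []
    for p in peaks:
        passed = [e for e in estimates if p.log2fc is not None and p.log2fc > e.min_log2fc]
        if not passed:
            out.append(replace(p, fdr=None))
            continue
        best = max(passed, key=lambda e: e.min_log2fc)
        out.append(replace(p, fdr=best.fdr))
    return out


def filter_peaks(
    peaks: list[PeakCall],
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    max_fdr: float = CONTROL_MAX_FDR,
) -> list[PeakCall]:
    """Keep peaks with log2FC strictly above and FDR strictly below threshold.

    A peak whose FDR is undefined (no observed peaks at its threshold) never
    passes.
    """
    return [
        p
        for p in peaks
        if p.log2fc is not None
        and p.log2fc > min_log2fc
        and p.fdr is not None
        and p.fdr < max_fdr
    ]


def peaks_to_frame(peaks: list[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.chrom, p.start, p.end, p.n_windows, p.summit, p.log2fc, p.min_p, p.fdr)
            for p in peaks
        ],
        columns=["chrom", "start", "end", "n_windows", "summit", "log2fc", "min_p", "fdr"],
    )


def peaks_to_bed(peaks: list[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.chrom, p.start, p.end, f"peak_{i + 1}", 0 if p.log2fc is None else round(p.log2fc, 3), ".")
            for i, p in enumerate(peaks)
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
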