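"""End-to-end orchestration: files in, tables out, one config, one seed.

The pipeline runs the six analysis stages for both conditions (control and
infected), writes every stage artifact under one output directory, and
records a manifest (parameters, seeds, input checksums) so a rerun with an
identical config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate as ann
from . import integrate as integ
from . import io as gio
from . import motif as mot
from . import peaks as pk
from . import scoring as sc
from . import windows as win
from .genome import Genome, WindowCountTrack


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run; round-trips through YAML."""

    # inputs
    reads_dam_control: str = ""
    reads_fusion_control: str = ""
    reads_dam_infected: str = ""
    reads_fusion_infected: str = ""
    chrom_sizes: str = ""
    gff: str = ""
    fasta: str = ""  # needed only for motif scanning
    de_table: str = ""
    # parameters
    window: int = 75
    extension: int = 300
    counting_mode: str = "footprint"
    pseudocount: float = 1.0
    n_floor: int = 100
    normalization_target: float = 0.0
    alpha: float = 0.01
    min_units: int = 4
    min_log2fc: float = 3.0
    max_fdr_control: float = pk.CONTROL_MAX_FDR
    max_fdr_infected: float = pk.INFECTED_MAX_FDR
    motif_pattern: str = mot.DEFAULT_PATTERN
    strand_mode: str = "both"
    n_relocations: int = mot.DEFAULT_RELOCATIONS
    moving_window: int = integ.DEFAULT_MOVING_WINDOW
    tss_window: int = ann.DEFAULT_TSS_WINDOW
    max_fold_infection: float = 2.0
    min_fold_change_de: float = 1.5
    max_padj_de: float = 0.1
    seed: int = 0
    outdir: str = "damidkit_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class ConditionResult:
    treatment: WindowCountTrack
    background: WindowCountTrack
    track: sc.LogRatioTrack
    peaks: list[pk.PeakCall]  # summarized, FDR attached
    filtered: list[pk.PeakCall]
    fdr_estimates: list[pk.FdrEstimate]


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: Genome
    control: ConditionResult
    infected: ConditionResult | None
    annotated: list[ann.AnnotatedPeak]
    tss_profile: object
    peak_genes: set[str]
    motif_report: mot.MotifEnrichmentReport | None
    integration: dict = field(default_factory=dict)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_condition(
    cfg: PipelineConfig,
    genome: Genome,
    treatment_path: str,
    background_path: str,
    max_fdr: float,
) -> ConditionResult:
    grid = win.build_windows(genome, cfg.window)
    t_reads = gio.read_bed_frame(treatment_path, genome)
    b_reads = gio.read_bed_frame(background_path, genome)
    treatment = win.count_reads(grid, t_reads, cfg.extension, cfg.counting_mode)
    background = win.count_reads(grid, b_reads, cfg.extension, cfg.counting_mode)
    kwargs = dict(
        min_units=cfg.min_units,
        pseudocount=cfg.pseudocount,
        n_floor=cfg.n_floor,
        normalization_target=cfg.normalization_target,
    )
    peaks, track = pk.call_and_summarize(treatment, background, alpha=cfg.alpha, **kwargs)
    estimates = pk.estimate_fdr(
        treatment,
        background,
        thresholds=[(cfg.alpha, fc) for fc in (0.0, 1.0, 2.0, cfg.min_log2fc)],
        **kwargs,
    )
    peaks = pk.attach_fdr(peaks, estimates)
    filtered = pk.filter_peaks(peaks, min_log2fc=cfg.min_log2fc, max_fdr=max_fdr)
    return ConditionResult(treatment, background, track, peaks, filtered, estimates)


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    for name in ("reads_fusion_control", "reads_dam_control", "chrom_sizes", "gff", "de_table"):
        path = getattr(cfg, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing or not found: {path!r}")

    genome = gio.read_chrom_sizes(cfg.chrom_sizes)
    genes = gio.read_gff_genes(cfg.gff)
    de = integ.read_de_table(cfg.de_table)

    control = run_condition(
        cfg, genome, cfg.reads_fusion_control, cfg.reads_dam_control, cfg.max_fdr_control
    )
    infected = None
    if cfg.reads_fusion_infected and cfg.reads_dam_infected:
        infected = run_condition(
            cfg, genome, cfg.reads_fusion_infected, cfg.reads_dam_infected, cfg.max_fdr_infected
        )

    annotated = ann.annotate_peaks(control.filtered, genes) if genes else []
    profile = ann.tss_distance_profile(annotated)
    peak_genes = ann.peak_associated_genes(annotated, cfg.tss_window)

    motif_report = None
    if cfg.fasta:
        seqs = gio.read_fasta(cfg.fasta)
        seq_genome = genome.with_sequences(seqs)
        peak_ivs = [pk_to_iv(p) for p in control.filtered]
        if peak_ivs:
            motif_report = mot.motif_enrichment(
                peak_ivs,
                seq_genome,
                pattern=cfg.motif_pattern,
                strand_mode=cfg.strand_mode,
                n_relocations=cfg.n_relocations,
                seed=_stage_seed(cfg.seed, "motif"),
            )

    integration: dict = {}
    up_genes = integ.select_deregulated_genes(
        de, cfg.min_fold_change_de, cfg.max_padj_de, "up"
    )
    integration["up_genes"] = up_genes
    integration["overlap"] = integ.intersect_targets(up_genes, peak_genes, universe=len(de))
    for key in ("fold_change", "absolute_change"):
        if len(de) >= cfg.moving_window:
            integration[f"curve_{key}"] = integ.moving_sum_association(
                de, peak_genes, key=key, window=cfg.moving_window
            )
    if infected is not None:
        integration["infection_classes"] = integ.classify_infection_response(
            control.filtered,
            infected.filtered,
            infected.treatment,
            infected.background,
            infected.track.factor,
            pseudocount=cfg.pseudocount,
            max_fold=cfg.max_fold_infection,
        )

    result = PipelineResult(
        config=cfg,
        genome=genome,
        control=control,
        infected=infected,
        annotated=annotated,
        tss_profile=profile,
        peak_genes=peak_genes,
        motif_report=motif_report,
        integration=integration,
    )
    if write:
        write_outputs(result)
    return result


def pk_to_iv(p: pk.PeakCall):
    from .genome import Interval

    return Interval(p.chrom, p.start, p.end)


def write_outputs(result: PipelineResult) -> Path:
    cfg = result.config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    for name, cond in (("control", result.control), ("infected", result.infected)):
        if cond is None:
            continue
        gio.write_bedgraph(cond.track, out / f"log2_ratio_{name}.bedgraph")
        pk.peaks_to_frame(cond.peaks).to_csv(out / f"peaks_all_{name}.tsv", sep="\t", index=False)
        pk.peaks_to_frame(cond.filtered).to_csv(
            out / f"peaks_filtered_{name}.tsv", sep="\t", index=False
        )
        gio.write_bed_frame(pk.peaks_to_bed(cond.filtered), out / f"peaks_filtered_{name}.bed")
        fdr_rows = [
            (e.alpha, e.min_log2fc, e.observed, e.null, "" if e.fdr is None else e.fdr)
            for e in cond.fdr_estimates
        ]
        import pandas as pd

        pd.DataFrame(
            fdr_rows, columns=["alpha", "min_log2fc", "observed", "null", "fdr"]
        ).to_csv(out / f"fdr_{name}.tsv", sep="\t", index=False)

    ann.annotated_to_frame(result.annotated).to_csv(
        out / "peaks_annotated_control.tsv", sep="\t", index=False
    )
    result.tss_profile.to_csv(out / "tss_distance_profile.tsv", sep="\t", index=False)

    if result.motif_report is not None:
        rep = result.motif_report
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "pattern": rep.pattern,
                    "strand_mode": rep.strand_mode,
                    "n_peaks": rep.observed.n_peaks,
                    "observed_total": rep.observed.total_occurrences,
                    "observed_peaks_with_motif": rep.observed.peaks_with_motif,
                    "null_total_mean": rep.null.total_counts.mean(),
                    "null_total_var": rep.null.total_counts.var(ddof=1),
                    "nb_size_total": rep.null.total_fit.size,
                    "poisson_fallback_total": rep.null.total_fit.poisson_fallback,
                    "p_total": rep.p_total,
                    "p_peaks_with_motif": rep.p_peaks_with_motif,
                }
            ]
        ).to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)

    if "overlap" in result.integration:
        ov = result.integration["overlap"]
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "n_up_genes": ov.n_a,
                    "n_peak_genes": ov.n_b,
                    "n_overlap": ov.n_intersection,
                    "universe": ov.universe,
                    "expected": ov.expected,
                    "hypergeom_p": ov.hypergeom_p,
                }
            ]
        ).to_csv(out / "de_peak_overlap.tsv", sep="\t", index=False)
    for key in ("fold_change", "absolute_change"):
        curve = result.integration.get(f"curve_{key}")
        if curve is not None:
            integ.association_to_frame(curve).to_csv(
                out / f"association_curve_{key}.tsv", sep="\t", index=False
            )
    classes = result.integration.get("infection_classes")
    if classes is not None:
        import pandas as pd

        df = pk.peaks_to_frame(result.control.filtered)
        df["infection_class"] = classes
        df.to_csv(out / "infection_response.tsv", sep="\t", index=False)

    manifest = {
        "package": "damidkit",
        "parameters": dataclasses.asdict(cfg),
        "stage_seeds": {"motif": _stage_seed(cfg.seed, "motif")},
        "inputs": {
            name: {"path": getattr(cfg, name), "sha256": _sha256(getattr(cfg, name))}
            for name in (
                "reads_dam_control",
                "reads_fusion_control",
                "reads_dam_infected",
                "reads_fusion_infected",
                "chrom_sizes",
                "gff",
                "fasta",
                "de_table",
            )
            if getattr(cfg, name) and Path(getattr(cfg, name)).exists()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
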