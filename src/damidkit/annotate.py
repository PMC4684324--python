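"""Stage 4 — peak-to-gene annotation and the summit-to-TSS distance profile.

Two complementary annotations are produced: (i) each peak is assigned the
gene whose TSS is closest to the peak summit, with a signed, orientation-
aware distance (negative = upstream/5' of the TSS); (ii) each peak lists
every gene whose body overlaps it by at least one bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GeneModel
from .peaks import PeakCall

DEFAULT_TSS_WINDOW = 5000


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: PeakCall
    nearest_gene: str | None
    tss_distance: int | None  # signed; negative = 5' of the TSS in gene orientation
    overlapping_genes: tuple[str, ...] = ()


def nearest_tss_annotation(peaks: list[PeakCall], genes: list[GeneModel]) -> list[AnnotatedPeak]:
    """Assign each peak the same-chromosome gene minimizing |summit - TSS|.

    Distance is signed in the gene's orientation: (summit - TSS) for '+'
    genes and (TSS - summit) for '-' genes, so negative always means the
    summit lies 5' (upstream) of the TSS. Ties break on lexicographic gene
    id; peaks on gene-less chromosomes are annotated as missing.
    """
    if not genes:
        raise ValueError("gene list is empty")
    by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom in {g.chrom for g in genes}:
        sub = sorted(
            (g for g in genes if g.chrom == chrom), key=lambda g: (g.tss, g.gene_id)
        )
        by_chrom[chrom] = (np.array([g.tss for g in sub], dtype=np.int64), sub)

    out: list[AnnotatedPeak] = []
    for peak in peaks:
        if peak.summit is None:
            raise ValueError(f"peak {peak.name} has no summit; summarize peaks first")
        if peak.chrom not in by_chrom:
            out.append(AnnotatedPeak(peak, None, None))
            continue
        tss_arr, sub = by_chrom[peak.chrom]
        dist = np.abs(tss_arr - peak.summit)
        ties = np.flatnonzero(dist == dist.min())
        gene = min((sub[j] for j in ties), key=lambda g: g.gene_id)
        raw = peak.summit - gene.tss
        signed = raw if gene.strand == "+" else -raw
        out.append(AnnotatedPeak(peak, gene.gene_id, int(signed)))
    return out


def overlap_annotation(peaks: list[PeakCall], genes: list[GeneModel]) -> list[tuple[str, ...]]:
    """Per-peak tuple of gene ids whose interval shares >= 1 bp with the peak."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    out: list[tuple[str, ...]] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        hits = sorted(iv.data for iv in tree.overlap(p.start, p.end)) if tree else []
        out.append(tuple(hits))
    return out


def annotate_peaks(peaks: list[PeakCall], genes: list[GeneModel]) -> list[AnnotatedPeak]:
    """Both annotation approaches combined into one record per peak."""
    nearest = nearest_tss_annotation(peaks, genes)
    overlaps = overlap_annotation(peaks, genes)
    return [
        AnnotatedPeak(a.peak, a.nearest_gene, a.tss_distance, ov)
        for a, ov in zip(nearest, overlaps)
    ]


def peak_associated_genes(
    annotated: list[AnnotatedPeak], tss_window: int = DEFAULT_TSS_WINDOW
) -> set[str]:
    """Gene set used for transcriptome integration: overlap-annotated genes
    plus nearest-TSS genes whose summit lies within ``tss_window`` bp of the
    TSS."""
    genes: set[str] = set()
    for a in annotated:
        genes.update(a.overlapping_genes)
        if a.nearest_gene is not None and a.tss_distance is not None:
            if abs(a.tss_distance) <= tss_window:
                genes.add(a.nearest_gene)
    return genes


def tss_distance_profile(
    annotated: list[AnnotatedPeak],
    bin_width: int = 100,
    max_distance: int = 5000,
) -> pd.DataFrame:
    """Histogram of signed summit-TSS distances.

    Bins of ``bin_width`` bp tile [-max_distance, max_distance); distances
    beyond the range are pooled into the two edge bins.
    """
    edges = np.arange(-max_distance, max_distance + bin_width, bin_width)
    dists = np.array(
        [a.tss_distance for a in annotated if a.tss_distance is not None], dtype=float
    )
    if len(dists):
        clipped = np.clip(dists, -max_distance, max_distance - 1)
        counts, _ = np.histogram(clipped, bins=edges)
    else:
        counts = np.zeros(len(edges) - 1, dtype=int)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts.astype(int)}
    )


def profile_mode(profile: pd.DataFrame) -> int:
    """Midpoint of the most populated histogram bin (leftmost on ties)."""
    i = int(profile["count"].to_numpy().argmax())
    return int((profile["bin_start"].iloc[i] + profile["bin_end"].iloc[i]) // 2)


def annotated_to_frame(annotated: list[AnnotatedPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                a.peak.chrom,
                a.peak.start,
                a.peak.end,
                a.peak.summit,
                a.peak.log2fc,
                a.peak.fdr,
                a.nearest_gene,
                a.tss_distance,
                ",".join(a.overlapping_genes),
            )
            for a in annotated
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "summit",
            "log2fc",
            "fdr",
            "nearest_gene",
            "tss_distance",
            "overlapping_genes",
        ],
    )
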