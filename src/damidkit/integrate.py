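"""Stage 6 — crossing DamID binding with differential expression.

Three views: (i) the overlap between significantly up-regulated genes and
peak-associated genes; (ii) classification of control-condition peaks by
their behaviour in the infected condition (reduced / retained / lost);
(iii) a moving-sum association curve — genes ranked by fold change or by
absolute expression change, with a sliding count of peak-bearing genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import WindowCountTrack
from .peaks import PeakCall

DE_COLUMNS = ["gene_id", "log2fc", "padj", "mean_treatment", "mean_background"]
DEFAULT_MOVING_WINDOW = 500


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: differential-expression table lacks column(s): {', '.join(sorted(missing))}")
    bad = ~df["padj"].between(0, 1)
    if bad.any():
        raise ValueError(f"{path}: adjusted p-values outside [0, 1]")
    return df


def absolute_change(table: pd.DataFrame) -> pd.Series:
    """Treatment minus background mean expression."""
    return table["mean_treatment"] - table["mean_background"]


def select_deregulated_genes(
    table: pd.DataFrame,
    min_fold_change: float = 1.5,
    max_padj: float = 0.1,
    direction: str = "up",
) -> set[str]:
    """Genes beyond a fold-change and adjusted-p cutoff (strict inequalities)."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    lfc_cut = np.log2(min_fold_change)
    if direction == "up":
        mask = (table["log2fc"] > lfc_cut) & (table["padj"] < max_padj)
    else:
        mask = (table["log2fc"] < -lfc_cut) & (table["padj"] < max_padj)
    return set(table.loc[mask, "gene_id"])


@dataclass(frozen=True)
class OverlapCounts:
    n_a: int
    n_b: int
    n_intersection: int
    universe: int

    @property
    def expected(self) -> float:
        """Intersection size expected under independence."""
        return self.n_a * self.n_b / self.universe if self.universe else float("nan")

    @property
    def hypergeom_p(self) -> float:
        """One-sided enrichment p for the observed intersection."""
        return float(
            stats.hypergeom.sf(self.n_intersection - 1, self.universe, self.n_a, self.n_b)
        )


def intersect_targets(de_genes: set[str], peak_genes: set[str], universe: int) -> OverlapCounts:
    return OverlapCounts(
        n_a=len(de_genes),
        n_b=len(peak_genes),
        n_intersection=len(de_genes & peak_genes),
        universe=universe,
    )


def classify_infection_response(
    control_peaks: list[PeakCall],
    infected_peaks: list[PeakCall],
    infected_treatment: WindowCountTrack,
    infected_background: WindowCountTrack,
    infected_factor: float,
    pseudocount: float = 1.0,
    max_fold: float = 2.0,
) -> list[str]:
    """Per control peak: 'lost' when no infected peak overlaps it; otherwise
    'reduced' when its fold change recomputed from the infected sample over
    the same windows drops below ``max_fold``; else 'retained'."""
    if not infected_treatment.grid.same_grid(infected_background.grid):
        raise ValueError("infected treatment and background tracks are on different grids")
    n_win = infected_treatment.grid.n_windows
    if any(p.first_window + p.n_windows > n_win for p in control_peaks):
        raise ValueError("control peaks index beyond the infected grid; grids must match")
    log2_cut = np.log2(max_fold)
    classes: list[str] = []
    for p in control_peaks:
        sl = slice(p.first_window, p.first_window + p.n_windows)
        t_sum = float(infected_treatment.counts[sl].sum())
        b_sum = float(infected_background.counts[sl].sum())
        lfc = float(np.log2(infected_factor * t_sum + pseudocount) - np.log2(b_sum + pseudocount))
        overlapping = any(
            q.chrom == p.chrom and q.start < p.end and p.start < q.end for q in infected_peaks
        )
        if not overlapping:
            classes.append("lost")
        elif lfc < log2_cut:
            classes.append("reduced")
        else:
            classes.append("retained")
    return classes


@dataclass(frozen=True)
class AssociationCurve:
    """Moving sum of the peak-bearing flag along a ranked gene list."""

    key: str
    window: int
    ranked_genes: tuple[str, ...]
    flags: np.ndarray
    values: np.ndarray

    @property
    def first_decile_mean(self) -> float:
        k = max(1, len(self.values) // 10)
        return float(self.values[:k].mean())

    @property
    def last_decile_mean(self) -> float:
        k = max(1, len(self.values) // 10)
        return float(self.values[-k:].mean())


def moving_sum_association(
    table: pd.DataFrame,
    peak_genes: set[str],
    key: str = "fold_change",
    window: int = DEFAULT_MOVING_WINDOW,
) -> AssociationCurve:
    """Rank genes (descending) by ``key`` and slide a window-of-500 sum of
    the has-binding-site flag along the ranking.

    ``key`` is 'fold_change' (log2 fold change) or 'absolute_change'
    (treatment mean minus background mean). Ties rank by gene id.
    """
    if key == "fold_change":
        keyvals = table["log2fc"]
    elif key == "absolute_change":
        keyvals = absolute_change(table)
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    n = len(table)
    if n < window:
        raise ValueError(f"need at least {window} genes, got {n}")
    order = (
        pd.DataFrame({"gene_id": table["gene_id"], "_key": keyvals})
        .sort_values(["_key", "gene_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    flags = order["gene_id"].isin(peak_genes).to_numpy(dtype=np.int64)
    values = np.convolve(flags, np.ones(window, dtype=np.int64), mode="valid")
    return AssociationCurve(
        key=key,
        window=window,
        ranked_genes=tuple(order["gene_id"]),
        flags=flags,
        values=values,
    )


def association_to_frame(curve: AssociationCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(curve.values) + 1),
            "lead_gene": curve.ranked_genes[: len(curve.values)],
            "moving_sum": curve.values,
        }
    )
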