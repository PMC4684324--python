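"""Stage 2 — normalization, per-window log2 ratios and the normal null.

The fusion (treatment) track is scaled so the mean log ratio to the Dam-only
(background) track is zero over eligible windows, per-window values
log2((f*t + c)/(b + c)) are computed with pseudocount c, a normal
distribution is fitted to the eligible values, and each window receives a
one-sided upper-tail enrichment p-value from that fit.

Eligibility (both raw counts >= 1) governs normalization and fitting;
windows with a zero count on either side otherwise dominate the fitted
spread without carrying ratio information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import WindowCountTrack, WindowGrid

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_N_FLOOR = 100


class DegenerateFitError(ValueError):
    """Raised when the log-ratio values carry no spread to fit."""


@dataclass(frozen=True)
class NormalFit:
    """Normal null for per-window log2 ratios (sample mean / sd, ddof=1)."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise DegenerateFitError(f"sigma must be positive and finite, got {self.sigma}")


@dataclass
class LogRatioTrack:
    """Normalized per-window log2(treatment/background) with its normal null."""

    grid: WindowGrid
    factor: float
    values: np.ndarray
    eligible: np.ndarray
    pvalues: np.ndarray | None = None
    fit: NormalFit | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.eligible = np.asarray(self.eligible, dtype=bool)
        n = self.grid.n_windows
        if self.values.shape != (n,) or self.eligible.shape != (n,):
            raise ValueError("track arrays must match the grid length")
        if not np.isfinite(self.values[self.eligible]).all():
            raise ValueError("eligible windows must carry finite values")

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["value"] = self.values
        df["eligible"] = self.eligible
        df["p"] = self.pvalues if self.pvalues is not None else np.nan
        return df


def _check_same_grid(treatment: WindowCountTrack, background: WindowCountTrack) -> None:
    if not treatment.grid.same_grid(background.grid):
        raise ValueError("treatment and background tracks are on different grids")


def eligibility_mask(
    treatment: WindowCountTrack, background: WindowCountTrack, min_count: int = 1
) -> np.ndarray:
    return (treatment.counts >= min_count) & (background.counts >= min_count)


def compute_normalization_factor(
    treatment: WindowCountTrack,
    background: WindowCountTrack,
    n_floor: int = DEFAULT_N_FLOOR,
    target: float = 0.0,
) -> float:
    """Scaling factor f with mean_eligible log2(f*t/b) equal to ``target``.

    ``target`` defaults to 0 (mean ratio of one). In closed form
    log2 f = target - mean(log2(t/b)) over eligible windows.
    """
    _check_same_grid(treatment, background)
    mask = eligibility_mask(treatment, background)
    n = int(mask.sum())
    if n < n_floor:
        raise ValueError(f"only {n} eligible windows (< floor {n_floor}); cannot normalize")
    log_ratio = np.log2(treatment.counts[mask]) - np.log2(background.counts[mask])
    return float(2.0 ** (target - log_ratio.mean()))


def compute_log_ratio(
    treatment: WindowCountTrack,
    background: WindowCountTrack,
    factor: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> LogRatioTrack:
    """Per-window value log2((f*t + c)/(b + c)); pseudocount c bounds sparse windows."""
    _check_same_grid(treatment, background)
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    t = treatment.counts.astype(float)
    b = background.counts.astype(float)
    values = np.log2(factor * t + pseudocount) - np.log2(b + pseudocount)
    return LogRatioTrack(
        grid=treatment.grid,
        factor=float(factor),
        values=values,
        eligible=eligibility_mask(treatment, background),
    )


def fit_normal(track: LogRatioTrack, n_floor: int = DEFAULT_N_FLOOR) -> NormalFit:
    """Fit the normal null to eligible window values (sample mean, sd with ddof=1)."""
    vals = track.values[track.eligible]
    if len(vals) < n_floor:
        raise ValueError(f"only {len(vals)} eligible windows (< floor {n_floor}); cannot fit")
    sigma = float(vals.std(ddof=1))
    if sigma == 0:
        raise DegenerateFitError("log-ratio values are constant; normal fit is degenerate")
    return NormalFit(mu=float(vals.mean()), sigma=sigma, n=len(vals))


def window_pvalues(track: LogRatioTrack, fit: NormalFit) -> LogRatioTrack:
    """One-sided upper-tail p per window; ineligible windows get p = 1."""
    z = (track.values - fit.mu) / fit.sigma
    p = stats.norm.sf(z)
    p = np.where(track.eligible, p, 1.0)
    track.pvalues = np.clip(p, np.nextafter(0, 1), 1.0)
    track.fit = fit
    return track


def score_tracks(
    treatment: WindowCountTrack,
    background: WindowCountTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    n_floor: int = DEFAULT_N_FLOOR,
    normalization_target: float = 0.0,
) -> LogRatioTrack:
    """Full stage-2 pass: normalize, log-ratio, normal fit, p-values."""
    factor = compute_normalization_factor(
        treatment, background, n_floor=n_floor, target=normalization_target
    )
    track = compute_log_ratio(treatment, background, factor, pseudocount=pseudocount)
    fit = fit_normal(track, n_floor=n_floor)
    return window_pvalues(track, fit)
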