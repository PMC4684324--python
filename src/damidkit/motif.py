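"""Stage 5 — Capicua octamer scanning and the peak-relocation null.

The HMG-box motif TGAATG[AG]A is searched inside peak sequences; the same
peaks are relocated uniformly at random in the genome many times, the motif
counts of the relocated sets are fitted to a negative binomial, and the
observed counts receive an upper-tail p-value under that fit. Counts are
overdispersed across relocations (sites differ in composition), hence the
negative binomial rather than a Poisson; when the null counts show no
overdispersion the fit falls back to a Poisson and says so.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .genome import Genome, Interval

DEFAULT_PATTERN = "TGAATG[AG]A"
DEFAULT_RELOCATIONS = 1000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _compile(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all counted
    return re.compile(f"(?=({pattern}))")


def scan_sequence(seq: str, pattern: str = DEFAULT_PATTERN, strand_mode: str = "both") -> list[int]:
    """Start positions (forward coordinates) of motif matches in one sequence.

    In ``both`` mode the reverse strand is searched by matching the reverse
    complement of the pattern on the forward sequence; positions of such
    hits are reported in forward coordinates. 'N' never matches.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand mode {strand_mode!r}")
    seq = seq.upper()
    hits = [m.start() for m in _compile(pattern).finditer(seq)]
    if strand_mode == "both":
        # literal-with-one-class patterns reverse-complement cleanly
        rc = _rc_pattern(pattern)
        hits.extend(m.start() for m in _compile(rc).finditer(seq))
    return sorted(hits)


def _rc_pattern(pattern: str) -> str:
    tokens: list[str] = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            tokens.append(pattern[i + 1 : j])
            i = j + 1
        else:
            tokens.append(pattern[i])
            i += 1
    out: list[str] = []
    for tok in reversed(tokens):
        comp = "".join(sorted(c.translate(_COMPLEMENT) for c in tok))
        out.append(comp if len(comp) == 1 else f"[{comp}]")
    return "".join(out)


@dataclass(frozen=True)
class MotifScanResult:
    total_occurrences: int
    peaks_with_motif: int
    n_peaks: int
    positions: tuple[tuple[int, ...], ...]  # per peak, genomic start coordinates


def scan_peaks(
    peaks: Sequence[Interval],
    genome: Genome,
    pattern: str = DEFAULT_PATTERN,
    strand_mode: str = "both",
) -> MotifScanResult:
    """Count motif occurrences inside each peak interval of a sequenced genome."""
    per_peak: list[tuple[int, ...]] = []
    total = 0
    with_motif = 0
    for p in peaks:
        seq = genome.sequence(p.chrom)[p.start : p.end]
        hits = scan_sequence(seq, pattern, strand_mode)
        per_peak.append(tuple(p.start + h for h in hits))
        total += len(hits)
        with_motif += bool(hits)
    return MotifScanResult(total, with_motif, len(peaks), tuple(per_peak))


def relocate_peaks(
    peaks: Sequence[Interval],
    genome: Genome,
    n_relocations: int = DEFAULT_RELOCATIONS,
    seed: int | np.random.Generator = 0,
) -> Iterable[list[Interval]]:
    """Yield ``n_relocations`` randomized peak sets.

    Every peak keeps its length and chromosome; its start is redrawn
    uniformly from [0, chrom_length - peak_length]. Relocated peaks may
    overlap each other and any annotation — no exclusion mask.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.array([len(p) for p in peaks], dtype=np.int64)
    chrom_lens = np.array([genome.length(p.chrom) for p in peaks], dtype=np.int64)
    if (lengths > chrom_lens).any():
        bad = int(np.flatnonzero(lengths > chrom_lens)[0])
        raise ValueError(
            f"peak {peaks[bad].chrom}:{peaks[bad].start}-{peaks[bad].end} is longer "
            "than its chromosome"
        )

    def generate():
        for _ in range(n_relocations):
            starts = rng.integers(0, chrom_lens - lengths + 1)
            yield [
                Interval(p.chrom, int(s), int(s + ln))
                for p, s, ln in zip(peaks, starts, lengths)
            ]

    return generate()


@dataclass(frozen=True)
class CountDistributionFit:
    """Negative-binomial (size, mean) fit to null counts, or Poisson fallback."""

    size: float | None
    mean: float
    poisson_fallback: bool
    n: int

    def sf(self, k: int) -> float:
        """P(X > k) under the fitted distribution."""
        if self.poisson_fallback:
            return float(stats.poisson.sf(k, self.mean))
        p = self.size / (self.size + self.mean)
        return float(stats.nbinom.sf(k, self.size, p))


def fit_negative_binomial(counts: Sequence[int]) -> CountDistributionFit:
    """Maximum-likelihood negative binomial fit parameterized by (size, mean).

    The MLE of the mean is the sample mean; the size parameter is profiled
    by a one-dimensional likelihood maximization. Underdispersed samples
    (variance <= mean) admit no finite size MLE and fall back to a Poisson
    with the same mean, flagged as such.
    """
    x = np.asarray(counts, dtype=np.int64)
    if len(x) < 2 or (x == x[0]).all():
        raise ValueError("need at least two distinct count values to fit a distribution")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if var <= mean:
        return CountDistributionFit(size=None, mean=mean, poisson_fallback=True, n=len(x))

    def nll(log_size: float) -> float:
        r = np.exp(log_size)
        p = r / (r + mean)
        return -float(stats.nbinom.logpmf(x, r, p).sum())

    # moment estimate as bracket center: var = m + m^2/r
    r0 = mean**2 / (var - mean)
    res = optimize.minimize_scalar(
        nll, bounds=(np.log(r0) - 8, np.log(r0) + 8), method="bounded"
    )
    return CountDistributionFit(size=float(np.exp(res.x)), mean=mean, poisson_fallback=False, n=len(x))


@dataclass(frozen=True)
class NullCountDistribution:
    """Relocation-null motif counts with their fitted distributions."""

    total_counts: np.ndarray
    peaks_with_motif_counts: np.ndarray
    total_fit: CountDistributionFit
    peaks_fit: CountDistributionFit
    n_relocations: int
    seed: int


def build_relocation_null(
    peaks: Sequence[Interval],
    genome: Genome,
    pattern: str = DEFAULT_PATTERN,
    strand_mode: str = "both",
    n_relocations: int = DEFAULT_RELOCATIONS,
    seed: int = 0,
) -> NullCountDistribution:
    totals = np.empty(n_relocations, dtype=np.int64)
    withs = np.empty(n_relocations, dtype=np.int64)
    for i, relocated in enumerate(
        relocate_peaks(peaks, genome, n_relocations=n_relocations, seed=seed)
    ):
        res = scan_peaks(relocated, genome, pattern, strand_mode)
        totals[i] = res.total_occurrences
        withs[i] = res.peaks_with_motif
    return NullCountDistribution(
        total_counts=totals,
        peaks_with_motif_counts=withs,
        total_fit=fit_negative_binomial(totals),
        peaks_fit=fit_negative_binomial(withs),
        n_relocations=n_relocations,
        seed=seed,
    )


def motif_enrichment_pvalue(observed: int, fit: CountDistributionFit) -> float:
    """Upper-tail p = P(X >= observed) under the fitted null distribution."""
    if observed <= 0:
        return 1.0
    return min(1.0, fit.sf(observed - 1))


@dataclass(frozen=True)
class MotifEnrichmentReport:
    pattern: str
    strand_mode: str
    observed: MotifScanResult
    null: NullCountDistribution
    p_total: float
    p_peaks_with_motif: float


def motif_enrichment(
    peaks: Sequence[Interval],
    genome: Genome,
    pattern: str = DEFAULT_PATTERN,
    strand_mode: str = "both",
    n_relocations: int = DEFAULT_RELOCATIONS,
    seed: int = 0,
) -> MotifEnrichmentReport:
    """Full stage-5 pass: scan, relocate, fit, p-values for both statistics."""
    observed = scan_peaks(peaks, genome, pattern, strand_mode)
    null = build_relocation_null(
        peaks, genome, pattern, strand_mode, n_relocations=n_relocations, seed=seed
    )
    return MotifEnrichmentReport(
        pattern=pattern,
        strand_mode=strand_mode,
        observed=observed,
        null=null,
        p_total=motif_enrichment_pvalue(observed.total_occurrences, null.total_fit),
        p_peaks_with_motif=motif_enrichment_pvalue(observed.peaks_with_motif, null.peaks_fit),
    )
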