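"""Shared genomic data model: chromosomes, intervals, reads, genes, window grids.

Every in-memory coordinate is 0-based half-open (BED convention). GFF3
conversion on read is the only place 1-based arithmetic happens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeIndex",
    "Genome",
    "Interval",
    "ReadAlignment",
    "GeneModel",
    "WindowGrid",
    "WindowCountTrack",
]


@dataclass(frozen=True)
class GenomeIndex:
    """One chromosome: a name, a length in bp and (optionally) its sequence."""

    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"chromosome {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


class Genome:
    """Ordered collection of chromosomes with unique names."""

    def __init__(self, chromosomes: Sequence[GenomeIndex]):
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {', '.join(dup)}")
        self._chroms: dict[str, GenomeIndex] = {c.name: c for c in chromosomes}

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __getitem__(self, name: str) -> GenomeIndex:
        return self._chroms[name]

    def __iter__(self) -> Iterator[GenomeIndex]:
        return iter(self._chroms.values())

    def __len__(self) -> int:
        return len(self._chroms)

    def length(self, name: str) -> int:
        return self._chroms[name].length

    def lengths(self) -> Mapping[str, int]:
        return {c.name: c.length for c in self}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self)

    def sequence(self, name: str) -> str:
        seq = self._chroms[name].sequence
        if seq is None:
            raise ValueError(f"chromosome {name!r} carries no sequence")
        return seq

    def with_sequences(self, sequences: Mapping[str, str]) -> "Genome":
        return Genome(
            [GenomeIndex(c.name, c.length, sequences.get(c.name, c.sequence)) for c in self]
        )


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ReadAlignment:
    """A single-end aligned read; only uniquely-mapped reads enter quantification."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."
    unique: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid read interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.name!r}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its strand-dependent transcription start site.

    The TSS is a base, not a boundary: first base of the interval on '+',
    last base (end - 1 in half-open coordinates) on '-'.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: invalid interval {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)


class WindowGrid:
    """Fixed-width tiling of a genome (last window per chromosome may be shorter).

    Windows are addressed by a flat global index running chromosome by
    chromosome in genome order; per-chromosome slices map back to coordinates.
    """

    def __init__(self, genome: Genome, width: int = 75):
        if width <= 0:
            raise ValueError(f"window width must be > 0, got {width}")
        self.genome = genome
        self.width = int(width)
        self._chrom_names = genome.names
        counts = np.array(
            [-(-genome.length(n) // self.width) for n in self._chrom_names], dtype=np.int64
        )
        self._n_windows = counts
        self._offsets = np.concatenate([[0], np.cumsum(counts)])

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chrom_names)

    @property
    def n_windows(self) -> int:
        return int(self._offsets[-1])

    def __len__(self) -> int:
        return self.n_windows

    def n_windows_of(self, chrom: str) -> int:
        return int(self._n_windows[self._chrom_names.index(chrom)])

    def chrom_slice(self, chrom: str) -> slice:
        i = self._chrom_names.index(chrom)
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    def window_bounds(self, index: int) -> tuple[str, int, int]:
        """Global window index -> (chrom, start, end)."""
        if not 0 <= index < self.n_windows:
            raise IndexError(f"window index {index} out of range")
        ci = int(np.searchsorted(self._offsets, index, side="right")) - 1
        chrom = self._chrom_names[ci]
        local = index - int(self._offsets[ci])
        start = local * self.width
        end = min(start + self.width, self.genome.length(chrom))
        return chrom, start, end

    def starts(self, chrom: str) -> np.ndarray:
        n = self.n_windows_of(chrom)
        return np.arange(n, dtype=np.int64) * self.width

    def ends(self, chrom: str) -> np.ndarray:
        return np.minimum(self.starts(chrom) + self.width, self.genome.length(chrom))

    def widths(self) -> np.ndarray:
        out = np.full(self.n_windows, self.width, dtype=np.int64)
        for name in self._chrom_names:
            sl = self.chrom_slice(name)
            rem = self.genome.length(name) - (self._n_windows[self._chrom_names.index(name)] - 1) * self.width
            out[sl.stop - 1] = rem
        return out

    def iter_windows(self) -> Iterator[tuple[str, int, int]]:
        for name in self._chrom_names:
            length = self.genome.length(name)
            for s in range(0, length, self.width):
                yield name, s, min(s + self.width, length)

    def to_frame(self):
        import pandas as pd

        rows = list(self.iter_windows())
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def same_grid(self, other: "WindowGrid") -> bool:
        return (
            self.width == other.width
            and self._chrom_names == other._chrom_names
            and self.genome.lengths() == other.genome.lengths()
        )


@dataclass
class WindowCountTrack:
    """Per-window read counts for one sample on one grid."""

    grid: WindowGrid
    counts: np.ndarray
    total_reads: int = 0
    assigned_reads: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.grid.n_windows,):
            raise ValueError(
                f"counts length {self.counts.shape} does not match grid "
                f"({self.grid.n_windows} windows)"
            )
        if (self.counts < 0).any():
            raise ValueError("window counts must be non-negative")
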