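"""Readers and writers for the external formats the pipeline touches.

BED6 is the canonical read input; a minimal SAM reader (single-end,
flag-derived strand, MAPQ-based uniqueness) is provided for convenience.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import Genome, GenomeIndex, GeneModel, ReadAlignment

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def read_chrom_sizes(path: str | os.PathLike) -> Genome:
    """Read a two-column TSV (chromosome name, length) into a :class:`Genome`."""
    chroms: list[GenomeIndex] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            name, raw_len = fields
            try:
                length = int(raw_len)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: length {raw_len!r} is not an integer") from None
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: chromosome {name!r} has non-positive length {length}")
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome name {name!r}")
            seen.add(name)
            chroms.append(GenomeIndex(name, length))
    return Genome(chroms)


def write_chrom_sizes(genome: Genome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f"{chrom.name}\t{chrom.length}\n")


def read_bed_frame(path: str | os.PathLike, genome: Genome | None = None) -> pd.DataFrame:
    """Read a BED6 file into a validated DataFrame (the fast path for counting)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BED6_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str, "strand": str},
        comment="#",
    )
    if df.empty:
        return df
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(bad.idxmax())
        raise ParseError(f"{path}: record {i + 1}: start >= end ({df.start[i]} >= {df.end[i]})")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        i = int(bad_strand.idxmax())
        raise ParseError(f"{path}: record {i + 1}: read strand must be '+' or '-', got {df.strand[i]!r}")
    if genome is not None:
        unknown = set(df["chrom"]) - set(genome.names)
        if unknown:
            raise ParseError(f"{path}: unknown chromosome(s): {', '.join(sorted(unknown))}")
        lengths = df["chrom"].map(genome.lengths())
        over = df["end"] > lengths
        if over.any():
            i = int(over.idxmax())
            raise ParseError(f"{path}: record {i + 1}: interval end {df.end[i]} beyond chromosome end")
    return df


def read_bed_reads(path: str | os.PathLike, genome: Genome | None = None) -> list[ReadAlignment]:
    """Read BED6 alignments into :class:`ReadAlignment` records, preserving file order."""
    df = read_bed_frame(path, genome)
    return [
        ReadAlignment(chrom=r.chrom, start=int(r.start), end=int(r.end), strand=r.strand, name=r.name)
        for r in df.itertuples(index=False)
    ]


def write_bed_frame(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


def read_sam_reads(
    path: str | os.PathLike,
    genome: Genome | None = None,
    min_mapq: int = 1,
) -> list[ReadAlignment]:
    """Minimal SAM reader: single-end records, strand from the flag.

    A read is treated as uniquely mapped when MAPQ >= ``min_mapq`` (a proxy;
    aligner-specific uniqueness tags are out of scope). Unmapped, secondary
    and supplementary records are dropped.
    """
    import pysam

    reads: list[ReadAlignment] = []
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            unique = rec.mapping_quality >= min_mapq
            if not unique:
                continue
            chrom = rec.reference_name
            if genome is not None and chrom not in genome:
                raise ParseError(f"{path}: read {rec.query_name!r} on unknown chromosome {chrom!r}")
            reads.append(
                ReadAlignment(
                    chrom=chrom,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    name=rec.query_name,
                )
            )
    return reads


def read_gff_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene features from GFF3 into :class:`GeneModel` records.

    GFF3 is 1-based inclusive; this is the single place the package converts
    to the internal 0-based half-open convention. Non-gene rows are skipped.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [None])[0]
        if gene_id is None:
            raise ParseError(f"{path}: gene at {feat.seqid}:{feat.start}-{feat.end} lacks an ID attribute")
        if gene_id in seen:
            raise ParseError(f"{path}: duplicate gene ID {gene_id!r}")
        seen.add(gene_id)
        if feat.strand not in ("+", "-"):
            raise ParseError(f"{path}: gene {gene_id!r} has unknown strand {feat.strand!r}")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tdamidkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into name -> uppercase sequence."""
    from pyfaidx import Fasta

    with Fasta(os.fspath(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_bedgraph(track, path: str | os.PathLike, name: str = "log2_ratio") -> None:
    """Serialize a per-window value track (e.g. log2 fusion/Dam-only) as bedGraph."""
    values = np.asarray(track.values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for i, (chrom, start, end) in enumerate(track.grid.iter_windows()):
            fh.write(f"{chrom}\t{start}\t{end}\t{values[i]:.6f}\n")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        skiprows=1,
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
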