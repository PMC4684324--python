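"""Synthetic DamID-Seq + RNA-Seq data with planted ground truth.

The generator emulates the statistical structure the pipeline assumes: a
random genome with non-overlapping genes on both strands, binding sites
planted around 500 bp 5' of the TSS of a subset of genes, Capicua octamer
motifs written into a fraction of the sites, overdispersed (negative
binomial) window counts with fusion-sample enrichment at the sites, an
infected condition in which binding at a subset of sites is attenuated,
and a differential-expression table in which site-bearing genes are
preferentially up-regulated.

Counts are generated per 75-bp window and then materialized as 50-bp
single-end reads placed inside the window, so the planted truth is exact
at the unit the downstream statistics operate on.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, Genome, GenomeIndex, Interval, WindowGrid
from . import io as gio

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic dataset; every artifact is a pure function
    of this object (same seed, same bytes)."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000)
    n_genes: int = 400
    n_sites: int = 100
    site_width: int = 600
    offset_mean: float = -500.0  # site center relative to TSS, gene orientation
    offset_sd: float = 200.0
    enrichment_log2fc: float = 4.0
    motif_plant_prob: float = 0.3
    depth: float = 20.0  # expected Dam-only reads generated per window
    nb_size: float | None = 20.0  # NB size parameter; None = Poisson counts
    attenuated_fraction: float = 0.5
    attenuation_factor: float = 0.2
    de_peak_mean: float = 1.2
    de_peak_sd: float = 0.5
    de_null_sd: float = 0.3
    gene_length_range: tuple[int, int] = (1000, 3000)
    window: int = 75
    read_length: int = 50
    motif: str = "TGAATGRA"  # R = A or G, written at plant time

    def __post_init__(self) -> None:
        for name in ("motif_plant_prob", "attenuated_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("site_width", "depth", "window", "read_length", "n_genes", "n_sites"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.site_width <= 0 or self.depth <= 0:
            raise ValueError("site_width and depth must be > 0")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if self.nb_size is not None and self.nb_size <= 0:
            raise ValueError("nb_size must be > 0 (or None for Poisson)")


@dataclass(frozen=True)
class TruthSite:
    """A planted binding site and everything recovery tests need to know."""

    chrom: str
    start: int
    end: int
    gene_id: str
    attenuated: bool
    motif_positions: tuple[int, ...] = ()

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: Genome  # carries sequences
    genes: list[GeneModel]
    truth: list[TruthSite]
    reads: dict[str, pd.DataFrame]  # dam/fusion x control/infected BED6 frames
    de_table: pd.DataFrame


def _child_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


_RNG_NAMES = [
    "genome",
    "sites",
    "reads_dam_control",
    "reads_fusion_control",
    "reads_dam_infected",
    "reads_fusion_infected",
    "expression",
]


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Genome, list[GeneModel]]:
    """Uniform-random genome plus non-overlapping genes on both strands.

    Genes are laid out one per equal-width slot so they can never overlap;
    a 5 kb margin at each chromosome end leaves room for upstream sites.
    """
    margin = 5000
    lengths = list(config.chrom_lengths)
    total = sum(lengths)
    chroms: list[GenomeIndex] = []
    sequences: dict[str, str] = {}
    for i, length in enumerate(lengths):
        name = f"chr{i + 1}"
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        chroms.append(GenomeIndex(name, length, seq))
        sequences[name] = seq
    genome = Genome(chroms)

    # apportion genes to chromosomes by length (largest remainder)
    quotas = np.array([config.n_genes * l / total for l in lengths])
    counts = np.floor(quotas).astype(int)
    rem = config.n_genes - counts.sum()
    for j in np.argsort(-(quotas - counts))[:rem]:
        counts[j] += 1

    gene_min, gene_max = config.gene_length_range
    genes: list[GeneModel] = []
    gene_no = 0
    for (chrom, length), k in zip(zip(genome.names, lengths), counts):
        if k == 0:
            continue
        usable = length - 2 * margin
        slot = usable // k
        if slot < gene_max + 1:
            raise ValueError(
                f"cannot place {k} non-overlapping genes on {chrom} "
                f"({length} bp); use longer chromosomes or fewer genes"
            )
        for s in range(k):
            glen = int(rng.integers(gene_min, gene_max + 1))
            lo = margin + s * slot
            start = int(rng.integers(lo, lo + slot - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            genes.append(GeneModel(f"gene{gene_no:05d}", chrom, start, start + glen, strand))
    return genome, genes


def _write_motif(seq: bytearray, pos: int, rng: np.random.Generator) -> None:
    instance = b"TGAATG" + (b"A" if rng.random() < 0.5 else b"G") + b"A"
    seq[pos : pos + 8] = instance


def plant_binding_sites(
    genome: Genome,
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[TruthSite], Genome]:
    """Plant one site per selected gene near its TSS; optionally write
    Capicua octamers into the site sequence.

    The site center is TSS + offset in the gene's orientation, offset drawn
    from N(offset_mean, offset_sd) — negative offsets are 5' of the TSS.
    """
    if config.n_sites > len(genes):
        raise ValueError(f"n_sites ({config.n_sites}) exceeds gene count ({len(genes)})")
    seqs = {name: bytearray(genome.sequence(name), "ascii") for name in genome.names}
    chosen = rng.choice(len(genes), size=config.n_sites, replace=False)
    half = config.site_width // 2
    sites: list[TruthSite] = []
    for gi in sorted(int(i) for i in chosen):
        gene = genes[gi]
        length = genome.length(gene.chrom)
        for attempt in range(100):
            offset = rng.normal(config.offset_mean, config.offset_sd)
            center = gene.tss + (offset if gene.strand == "+" else -offset)
            start = int(round(center)) - half
            end = start + config.site_width
            if 0 <= start and end <= length:
                break
        else:
            raise ValueError(
                f"could not place a site near {gene.gene_id} within chromosome bounds"
            )
        motif_positions: list[int] = []
        if rng.random() < config.motif_plant_prob:
            k = int(rng.integers(1, 4))
            while len(motif_positions) < k:
                pos = int(rng.integers(start, end - 8 + 1))
                if all(abs(pos - q) >= 8 for q in motif_positions):
                    motif_positions.append(pos)
            for pos in sorted(motif_positions):
                _write_motif(seqs[gene.chrom], pos, rng)
        attenuated = bool(rng.random() < config.attenuated_fraction)
        sites.append(
            TruthSite(
                chrom=gene.chrom,
                start=start,
                end=end,
                gene_id=gene.gene_id,
                attenuated=attenuated,
                motif_positions=tuple(sorted(motif_positions)),
            )
        )
    updated = genome.with_sequences({n: s.decode("ascii") for n, s in seqs.items()})
    return sites, updated


def _window_means(
    grid: WindowGrid, truth: list[TruthSite], config: SimulationConfig, fusion: bool, infected: bool
) -> np.ndarray:
    means = np.full(grid.n_windows, config.depth, dtype=float)
    if not fusion:
        return means
    for site in truth:
        sl = grid.chrom_slice(site.chrom)
        w0 = site.start // grid.width
        w1 = (site.end - 1) // grid.width
        lfc = config.enrichment_log2fc
        if infected and site.attenuated:
            lfc *= config.attenuation_factor
        means[sl.start + w0 : sl.start + w1 + 1] = config.depth * 2.0**lfc
    return means


def _draw_counts(
    means: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.nb_size is None or not np.isfinite(config.nb_size):
        return rng.poisson(means)
    r = config.nb_size
    return rng.negative_binomial(r, r / (r + means))


def _materialize_reads(
    grid: WindowGrid, counts: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Turn per-window counts into 50-bp BED6 alignments placed inside their
    window; the 300-bp 3' extension then re-covers the source window."""
    rl = config.read_length
    frames = []
    for chrom in grid.chrom_names:
        sl = grid.chrom_slice(chrom)
        length = grid.genome.length(chrom)
        c = counts[sl]
        n = int(c.sum())
        if n == 0:
            continue
        win_starts = np.repeat(grid.starts(chrom), c)
        win_ends = np.repeat(grid.ends(chrom), c)
        span = np.maximum(win_ends - win_starts - rl, 0)
        offset = rng.integers(0, span + 1)
        plus = rng.random(n) < 0.5
        start = np.where(plus, win_starts + offset, win_ends - offset - rl)
        start = np.clip(start, 0, length - rl)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": start.astype(np.int64),
                    "end": (start + rl).astype(np.int64),
                    "name": ".",
                    "score": 0,
                    "strand": np.where(plus, "+", "-"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=gio.BED6_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    df["name"] = [f"r{i}" for i in range(len(df))]
    return df


def simulate_damid_reads(
    genome: Genome,
    truth: list[TruthSite],
    config: SimulationConfig,
    rngs: dict[str, np.random.Generator],
) -> dict[str, pd.DataFrame]:
    """Four read sets: Dam-only / Dam-fusion x control / infected."""
    grid = WindowGrid(genome, config.window)
    out: dict[str, pd.DataFrame] = {}
    for condition in ("control", "infected"):
        infected = condition == "infected"
        for sample in ("dam", "fusion"):
            means = _window_means(grid, truth, config, fusion=sample == "fusion", infected=infected)
            rng = rngs[f"reads_{sample}_{condition}"]
            counts = _draw_counts(means, config, rng)
            out[f"{sample}_{condition}"] = _materialize_reads(grid, counts, config, rng)
    return out


def simulate_expression_table(
    truth: list[TruthSite],
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Differential-expression table with site-bearing genes up-regulated.

    log2 fold changes come from the peak-gene effect model for site owners
    and from a null model otherwise; adjusted p-values are a monotone map
    of a noisy standardized effect (BH-corrected two-sided normal tail), so
    strong effects get small padj without a full count model.
    """
    peak_gene_ids = {s.gene_id for s in truth}
    n = len(genes)
    is_peak = np.array([g.gene_id in peak_gene_ids for g in genes])
    lfc = np.where(
        is_peak,
        rng.normal(config.de_peak_mean, config.de_peak_sd, size=n),
        rng.normal(0.0, config.de_null_sd, size=n),
    )
    se = 0.25
    stat = lfc + rng.normal(0.0, 0.1, size=n)
    p_raw = 2.0 * stats.norm.sf(np.abs(stat) / se)
    padj = stats.false_discovery_control(np.clip(p_raw, 1e-300, 1.0), method="bh")
    mean_background = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n)
    mean_treatment = mean_background * 2.0**lfc
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "log2fc": lfc,
            "padj": np.minimum(padj, 1.0),
            "mean_treatment": mean_treatment,
            "mean_background": mean_background,
        }
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """End-to-end generation of one fully self-consistent dataset."""
    rngs = _child_rngs(config.seed, _RNG_NAMES)
    genome, genes = simulate_genome(config, rngs["genome"])
    truth, genome = plant_binding_sites(genome, genes, config, rngs["sites"])
    reads = simulate_damid_reads(genome, truth, config, rngs)
    de_table = simulate_expression_table(truth, genes, config, rngs["expression"])
    return SyntheticDataset(
        config=config, genome=genome, genes=genes, truth=truth, reads=reads, de_table=de_table
    )


def truth_to_frame(truth: list[TruthSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.chrom,
                s.start,
                s.end,
                s.gene_id,
                int(s.attenuated),
                ",".join(map(str, s.motif_positions)),
            )
            for s in truth
        ],
        columns=["chrom", "start", "end", "gene_id", "attenuated", "motif_positions"],
    )


def truth_from_frame(df: pd.DataFrame) -> list[TruthSite]:
    sites = []
    for r in df.itertuples(index=False):
        pos = tuple(int(x) for x in str(r.motif_positions).split(",")) if str(r.motif_positions) not in ("", "nan") else ()
        sites.append(
            TruthSite(r.chrom, int(r.start), int(r.end), r.gene_id, bool(r.attenuated), pos)
        )
    return sites


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Serialize every artifact (FASTA, GFF3, BED6 x 4, sizes, truth, DE)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = out / "genome.fa"
    gio.write_fasta({n: dataset.genome.sequence(n) for n in dataset.genome.names}, paths["fasta"])
    paths["chrom_sizes"] = out / "genome.chrom.sizes"
    gio.write_chrom_sizes(dataset.genome, paths["chrom_sizes"])
    paths["gff"] = out / "genes.gff3"
    gio.write_gff_genes(dataset.genes, paths["gff"])
    paths["truth"] = out / "truth_sites.tsv"
    truth_to_frame(dataset.truth).to_csv(paths["truth"], sep="\t", index=False)
    for key, df in dataset.reads.items():
        paths[key] = out / f"reads_{key}.bed"
        gio.write_bed_frame(df, paths[key])
    paths["de_table"] = out / "de_table.tsv"
    dataset.de_table.to_csv(paths["de_table"], sep="\t", index=False)

    import yaml

    cfg = asdict(dataset.config)
    cfg["chrom_lengths"] = list(cfg["chrom_lengths"])
    cfg["gene_length_range"] = list(cfg["gene_length_range"])
    paths["config"] = out / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
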