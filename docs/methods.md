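# Methods

## Model and procedure

DamID profiles protein–DNA contact by expressing a Dam-methylase fusion
at trace levels; methylated fragments are amplified and sequenced, and
binding is read out as local enrichment of the fusion library over a
Dam-only control. The analysis here treats the genome as a fixed grid of
75 bp windows. Each uniquely mapped single-end read is extended 300 bp
toward its 3' end as a proxy for the methylated fragment it tags, and a
read contributes a count to every window its extended footprint overlaps
(footprint semantics; see *Design choices*).

Let t_i and b_i be fusion and Dam-only counts in window i. The fusion
track is rescaled by a factor f chosen in closed form so that the mean of
log2(f·t_i/b_i) over *eligible* windows (t_i ≥ 1 and b_i ≥ 1) is zero —
i.e. the mean ratio between the two libraries is one. The per-window
statistic is

    x_i = log2((f·t_i + c) / (b_i + c)),   c = 1 (pseudocount).

Across eligible windows the x_i are well described by a normal
distribution; its mean and standard deviation are estimated by the sample
moments (the maximum-likelihood estimates, sd with ddof = 1), and each
window receives the one-sided upper-tail p-value under that fit.
Enrichment is one-sided by construction: a binding site is evidence of
fusion > control, never the reverse.

A candidate binding site is a maximal run of at least 4 consecutive
windows with p < 0.01; runs never cross chromosome ends and are never
merged across a non-significant window. Each peak is summarized by its
span, its summit (midpoint of the window with the largest x_i, leftmost
on ties) and a fold change computed from summed counts,
log2((f·Σt + c)/(Σb + c)), which is more stable over a 4–10-window run
than averaging per-window log ratios.

**Empirical FDR.** The pipeline is re-run with treatment and background
exchanged. Under the null hypothesis of no specific binding the two
labels are exchangeable, so the number of "peaks" called in the swapped
direction estimates the false-call count at each threshold pair
(α, min log2FC); FDR(θ) = N_swap(θ)/max(N_obs(θ), 1), reported as NA when
nothing is observed. Each peak carries the FDR of the most stringent
fold-change threshold it passes. The default reporting thresholds are
log2FC > 3 with FDR < 0.01 % (control condition) and < 0.1 % (infected
condition); both comparisons are strict. A window-permutation null was
considered and rejected as the default because it destroys the spatial
autocorrelation that read extension induces, making it anti-conservative
for run-based calling.

**Annotation.** Two complementary peak-to-gene maps are produced. The
summit-based map assigns the same-chromosome gene minimizing
|summit − TSS|, with ties broken by lexicographic gene id; the distance
is signed in the gene's orientation (summit − TSS for '+' genes,
TSS − summit for '−' genes), so negative always means 5'/upstream. The
overlap-based map lists every gene whose body shares ≥ 1 bp with the peak
(half-open intervals; touching is not overlap). The gene set used for
transcriptome integration is the union of overlap-annotated genes and
nearest-TSS genes with |distance| ≤ 5 kb. The minus-strand TSS is end − 1
in half-open coordinates: the TSS is a base, not a boundary.

**Motif enrichment.** The Capicua HMG-box octamer TGAATG[AG]A is matched
by literal scan; overlapping occurrences all count, `N` never matches,
and by default both strands are scanned (the motif is not palindromic) by
matching the reverse-complement pattern T[CT]CATTCA on the forward
sequence. The null keeps every peak's length and chromosome and redraws
its start uniformly, 1000 times; relocated peaks may overlap anything —
no exclusion mask — because the observed peaks were equally free to fall
anywhere. Both null statistics (total occurrences; peaks containing ≥ 1
match) are fitted to a negative binomial parameterized by (size, mean):
the mean MLE is the sample mean and the size is profiled by 1-D bounded
likelihood maximization seeded at the moment estimate m²/(s² − m). When
the null counts are underdispersed (s² ≤ m) no finite size exists and the
fit falls back to a Poisson with the same mean, flagged in the report.
The p-value is the upper tail P(X ≥ observed) = 1 − F(observed − 1).

**RNA-Seq integration.** Differential expression is consumed as a table
(gene id, log2 fold change, BH-adjusted p, mean expression in treatment
and background); fitting the DE model itself is out of scope. "Up"
genes satisfy fold change > 1.5 and adjusted p < 0.1 (strict). The
peak-gene / up-gene overlap is tested one-sided against the
hypergeometric independence expectation. Control peaks are re-scored in
the infected sample over the same windows: a control peak is *lost* if no
filtered infected peak overlaps it, *reduced* if its infected fold change
drops below 2 (log2 < 1), and *retained* otherwise; lost is checked first
because absence of any infected call is the stronger statement. The
association curve ranks all genes by fold change (or absolute change =
treatment mean − background mean; both reported, since either ranking is
defensible) descending, ties by gene id, and slides a window-of-500 sum
of the binary has-binding-site flag.

## Synthetic data: what it emulates and what it does not

The generator plants everything the statistics assume:

| parameter | default | meaning |
|---|---|---|
| chrom_lengths | 2 × 1 Mb | genome size of the test universe |
| n_genes / n_sites | 400 / 100 | non-overlapping genes; one site per selected gene |
| site_width | 600 bp | planted binding-site footprint (≈ 8 windows) |
| offset model | N(−500, 200²) bp | site centre relative to TSS, orientation-aware |
| enrichment_log2fc | 4 | fusion/control window-mean ratio inside sites |
| motif_plant_prob | 0.3 | fraction of sites given 1–3 written octamers |
| depth | 20 | expected Dam-only reads generated per window |
| nb_size | 20 | NB size ⇒ variance/mean = 2 at depth 20 (None = Poisson) |
| attenuated_fraction / factor | 0.5 / 0.2 | infected condition: half the sites drop to log2FC 0.8 |
| DE effect | N(1.2, 0.5²) vs N(0, 0.3²) | log2FC model for site-bearing vs other genes |

Counts are drawn per window and then materialized as 50 bp reads placed
inside their window (both strands), rather than simulating GATC-fragment
chemistry: the downstream statistics operate on window counts, so this
keeps the planted truth exact at the unit of inference. Depth, library
size and the mild overdispersion (variance/mean ≈ 2) are calibration
choices typical of a shallow DamID library, not estimates of any
particular experiment. Adjusted p-values in the DE table are a monotone
map of a noisy standardized effect with BH correction — enough structure
for threshold logic, not a count model.

Features of real data the generator does **not** emulate: GATC-site
spacing and fragment-level amplification bias, mappability and GC bias,
sequencing error, replicate structure, and transcript-level (multi-TSS)
gene models. Passing tests therefore demonstrate the correctness and
calibration of the inference given its own model assumptions, not
robustness to those artefacts.

Determinism: one master seed is fanned out to named child streams
(genome, sites, one per read library, expression) via
`numpy.random.SeedSequence.spawn`, so every artifact is a pure function
of the configuration and stages can be regenerated independently.

## Numerical choices and degenerate inputs

- Pseudocount c = 1 on both ratio terms bounds sparse-window values; the
  normalization factor itself is computed on raw counts over eligible
  windows (closed form), so the pseudocount never biases the scale.
- Ineligible windows (a zero on either side) get p = 1 and can never seed
  or extend a peak; without this the fitted σ is dominated by zeros.
- Constant log-ratio tracks raise a degenerate-fit error rather than
  returning σ = 0; normalization and fitting require ≥ 100 eligible
  windows (configurable floor).
- p-values are clipped away from exact 0 so downstream −log10 transforms
  stay finite.
- Summit ties take the leftmost maximal window; peak tables are ordered
  by (chromosome, start) — all outputs are byte-deterministic.
- The truncated final window of each chromosome is kept (tiling
  conservation is exact); reads are clamped to chromosome bounds on
  extension.
- "Unique mapping" for the optional SAM reader is MAPQ ≥ 1, exposed as a
  parameter, since aligner-specific uniqueness tags vary.
- The normalization target is configurable (`normalization_target`,
  default 0 = mean ratio of one) for sensitivity analysis against the
  alternative reading of a unit *mean log* ratio, which would shift every
  fold-change threshold by one log2 unit.

## Design choices that were genuinely open

- **Read→window assignment.** A 350 bp extended footprint spans ~5
  windows; it is counted in each of them (the extension models the
  methylated fragment). The alternative — assign each read only to its
  5'-position window — is available as `counting_mode="five_prime"` for
  sensitivity analysis. Footprint counting smooths counts across
  neighbouring windows; tests that assume independent windows
  (e.g. two-sample KS on null tracks) subsample every 6th window.
- **FDR construction.** Label swap was chosen over window permutation or
  parametric peak-level nulls: it is symmetric, assumption-light, and
  respects the autocorrelation of the track.
- **Strand mode for motif scanning** defaults to both strands; the motif
  is non-palindromic and binding is strand-agnostic.
- **Relocations stay on their source chromosome**, preserving chromosome
  composition of the peak set while remaining uniform within it.
- **Moving-sum window.** The integration default is 500 genes; analyses
  of the 400-gene synthetic universe use 100 so the curve retains ≥ 300
  evaluation points. Deciles of the curve are compared to quantify the
  coupling between ranking and binding.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use the default 2 Mb / 400-gene
/ 100-site simulation (seeds fixed per test), 10 seeds for null
calibration, 20 seeds at 200 relocations for motif-null calibration, and
1000 relocations for the headline motif p-value. On one CPU the full
suite runs in well under a minute of compute per criterion.

## Known limitations

- The empirical FDR is resolved per threshold, not per peak; peaks
  passing the same threshold share an FDR value.
- With very strong planted signal the swapped-label null yields zero
  peaks and the FDR is reported as exactly 0; a small-sample upper bound
  (e.g. (N_swap + 1)/(N_obs + 1)) is not applied, matching the plain
  ratio definition.
- Peak fold changes are mildly diluted relative to the planted per-window
  enrichment because runs include partially enriched shoulder windows and
  the normalization factor absorbs part of the genome-wide signal mass;
  this is inherent to the method, not a defect of the generator.
- Nearest-TSS annotation considers gene starts only; alternative TSSs of
  multi-isoform genes are out of scope.
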