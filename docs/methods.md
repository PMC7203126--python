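# Methods

This note documents the statistical procedures `bgcprof` implements,
the defaults it ships, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the conventions left
room.

## Expression quantification and differential expression

Expression is quantified as RPKM: `count / ((length_bp/1e3) ·
(library_size/1e6))`, with library size defaulting to the sample's
column sum (mapped reads). No between-sample normalisation beyond RPKM
is applied (no TMM or median-of-ratios size factors): the two-strain
chemostat design this pipeline targets has closely matched library
sizes, and replicates are simply averaged per strain.

Per gene, the comparison between a reference strain A and a test
strain B follows three conventions:

* **Silence floor** (`silent_rpkm = 0.3`): genes below 0.3 RPKM are
  treated as silent. Genes silent in *both* strains are excluded from
  the DE table entirely — at that depth a nonzero count is as likely
  genomic-DNA carry-over as transcription.
* **Cap** (`fc_cap = 7`): a gene silent in exactly one strain gets
  log2 FC = ±7 with the sign of the expressed strain, and no p-value
  (one side has no variance model; the cap alone carries the DE call).
  Ratios of two expressed means are clamped to the same ±7 range.
* **Welch test**: a two-sided t-test assuming unequal variances over
  replicate RPKM, with Welch–Satterthwaite degrees of freedom. Welch is
  used everywhere a t-test appears in the pipeline, including the
  biomass and metabolite comparisons — with n of 3–7 per group and no
  reason to assume equal variances, the pooled test's extra power is
  not worth its size distortion.

A gene is called differentially expressed when |log2 FC| > 0.25
(strict) and p < 0.05, or when the fold change is capped.

Orientation is always *test over reference* (deletion strain over
parent).

## The silencing screen

The screen decides which BGC core genes (the cluster's synthase or
synthetase) are worth deleting. For each core gene, a compendium
condition counts as "not expressed" when the gene's expression is
below `actin_rel_silent = 2 %` of the γ-actin reference level in that
condition; a core is silent overall when that happens in at least 22
of the 26 conditions. The 2 % cutoff is a deliberate choice: the qPCR
convention in this workflow treats "below 5 % of actin" as low
expression, so the silence bound is set conservatively below it, and
it is configurable. Actin-relative screening (rather than an absolute
per-dataset cutoff) keeps the rule meaningful across heterogeneous
platforms and normalisations.

Non-silent cores are ranked by median actin-relative expression,
highest first — the most robustly expressed clusters contribute most
to the secondary-metabolite burden and are the deletion priorities.

## Cross-platform z-score

For each DE gene the RNA-seq log2 FC ("raw score") is compared against
the log2 FCs the same gene shows across a compendium of microarray
high-versus-low production contrasts:

    z = (raw_fc − mean(pop)) / sd(pop)

with the sample (n−1) SD; the population-SD variant differs by < 2 %
at n = 26 and the sample SD is the honest choice for an estimated
population. A gene enters the analysis only when present in ≥ 50 % of
compendium datasets (13 of 26). Genes whose population SD is zero (or
indistinguishable from zero at double precision) are reported
uncovered.

Bands partition the covered genes:

| band | rule |
|---|---|
| similar | \|z\| < 0.2 (strict) |
| altered | 0.2 ≤ \|z\| ≤ 1.25 (ties at either boundary land here) |
| divergent_pos / divergent_neg | z > 1.25 / z < −1.25 (strict) |

The divergence boundary 1.25 is a fixed convention of this workflow.
It is *not* the two-sided 5 % normal quantile (1.96), and no stated
normal-theory derivation reproduces it; rather than silently
substituting a different constant, the package ships 1.25 as the
default and offers `calibrate_threshold` as the principled
alternative: per gene, simulate a pseudo-population of `n_covered`
normal draws plus one raw draw, studentise, pool |z| over genes and
simulations, and take the (1 − FPR) quantile. The pseudo-population is
realised through the exact sampling distributions of its sufficient
statistics — sample mean ~ Normal(μ, σ/√n), sample SD ~
σ·√(χ²(n−1)/(n−1)) — which is distributionally identical to
materialising the draws and keeps n_covered = 10⁴ calibrations
instant. At large n_covered the threshold converges to the normal
quantile (1.96 at 5 % FPR); at n_covered ≤ 10 it sits visibly above it
(the studentised statistic is a scaled t).

## Cluster footprints

z-scores are laid out in catalog order (contigs in file order, genes
by start coordinate) and scanned for maximal runs of ≥ `min_run = 3`
consecutive genes whose z all exceed +1.25 or all fall below −1.25.
Uncovered genes break runs and runs never span contig boundaries.
`min_run = 3` matches the smallest multi-gene cluster deletion the
workflow is designed to detect; deleted single-gene synthetases appear
as "divergent singletons", reported separately. Genes with capped raw
FCs participate — deleted-cluster genes are exactly the strongest
signals the scan exists to find.

Recovery performance is scored at the call level: a call recovers a
planted cluster when it overlaps it, and a call overlapping no planted
cluster is a false cluster. Boundary jitter (an adjacent divergent
gene extending a call by one) is therefore not counted as a detection
failure; it is visible in the reported first/last positions.

## Enrichment

Category enrichment of a gene set against a background uses the
upper-tail hypergeometric probability P(X ≥ k) per category and
Benjamini–Hochberg adjustment across the tested categories (flat label
set, no hierarchy-aware correction); `enriched` flags q < 0.05.

## Metabolite conventions

Replicate concentrations are summarised per (analyte, compartment,
strain). Replicates flagged below the detection limit carry no value;
in a mixed cell they are dropped rather than imputed at LOD/2 — the
floor convention below only applies to *fully* undetected conditions,
and imputation would manufacture variance where none was measured.

* both strains detected → log2(test/ref), Welch p over detected
  replicates;
* detected in exactly one strain → log2 FC floored at ±5
  (`lod_floor`), p undefined, marker "floored";
* both undetected → excluded.

The metabolite floor (±5) is deliberately distinct from the RNA-seq
cap (±7); both are configurable. Markers: p < 0.05 "significant",
0.05 ≤ p < 0.10 a trend "(+)" or "(−)" by direction, else "ns".

The untargeted feature filter keeps m/z features with log2 FC > 2 and
a larger normalized peak area > 10⁶ (both strict); quantities can be
divided by cell dry weight to correct production levels for growth
differences.

## qPCR

Technical replicates are averaged in Ct space before ΔCt; relative
expression is 2^−ΔΔCt against the γ-actin reference and a calibrator
sample, with amplification efficiency fixed at 2.0 per cycle (no
standard-curve correction). Actin-relative level is 2^−(Ct_target −
Ct_actin), conventionally "low" below 5 %. Copy numbers from
genomic-DNA plates use a single-copy reference gene and a known
single-copy calibrator strain; the relative quantity is rounded half
away from zero.

## Synthetic-data generator

The generator emulates the study design the pipeline assumes, at desk
scale, reproducibly from one integer seed (each generator draws from
its own `SeedSequence` substream, so stages are reproducible when run
separately). Defaults:

| parameter | default | rationale |
|---|---|---|
| `n_genes`, `n_contigs` | 2000, 8 | desk-scale stand-in for a ~13k-gene fungal genome over dozens of contigs |
| `gene_length_range` | 500–5000 bp | typical fungal gene spans |
| `bgc_specs` | 4 clusters of 3–7 genes | the four-cluster deletion design |
| `baseline_mean_range` | 5–500 expected counts (log-uniform) at a 2×10⁶-read library | matches shallow 2M-read RNA-seq; BGC members draw from the top decade of the range because the clusters worth deleting are the highly expressed ones |
| `dispersion` | 10 | NB size parameter k (variance = m + m²/k), i.e. squared biological CV ≈ 0.1, typical for isogenic replicate cultures |
| `n_datasets` | 26 | compendium size and screen conditions |
| `missing_rate` | 0.3 | yields ~90 % of genes passing the 50 % coverage filter, mirroring realistic compendium coverage |
| `compendium_sigma_range` | 0.3–0.8 log2 units | dataset-to-dataset spread of microarray contrasts |
| `burden_effect` | 1 log2 unit, 100 genes | genome-wide responders to the relieved production burden; these genes carry the same μ in the compendium, so their z ≈ 0 — the generator plants the very signature the z-score exists to separate |
| `lod_nm` | 0.02 nM | an LOD consistent with sub-0.1 nM analytes being quantified while others censor |
| `metabolite_cv` | 10 % | technical-replicate spread of targeted LC-MS |
| `screen_silent_fraction` | 17/49 | fraction of core genes planted silent in the screen matrix |

What the generator does **not** emulate: read-level data (counts are
drawn directly, no FASTQ/mapping), microarray probe effects or
between-dataset correlation (compendium values are independent given
(μ_g, σ_g)), gene-length biases in counts, compositional effects of
removing highly expressed transcripts on library size, batch structure
in metabolite replicates, or qPCR efficiency drift. Passing tests on
synthetic data therefore demonstrate that the *procedures* are
implemented correctly and recover planted signals under the assumed
noise model — not that the assumed noise model captures every property
of real chemostat RNA-seq.

Validation sizes used by the test suite: planted-cluster recovery runs
the full pipeline on 600-gene genomes across 20 seeds with
`missing_rate = 0.1` (the recovery property is stated for genes
covered by ≥ 13 of 26 datasets, which that rate guarantees); null
calibration pools 50 genes × 8000 simulations at n_covered = 10⁴; the
Welch type-I check uses 10⁴ null gene pairs (n = 5 vs 7); metabolite
recovery uses 4 replicates at 5 % CV (within the ≤ 10 % regime the
recovery property assumes) across 20 seeds.

## Numerical choices and degenerate inputs

* Fold changes of zero-vs-zero means are never computed (excluded
  upstream); detected means must be positive.
* Welch with both variances zero: equal means give (t = 0, p = 1);
  unequal means with zero variance give p = 0 in the vectorised DE
  path and an error in the scalar API (no variance model to divide
  by).
* Population SDs below 1e−12·max(1, |mean|) are treated as zero
  (constant population up to rounding) and the gene reported
  uncovered.
* Matrices round-trip through TSV bit-exactly (shortest-repr float
  writing, round-trip float parsing); blank cells are the only missing
  marker.
* Copy numbers round half away from zero, a deterministic tie rule.
* BGC region bounds, overlaps, replicate counts ≥ 2, positive library
  sizes and positive dispersions are validated at configuration time.

## Known limitations

* The DE p-values are per-gene Welch tests without multiple-testing
  correction, matching the workflow this package reproduces; the FDR
  machinery is applied only in category enrichment.
* The z procedure treats the compendium mean and SD as estimated but
  ignores estimation error in the raw RNA-seq fold change itself.
* The silencing screen assumes the actin reference is stably expressed
  across all compendium conditions.
* `calibrate_threshold` assumes normal population log2 FCs per gene;
  heavy-tailed compendia would need a resampling variant.
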