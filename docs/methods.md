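# Methods

This note documents the statistical procedures implemented in `ontarget`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Study design

The framework assumes a five-group design within one cell line: a shared
control group (default 6 replicates) and four treated groups of triplicates
— two independent siRNA knockdowns of the drug's primary target (`kd1`,
`kd2`) and drug treatment sampled at 6 h and 48 h.  Using two different
siRNAs is what makes the on-target definition conservative: an effect must
be reproducible across both silencing reagents (or at least not contradict
them) before it can be attributed to target inhibition rather than to
siRNA-specific artifacts.  Multi-cell-line studies are independent runs of
the same pipeline, one per cell line.

A single control group serves both the knockdown and the drug contrasts.
Real experiments often carry separate vehicle controls (DMSO for the drug,
negative-control siRNA for the knockdowns); the package accepts arbitrary
contrast definitions (`ontarget.diffexpr.Contrast`), so split controls are
supported — the simulator simply does not generate them, because vehicle
effects are not part of what it emulates.

## Normalization and transformation

**RLE size factors.** The reference profile is the per-promoter geometric
mean across samples, computed over promoters with positive counts in every
sample; each sample's factor is the median ratio of its counts to the
reference, and factors are rescaled to geometric mean 1.  On sparse inputs
with no all-positive promoter, an explicit fallback computes the reference
over promoters positive in ≥ 90% of samples.

**Effective library size.** The median-of-ratios factor already carries
each sample's relative sequencing depth.  CPM therefore uses an effective
library size of (geometric-mean raw library) × factor rather than
(raw library × factor): multiplying depth in twice would make normalized
values depend on per-sample scaling, defeating the purpose of the
normalization.  With this definition, scaling one sample's counts by c
changes all normalized values by a single global constant only — the
invariance the test suite asserts.

**CPM filter.** A promoter is kept iff its CPM reaches the threshold
(default 5, inclusive) in at least one sample, i.e. promoters below
threshold in *all* samples are discarded.  The filter is monotone in the
threshold.

**Voom-style weights.** Values are log2((count + 0.5)/(effective library
+ 1) × 10⁶).  Residual standard deviations after removing group means are
fit against mean log-count with lowess (span 0.5); each observation's
predicted sqrt-sd at its fitted log-count gives weight = prediction⁻⁴,
capped at 10⁴, with an sd floor of 10⁻⁴ guarding degenerate all-equal
rows.  When no group has ≥ 2 replicates the weights fall back to 1 with a
warning.  Span, cap and floor are exposed as function arguments.

## Differential expression

Each contrast is a per-promoter weighted least-squares fit of the
transformed value on an intercept and a group indicator — the fixed-effects
ANOVA for a two-group comparison — optionally with batch indicator
covariates (the transparent equivalent of a dedicated batch-removal step;
a confounded batch/group design raises an error rather than silently
absorbing the effect).  No empirical-Bayes variance moderation is applied:
the test is the plain per-promoter t statistic on the group coefficient.
BH adjustment runs within each contrast, matching how per-condition tables
are reported.  The ternary sign call is sgn(lfc) gated at q ≤ α
(α = 0.05, inclusive).

The ranking used for signatures orders rows by ascending p, breaking ties
by |lfc| descending and then lexicographic ID, so every downstream object
is bit-reproducible.

## Step-wise target classification

For each entity (promoter, gene or pathway) under one drug, the four signs
(s_kd1, s_kd2, s_6h, s_48h) are filtered in order:

1. s_kd1 · s_kd2 = −1 → `excluded_kd_conflict`.
2. s_6h · s_48h = −1 → `excluded_time_conflict`.
3. Drug sign d = s_48h if nonzero else s_6h (the long-term response is
   preferred); knockdown consensus k = sgn(s_kd1 + s_kd2).
   d = 0 → `null` (a knockdown-only change is not a drug response);
   d = k ≠ 0 → `on_up`/`on_down`; d ≠ 0 with k ∈ {0, −d} →
   `off_up`/`off_down`.

The classifier is total on ternary inputs, symmetric in the two
knockdowns, and sign-equivariant.  Two documented variants: `kd_both=True`
requires both knockdowns significant for an on-target call (the permissive
default only excludes outright conflicts, because a consensus from one
significant siRNA plus one null siRNA is still evidence in the same
direction); `kd_conflict_to_off=True` routes knockdown-conflict entities
into the off-target class instead of excluding them.

Gene-level calls collapse the promoter table by taking, per gene and
contrast, the row of the most significant promoter (same deterministic
tie-break), then classifying the gene's sign vector.

## Gene-set enrichment

Genes are ranked by signal-to-noise (μ_a − μ_b)/(σ_a + σ_b), each σ
floored at max(0.2·|μ|, 0.2), ties broken by gene ID.  The enrichment
score walks the ranked list, rising by |metric|^p (normalized over the
set's members) at each hit and falling by 1/(N − N_hits) at each miss; the
ES is the signed maximal deviation (ties resolve to the positive
extremum).  The default weight is p = 1, with p = 0 giving the classical
unweighted KS statistic; p = 0 scores are invariant under strictly
monotone transforms of the metric.

The null distribution per set comes from random same-size gene sets drawn
from the ranked universe (gene-set permutation, default 1000 draws).  The
nominal p is the one-sided tail fraction among same-signed null scores
with a +1 pseudocount — computed within the matching sign so that null p
values are approximately uniform.  NES divides the ES by the mean |null
ES| of the same sign; `nes_mode="max"` instead divides every ES by the
maximum |ES| of the analysis (a normalization that bounds |NES| by 1, kept
as an option for comparability with analyses defined that way).  FDR is
the standard ratio of null to observed NES tail areas, capped at 1.  Sets
outside [5, 500] members (within the ranked universe) are dropped before
testing.  Pathway significance uses p ≤ 0.05 or FDR ≤ 0.20 (both
inclusive); significant pathways get sign sgn(NES) and enter the same
step-wise classifier as genes.

## Motif activity response analysis

The model is E_ps = c_p + c_s + Σ_m N_pm·A_ms + ε: promoter expression is
explained by predicted transcription-factor binding-site counts N (for
CAGE data, sites within −300..+100 bp of the promoter peak; a helper
counts sites in that strand-oriented half-open window when a site BED is
supplied).  Column-centering N absorbs the promoter intercepts and double-
centering E absorbs both intercept families, so per sample the activity
vector is the ridge solution (ÑᵀÑ + λI)⁻¹ Ñᵀ e_s, computed through one
SVD.  λ is selected by generalized cross-validation on a log-spaced grid
spanning 10⁻⁴–10⁺⁴ times the mean squared singular value (25 points);
λ = 0 reproduces ordinary least squares.  Standard errors come from the
ridge sandwich σ²_s·V diag(d²/(d²+λ)²) Vᵀ, the per-motif z-score is the
root-mean-square of A/σ across samples, and activities are exactly
centered per motif.  Ridge-with-GCV is used as the fully specified
equivalent of a Gaussian-prior marginal-likelihood fit: both shrink the
activity estimates, and the cross-validated λ makes the shrinkage level a
measured quantity rather than a tuning constant.

Motifs with predicted sites on fewer than 150 promoters (default) are
excluded before fitting.  Differential activity between two sample groups
is a two-group t test on activities with inverse-variance weights (1/σ²),
BH-adjusted across motifs and sign-gated at q ≤ 0.05.

## Motif–pathway association

A gene is a target of a motif iff any of its promoters carries ≥ 1
predicted site.  For each (motif, pathway) pair the expressed-gene
universe — genes surviving the CPM filter with at least one promoter in
the site matrix — is partitioned into the 2×2 table (in-pathway ∩ target,
in-pathway only, target only, neither).  The two-sided Fisher's exact
p-value uses the minimum-likelihood convention (sum over hypergeometric
outcomes no more probable than observed, margins fixed); the reported odds
ratio is the sample estimate ad/bc.  BH runs across all tested pairs; a
pair is reported as associated when q < 0.05 *and* the overlap exceeds its
independence expectation (depletion is only reported on request).  By
default the scan is restricted to differentially active motifs ×
significantly enriched pathways, mirroring how the association step is
meant to explain already-detected responses; an unrestricted mode tests
every pair.

## Connectivity signatures

A query signature is the top-k up- and down-regulated genes (default
k = 50) by DE significance.  Against a reference ranked profile the score
is 100·(ES(up) − ES(down))/2 with the unweighted (p = 0) enrichment score,
giving exactly +100 for perfect concordance, −100 for its flip, and exact
antisymmetry under swapping the up/down lists.  Significance is calibrated
with n random k+k signatures (default 100) drawn from the reference
universe; the one-sample t-test treats the observed score as the
hypothesized mean of the null sample (an empirical-percentile alternative
is available).  The reporting rule is |score| ≥ 80 (inclusive) with BH
FDR ≤ 5% across references.  This score is this package's own fully
specified connectivity measure in the CMAP tradition; reference libraries
are pluggable TSVs (reference, gene, rank metric).

## Synthetic data generator

Counts are negative binomial with var = μ + φμ² (φ default 0.05, a typical
tag-count overdispersion; φ = 0 falls back to Poisson).  Promoter
baselines are log-normal (log2 mean 5, sd 1.5) normalized to relative
abundances, and each sample's expected library size is drawn uniformly
from 0.8–1.2 million tags, so depth variation is planted and must be
removed by normalization.  Planted effects, all in log2 units with
magnitude 2.0 by default:

* **on-target** genes shift identically in kd1, kd2 and both drug
  timepoints (half up, half down);
* **off-target drug-only** genes shift in the drug groups only;
* **off-target reversed** genes shift up under drug and down under both
  knockdowns;
* **active motifs** (default 3 of 20) add site_count × activity to the
  log2 mean of promoters carrying sites (5% of promoters per motif, 1 + 
  Poisson(1) sites), with activity ±0.3 under drug and half that under
  knockdown — the linear structure MARA is designed to recover;
* **pathways**: one gene set per planted class, one set sampled from the
  first active motif's targets (the planted motif–pathway association),
  and random sets to fill 20 total (sizes 10–60).

Defaults (5000 promoters, 2000 genes, 50/50/30 planted genes, triplicate
treatments with 6 controls) give each stage realistic power at desk scale;
the dedicated calibration analyses use 10,000 signal-free promoters.  All
randomness flows from a single integer seed; the pipeline fans one global
seed out to per-stage seeds through `numpy.random.SeedSequence.spawn`, so
stages rerun standalone are reproducible and a full rerun is bit-identical.

What the generator does **not** emulate: read-level CAGE tags, mapping
artifacts or sequencing error; batch effects (the metadata carries batch
labels and the DE stage accepts a batch covariate, but no batch signal is
planted); vehicle-control effects; correlated gene programs beyond the
planted motif structure; multi-mapping promoters shared between genes.
Passing tests therefore demonstrate the correctness and calibration of
the algorithms under the stated noise model — not robustness to every
artifact of real CAGE libraries.

**Ground-truth evaluation.** Sensitivity is the fraction of planted
on-target genes called on-target with the planted direction.  Label
accuracy is measured over planted (non-null) genes recovered as any
non-null, non-excluded call: motif-driven expression shifts can make
class-null genes genuinely differentially expressed, so counting them as
classifier errors would conflate generator realism with classifier
correctness.

## Numerical choices

* Ties in every ranking are broken deterministically (p, then |lfc|
  descending, then ID; gene ID for the enrichment metric).
* ES sign ties (|max| = |min| of the running sum) resolve positive.
* The permutation null for sets of equal size is computed once and shared
  (the draws depend only on set size).
* σ floors: 0.2 (signal-to-noise), 10⁻⁴ (voom sd), 10⁻¹² (activity
  standard errors).
* Degenerate inputs: all-zero metric weights fall back to unweighted
  steps; a gene set covering the whole ranked list scores ES = 1 with a
  warning; empty intersections raise.
* BED conventions: half-open 0-based intervals, single-base CTSS
  positions, strand-aware assignment; counts are conserved (assigned +
  unassigned = input).

## Known limitations

* The ANOVA is a two-group fixed-effects contrast; time-course or
  mixed-effects models are out of scope.
* Gene-level collapse by best promoter discards secondary-promoter
  information (promoter-level switching within one gene is invisible at
  the gene level).
* The GSEA FDR is the standard tail-area estimate and can be
  conservative for small set collections.
* MARA assumes additive, linear motif contributions on the log scale and
  cannot separate perfectly collinear motifs.
* Connectivity scores depend on the reference universe; queries with few
  genes in the universe are scored on the overlap only (logged).
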