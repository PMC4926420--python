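# Methods

## The gene set regularity (GSR) model

The package quantifies "function regularity": for a gene set G = {G1, …, Gm} with
expression profile E = (E1, …, Em), every one of the m(m−1)/2 gene pairs has an ordering
relation within each sample.  A **baseline ordering template** B is estimated from the
control samples: pair (i, j) receives orientation "A" when Pr(Ei < Ej | control) > 0.5
and "B" otherwise.  A sample's **GSR index** R for that set is the fraction of pairs
whose observed strict-order relation matches B.  R = 1 means the sample reproduces the
control-consensus ordering everywhere; R = 0 means every pair is reversed; i.i.d.-random
expression gives R ≈ 0.5 on average.  This is a modified DIRAC (differential rank
conservation) score: instead of contrasting rank matching between two phenotypes, it
anchors every sample to the control-derived template, so one number per set and sample
expresses departure from the normal ordering.

Because only order relations enter, R is invariant under any strictly increasing
per-sample transform of the expression values.  This is what makes cross-platform
integration workable: monotone platform effects cancel exactly.

### Conventions and degenerate inputs

* **Ties in expression** count as "not less" (encode "B"): the tested relation is the
  strict `Ei < Ej`.  Deterministic, and consistent with the template rule below.
* **Template fraction exactly 0.5** encodes "B" (the majority rule is `> 0.5` for "A").
* A set is scored only if **at least 2 of its genes** are present on the platform; sets
  failing this are reported in `skipped_sets` with the reason, never silently dropped.
* Templates require at least one control sample; duplicating every control leaves the
  template unchanged (the fraction is a per-pair average).
* R is kept at full float precision internally; result writers round only at display.

One published formulation expresses R as a count of "A" symbols over all pairs; we
implement the match-fraction definition, which is the only reading under which a sample
identical to the control consensus scores exactly 1 and a fully reversed sample exactly 0
(both are enforced in the acceptance checks).

## Deregulation statistics

Per gene set, stage-vs-control differences in GSR indices are tested with a two-sided
Mann-Whitney U.  Exact enumeration is used when both groups have ≤ 8 samples and the
pooled values are tie-free; otherwise the tie-corrected normal approximation.  Two-sided
because the direction of deregulation is not pre-specified.  p-values are
Benjamini-Hochberg adjusted across all sets of the comparison; ranks are assigned by
ascending p with a lexicographic tie-break on set name so results are identical across
runs and platforms.  Degenerate case: a set with identical GSR values in both groups gets
p = 1.

**Top-k set analysis** counts every non-empty logical region among the groups' top-k
lists (k = 200 by default); region counts sum to the union size by construction, and the
all-groups intersection is emitted as the "commonly deregulated" list.

**Progressive-ranking selection** keeps sets with p < α (default 0.05) at every stage,
final-stage rank below 200, and a rank improvement of more than 15 positions between
consecutive stages.  Two readings of the drop rule are possible; the default requires the
drop for *every* consecutive stage pair (`drop_mode="every"`), with `"any"` available.
Raw p (not q) feeds criterion 1, mirroring the α = 0.05 phrasing of the selection rule.

## Classification and clustering

Informativeness of the functionome pattern (one GSR value per set, per sample) is
measured by a linear soft-margin SVM under stratified 5-fold cross-validation repeated 10
times.  Cost C = 1 (the common default of linear soft-margin implementations; the
original analysis does not state a tuned value) and one-vs-one voting for multiclass;
both are exposed as options.  Sensitivity, specificity and accuracy come from the
cumulative confusion counts over all repeats; the binary AUC pools out-of-fold decision
scores across repeats.  GSR features already share the [0, 1] scale, so no
standardization is applied — reports are reproducible from the GSR matrix and the seed
alone.  Folds are stratified to avoid empty-class folds at small n.

Group structure is summarized by complete-linkage hierarchical clustering of the
per-group mean GSR vectors under Euclidean distance; the merge sequence and leaf order
are returned as data (no dendrogram rendering).

## Mutual-information network

Pairwise dependence between gene-set GSR profiles uses the Kraskov variant-1 kNN
estimator (Chebyshev metric, k = 3 by default, nats, clamped at 0).  kNN estimators are
undefined under exact ties, so tied marginals receive an index-scaled deterministic
jitter (value + i·range·1e−10) before distance computation.  ARACNE pruning uses the
multiplicative data-processing-inequality rule: edge (i, j) is removed when some third
node z satisfies mi(i, j) < τ · min(mi(i, z), mi(j, z)), with τ = 1 (strict model) by
default.  All removals are judged against the original matrix, making pruning
order-independent and idempotent; raising τ can only remove more edges.  The largest
connected component is extracted for export (ties broken toward the component containing
the lexicographically smallest label), written as GML with node labels and edge weights.

## Cross-platform integration and differential expression

Each sample is rescaled to **cumulative proportions**: a gene's transformed value is the
share of the sample's total signal carried by genes expressed strictly below it.  The
lowest gene maps to exactly 0; the top gene approaches but never attains 1 (the inclusive
cumulative sum makes 1 a supremum); tied values share their block's lowest output; the
within-sample ordering is preserved, so GSR indices computed before and after the
transform are identical (asserted as a cross-module test).  Log-ratio inputs with
negative values are shifted by the per-sample minimum first, since the transform
distributes nonnegative mass.

Datasets are merged on the intersection of gene symbols.  If the intersection falls below
`min_common` (default 4000 genes), datasets are dropped greedily — each step removes the
dataset whose removal most enlarges the intersection — until the threshold is met; an
exhaustive subset search (fewest drops, then largest intersection, then lexicographic
ids) is available for small collections.  Dropped datasets are logged with reasons.

Differential expression uses a per-gene two-group linear model with empirical-Bayes
variance moderation: prior degrees of freedom d0 and prior variance s0² are estimated by
moment-matching the log sample variances against a scaled-F model (trigamma inversion by
Newton iteration); the posterior variance is the convex combination
(d0·s0² + df·s²)/(d0 + df) and the moderated t carries d0 + df degrees of freedom,
followed by BH across genes.  Setting d0 = 0 recovers the ordinary two-sample t exactly.
When the log-variances show no excess dispersion (the degenerate equal-variance limit),
d0 = ∞ and s0² is the plain average of the sample variances, so shrinkage toward the
common value is a no-op.  The implementation reproduces Bioconductor limma's
`lmFit`/`eBayes` on shared inputs to ~1e−6 relative error; limma serves as an independent
oracle in the test suite, never as the implementation.

## Synthetic cohorts

The generator emulates the structure the model is built to detect, with ground truth:

* **Controls** share one latent gene ordering: latent means drawn N(0, 1) per gene, each
  control sample adds i.i.d. N(0, σ²) observation noise.
* **Gene sets partition a shuffled gene space** (sizes uniform on 10–40, 200 sets, 6000
  genes by default).  Disjointness is deliberate: overlapping perturbed sets would
  re-scramble each other's genes and detach the realized discordance from its target.
  The cost is that between-set correlation of real collections is not represented
  (a stated non-goal alongside probe and batch effects).
* **Cases** in stage g carry, in a designated fraction π_g of the sets, a within-set
  reordering of the latent means whose discordant-pair (Kendall) fraction is λ_g; the
  noise is added after, so deregulation is a property of the phenotype, not of one
  observation.  Perturbed-set rosters are nested across stages, so deregulation
  accumulates with severity, as progressive-ranking analysis expects.
* The reordering permutation is sampled through its **Lehmer code** with exactly
  round(λ·m(m−1)/2) inversions, realizing any λ ∈ [0, 1] exactly (the realized value is
  recorded as truth).  A random adjacent-transposition walk cannot do this: it converges
  to a uniformly random permutation, whose expected discordant fraction saturates at 0.5,
  below the λ = 0.6 the severest stage requires.

Two configurations matter:

* **Default (recovery) configuration** — σ = 0.05.  Noise flips almost no pairs, so the
  injected discordance reappears as 1 − R one-for-one: regressing (1 − GSR) of perturbed
  sets on λ recovers slope 1 (±0.1 enforced).  This isolates the estimator from noise
  attenuation.
* **Staging preset** — σ = 0.8, π = (0.1, 0.2, 0.35, 0.5), λ = (0.3, 0.4, 0.5, 0.6),
  60 controls + 30 cases per stage.  For latent gaps Δ ~ N(0, 2), a pair flips in a
  control sample with probability arccos(1/√(1+σ²))/π ≈ 0.21 at σ = 0.8, putting the
  control GSR mean near 0.78 — the level typical of noisy array cohorts — and attenuating
  the case effect by ≈ (1 − 2·0.21).  The preset produces the hallmark staging pattern:
  strictly decreasing stage-mean GSR (≈ 0.77 → 0.61 against controls at 0.79) and an
  increasingly prominent low-GSR mode.  Noise attenuation is also why slope recovery is
  defined on the low-noise configuration, not on this preset.

Bimodality is assessed by Ashman's D from a two-component Gaussian mixture fit
(D = √2·|μ1 − μ2|/√(σ1² + σ2²)); D > 2 indicates clearly separated modes.  On the preset,
controls sit near D ≈ 0.8 and stage IV near D ≈ 6.

What passing these tests shows — and does not.  The synthetic cohorts verify that the
scoring, ranking, classification and network machinery recover a known ordering
perturbation under Gaussian noise.  They do not establish performance on real tumor
cohorts, where probe effects, batch structure, correlated sets and non-Gaussian noise
intervene; headline accuracies from published multi-cohort analyses are therefore not
reproduced here and are out of the validation surface.

## Problem sizes used in validation

The default test run and the acceptance script use desk-scale inputs chosen as the
smallest sizes at which each property is stable: the staging preset (6000 genes × 180
samples × 200 sets), a low-noise clone of it for slope recovery, 10⁴ random samples for
null calibration, n = 2000–5000 for the MI estimator's closed-form checks, and 6-node
matrices for exhaustive DPI enumeration.

## Pipeline determinism

`gsr run` executes score → test → venn/progressive → classify/cluster → network with a
JSON manifest recording parameter and SHA-256 input/output hashes per stage.  Re-running
an identical configuration is a no-op; a corrupted artifact triggers re-execution of its
stage and everything downstream.  A single seed fixes fold assignments and every other
stochastic choice, making numeric outputs byte-identical across reruns.
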