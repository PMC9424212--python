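# Methods

## The colour-population model

A population is a named point **P** = (P₁, P₂, P₃) in [0,1]³ with a noise
scale N (an SD, default 0.01). An individual is drawn as

    x = P + R · N,   R ~ Normal(0, I₃)

so the three colour coordinates play the role of markers and the true
between-population geometry is the Euclidean geometry of the mean colours
(e.g. Red–Black = 1, Red–Green = √2). Two modelling choices deserve
comment:

- **Additive, not multiplicative, noise.** A multiplicative reading
  (Pᵢ·R·N) would pin every zero component at exactly zero, collapsing
  Black to a single point and making Red and Green indistinguishable on
  their shared zero coordinates; no scatter of distinct colour clouds
  could arise. The additive model is the only one consistent with the
  intended behaviour.
- **No clipping to [0,1].** Clipping would halve the noise on boundary
  components (all canonical colours sit on the cube surface) and bias
  every centroid inward by O(N); at N = 0.01 the excursions outside the
  cube are physically meaningless but statistically essential.

"Ancient" variants of a canonical colour set its nonzero components to
0.95 with SD 0.05 (brighter, more diverse); "modern" variants use 0.6 with
SD 0.02 (darker, tighter). The era SD applies to all three coordinates;
zero components stay zero.

**Seeding.** A cohort has one root seed; each member population draws from
a child seed obtained by hashing (member index, name) with BLAKE2b. This
makes cohorts bit-reproducible and — more importantly — *editable*:
appending a population never changes the draws of earlier ones, so
seed-sensitivity experiments vary exactly one thing.

## PCA conventions

Columns are centred by their means; no per-marker variance scaling is
applied by default (a `normalize` flag exists). Components come from the
SVD of the centred matrix; eigenvalues use the sample (n−1)
normalisation; r = min(n−1, p) components are retained. Each component's
sign is fixed by making its largest-magnitude loading positive — axis
flips carry no information, and all cross-run comparisons additionally go
through a Procrustes alignment that absorbs rotation, reflection and
scale. Explained variance is reported as a fraction and, for display, as
an integer percentage rounded half away from zero (8/9 → 89%).

Held-out samples are projected **one at a time**: the centring vector and
loadings are restricted to the sample's observed features and each
coordinate is rescaled by p/p_obs so that score magnitudes remain
comparable across samples with different missingness. The factor is
configurable (`rescale=False` gives the bare restricted projection). No
least-squares/shrinkage correction is applied; at the dimensionalities
used here (3–3600 features, no LD) projection shrinkage is not a relevant
regime.

Degenerate inputs: datasets with missing entries are refused by `PCA`
(collapse windows first); constant datasets yield all-zero eigenvalues and
explained fractions of zero.

## Distance distortion

For population centroids or seeded random individual pairs we record the
original-space Euclidean distance and the top-k score-space distance.
Two exact facts anchor the metrics: over all r components the distances
are equal (centring + orthonormal rotation is an isometry), and over
k < r components the score-space distance is never larger (truncation is
a contraction). Distances are computed on raw scores; the optional
min–max normalisation (each axis mapped to [0,1] independently) serves
x = y scatter comparisons. The "correctly projected" tolerance defaults
to 0.05. Configuration agreement between two runs is the Procrustes
disparity of their centroid configurations (0 = identical geometry).

## Cluster homogeneity

k-means (scikit-learn, squared-Euclidean, best of 20 restarts, seeded)
on the top two PCs with K = round(√n) (half away from zero, floor 1).
A cluster is homogeneous iff all members carry one population label.
Reported: % homogeneous clusters, % individuals inside them, mean sizes
of the two cluster classes with a Kruskal–Wallis test, and the number of
singleton clusters — singletons are vacuously homogeneous and inflate the
metric, so they are surfaced rather than hidden. K can be recomputed per
cohort or fixed across comparisons; both modes are supported via the `K`
argument.

## Windows, missingness, noise

Each colour component is replicated across a window of 200 features,
yielding 600 "SNPs"; recovery is the missing-aware mean over a
component's observed window features (a component with no observed
feature is missing in the output). Replication + mean, rather than
dividing the value across the window, keeps the per-feature structure
signal at the component scale, so recovery error under missingness
follows the 1/√(observed count) law. Missingness nullifies a uniformly
random set of exactly round(rate·n·p) entries and refuses configurations
that leave a sample with no observed feature.

Noise markers are i.i.d. uniform [0,1] features. They are appended to the
*component-scale* colour marker set: appending them to the replicated
600-SNP windows would be a vacuous test, because replication multiplies
the structure eigenvalues by the window size and no realistic number of
unit-scale noise markers can then compete. On the component scale the
registry's 30/300/3000 grid spans the retained → degraded → lost
transition of the population structure (measured as cluster homogeneity
against a random-relabeling envelope and as Procrustes retention). The
"low-level noise in all markers" scenario uses additive uniform noise of
configurable magnitude, default 0.1.

## Case–control stratification

The structured design mirrors a confounded study: one minority population
(default: the smallest) is placed entirely in the control arm; remaining
labels are drawn at random to reach evenly sized arms. Markers are
simulated as dosages ~ Binomial(2, f), where f starts from a base
frequency ~ U(0.2, 0.8) and is shifted along one colour channel by
`freq_spread` (default 0.6) times the population's deviation from the
cohort mean colour; causal markers additionally shift ±effect/2 (default
log-odds 1.0) on the logit scale between arms. Frequencies are clipped
into (0.01, 0.99) with a warning. Association is per-marker logistic
regression (statsmodels) with a Wald p-value; the unadjusted scan also
reports the Cochran–Armitage trend statistic as a model-free cross-check.
Markers with separation or non-convergence are flagged and excluded from
counts. PC covariates are recomputed per replicate from the simulated
marker panel itself — the standard practice of adjusting with ancestry
PCs of the genotyped markers (and the only construction under which a
10-PC adjustment is meaningful, since the colour matrix has rank ≤ 3).
"Weaker p-values" is operationalised as the median causal-marker p; the
adjusted-vs-unadjusted comparison across replicates uses a one-sided sign
test on true-positive counts.

## The scenario registry

Every in-scope synthetic scenario is a declarative `ExperimentSpec`
(cohort, stages, seed) keyed by its figure tag. Scenarios whose published
sample sizes or colours are stated only as ranges or sets carry
`ambiguous=True` plus a note describing the pinned assignment (e.g. the
fig10C/D size sets, the fig17B–D 10–300 ranges, a caption that assigns
Blue the coordinates of Red). Experiment bundles (TSV tables, manifest
with config + seed + version, optional true-colour scatter plot) are
byte-identical under a fixed seed. The driver accepts a uniform
sample-size `scale` factor; the test suite exercises the whole registry
at scale 0.12, and the properties asserted there (full homogeneity of
separated colours, retention under missingness, collapse under 3000 noise
markers, adjustment losing power) are scale-robust.

## What the generator does and does not emulate

The colour model captures: population structure as mean displacement in a
low-dimensional feature space, within-population diversity as isotropic
Gaussian noise, admixture as intermediate colours, heterogeneity as large
SDs, missingness, and uninformative markers. It does **not** emulate
allele-frequency spectra, LD between markers, drift/coalescent dynamics,
or genotype discreteness of the structure features; consequently, passing
tests certify the *geometric and statistical machinery* (what PCA, the
distance metrics, k-means and the association scans do to data with known
structure), not population-genetic realism. Real-dosage replication runs
through `pcaudit.genotype_io` on EIGENSTRAT/PLINK text exports (samples
with more than a configurable number of missing markers — default 5 —
are dropped), but no human datasets ship with, or are downloaded by, the
package.

## Numerical tolerances and problem sizes

Closed-form checks use 1e-12 (simplex eigenvalues), exact-arithmetic
identities 1e-10 – 1e-8 (orthonormality, rotation invariance,
reconstruction); stochastic checks use explicit standard-error budgets
(3–5 SE) or 99% binomial envelopes. Default test problem sizes — cohorts
of 50–300 samples, 600–3600 markers, 11–20 replicate seeds — were chosen
as the smallest sizes at which the asserted effects are comfortably
outside their sampling noise.
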