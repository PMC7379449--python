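# Methods

## Asymmetry-index features

For each of 13 left/right homologous region pairs, the feature is the
asymmetry index of the pair's mean uptakes,
`AI = 200·(L − R)/(L + R)`. The mean is the plain arithmetic mean over
labeled voxels — no trimming, no intensity normalization — because the
ratio cancels any common multiplicative factor exactly; this is the
property that makes AI-based lateralization independent of global count
normalization. AI is computed from the two pair means, never voxel-wise
and then averaged: the operations do not commute and the definition
acts on regional values. Feature columns are fixed to a canonical
region order for stable serialization.

Inputs must already be atlas-aligned: `load_volume` enforces an
affine match (absolute tolerance 1e-4 per element) and an identical
grid shape, and registration/normalization is out of scope. Hemisphere
membership is carried in the region table, not inferred from voxel
coordinates, so the pipeline is agnostic to RAS/LAS conventions.

Sign convention: positive AI means higher uptake on the left. Left-TLE
subjects therefore show negative temporal AIs, which is the convention
the reference rules encode (e.g. `AI[Hippocampus] ≤ 3.18 → Left`).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not PET physics. An atlas of 13 axis-aligned block pairs is placed
mirror-symmetrically about the midsagittal plane — geometry is
irrelevant because only region means enter the features. Per subject,
each affected pair's ipsilateral member is scaled by `1 − δ` (and the
contralateral member by `1 + g`, default `g = 0`), independent Gaussian
noise is added per voxel, and the whole volume is multiplied by one
global factor drawn from U(0.8, 1.2) — exactly the nuisance AI must
cancel. The closed form for the resulting AI is
`200·((1−δ) − (1+g)) / ((1−δ) + (1+g))`, i.e. `−200·δ/(2−δ)` on the
left for `g = 0`; δ = 0.06 gives −6.186.

Defaults define the study conditions: 49 subjects at 27 Left : 22
Right; planted reductions of 6% (hippocampus), 5% (parahippocampal
gyrus, amygdala), 4% (temporal poles), 3% (temporal gyri), 2%
(insula, thalamus, opercula, supramarginal gyrus), giving AI magnitudes
of about 2–6, the range implied by the reference thresholds; voxel
noise SD 10 counts on ~80–120-count baselines. A feature-table shortcut
draws AIs directly as Gaussians (SD 2.0) around the closed form, which
keeps replicate studies cheap; it shares the class-assignment logic
with the volume route. One `SeedSequence` per cohort is split per
subject by counter, so partial regeneration is reproducible.

What the generator does **not** emulate: scanner point-spread and
partial-volume effects, attenuation/reconstruction artifacts, anatomical
shape, inter-regional correlation of hypometabolism, or the heavy-tailed
heterogeneity of real patient effect sizes. Passing tests on this
generator therefore demonstrate correctness of the pipeline's
arithmetic and the classifiers' behavior under the assumed signal
model, not clinical performance on real cohorts.

## C4.5-style tree

Greedy top-down induction over binary numeric splits. Candidate
thresholds are midpoints between consecutive distinct sorted values
(an option reports the lower observed value instead; which convention
produced any given published threshold is not recoverable without the
original per-patient values). The split maximizes gain ratio
(information gain / split information), with ties broken toward the
lower feature index and lower threshold; growth stops at pure nodes or
below two instances per leaf. Pruning is bottom-up subtree replacement
using the pessimistic error estimate: the one-sided binomial upper
confidence limit on the error count at confidence 0.25 (the
conventional default), with ties favoring the pruned leaf. Leaf ties in
class counts resolve to Right so prediction is deterministic.

## Logistic model tree

Leaf models are additive logistic regressions fitted by two-class
LogitBoost with *simple* base learners: each iteration fits a weighted
least-squares line on every single feature (working response clamped at
±3, weights floored at 1e-10) and keeps the one with least weighted
SSE. Every base learner is linear in one feature, so the boosted score
collapses to a single linear function reported as antisymmetric
per-class scores; the class with the larger score is predicted, with
exact ties going to Right. The iteration count (cap 200) is chosen by
seeded internal 5-fold cross-validation, minimizing held-out
misclassifications with ties toward fewer iterations. Internal folds
are plain shuffled partitions rather than stratified ones so that
swapping the two labels negates the fitted model exactly.

A node is considered for splitting only when it holds at least
`min_split = 15` instances **and** its logistic model still
misclassifies training rows; the candidate split (gain-ratio criterion)
is kept only if it strictly reduces the same internal-CV error, with
child models warm-started from the parent score and their iteration
counts frozen during the comparison. On cohorts of a few dozen subjects
the leaf model virtually always wins, so training returns a single
root linear score — the regime in which a logistic model tree and a
boosted simple logistic regression coincide, and the regime all the
published reference models exhibit. No attempt is made to reproduce the
reference models' exact coefficients: they depend on a specific
implementation's internals and on unavailable patient data.

## Evaluation

Holdout splits are uniform random permutations honoring the requested
train fraction to rounding. k-fold assignment is a shuffled
within-class round-robin with the fold pointer carried across classes,
which yields fold sizes differing by at most one and per-fold class
ratios as even as integer arithmetic allows (49 subjects into 5 folds
gives four folds of 10 and one of 9). The fold partition is asserted on
every run. `CrossValResult.mean_ratio` is the pooled ratio (total
correct / cohort size); the average of per-run ratios is exposed
separately since both conventions appear in practice and agree at these
fold sizes.

Cohen's kappa is computed from the agreement table:
`κ = (p_o − p_e)/(1 − p_e)` with chance agreement from marginal
products. Significance uses the null-hypothesis standard error
`SE₀ = sqrt(p_e + p_e² − Σᵢ p_{i+} p_{+i}(p_{i+} + p_{+i})) / ((1−p_e)√n)`
and `z = κ/SE₀` referred to a standard normal, two-sided; this
statistic reproduces the reference report's printed values to three
decimals and is cross-checked against statsmodels in the tests.
Degenerate marginals (`p_e = 1`) raise rather than return a value. A
"No lateralization" token in a prediction column is representable and
always counted as incorrect by `correct_ratio`.

## Numerical and design notes

- AI requires strictly positive means; zero or negative region means
  raise, since PET counts are positive and the denominator must not
  vanish.
- All training is deterministic given its inputs and the explicit
  `random_state`; generator cohorts are bit-identical under a fixed
  seed.
- Models serialize to a versioned JSON schema; parsing validates
  feature names against the canonical region list, and round-tripping
  reproduces predictions exactly.
- Problem sizes in the test suite and acceptance script (cohorts of
  49, 20 replicates, 800-subject calibration draws) were chosen to make
  Monte-Carlo error small relative to the assertions while keeping a
  default run fast on one CPU.

## Known limitations

Binary classes only; missing feature values are rejected rather than
imputed; no ROC analysis or reader-comparison statistics beyond kappa;
the synthetic generator's independence assumptions (between regions and
between subjects) are optimistic relative to real FDG-PET cohorts.
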