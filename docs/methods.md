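# Methods

This note documents the models implemented in `chronolex`, the
assumptions behind them, the parameters that matter, and what the
synthetic-data studies do and do not establish.

## Representational similarity analysis

All comparisons operate on representational similarity matrices (RSMs):
symmetric word-by-word similarity matrices over a shared, lexically
sorted vocabulary. Two RSMs are compared by Spearman rank correlation of
their strict upper triangles (row-major, `v(v−1)/2` cells), with average
ranks for ties. Working at this second order abstracts away from the
incommensurable raw formats (vectors, cue–response counts, Likert
ratings) and makes the comparison invariant to any monotone transform of
either side's similarity scale. Degenerate cases (constant cell vectors,
as arise under permutation shuffles) are returned as flagged results
rather than errors.

Split-half reliability partitions *participants* — never individual
records — into random halves, rebuilds the measure per half, and averages
the half-vs-half correlation over splits (the split count is a parameter;
5 and 100 are both conventional depending on data volume). Participant-
level splitting prevents within-participant leakage and makes the
statistic an honest upper bound on any cross-source correlation.
Inter-annotator agreement is each rater's Spearman correlation with the
item-wise mean of all other raters on shared items (raters with fewer
than three shared items are skipped with a warning), averaged per cohort.

The temporal permutation test asks whether RSM similarity between
decades decays with their temporal distance. The statistic is the
Spearman correlation between `|decade_i − decade_j|` and representational
divergence (the negative of the pairwise RSA), so decaying similarity
yields a positive value. The null distribution shuffles decade labels
and recomputes; the central 95% interval uses the empirical 2.5/97.5
percentiles. Fewer than ~100 permutations triggers an instability
warning.

## Embedding spaces and alignment

Per-decade embeddings are consumed, never trained, in the word2vec text
dialect (optional `n d` header; one `word v1 … vd` line per word). Stored
vectors are not re-normalized on load — normalization happens inside the
cosine computations — and zero-norm vectors are an error wherever a
cosine is requested, named per word.

Independently trained decade spaces differ by an arbitrary orthogonal
transform, so each decade is mapped onto a reference decade (default:
the latest) by orthogonal Procrustes — the rotation minimizing the
Frobenius distance, computed from the SVD closed form via
`scipy.linalg.orthogonal_procrustes`. Alignment is direct-to-reference
rather than chained decade-to-decade, which keeps every pair of decades
comparable and avoids accumulating alignment error. After alignment, the
cosine between a word's vectors in two decades (its *self-similarity*)
measures how much its dominant usage changed.

## Association-network similarity

Cue–response records (participant age, cue, response, response index
1–3) are aggregated per age cohort into a directed count matrix; all
three response positions weigh equally, and cohort windows are half-open
`[min, max)` so adjacent cohorts partition the age axis. Cues with fewer
than 15 responses in a cohort are dropped (inclusive threshold, applied
once); words appearing only as responses are kept as columns (features)
with zero out-rows.

Similarity follows the standard association-network chain: PPMI
(`max(0, log2 p_ij / (p_i p_j))`, marginals from the matrix itself, zero
cells preserved), row normalization into a transition matrix `P`, the
decaying Katz walk `Σ_{k≥0} α^k P^k = (I − αP)^{-1}` adding discounted
indirect paths, a second PPMI pass (same implementation for both
passes), renormalization to conditional probabilities, and cosine
between rows. Row-stochastic `P` has spectral radius ≤ 1, so any
`α < 1` keeps the series summable. The decay `α` defaults to 0.75 but is
deliberately exposed: no principled value exists for arbitrary data, and
downstream correlations are mildly sensitive to it.

## Weighting hypotheses

A cohort's semantic space is modelled as a convex combination of decade
RSMs with geometric weights `base^x` (base 0.5, normalized to sum 1),
where `x` counts decades from the favored end (the favored decade gets
`base^0 = 1`; normalization makes any common offset irrelevant). Three
schemes are compared: *early* (non-increasing weights over time),
*uniform*, and *recent* (non-decreasing). `hypothesis_rsa` builds all
three combinations — over the full decade axis by default, or restricted
to a cohort's experienced decades — scores each against a behavioral RSM,
and reports every argmax label on an exact tie rather than breaking it
silently.

Default cohort exposure windows map a 20–35 / 35–50 / 50–90 age split
observed at the end of a ten-decade axis: the youngest cohort has
experienced the last 4 decades, the middle the last 6, the oldest all 10.

## Ablation models

**Gaussian family.** A cohort RSM's upper-triangle cells are regressed on
the corresponding cells of every decade RSM (OLS with intercept). Each
decade column is ablated in turn; per fold of a 5-fold CV, the full and
ablated models are fit on the training portion and scored on the held-out
portion by Gaussian log-likelihood (training-fit residual scale), R²
around the held-out mean, and AIC computed from the held-out likelihood
with parameter count `k + 2` (slopes + intercept + residual scale).
Reported deltas average over folds and are oriented so positive always
means the ablated model is worse. A nested extra-sum-of-squares F-test on
the full data accompanies each ablation; the ten per-decade p-values are
reported uncorrected.

**Ordinal family.** Ratings on the 0–6 scale are modelled with a
maximum-likelihood cumulative-logit proportional-odds fit (statsmodels
`OrderedModel`; monotone thresholds via log-difference
reparameterization; BFGS, gradient tolerance 1e-8, max 500 iterations;
non-convergence is flagged, not raised). With exactly two observed
levels the model reduces to plain logistic regression with one cutpoint.
Decade impact is the k-fold (stratified by response level) expected log
predictive density difference, ablated minus full; the standard error
treats fold sums as replicates by default, with a pointwise variant also
reported, and |ΔELPD| < 4 is flagged negligible per the usual rule of
thumb. This maximum-likelihood + k-fold machinery deliberately replaces
fully Bayesian multilevel estimation (random subject/pair effects,
posterior intervals, PSIS-LOO): the questions asked here are about
predictive contribution of decades, for which fixed-effects ML with
held-out predictive density is the appropriate lighter-weight tool.
Repeated-measures structure can be approximated with subject fixed
offsets where needed.

The factorial rating model crosses age group (effect-coded ±0.5, so main
effects are level differences), meaning change (effect-coded ±0.5), and
pair type (dummy-coded against the non-neighbor reference). The contrast
table reports latent-scale marginal means per (change, pair-type) cell
averaged over age, the pairwise neighbor contrasts, and the between-age
difference of the 1950s-vs-1990s gap — the key test of whether older
cohorts weight historical meanings differently — with delta-method Wald
standard errors and 95% intervals.

## Stimulus construction

Words are classified *changed* / *unchanged* by their aligned 1950↔1990
self-cosine against a 0.35 threshold with strict inequalities; a word
exactly at the threshold is excluded with a warning rather than binned.
Changed targets are ranked by ascending self-similarity (most changed
first), unchanged by descending; an optional log-frequency window filters
candidates when frequency covariates are supplied (they are accepted,
never computed). Each target gets its 10 nearest cosine neighbors from
each of the two decades (exact ties broken lexicographically for
determinism) and 10 uniform samples from the vocabulary minus the 20
selected neighbors minus itself.

The counterbalance builder deals each target into `k` lists (one partner
of each type per appearance, cycling through partners), so 300 targets ×
10 appearances fill 120 lists of 25 targets / 75 pairs with 12 or 13
changed targets each and every pair covered by at least one list;
incompatible list counts raise with the slot deficit. Rating hygiene:
participants are kept only with a perfect 5/5 catch score and duration
strictly greater than 4 minutes; duplicated unordered pairs (a partner
shared by both neighbor lists) collapse to one pair key with the
first-listed pair type winning; and ratings are subsampled, seeded, to
exactly 5 per cohort per pair (error or drop-with-warning on
under-sampled pairs, per configuration).

## Synthetic data

The generators exist so the full chain runs with known ground truth.

**Drift.** Word vectors live on the unit sphere. A *cumulative* latent
walk carries genuine change: decade-0 vectors are isotropic Gaussian
directions; each step adds Gaussian jitter (scale σ) and, for the planted
changed class, a pull at rate r toward a fresh random anchor, then
re-normalizes. Each decade's *observed* vectors add non-cumulative
observation noise (scale τ) standing in for decade-specific corpus
sampling variability — without it, consecutive decade similarity spaces
correlate far more than decade-trained embedding spaces do. Three
anchors drive calibration by 1-D root-finding on fixed-inner-seed
Monte-Carlo expectations (alternated to a fixed point, tolerance well
under ±0.01 on the expectation): observed first↔last cosine 0.71 for
unchanged words (sets σ given τ), adjacent-decade RSM Spearman 0.70
(sets τ given σ), and observed first↔last cosine 0.21 for changed words
(sets r). With default dimensions (d = 50) the calibrated generator
reproduces all three anchors and a monotone distance-decay gradient in
inter-decade RSM correlations. Passing `base_drift_sd` explicitly
bypasses calibration entirely (observation noise then defaults to 0, so
`base_drift_sd=0` yields literally identical decades).

**Cohorts, associations, ratings.** A cohort RSM is the
hypothesis-weighted mean of its experienced decades' RSMs plus symmetric
cellwise Gaussian noise (diagonal reset to 1). Association responses are
sampled per synthetic participant as three distinct responses per cue,
probability ∝ `exp(similarity / temperature)` over non-cue words (Gumbel
top-k; temperature 0.15 by default — a modelling convenience with no
empirical counterpart, exposed as a parameter). Ratings pass an affine
map of planted similarity (slope 3, intercept 0, mapping cosine −1…1
across the threshold grid) plus Gaussian latent noise through six
ordered thresholds; generated keepers carry perfect catch scores and
plausible durations, and violator participants can be planted to
exercise the cleaning filters. Ages are uniform within cohort windows,
since cohort membership, not age itself, drives every analysis.

**What passing tests show.** The synthetic data are isotropic, with no
Zipfian frequency structure, no polysemy, no response chaining, no rater
idiosyncrasies beyond i.i.d. noise, and drift that is homogeneous within
each planted class. Recovery and calibration results therefore establish
that the pipeline is correct and sensitive under its own assumptions —
not that real association or rating data satisfy those assumptions.

## Study sizes and numerical choices

The reproducibility studies (`chronolex.evaluation`, driven by
`scripts/acceptance.py` and the end-to-end tests) use sizes chosen for
stable rates on one CPU in minutes: hypothesis recovery over 50 seeds ×
3 cohorts × 3 hypotheses at 100 words / 10 decades / cell noise 0.05;
pattern checks over 50 seeds; 100 random cases for each numerical oracle
(walk decay sampled in 0.1–0.6 so the 50-term series is converged far
beyond the 1e-8 comparison tolerance); 100 planted-signal and 1000 null
ablation runs at 25-word RSMs (300 cells); ordinal recovery at
n = 20,000; ELPD calibration over 20 runs at n = 2,500 with a planted
slope of 2; the stimulus audit at full scale (450-word pool, 200 planted
changed, 5 decades spanning 1950–1990, 120 lists). RSM symmetry is
enforced within 1e-8, row normalization within 1e-12, and weight vectors
within 1e-12 of unit sum.

## Known limitations

- The proportional-odds stand-in ignores random-effect structure;
  standard errors on real repeated-measures data will be optimistic.
- The Katz decay α and softmax temperature have no data-derived values.
- Calibration anchors bind the *means* of the planted classes; their
  spread is emergent, not controlled.
- The counterbalance dealer requires target × appearance counts to
  divide evenly into lists; ragged designs are rejected rather than
  approximated.
- Association similarity assigns zero similarity to words with empty
  final-stage profiles (response-only words) rather than excluding them.
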