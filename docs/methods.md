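# Methods

This note documents the statistical procedures `facebench` implements, the
generative model behind its synthetic data, the numerical choices that were
genuinely open, and what the package's tests do and do not establish about
real data.

## Task and data model

The unit of data is a 2AFC trial: an image from one of two categories is
shown, the observer answers with one of the two categories. A trial table
(one row per trial: subject, pool, image, true category, response,
session) is the substrate for every statistic; no-choice trials are
assumed excluded upstream. Analyses pool trials across the subjects of a
pool; subject identity is used only by the exclusion rules (below) and
optional per-subject breakdowns.

## Per-image sensitivity and i1n

For image *j* with hit rate `HR_j` and category false-alarm rate `FA_j`
(trials of the other category answered with *j*'s category),
`d'_j = z(HR_j) − z(FA_j)`. Two consequences of the shared false-alarm
pool are worth keeping in mind:

- Within a category, i1 differences are driven entirely by hit rates.
- Each image's estimated d' splits its latent signal between its own
  hit-rate term and the category-level FA term, so the per-image estimator
  has expectation ≈ `d_j/2 + (mean latent d of the category)/2` rather
  than `d_j` when difficulty varies across images. This is a property of
  the estimator, not a bug; correlation-based comparisons (i1n, R_nc) are
  unaffected because the transform is affine within category, and
  condition means are unaffected because the halves recombine.

Empirical rates of exactly 0 or 1 are clipped to `1/(2N)` and `1 − 1/(2N)`
with `N` the relevant denominator, keeping d' finite and monotone in the
counts; the clip activates only at the extremes. Images whose category has
an empty false-alarm pool are flagged unscorable (NaN) rather than
dropped. i1n subtracts each category's mean d' over scorable images; in
per-condition analyses, both d' (including FA pools) and the i1n
normalization are recomputed within the analyzed image subset.

## Lapse rate

The lapse rate is the cross-validated error rate of the best image:
trials are split in half (stratified per image), the image with the
highest accuracy in one half (ties → more trials, then lexicographic id)
is scored in the other half, both directions are used, and the estimate
averages 50 random partitions by default (a single split is unbiased but
noisy). The measured floor equals the true lapse rate only when the best
image is genuinely perfect; otherwise it includes that image's residual
perceptual error and overestimates λ (visible in pools whose difficulty
distribution keeps every image off ceiling). Two correction models are
offered: `always_wrong` (default; the floor is λ itself, corrected
accuracy `p/(1−λ)`) and `guess` (lapses are coin flips; the floor is λ/2,
corrected accuracy `(p − λ*/2)/(1 − λ*)` with `λ* = 2·floor`). Results are
clamped to [0, 1]. Which model a given dataset warrants is not decidable
from the floor measurement alone; both are exact inverses of their own
generative assumptions.

## Split-half noise-corrected correlation

Per random partition, each pool's trials are split in half stratified by
image; i1n is computed per half; the cross-system correlation is
`½(r(V_a0,V_b1) + r(V_a1,V_b0))` and each system's internal consistency is
its own half-to-half correlation. Components are averaged over partitions
(default 100) before the ceiling is applied. The default ceiling is the
geometric mean `√(r_a · r_b)` — the standard attenuation correction; a
`√(r_a + r_b)` variant (`printed_sum`) is provided because that form also
circulates, and both are reported. A non-positive ceiling yields an NaN
R_nc with a warning rather than an error. Images unscorable in any half of
either pool in a partition are dropped pairwise for that partition.

Implementation: for a 2AFC table a stratified half-split is fully
summarized by per-image (n, k) counts, and the random alternate-assignment
split induces exactly a hypergeometric draw of per-half corrects. The
partition loop therefore runs vectorized on count arrays — distributionally
identical to physically splitting the table, and what makes averaging 100
partitions over hundreds of thousands of trials cheap. The same partition
seed drives both pools' splits, so identical input tables give R_nc = 1
exactly. A consequence of seeded per-image draws is that relabeling image
ids permutes the random-stream alignment: R_nc is invariant under
relabeling in distribution, not bit-for-bit.

## Condition effects

The canonical conditions are upright ≔ (upright, lit from above),
inverted ≔ (inverted, lit from below — the light source stays overhead in
world coordinates), and contrast-reversed ≔ (upright, reversed polarity);
token images belong to no condition. An effect is the difference of mean
per-image d' between two conditions, each computed with condition-restricted
FA pools. Uncertainty comes from an image-subsampling bootstrap: each
replicate draws `subsample_k` images (default 25 of 50) from each condition
without replacement and recomputes the mean d' over the drawn images,
re-tallying the FA pools from the drawn images of the other category. The
re-tally matters: freezing the FA pools would hide the half of each
image's latent variance that lives in the category term and roughly halve
the CI width (measured 95% CI coverage drops from ~96% to ~70% for
injected effects). 95% CIs are the 2.5/97.5 percentiles. Subsampling half
the images without replacement gives a replicate variance of `σ²/49` per
condition against an estimator variance of `σ²/50` — the classic
half-sampling approximation. Draws that land entirely in one category
(possible for small conditions) are redrawn. Each condition's subsample
stream is seeded by (seed, condition label), which makes
`effect_size(a, b)` and `effect_size(b, a)` exact mirror images.

Two effect-comparison methods are labeled explicitly: `percentile_diff`
(default; two-sided sign-crossing p from the bootstrap distribution of the
difference of deltas, replicates paired by index) and `welch_boot` (a
Welch t over the replicate arrays — descriptive only, since bootstrap
replicates are not independent observations; a warning says so).

## Linear-readout model observer

The decoder consumes plain per-image feature matrices (no network weights
ship with the package). Per resample (default 100, up to 1000 for
production runs), `n_train_per_class` images are drawn without replacement,
features are standardized per dimension with training-fold statistics only,
and a hinge-loss, L2-regularized linear SVM (`LinearSVC`, C default 1.0,
tol 1e-3) is fit; test margins are signed distances to the hyperplane
oriented so positive = correct side. Accuracy is the fraction of positive
oriented margins, so margin signs and accuracy agree exactly by
construction. Per-image margins are averaged across all resamples
(single-fit available); category-mean subtraction yields a model i1n.
Because of the training-fold standardization, margins are invariant to a
global rescaling of the feature space — and, like raw distances, they are
not calibrated in d' units across feature spaces; only their image-level
pattern is meant to be compared. The learning curve reports one result per
training-set size and the smallest size within 0.005 of the maximum
accuracy (the saturation point).

## Synthetic data: what it emulates, and what it does not

`generate_stimulus_set` reproduces the stimulus bookkeeping: 2 categories
× 6 contexts (2 orientations × 3 lighting contexts) × 25 images, plus one
frontal, upright, background-free token per category — 302 images — with
latent size (4.5–9° visual angle), horizontal rotation (−90° to +90°), and
vertical rotation (−45° to +45°) drawn i.i.d. uniform, and one of 10
background ids. Metadata only; no pixels are rendered. Display-geometry
differences between setups (e.g. ~20° full-image size on a touchscreen vs
4–12° estimated on a desktop) are deliberately not modeled.

Observers have a latent per-image d' mapped to accuracy by
`p_true = Φ(d'/2)` (symmetric criterion), so the downstream estimator
recovers latent d' in expectation for homogeneous difficulty; lapses occur
with probability λ and respond independently of the image, parameterized
by the probability a lapse is scored correct (0 = always-wrong, 0.5 =
coin flip) and a category-A response bias. Observed per-image accuracy is
`(1−λ)p_true + λ·lapse_guess_correct`. Linked pools draw per-image latent
pairs from a bivariate normal; condition deficits are additive latent
shifts per (orientation, lighting) context, combining additively for
doubly-deviant contexts. When deterministic shift patterns are shared
between pools they themselves induce image-level correlation, so the
generator can alternatively take the *total* category-centered latent
correlation as the target and solve for the image-specific component
analytically (`rho_is_total=True`).

Defaults chosen once and used throughout the recovery tests: latent mean
d' 1.5 and spread 0.4 (accuracy mostly 0.6–0.9, the estimator's
near-linear range), 200 trials per image for reliability/effect studies.
The end-to-end demo uses a high-sensitivity pool (mean 3.2, spread 0.4,
inversion −0.9, reversal −0.4) and a lower-sensitivity pool (mean 1.8,
spread 0.3, inversion −0.31, reversal −0.6), 2% lapses, total latent i1n
correlation 0.4, 4 subjects per pool, ~37 presentations per image per
subject. The narrower spreads keep the 25-image subsample CIs well below
the smallest injected effect; a consequence is that the demo's
lower-sensitivity pool has no near-ceiling image, so its measured lapse
floor overestimates λ and the corrected accuracy overshoots — the raw
accuracy is the number to compare against the configured ~0.78.

What passing tests show: the estimators invert their own generative
assumptions at realistic scale — d' matches an independent quantile
oracle, R_nc recovers latent correlations within ±0.07 across ρ ∈ {0,
0.4, 0.8, 1}, effect CIs attain 93–97% coverage for injected deficits,
lapse recovery is within ±0.005 under the always-wrong model. What they do
not show: real observers are not binomial with stationary per-image
accuracy (session drift, serial dependence, stimulus-independent response
biases beyond lapses), real lapse processes are not cleanly always-wrong
or coin-flip, and real feature representations are not isotropic Gaussian
clouds. Estimates on real data inherit those caveats.

## Pipeline, exclusions, determinism

Subject exclusion follows two rules: fewer than `min_trials` (default 20)
trials, or near-chance performance — by default a one-sided binomial test
of accuracy > 0.5 at α = 0.05 (a fixed 0.55 threshold mode exists because
"near chance" admits either reading). Excluding every subject is an error.
The `report` pipeline runs metrics → lapse → conditions → effects →
reliability (→ decoder when features are configured), records every seed,
count, and mode flag in the JSON report, and is byte-identical across
reruns of the same config (the output directory is excluded from the
echoed provenance for that reason). All randomness everywhere descends
from explicit integer seeds via `numpy.random.SeedSequence`; no global
state is touched.

Problem sizes in the shipped tests and acceptance script (302 or 300
images, 150–200 trials per image, 20 recovery replicates, 500 coverage
replicates, 100-partition split-halves, 100-resample decoders) were chosen
as the smallest scales at which the recovery tolerances above are
comfortably met; all complete in a few minutes on one CPU.
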