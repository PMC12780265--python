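# Methods

This note documents the models implemented in `histoprog`, the synthetic
data they are exercised on, and the numerical and design choices a
maintainer would want spelled out. It states no empirical result that the
test suite does not itself compute.

## The reasoning-oriented scale

The scale (`histoprog.reasoning`) maps the nine clinically occurring
Gleason pattern pairs to base grades 2–10 in the order
3+3, 3+4, 4+3, 4+4, 3+5, 4+5, 5+3, 5+4, 5+5. Two properties are
deliberate and must not be "fixed":

* it separates pairs that share a Gleason score (3+4 vs 4+3, and the three
  score-8 pairs), and
* it is **not monotone in the Gleason score** — 5+3 (score 8) ranks above
  4+5 (score 9) — reflecting the prognostic reading of a dominant
  pattern-5 component.

Any other (score, primary, secondary) triple raises: the scale is a total
function on exactly nine inputs. During training each sample's base grade
is shifted +1 if it later recurred and −1 otherwise (range 1–11). The
shift encodes outcome information *into the regression target only*; the
fitted model predicts the shifted grade from histology and never sees the
outcome at inference. Leakage guards enforce this: any design table
containing a `bcr` column is rejected at both fit and predict time, and
the cross-validation driver asserts patient-id disjointness between
training and test folds.

Scores are scaled to [0, 1] by their **theoretical** range ((s−1)/10 for
the reasoning scale, (g−6)/4 for the Gleason score), not the empirical
min/max, so the scaler is independent of the training sample and stable
under external validation. The Gleason comparison target is the numeric
score 6–10 rather than grade groups.

## Intermediate regression

`IntermediateScoreModel` fits ridge regression
min ‖y − Xw − b‖² + λ‖w‖² of the scaled grade on composition vectors.
λ is selected from a log-spaced grid 10⁻³…10³ (7 points) by 5-fold
shuffled cross-validated MSE, ties going to the smaller penalty; the model
is then refitted on all samples. Predictions are reported on the scaled
axis, back-mapped to the native grade, and additionally clipped to the
scale for display — ranking uses the unclipped values.

## Final BCR models and recalibration

`BcrModel` fits ordinary least squares of the binary 5-year label on one
of five designs (Gleason only; all k compositions; predicted Gleason;
predicted reasoning score; PSA + predicted reasoning score). PSA enters
untransformed by default, with a log option. When the all-compositions
design has n ≤ k the fit falls back to ridge with λ = 1.

The raw linear score is used for discrimination. For probability metrics a
logistic recalibration p = logistic(a + b·score) is fitted on training
data by maximum likelihood (statsmodels Newton; a weakly regularised fit
is the fallback under perfect separation). Both intercept+slope (default)
and intercept-only updating are provided. The MLE score equation makes the
mean recalibrated training probability equal the observed incidence, which
the tests assert to 10⁻⁶. A constant design degenerates gracefully to the
incidence-probability model.

One subtlety: on training data the linear fit itself minimises the Brier
score (it is least squares on a 0/1 target), so the likelihood-fitted
recalibration may trail the clipped raw score's Brier by a vanishing
margin (~10⁻⁶); the suite checks the recalibrated Brier is no worse than
the clipped raw score's by more than 10⁻³, as a gross-failure guard.

## Visual codebook

The default patch embedding is a 20-dimensional handcrafted descriptor:
per-channel mean and standard deviation (6), a magnitude-weighted
gradient-orientation histogram over 8 bins (zero for constant patches),
and 6 radial bins of the grey-level power spectrum (DC removed,
L1-normalised). A supervised variant appends the coordinate of a linear
discriminant trained on patch-level outcome labels — a miniature of
learning a penultimate representation under outcome supervision. Any
callable with a declared dimensionality can replace it.

The codebook is k-means++ (best of 4 restarts) with k = 100 by default;
k is fully configurable and the tests run at k = 10. Assignment is
nearest-centroid under the Euclidean metric with ties broken toward the
lowest cluster index — both conventions pinned for reproducibility.
Impact scores use the smoothed positive fraction
(n⁺ + s)/(n⁺ + n⁻ + 2s) with s = 1 by default (0.5 neutral; strictly
interior for s > 0), and features render at size |0.5 − impact| + 2.5.
Composition vectors tally **tissue patches only**: the HSV background rule
(saturation > 0.08, value < 0.95, stained fraction > 0.5) is applied
before normalisation. Overlapping inference-time patches are tallied as
drawn, without deduplication.

## Tiling conventions

Patch origins lie on the stride lattice with right/bottom remainders
dropped (no padding); coordinates are 0-based half-open intervals. Stride
= patch size gives the non-overlapping training convention; stride < patch
size the overlapping inference convention. The source imagery gives no
physical pixel size, so the default 128 px patch (32 px for synthetic
slides) is a configuration knob, logged in each run manifest, with
magnification treated as metadata.

## Synthetic data: what it emulates and what it does not

`histoprog.synthetic` generates cohorts with the structure the pipeline
needs: Gleason pairs drawn over the nine combinations (defaults weighted
toward 6–7 disease: 0.28, 0.25, 0.17, 0.10, 0.04, 0.08, 0.02, 0.04,
0.02), log-normal PSA (median 9 ng/mL, σ = 0.55), a latent histologic
signal h ~ N(0, 1), and outcome
BCR ~ Bernoulli(logistic(β₀ + 0.3·base + 0.7·log PSA + 1.6·h)), with β₀
solved so the prevalence is ≈ 0.45 at mean covariates. Patch compositions
follow Dirichlet(c·softmax(h·L_imp + g̃·L_grade + δ)) with concentration
c = 500, loadings of amplitude 0.7 on disjoint cluster blocks (first/last
fifth for the hidden signal, adjacent fifths for the centred grade g̃),
and 500–1000 patches per sample drawn multinomially. The effect sizes
were chosen so Gleason alone is moderately prognostic while the hidden
signal carries substantial extra risk information recoverable from
composition — the premise that same-grade patients differ in risk — and
the per-cluster signal stands clear of Dirichlet/multinomial sampling
noise at desk scale (the clinical setting has millions of patches per
sample, i.e. negligible tallying noise).

The external-institution shift multiplies the concentration by 0.7, adds
a fixed centred log-weight offset (0.15 on every third cluster) and
offsets the rendered stain channels — marginal statistics move, the
outcome mechanism does not, so a well-specified pipeline should transfer.

Slides render each patch as an oriented sinusoidal grating on an
orientation × frequency × colour-mix grid between haematoxylin- and
eosin-like stains, on a near-square grid in seeded random order with a
ground-truth patch table. This supports testing tiling, background
removal, embedding separability and composition recovery. It does **not**
emulate nuclear morphology, stain physics, spatial correlation between
neighbouring patches, PSA-trajectory ascertainment of recurrence, or
censoring — so green tests demonstrate pipeline correctness and
transfer-under-shift on data with these statistics, not clinical
performance.

All randomness descends from one integer seed via a documented
stream-splitting rule (`histoprog._seeds`): stage labels are CRC-32
hashed into the entropy of a `numpy SeedSequence`, giving independent,
reproducible streams per stage; derived seeds stay below 2³¹.

## Evaluation protocol

AUROC is the Mann–Whitney probability with ties at ½. Bootstrap CIs are
patient-level percentile intervals (10,000 resamples by default; tests
and the demo use fewer); resamples missing an outcome class are redrawn
rather than skipped, keeping the resample count exact at negligible bias
for the cohort sizes used. Internal validation is stratified 3-fold CV
(stratification guards against class-empty folds at small n) with every
learning stage — intermediate regressor, final model, recalibration —
refitted inside each training fold and pooled out-of-fold predictions
evaluated. External validation fits once on the training cohort and
applies the bundle unchanged. Calibration tables use equal-width bins
(10 by default; the published choice of binning is not stated), empty
bins omitted. Decision curves use the threshold grid 0.05–0.60 in steps
of 0.05 as the clinically relevant range. Fisher's exact test is two-sided
under the minimum-likelihood rule; the rank-sum test enumerates exactly
(with midranks) for total n ≤ 10 and otherwise uses the
continuity-corrected normal approximation.

## Problem sizes

The default study simulates 170 training and 71 + 39 external patients at
k = 100 clusters with 500–1000 patches per sample — matching the cohort
geometry the pipeline is designed for. Unit and acceptance tests run at
k = 6–20 with 30–170 patients, 25 simulation replicates for the
cross-study ordering check, and reduced bootstrap counts; these sizes were
chosen so the full suite exercises every path at interactive speed while
keeping Monte-Carlo margins comfortable.

## Known limitations

* The handcrafted descriptor separates procedural textures, not real
  histology; on real slides a learned embedding should be plugged in via
  `EmbeddingBackend`.
* The impact-score definition (smoothed positive-patch fraction) fixes a
  scale with 0.5 neutral consistent with the display-size formula; other
  definitions satisfying the same contract exist.
* Intercept+slope recalibration is the default; intercept-only updating
  is available but the published choice between them is not stated.
* Whether score scaling used theoretical or empirical ranges upstream is
  unstated; the theoretical choice here is the externally stable one.
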