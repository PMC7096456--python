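# Methods

## Model and workflow

`mdwfuse` combines L independently calibrated sensors into one quantitative
prediction. The workflow per sensor is:

1. **Autoscaling.** Every wavenumber column is standardized to zero mean and
   unit variance using calibration-set statistics (SD with denominator
   n−1). Autoscaling gives all variables equal a-priori weight regardless
   of absolute absorbance. A zero-variance column is a hard error: flooring
   its SD would inject an arbitrary, silently huge weight into the
   regression. Callers who want the permissive behaviour can drop constant
   columns explicitly (`--drop-constant-columns` in the CLI).
2. **PLS1 by NIPALS, X-deflation only.** Deterministic, no random element;
   refitting identical input reproduces coefficients exactly. The
   calibration score matrix T (n_cal × k) falls out of the decomposition
   and satisfies T = X_c R with the rotation matrix R = W(PᵀW)⁻¹, so new
   samples are projected by the same linear map that generated the
   calibration scores — projection of the calibration matrix reproduces T
   to machine precision. With all feasible components retained, PLS1
   reproduces the least-squares solution; the tests use that limit (and
   scikit-learn's PLSRegression) as independent oracles.
3. **LV selection.** k-fold cross-validation (default 5). Folds are
   venetian blinds over the concentration-ordered calibration samples
   (position i → fold i mod k): deterministic, and every fold spans the
   concentration range. RMSECV(k) = √(Σ held-out squared errors / n). Ties
   within 1e-12 of the minimum resolve to the smallest count; an optional
   parsimony tolerance (`lv_parsimony_tol`, off by default) accepts the
   smallest k within (1+tol)·min. When a fold's training matrix runs out of
   rank before `max_lv` components, predictions for larger k reuse the last
   available component set, so the RMSECV curve flattens rather than
   truncating.
4. **Mahalanobis distance (MD) in score space.** D(x) = √((s−s̄)ᵀC⁻¹(s−s̄))
   with s̄, C the mean and (n−1)-covariance of the calibration scores.
   Score space (a few dimensions, well-conditioned) is used instead of
   wavenumber space precisely because the spectral covariance is singular.
   The covariance is solved by Cholesky factorization; if its condition
   number exceeds 1e12 the pseudo-inverse is used and a warning issued.
   Calibration distances are computed leave-in (each calibration sample
   against the full calibration covariance); the distinction from
   leave-one-out is immaterial at n_cal ≫ k and leave-in matches how the
   threshold is consumed.
5. **Threshold and weights.** The applicability threshold per sensor is
   3 × mean of the calibration samples' own distances. Per validation
   sample, sensors with D ≤ threshold (inclusive: only strict exceedance
   excludes) receive raw weight 1/max(D, 1e-12); raw weights are normalized
   to sum to 1; excluded sensors get exactly 0. The ε-cap means a
   zero-distance sensor dominates with weight ≈ 1, which is the correct
   limit. If *every* sensor exceeds its threshold, the sample is flagged as
   extrapolation and the weights fall back to normalized reciprocal
   distances over all sensors — the pipeline always emits a prediction, and
   the flag surfaces the caveat. A `weight_power` option (default 1)
   exposes 1/D^p for users who prefer squared-distance weighting.
6. **Fusion and evaluation.** y_fused = Σ y_i w_i per sample (convex
   combination, so the fused error is bounded by the worst sensor's error
   sample-wise). Metrics: RMSEP, mean bias, and the OLS slope of predicted
   vs. actual (ideal 1); the intercept is not reported.

## Calibration/validation split

Samples are ranked by concentration from high to low (stable sort; ties
keep input order) and n_val = round(n·fraction) validation samples are
taken at centered systematic positions ⌊(j+0.5)·n/n_val⌋ of the ranking.
This yields 63/15 at n=78 (fraction 15/78) and 45/15 at n=60 (fraction
0.25), keeps the validation extrema strictly inside the calibration
extrema, and is fully deterministic. A systematic rule was chosen over a
contiguous block so the validation set samples the whole calibrated range.

## Monte-Carlo outlier screening

`mc_outlier_detect` repeatedly (default 1000 runs, required ≥ 100) holds
out a random 20% of the calibration set, fits PLS on the remainder, and
records held-out absolute residuals. Both the mean and the SD of each
sample's residual distribution are reported. Flagging is driven by the
mean: a response outlier is mispredicted by a large near-constant offset,
so its residual SD is *small*, and any rule demanding an elevated SD as
well would mask exactly the most important case. Residual means are
strongly right-skewed across samples, so the test operates on
log(mean residual), which is close to normal; sample i is flagged when its
log-mean exceeds the mean + 3·SD (multiplier configurable) of the *other*
samples' log-means. The jackknife keeps a gross outlier from inflating its
own cut. On clean synthetic calibration sets this yields zero flags; a
sample whose reference value is corrupted by +10·SD(y) is flagged reliably.

## Synthetic benchmark generator

Real NIR/MIR pesticide-formulation spectra are not redistributable, so the
generator emulates the regime the method targets: 78 samples, analyte
content uniform on 0.1–4.98 % w/w (uniform, matching a designed calibration
series rather than a natural population), two sensors.

Each spectrum is a sum of Gaussian bands: analyte bands with height
proportional to concentration (Beer–Lambert linearity — with nuisance terms
off, absorbance at a band center is affine in concentration to R² > 0.9999);
interferent bands with random per-sample amplitudes (N(1, 0.3), clipped at
0); a random linear baseline; i.i.d. Gaussian noise (NIR 0.002 AU, MIR
0.004 AU — the "sharper but noisier" channel). The NIR-like sensor covers
4500–9000 cm⁻¹ at 25 cm⁻¹ (181 points), the MIR-like 600–1800 cm⁻¹ at
4 cm⁻¹ (301 points).

10% of samples per sensor additionally receive a spurious artifact: a fixed
two-band shape with a random per-sample scale, *disjoint* between sensors,
so every sample has at least one clean channel — the regime in which
per-sample distance weighting provably helps. Artifacts are additive and
overlap the analyte-band region; two design facts matter:

- Because artifact samples are also present in the calibration set, the
  score covariance partially absorbs the artifact direction; an artifact
  sample's displacement along that axis is ≈ (1−f)/√(f(1−f)) SDs
  independent of band magnitude. A two-band signature (two score-space
  directions) and a modest fraction f = 0.1 keep artifact samples clearly
  more distant than clean ones, which is the mechanism the weighting
  exploits (verified as a 20-seed property test).
- The artifact inflates the affected sensor's apparent analyte signal, so
  the same samples that acquire a large distance also acquire a large
  prediction error — sample-dependent relative accuracy between sensors.

Randomness is layered over one master seed: concentrations from stream
(seed, 0), sensor i's nuisance terms from (seed, i+1), artifact assignment
from a shared permutation under (seed, 999). Adding a sensor therefore
never perturbs existing sensors' data, and datasets are bit-reproducible.

What the generator does **not** emulate: realistic instrument line shapes,
wavelength drift, multiplicative scatter effects, detector nonlinearity,
and correlated (non-white) noise. Passing the benchmark therefore shows
the fusion machinery behaves correctly under the intended mechanism — it
does not certify performance on any particular real instrument pair.

## Problem sizes and tolerances

The property suites run at desk scale, chosen to keep the full test run in
a few minutes while leaving comfortable statistical margins: 20 seeds for
the fusion-ordering and artifact-linkage properties (n=78, two sensors,
5-fold CV up to 15 LVs per seed), 100 random geometries for the distance
oracle (n_cal 20–50, 2–8 dimensions, agreement to 1e-9), 5 seeds × 300 runs
for clean outlier screens and 1000 runs for the planted-outlier recovery.
Exact linear-algebra identities are asserted at 1e-6–1e-12 depending on
conditioning; weight-row normalization at 1e-12.

## Known limitations

- Reciprocal-distance weighting is one defensible reading of
  "weight inversely related to distance"; a bounded linear map from 100% at
  D=0 to 0% at the threshold is an alternative. The reciprocal form is the
  package's rule; `weight_power` offers the squared variant.
- Thresholds derive from leave-in calibration distances; with very small
  calibration sets the leave-in distances are biased low, making the 3×
  threshold conservative.
- The outlier screen assumes a single dominant population; heavy
  contamination (several gross outliers) would call for robust covariance /
  iterative trimming, which is out of scope.
- MD-based weights measure *representativeness*, not accuracy: a sensor can
  be near its calibration distribution yet systematically wrong (e.g. an
  uninformative channel). Fusion softens but does not eliminate such a
  sensor's contribution.
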