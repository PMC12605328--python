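# Methods

`seqqc` addresses a quality-control question in multi-site structural MRI:
given a "human phantom" design — one subject scanned with 2–6 back-to-back
repeat scans per scanning session, each session representing a different
combination of scanner and acquisition sequence — decide which acquisition
sequences yield poor test-retest stability of automated hippocampus
volumetry, and predict that stability class from cheap, no-reference
image-quality metrics (IQMs) so that new sequences can be vetted without
running a volumetry panel at all.

## Stability statistic and labeling

For every volumetry tool *t* and hemisphere *h* separately:

1. **Within-session CoV.** For session *j*,
   `CoV = 100 · SD / mean` of the HV estimates across the session's
   back-to-back repeats. The *sample* SD (denominator n−1) is used:
   sessions hold only 2–6 repeats, so the small-sample convention
   materially changes the value and must be pinned.
2. **Outlier flagging.** Sessions outside the Tukey fences
   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` of the CoV distribution across sessions
   are flagged. Quartiles use linear interpolation (`numpy.percentile`
   default); Tukey fences are sensitive to the quartile rule, so the rule
   is fixed and the fence multiplier `k = 1.5` is a parameter.
3. **Box-Cox + z-scoring.** A Box-Cox exponent λ is fitted by maximum
   likelihood on the non-outlier CoVs (CoV distributions are strongly
   right-skewed; for log-normal CoVs the fit lands near λ = 0). All
   sessions — including flagged outliers — are transformed with that λ
   and standardized by the mean and sample SD of the transformed
   non-outlier values, so non-outlier z-scores have mean 0 / SD 1 exactly
   while outliers keep large, honest z-scores. CoVs of exactly zero
   (possible with deterministic volumetry on identical inputs) are handled
   by a fixed shift ε = 1e−6 applied to every value of the affected group;
   the shift is recorded in the transform model.
4. **Tool exclusion.** A tool whose mean non-outlier CoV exceeds 3× the
   median across tools is dropped before averaging (a grossly unstable
   tool would otherwise dominate every session's score). The factor is a
   parameter; `inf` disables the rule.

The per-session score is the unweighted mean z over all kept tools × both
hemispheres. A session missing any kept (tool, hemisphere) cell is an
error rather than silently averaged over fewer cells.

**Labeling.** The score distribution is a mixture: a central bulk of
ordinary sessions plus a right tail of genuinely unstable ones. To set a
cutoff from the bulk alone, a Gaussian with mean fixed at 0 is fitted by
least squares to the histogram of scores (bin width 0.1, range ±4 sample
SDs; amplitude and SD free). The histogram fit is used instead of the raw
sample SD precisely because it is robust to the upper tail — adding a
far-right cluster moves the fitted SD far less than the sample SD. A
session is labeled **poor** iff its mean z-score is *strictly greater*
than `cutoff_multiplier × SD` (default +1 SD); a score exactly at the
cutoff is good. With all sessions statistically identical, this labels
roughly the >1 SD tail mass (~16%) poor by construction — the rule ranks
sequences relative to the cohort, it does not certify absolute quality.
The fit requires ≥ 20 sessions and ≥ 3 occupied histogram bins.

## Image-quality metrics

Tissue masks (GM, WM, air background) are inputs; no segmentation is
implemented. Segment variances use the population convention
(denominator n; configurable via `ddof`) — segments are large, so the
choice is immaterial but fixed for bit-reproducibility.

- **CNR** `= |μ_GM − μ_WM| / sqrt(σ²_GM + σ²_WM + σ²_Air)`. Scale
  invariant; zero iff the tissue means coincide; an all-zero-variance
  input raises rather than returning infinity.
- **CJV**: default is the standard SD-based form
  `(σ_GM + σ_WM)/|μ_GM − μ_WM|`; a `variant="variance"` switch selects
  the variance-based rendering that circulates in some method
  descriptions. The air background is read directly from the provided air
  mask; no synthetic background ("hat") estimators are used.
- **EFC**: Shannon entropy of `y_j = x_j / ||x||₂` over non-negative
  intensities (negatives are clipped to zero as background), normalized
  by the entropy of a uniform image of the same voxel count so the score
  lies in [0, 1] with uniform = 1 and single-hot = 0.
- **FWHM**: classic first-difference estimator per axis,
  `FWHM = d · sqrt(−2 ln 2 / ln(1 − s²_diff/(2 s²)))`, where `s²_diff` is
  the variance of first differences between neighbouring in-mask voxels
  and `s²` the in-mask variance. For white noise smoothed with a Gaussian
  kernel the estimator returns the kernel FWHM (verified by
  smoothing-recovery simulation: a 4 mm kernel at 1 mm spacing is
  recovered within 15%). An axis rougher than white noise
  (`s²_diff ≥ 2 s²`) is undefined: NaN, warned, excluded from the 3-axis
  mean. The estimator assumes noise-dominated input; `scan_iqm` therefore
  applies it to the residual (intensity minus segment mean) within the
  GM+WM mask. The ACF-based variant of modern AFNI is out of scope.
- **FOVx / FOVy**: voxel count × spacing along the grid axis whose
  direction cosine is largest for the left-right / anterior-posterior
  anatomical axis (RAS convention). An oblique affine with no dominant
  axis (max |cosine| < 0.6) warns and uses the argmax anyway.
- **Session aggregation**: arithmetic mean of CNR, FWHM, CJV, EFC across
  the session's scans; FOV is taken from the shared geometry and any
  mismatch between back-to-back scans is an error (it would violate the
  same-sequence design). Classification always uses session means, not
  per-scan values.

## The decision tree

A from-scratch CART restricted to be auditable: Gini-Simpson impurity
`1 − Σ p²`; split candidates at midpoints between consecutive sorted
unique feature values, `x ≤ threshold` going left; a split requires
parent ≥ 20, each child ≥ 3, impurity improvement (parent Gini minus
size-weighted child Gini) ≥ 0.02; maximum depth 2. Improvement ties are
broken by feature column order, then by the lower threshold, making
training fully deterministic; a tied leaf vote is labeled poor (in QC,
flagging is the conservative default). Equal priors and equal
misclassification costs are assumed. No pruning, surrogate splits or
multi-class support.

The **published reference tree** (`published_tree()`) is the fixed rule
`FOVx ≤ 150 mm → poor; else CNR ≤ 3.147 → poor; else good`. Values
exactly at a cutoff are classified poor (the risk side); the source
figure does not disambiguate the boundary, so this orientation is a
documented package choice, adjustable only via the cutoff values.

**Cross-validation** uses a hand-rolled deterministic stratified k-fold
(per class, seeded shuffle then round-robin deal). Pooled held-out
metrics are reported alongside resubstitution metrics of the all-data
tree; whether a headline accuracy refers to resubstitution or CV matters,
so both are always computed.

## Evaluation

Confusion metrics take **good as the positive class**: accuracy,
sensitivity, specificity (percent, reported to 1 decimal), the
good-to-poor ratio among all sessions and among sessions predicted good
(the enrichment the filter buys), and the percentage of good sessions
lost. Zero-denominator metrics are NaN and flagged, never raised.
Group comparisons are Welch's t (Satterthwaite df; two constant equal
groups return p = 1 by convention) and the Pearson chi-square for 2×2
tables without continuity correction. The per-class CoV summary collapses
each session to its mean CoV over (tool × hemisphere) cells and reports
the class mean with the SE across session means; a full repeated-measures
ANOVA is deliberately not implemented — the claim of interest (good
sessions have smaller CoV than poor ones) is testable with the marginal
means and Welch's t.

## Synthetic data: what it emulates, what it does not

`generate_cohort` mirrors the structure of the motivating design:
122 sessions by default; scans per session drawn from the empirical
2–6 distribution (median 4); 19 tools × 2 hemispheres with tool mean HVs
spanning 2.15–5.99 ml (right 7% smaller) and within-session CoVs
geometrically spaced over 0.3–1.8%; one deliberately unstable tool at 8×
the median CoV to exercise the exclusion rule; a planted poor fraction of
27/122 whose within-session noise is multiplied by 3 (HV noise is
multiplicative Gaussian, `hv = mean · (1 + ε)`, ε ~ N(0, CoV/100 × m),
matching the CoV parameterization of the stability measure; a floor at
1% of the mean guards against non-physical negative volumes at extreme
noise). Poor sessions' IQMs are a mixture — 60% narrow FOVx
(~140 mm, normal CNR) and 40% low CNR (~2.6, normal FOVx) — while FOVy
and FWHM differ at most mildly between classes, so the two genuinely
discriminative predictors are FOVx and CNR. No per-class IQM parameters
are available for the real cohort; these defaults are chosen for
separability and fixed once. Which of FOVx and CNR wins the *first*
split on a default cohort depends on which poor subgroup the draw made
larger (the planted rule is a symmetric OR); `generate_rule_cohort`
additionally provides cohorts whose labels follow the exact rule
`FOVx < 150 → poor, else CNR < 3.1 → poor` with feature distributions
straddling both cutoffs, for threshold-recovery tests.

`generate_phantom` produces a three-tissue ball phantom (WM core, GM
shell, air background) with per-tissue Gaussian noise, optional Gaussian
smoothing to a requested FWHM (a request below the voxel size warns and
is skipped) and a multiplicative low-order polynomial bias field whose
amplitude is the maximum fractional deviation. It exists to exercise the
IQM code with known ground truth — it contains no MR physics (no k-space,
coil sensitivity, motion, Rician noise), so passing IQM tests shows the
estimators are correct on their stated model, not that they are robust to
every artifact of real scanners. Likewise the cohort generator draws
(tool × hemisphere) noise independently; real tools share failure modes
across hemispheres, which would widen the mean-z distribution relative to
the synthetic case.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations reproduce
bit-identical outputs.

## Numerical choices and degenerate inputs

- CoV: error for < 2 repeats or non-positive mean.
- Tukey fences: error below 4 sessions; Box-Cox fit: error below 4
  non-outlier sessions or zero non-outlier variance.
- Gaussian-SD fit: `scipy.optimize.curve_fit` with amplitude bounded
  below by 0 and SD by 1e−9; initial values (max bin count, sample SD).
- CART: constant features or label-independent features yield a root
  leaf (no split clears the 0.02 gate); predictions with a missing or NaN
  feature raise.
- Strictly monotone transforms of a predictor change thresholds but not
  training-set predictions (split order statistics are preserved).

## Problem sizes

The test-suite and acceptance-script simulations use 122–300 sessions,
split-oracle instances of n ≤ 50, 5 000 samples for the Gaussian-SD
recovery, and 40³–64³ voxel volumes for the IQM recoveries; at these
sizes every stochastic check sits comfortably away from its threshold
(e.g. planted-label balanced accuracy ≈ 1.0 against a 0.9 requirement)
while the full suite runs in seconds.

## Known limitations

- The labeling is cohort-relative: it always finds a "poor" tail, even
  in a cohort of uniformly excellent sequences.
- The published-tree cutoffs were derived on one dataset; applying them
  to other scanners, volumetry targets or field strengths is
  extrapolation.
- The CJV printed-formula ambiguity (SD vs variance numerator) cannot be
  resolved from public descriptions; both are provided, the SD form is
  the default, and the two are not numerically interchangeable.
- Masks must be supplied; there is no segmentation, brain extraction or
  bias-field correction.
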