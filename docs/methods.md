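# Methods

## Problem setting

Brand authentication from NIR spectra is a one-class problem: genuine
samples of the declared brand are available, but "fakes" are whatever else
may be passed off as that brand, so no representative outlier sample can
exist.  Each model therefore learns a closed acceptance region from
target-class data only, and the other brands in the study stand in for
fakes purely at evaluation time.  Performance is reported as sensitivity
(fraction of genuine test samples accepted) and specificity (fraction of
outlier test samples rejected), in percent.

## Preprocessing and features

**SNV.** Each spectrum is centred and scaled to unit standard deviation
(sample s.d., divisor n−1 — the dominant chemometrics convention; the
choice only rescales all rows identically and has no effect downstream).
SNV exactly removes per-spectrum additive offsets and positive
multiplicative factors, the signature distortions of diffuse-reflectance
measurements of granular solids.  A constant spectrum has no SNV image and
raises an explicit error naming the sample.

**PCA.** Mean-centred PCA via SVD.  Loading signs are fixed by orienting
each column so its largest-magnitude entry is positive, making scores
platform-reproducible.  The pipeline default projects onto the first two
scores (`pc2`), matching the study protocol in which PCA is fitted **once on
all samples jointly** before the per-class splits.  This deliberately lets
unlabeled test structure into the feature axes; it does not leak labels, but
a strict variant (`strict_pca=True`) is provided that ranks the target class
in SNV space and fits PCA on the 30 training spectra only.  The `original`
feature space (full SNV spectra) is also supported end to end.

**Kennard–Stone split.** The target class is ranked by the classical maximin
procedure: start with the most distant pair, then repeatedly add the sample
whose minimum distance to the already-selected set is largest.  The one-line
textbook description admits a max-sum reading; the standard maximin form is
implemented.  Ties (exactly equal distances) go to the lowest sample index,
and the initial pair is ordered ascending, so the ranking is deterministic;
it also has the prefix property (the first m selections are independent of
how far the ranking is read).  Ranking happens in the same feature space the
models use; the first 30 ranked samples train, the remaining target samples
plus all other-class samples test.

## The three descriptions

**SVDD.** Minimum enclosing hypersphere in kernel space with slack, penalty
parameterized by the rejection fraction f as C = 1/(N·f) (f is the
user-facing knob: the approximate fraction of training samples allowed
outside).  Dual: maximize Σαᵢ K(xᵢ,xᵢ) − ΣΣ αᵢαⱼK(xᵢ,xⱼ) subject to
Σαᵢ = 1, 0 ≤ αᵢ ≤ C.  The RBF kernel is exp(−‖·‖²/σ²), with **no factor 2**
in the denominator; this is stated prominently because conventions differ
(σ_here = √2·σ_conventional, scikit-learn gamma = 1/σ²).

*Solver.* Pairwise coordinate ascent on the most-KKT-violating pair
(the pair update has a closed form; the step is clipped to the box).  The
stop rule is a maximum KKT violation below 1e−8, scaled by the kernel
magnitude so the linear kernel behaves sensibly on unstandardized data, with
a cap of 1e5 pair updates and a convergence warning if hit.  α below
1e−10·C is treated as zero, α above C·(1−1e−8) as bounded.  The squared
radius is the mean squared centre-distance over unbounded support vectors
(numerically stabler than a single one, exact in exact arithmetic); if all
support vectors are at bound — possible for extreme f — the maximum
support-vector distance is used and a warning emitted.

*Decision rule.* Accept iff dist²(z) ≤ R² + tol.  The tolerance has a 1e−9
floor and is widened to the observed spread of unbounded-support-vector
distances around R²: the solver stops at a finite KKT residual, so boundary
points sit within that residual of the sphere and must not be rejected by
round-off.  A single-point training set yields α = [1], R² = 0, and accepts
exactly that point.

**KNNDD.** Novelty score ‖z − NN_k(z)‖ / ‖NN_k(z) − NN_k(NN_k(z))‖, where
NN_k is the k-th nearest training neighbour (the denominator search excludes
the neighbour itself); accept iff score ≤ threshold.  Defaults k = 1,
threshold 1.0 — accept when the local density at z is at least that at its
neighbour.  Degenerate denominators: 0/0 scores 0 (a duplicate of a
duplicated training point: accept); x/0 scores +∞ (reject).  Neighbour
queries use a k-d tree.

**GAUSS.** Sample mean and covariance (divisor n−1); acceptance iff
squared Mahalanobis distance ≤ χ²_d quantile at the chosen coverage
(default 0.95), the exact population acceptance rate when the data are
d-variate normal.  (A full d-dimensional Gaussian has d + d(d+1)/2 free
parameters, which is why n ≥ d+1 is recommended.)  Singular or
ill-conditioned covariance is handled by Tikhonov regularization
Σ′ = Σ + λI with scale-aware default λ = 1e−6·trace(Σ)/d, or by the
Moore–Penrose pseudoinverse (`inv_mode="pseudoinverse"`); a rank-deficient
covariance with λ = 0 in regularized mode raises an error that names both
remedies.  In the `original` feature space (d = 1557 ≫ n) the regularized
mode is only formally invertible; results there are dominated by the
regularizer and should be read as a smoke-level comparison, as for any
covariance model with n ≪ d.

## Kernel-width selection

The SVDD boundary character is governed by σ relative to two data scales:
near the mean nearest-neighbour distance the description degenerates toward
Parzen windows around individual points; beyond the data diameter it
approaches the rigid hypersphere.  The automatic scan therefore uses a
25-point log grid between exactly those two scales (computed from the
training scores only).

The selection rule is the *tightest simple boundary containing all training
samples*: among scanned widths whose description accepts every training
sample, pick the one with the fewest support vectors, breaking ties toward
the smallest σ; if no width accepts all training samples, minimize
rejections first.  The support-vector count is used as the complexity
measure because it falls monotonically in regime terms from the
Parzen-window limit (every point a support vector, a wiggly union of
bubbles) to the rigid sphere.  A rule of "smallest all-accepting σ" alone is
degenerate: in the Parzen regime every training point sits (within solver
tolerance) on its own bubble boundary and is accepted, so that rule always
returns the grid minimum and generalization collapses.  A fixed σ may be
supplied via `StudyConfig(sigma=...)` to bypass the scan.

## Synthetic study data

The generator emulates the statistical structure of FT-NIR diffuse
reflectance spectra of milled grain on a 1557-point axis spanning
10,000–4,000 cm⁻¹ (stored descending, as acquired).  Each spectrum is

    scatter · Σ_b A_b·(1+jitter_b)·exp(−(ν−c_b)²/(2w_b²)) + offset + slope·t + noise

with shared band centres {4266, 4335, 5175, 6930, 8400} cm⁻¹ — the C–H
stretch/deformation pair, the water combination band, the O–H/water first
overtone and the C–H second-overtone region — and per-brand band
*amplitudes*.  Brands differ only in amplitude ratios (constituent balance,
not chemistry), scaled by a single `separation` parameter: 0 makes the three
brands exchangeable (a null control used in tests), 1 is the default study
condition with ratio differences of ~5–12% per band.

Per-sample effects and defaults: multiplicative scatter factor U(0.8, 1.25)
and additive baseline offset U(−0.05, 0.05) AU — both removed exactly by
SNV; a mild baseline slope U(−0.01, 0.01) AU across the axis — *not*
removed by SNV, contributing a small realistic residual; band-amplitude
jitter (1% relative s.d.) representing within-brand constituent variation;
instrument noise s.d. 0.003 AU.  The study design is 48/46/48 samples for
brands A/B/C (142 total); an optional per-batch amplitude offset mirrors the
3/2/3 batch structure and is off by default since the analysis never uses
batch identity.  All randomness flows from one explicit generator seed.

What the generator does **not** model: radiative-transfer physics,
wavelength-dependent scatter, water-vapour/temperature drift, detector
nonlinearity, or overlapping minor constituents.  Consequently the synthetic
brands are cleanly separable in two PC scores, and pipeline results on these
data (specificity 100%, sensitivity ≥ 94%) demonstrate the machinery works
under the assumed structure — they are not a claim about any real product,
where class overlap, instrument drift and batch effects can only degrade
both numbers.

## Report arithmetic

Sensitivity and specificity are computed in full precision and rounded
half-up to one decimal only at formatting; the Average row is the arithmetic
mean of the *unrounded* class values, then rounded (so 17/18, 15/16, 17/18
average to 94.2, not the 94.2/94.166 ambiguity of averaging rounded cells).
A test set lacking either targets or outliers makes the metrics undefined
and raises rather than reporting a vacuous 0 or 100.

## Problem sizes and determinism

The test and acceptance runs use the full 142 × 1557 study (fast: the heavy
objects are 30-sample fits in two dimensions), 10,000 draws for the Gaussian
coverage check, and ≤ 30-point instances for the solver-optimality oracles
(a generic SLSQP QP, an exact minimum-enclosing-ball enumeration, and a
ν-one-class-SVM with matched width, which is dual-equivalent to SVDD for
RBF kernels).  Every stochastic path takes an explicit seed; fitted models
and predictions are deterministic given their inputs.

## Known limitations

* The SMO solver is dense O(n²) in memory; fine for calibration-sized
  one-class training sets (tens to hundreds of samples), not for n ≫ 10⁴.
* Only RBF and linear kernels; no polynomial kernels, no Parzen or
  Gaussian-mixture densities.
* Width selection is the grid heuristic above; cross-validation, bootstrap
  or consistency-based selection are out of scope.
* The joint-PCA default reproduces the study protocol; for a deployable
  authentication model the strict mode is the defensible choice.
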