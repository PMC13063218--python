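# Methods

## Error model and estimation

Each specimen is scanned `r` times with repositioning; the replicate mean
X̄ serves as the estimate of the true spectrum and the residuals X_k − X̄
as draws of the measurement error. The experimental error covariance matrix
(ECM) of one specimen is the sample covariance of those residuals
(divisor r − 1). Because an ECM from 5 replicates is very noisy, per-specimen
ECMs are pooled by an unweighted element-wise mean over all specimens of one
(instrument, bone-type) stratum, across both classes. Two alternatives were
deliberately rejected: per-specimen ECMs (far too few replicates to support
an m×m covariance) and class-specific ECMs (the class of a new specimen is
exactly what the model must predict, so no ECM could be assigned at
prediction time). Pooling is unweighted because every specimen contributes
the same replicate count by design; a replicate-weighted mean would coincide.

The error correlation matrix divides the ECM by the outer product of its
diagonal square roots. Channels with zero error variance are masked
(NaN + boolean mask) rather than zero-filled, so a dead channel can never
masquerade as "uncorrelated". The `iid_score` diagnostic condenses the
departure from iid errors into two terms reported separately and summed 1:1
— the mean absolute off-diagonal correlation and the coefficient of
variation of the variance diagonal. The 1:1 weighting is a package choice;
the underlying criterion (flat diagonal, empty off-diagonal) is qualitative,
which is why both components are always exposed alongside the sum.

## Maximum-likelihood PCA

Only the directly solvable error structures are implemented: case A
(homoscedastic uncorrelated — identical to classical PCA), case B
(heteroscedastic uncorrelated, common structure — whiten by diag Σ), and
case D (correlated, one common wavelength-wise structure — whiten by the
full Σ). The orientation of case D is across wavelengths: one pooled ECM
applies to every sample spectrum. Cases C/E/F require iterative algorithms,
are not needed for a common pooled ECM, and raise `NotImplementedError`.

The fit whitens rows with the symmetric inverse square root
W = V Λ^(−1/2) Vᵀ of the (ridge-adjusted) ECM — symmetric eigendecomposition
rather than a triangular factor, so W is unique and deterministic — takes
the best rank-p subspace by SVD, and back-transforms loadings with W⁻¹.
S² equals the sum of discarded squared singular values and, by construction,
the direct evaluation of the weighted objective with the same ridge-adjusted
inverse (asserted in tests to 1e−6 relative). Loading sign is fixed by
making the largest-magnitude element of each original-space loading
positive. MLPCA solutions are not nested across ranks (except case A), so a
rank grid refits every rank from scratch.

A pooled ECM estimated from 40 specimens × 5 replicates can be numerically
singular at m > 200 channels. The whitener therefore adds a ridge, default
1e−8 × mean error variance, escalating by decades until the matrix is
numerically positive definite; the ridge actually used is stored on the
model and reused in every objective evaluation and projection for
self-consistency.

Two modeling choices were genuinely open and are exposed as flags:

* **Centering.** MLPCA inputs are column-mean-centered by default. An
  un-modeled global offset would otherwise load onto the first component
  and dilute it; the plain (unweighted) column mean is used. No-centering is
  available; error-weighted mean centering is not implemented.
* **ECM scaling for replicate means.** The subspace is fitted to replicate
  means, whose error covariance is Σ/r rather than Σ. Rescaling Σ by a
  constant rescales S² but leaves the whitened directions, hence the fitted
  subspace, scores and all downstream classification unchanged, so the
  pooled Σ is used as estimated.

New spectra are projected by maximum likelihood,
t = (Pᵀ Σ⁻¹ P)⁻¹ Pᵀ Σ⁻¹ (x − center), computed as the orthogonal projection
in whitened coordinates (the two coincide because whitened loadings are
orthonormal; the equivalence is asserted in tests). The prediction-time ECM
is always the training pooled ECM — test replicates never touch the
whitener.

## Logistic regression on scores

Scores are autoscaled (training mean/sd, frozen for prediction) so the
high-variance first component cannot dominate; coefficients then reflect
discriminative power only. The fitter is a damped Newton/IRLS maximising
the log-likelihood minus (λ/2)‖β‖² on the slopes (intercept unpenalised),
zero-initialised, with step-halving whenever the penalised likelihood would
decrease, converging at relative change < 1e−10 or 100 iterations.

The default ridge λ = 1e−4 exists because the expected operating regime is
*perfect separation* of the classes in score space, where the unpenalised
MLE diverges. A tiny ridge keeps coefficients finite and reproducible while
moving the decision boundary negligibly; with λ → 0 on non-separable data
the fit agrees with the unpenalised MLE (cross-checked against statsmodels
in the test suite). Ties at the 0.5 probability threshold are assigned to
the positive (historical) class — deterministic, and conservative for a
screening application whose primary interest is the historical class.

## PLS-DA baseline and preprocessing selection

Single-response NIPALS PLS1 (chosen over SIMPLS for transparency; the two
coincide for one response) on replicate-mean spectra against a 1/0 dummy
response, thresholded at 0.5 with the same tie rule. The preprocessing
search applies each candidate pipeline — ordered smoothing → scatter
correction (SNV or MSC) → derivative — to every training replicate,
recomputes the pooled error correlation, and ranks candidates by iid score
ascending, ties broken by fewer operators then smaller window. The candidate
grid spans {none, SNV, MSC} × {none, SG smoothing w ∈ 7..21 odd} ×
{none, 1st, 2nd SG derivative}; the derivative window follows the smoothing
window when both are present. Savitzky–Golay operators use polynomial order
2, per-channel-index derivatives (the chemometric convention; the grid is
uniform so per-nm would differ only by a constant), and one-sided polynomial
fits at the edges (scipy's `mode="interp"`) so the channel count — and with
it the ECM dimension — is preserved. Mean-centering is the final step of
every pipeline; it subtracts a per-channel constant across samples and
therefore cannot change replicate residuals, so it is folded into the PLS
fit's own centering. The MSC reference is the training mean spectrum, frozen
and reused for test data to avoid leakage.

## Validation machinery

All resampling is at specimen level; a specimen's replicates always travel
together. The train/test partition allocates per-class training counts by
largest remainder (33 + 26 specimens into 40 training reproduces 22/18
training and 11/8 test exactly, for every seed). Stratified k-fold deals
shuffled class members cyclically across folds, carrying the offset between
classes, which guarantees fold sizes and per-class fold counts each differ
by at most one and supports k = n (leave-one-out). Cross-validation refits
everything — ECM, subspace, scaler, classifier, or the PLS-DA preprocessing
— inside each training fold, and pools out-of-fold predictions before
computing one metric panel per rank (with 4-specimen folds, per-fold metrics
would be mostly undefined; pooling is the package's choice). The
cross-validated AUC uses the pooled out-of-fold probabilities. Rank
selection is parsimonious: the smallest rank attaining the maximum accuracy,
ties broken by AUC, then by smaller rank.

The bootstrap draws specimens with replacement (plain, not stratified),
refits the full pipeline per iteration, and scores the out-of-bag
specimens. Draws lacking a class are redrawn so the requested number of
effective iterations is kept. Metrics undefined in an iteration (zero
denominator, or single-class OOB for AUC) are excluded from that metric's
mean/std, with the effective count reported — never imputed. Confusion-based
metrics with zero denominators are reported as undefined (None) everywhere.
Display rounding is decimal half-up at 2 decimals; computation is always at
full precision.

## Synthetic data

The generator emulates replicate NIR spectra of bone-like samples: a sloped
baseline plus Gaussian bands at 970, 1200, 1450, 1500, 1720, 1940, 2050,
2180, 2330 nm (water, collagen/lipid C–H, collagen amide assignments),
clipped to the instrument range — 908–1676 nm (125 channels) or
1350–2550 nm (228 channels); channel counts are package defaults, not
instrument facts, and are configurable. The historical class carries a 1.30
amplitude multiplier on the 1450/1940 nm water bands (diagenetically porous
bone retaining more moisture). Per-specimen, per-band amplitude jitter
(sd 5% of the base amplitude) makes between-specimen variance exceed
replicate variance. Each replicate is a·clean + b + ε with a ~ N(1, 0.05),
b ~ N(0, 0.005), ε heteroscedastic white noise (sd 0.002 by default,
per-channel vectors accepted) — giving exactly the positively correlated,
signal-proportional error structure whose analytic covariance
sd_a²·ssᵀ + sd_b²·11ᵀ + diag(σ²) is exported for oracle tests. Defaults are
30 specimens per class, 5 replicates. Effect sizes are set for test
stability: strong enough that the two-step pipeline separates the classes
at rank 2, weak enough that label permutation drops accuracy to chance.

What the generator does **not** emulate: real band shapes and overlaps
beyond Gaussians, instrument line-shape and detector noise spectra,
session/operator drift (a session-offset hook exists but is off by
default), inter-correlated band amplitudes from shared chemistry, and the
class overlap of real mandible data. Passing tests therefore demonstrate
the correctness and internal consistency of the machinery under a known
error model — not field performance on museum specimens.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run deliberately small
configurations chosen as representative: 20–60 channel grids for repeated
refits, the full 125-channel default for the end-to-end study, bootstrap at
1000 iterations where the OOB limit is checked and 200 where only a mean
accuracy is needed, 1e5 Monte-Carlo replicate draws for the ECM consistency
check. Whitener tolerance for positive definiteness is 1e−14 × mean
variance; PSD validation of ECMs tolerates eigenvalues above −1e−8 × scale
to absorb rounding.

## Known limitations

* Only MLPCA cases with a single common error structure (A, B, D) are
  implemented; per-sample or fully general error covariances are out of
  scope.
* Logistic coefficients under perfect separation depend on the ridge
  magnitude; decisions and labels are stable, coefficient values are not
  reproduction targets.
* The preprocessing search optimises error-structure compliance, not
  classification accuracy; on data whose dominant artefact is not
  scatter-like, the two criteria can disagree.
* Binary classification only; no multinomial extension, no probability
  calibration.
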