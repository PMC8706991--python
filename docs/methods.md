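# Methods

## Design construction

A k-factor central composite design is the union of the 2^k factorial
points (coded ±1), 2k axial points at ±α on one axis and 0 on the others,
and n_center replicated center runs, for 2^k + 2k + n_center runs in
total. α defaults to the rotatable value (2^k)^(1/4) (1.682 at k = 3), so
prediction variance depends only on distance from the center. Coded and
actual units are related per factor by `actual = center + coded ×
half_width`; the transforms are exact algebraic inverses and axial levels
are stored at full precision (1.6818…, not a rounded 1.682) — printed
run sheets that round to 2 dp are compared at that rounding.

Run order is canonical and deterministic (factorial points in binary
counting order, axial points factor by factor with −α before +α, then
centers); an optional seed applies a reproducible permutation. Fixtures
and regression tests need a stable order more than they need
randomization, which matters only at the bench.

## Quadratic response-surface models

Each response is modelled by the full second-order polynomial
(p = 1 + k + k(k−1)/2 + k terms; 10 at k = 3) fitted by ordinary least
squares (statsmodels OLS is the backend). Reduced term lists are
available explicitly but the full model is always the default. Fits can
be expressed in coded or actual units; these are linear
reparameterizations, so R², adjusted R², predicted R², the overall F
test and all fitted values are identical between the two (verified to
1e−10 in the tests) — only the coefficient vector changes. Diagnostics
are conventionally reported from the coded fit, the human-readable
equation from the actual-units fit.

Beyond the standard OLS output the results object computes:

* **PRESS** = Σ (eᵢ/(1−hᵢᵢ))², with leverages hᵢᵢ taken from a QR
  factorization of the model matrix; tests verify the shortcut equals
  brute-force leave-one-out refitting. **Predicted R²** = 1 − PRESS/SST.
  A leverage numerically equal to 1 raises rather than returning a
  meaningless number.
* **Adequate precision** = (max ŷ − min ŷ over the design points) /
  √(p·MSE/n), the signal-to-noise convention of RSM software; > 4 is
  read as an adequate signal. When the residual mean square is
  indistinguishable from floating-point noise (MSE ≤ 1e−12 × SST/(n−1)),
  the fit is treated as exact: adequate precision reports `inf` and the
  per-term t-tests return NaN sentinels instead of p-values computed
  from a zero variance.

Rank-deficient model matrices and constant responses raise dedicated
errors (`SingularDesignError`, `DegenerateResponseError`) rather than
producing unstable pseudo-inverse fits.

### Agreement with the packaged study table — a known discrepancy

Refitting the packaged 20-run table gives R² = 0.961 (size), 0.945
(entrapment) and 0.952 (loading), with adequate precisions of 16–18.
The source study printed far higher values (R² up to 0.9999, adequate
precision up to 494) together with model equations whose coefficients
disagree with any least-squares fit of its own printed run table: the
printed size equation has a residual sum of squares four times larger
than the OLS minimum on those runs, driven by two ~40 nm residuals.
The printed run table and the printed statistics are therefore mutually
inconsistent — most plausibly transcription errors in the published
table — and no choice of fitting convention can reproduce both. The
package preserves the printed run values verbatim and reports the
honestly recomputed statistics; it does not adjust the data to match
the published diagnostics.

## Desirability optimization

Individual desirability is the one-sided linear ramp: for a maximize
goal, d = 0 at or below y_min, 1 at or above y_max, linear between; a
minimize goal is the mirror image. Weights and Derringer shape exponents
are deliberately out of scope (everything is weight-1, linear). The
overall objective is the geometric mean, so one unacceptable response
zeroes the whole score.

Default acceptability bounds are each response's observed min/max over
the design runs — the common default when no specification limits exist
— and are overridable. The search region defaults to the factorial cube
[−1, +1]^k rather than the axial sphere: optima of formulation studies
are typically quoted at (or within) the factorial levels. The optimizer
is a dense grid search at 0.02 coded resolution (exhaustive, ties broken
by first occurrence in canonical grid order) followed by a Nelder-Mead
polish of the clipped objective; it is deterministic for a fixed step.
If D = 0 everywhere on the grid the optimizer returns the point
maximizing the minimum individual desirability and flags `all_zero`.

On the packaged study (minimize size, maximize entrapment and loading,
observed-range bounds) the optimum lands on the cube corner
(+1, −1, +1): 5.0 mM drug, 10.0 mM lipid, 50.0% cholesterol, D = 0.76,
matching the formulation the source study selected (it quotes 10.1 mM
lipid; the tests assert the interval [10, 12]).

## Release curves and kinetics

Withdraw-and-replace sampling dilutes the medium at every timepoint; the
only mass-consistent reconstruction of cumulative release is
Qₙ = CₙV + Vₛ·Σᵢ<ₙCᵢ, and CR = Q/dose. The companion simulator tracks
the medium composition through withdrawals exactly, so the correction is
validated as the literal inverse of the sampling process (to 1e−6 in the
tests, by construction exact up to rounding).

The four kinetic laws are fitted on (t, CR) with CR a fraction in [0,1]
and t in hours. Initialization: k₁ from log-linear regression of
−ln(1−CR), k₀/k_H from closed-form linear least squares through the
origin, Korsmeyer-Peppas from log-log regression (t = 0 / CR = 0 points
excluded from the log-log step only); bounded Levenberg-Marquardt /
trust-region refinement follows. Non-convergence raises
`FitFailureError` carrying the best attempt. Korsmeyer-Peppas is fitted
on all points by default; the conventional ≤ 60%-released truncation is
available (`kp_60`) and engages only when at least 3 points qualify.
Ranking is by R², ties broken by fewer parameters. With n fixed at 0.5
Korsmeyer-Peppas degenerates to Higuchi; the tests verify both fits
coincide on square-root data.

The published rate constants for this study are not regression targets:
the underlying time series exists only as a figure, and the printed
"×10⁻²" scaling of the table is internally inconsistent with the stated
complete-release-by-12 h behavior. The kinetics stage is instead
validated by exact recovery on noiseless model-generated curves, by a
seeded 200-replicate recovery study (noise SD 0.02 on CR; mean k̂₁
within 5% of truth), and by shape-level checks: on the two canonical
profiles — "fast" (first-order, essentially complete by 12 h) and
"sustained" (saturating exponential through 80% at 4 h and a 98% plateau
at 48 h, the published description of the vesicle profile) — first-order
ranks first with R² ≥ 0.99.

## Assay metrics

EE and DL are implemented exactly as defined above; DL requires drug and
lipid in a common unit and this is a documented precondition, not a
hidden conversion. Franz-cell cumulation applies the same mass-balance
correction per area; receptor volume has no default — it must be given
explicitly for any computation intended for comparison. The
transfollicular statistic is the plain difference full − blocked,
unit-agnostic, with an exact-grid alignment check; a two-route simulator
(transepidermal + follicular flux, follicular zeroed for blocked skin)
verifies that the difference recovers the injected follicular component.

The Draize primary irritation index is the arithmetic mean of all
recorded category scores, Σ(erythema + edema)/(2T) over the T observed
timepoints, reported to 2 dp. This convention reproduces the packaged
positive-control value (5.25/8 = 0.65625 → 0.66 vs the printed 0.65 —
the source evidently truncated) where the classic 24–72 h-only Draize
mean does not. Class bands: [0, 0.5) none, [0.5, 2) slight, [2, 5)
moderate, [5, 8] severe, applied to the rounded index.

## Synthetic data generation

The surface generator draws y = quadratic(x)·β + N(0, σ²) independently
per run; center replicates share the surface value but draw independent
noise, emulating replicated preparations. Default noise for
realistic-scale demonstrations is a few units of response (σ = 3 nm for
vesicle size), the order of the replicate SDs in the packaged table. The
release and permeation simulators are exact mass-balance models of the
sampling protocols (20 mL medium / 1 mL aliquots at 1–48 h for release;
0.5 mL aliquots, 3.5 cm² area for Franz cells), with optional Gaussian
measurement noise applied to observed concentrations only — withdrawal
always removes mass at the true concentration. All generators are pure
functions of (inputs, seed).

What the generators do *not* emulate: inter-batch variability beyond iid
Gaussian noise, drift or degradation over a release run, membrane lag
times, non-sink receptor conditions, or heteroscedastic assay error.
Passing tests therefore demonstrate correctness of the computations
under the stated statistical model, not robustness to every artifact of
real laboratory data.

## Numerical choices and limitations

* OLS via statsmodels (pinv-based); leverages via QR.
* Grid search is O(resolution^k); at the default 0.02 step it is
  exhaustive for k ≤ 3 and chunked to bound memory for larger k.
* Desirability ramps are piecewise linear, so the polished optimum can
  sit on a ramp plateau; the grid result is kept unless the polish
  strictly improves D.
* Kinetic fits bound all rate constants strictly positive and n ∈
  (0, 5]; exact-zero responses cannot occur at t > 0 under any of the
  four laws.
* The package computes descriptive statistics only; the hypothesis-test
  machinery of comparative animal studies (ANOVA, Kruskal-Wallis) is out
  of scope.
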