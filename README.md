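# formudoe

Design-of-experiments toolkit for formulation scientists optimizing
vesicular drug carriers (niosomes, proniosomes, liposomes and similar
systems). It covers the full computational arc of a formulation
optimization study:

* **Design construction** — rotatable central composite designs (CCD):
  the 2^k factorial core at coded ±1, axial points at ±α = (2^k)^(1/4),
  replicated center points, and exact coded ↔ actual unit conversion.
* **Response-surface regression** — full quadratic models
  y = b₀ + Σᵢbᵢxᵢ + Σᵢ<ⱼbᵢⱼxᵢxⱼ + Σᵢbᵢᵢxᵢ² fitted by OLS, with the
  diagnostics RSM software reports: R², adjusted R², PRESS and predicted
  R² (1 − PRESS/SST from leave-one-out residuals eᵢ/(1−hᵢᵢ)), adequate
  precision (range(ŷ)/√(p·MSE/n), >4 is an adequate signal), and
  per-term t-tests.
* **Desirability optimization** — Derringer-type linear ramps dᵢ ∈ [0,1]
  per response, combined by the geometric mean D = (∏dᵢ)^(1/m) and
  maximized over the coded cube by dense grid search with local polish.
* **Release kinetics** — withdraw-and-replace corrected cumulative
  release (Qₙ = CₙV + Vₛ·Σᵢ<ₙCᵢ) and least-squares fits of the zero-order,
  first-order (CR = 1 − e^(−k₁t)), Korsmeyer-Peppas (CR = k·tⁿ) and
  Higuchi (CR = k·√t) laws, ranked by R².
* **Assay metrics** — entrapment efficiency, drug loading, Franz-cell
  cumulative permeation per area, the follicle-blocking transfollicular
  difference, and Draize primary irritation index (PII) scoring with the
  conventional class bands.
* **Synthetic data** — mass-balance simulators for sampled release and
  permeation runs and a quadratic-surface generator, so every stage can
  be validated against known ground truth.

The package ships a complete worked example: the published 20-run CCD of
a finasteride-loaded proniosome study (3 factors — drug concentration,
total lipid, cholesterol fraction; 3 responses — vesicle size, %
entrapment, % drug loading) together with its Draize irritation table.

## Worked example

```python
import formudoe as fd
from formudoe import datasets

design = datasets.proniosome_design()          # packaged 20-run CCD
size = fd.ResponseSurface(design, "size_nm").fit()
print(size.summary())
```

```
Quadratic response surface: size_nm  [coded units]
  n = 20, p = 10
  R^2 = 0.9607   adj R^2 = 0.9254   pred R^2 = 0.6949
  PRESS = 7321.4144   adequate precision = 17.0806
  model F p-value = 7.11e-06
  ...
```

The vesicle-size surface explains 96% of the run-to-run variation; the
adequate precision of 17 (≫ 4) says the fitted signal towers over the
average prediction error, so the surface is usable for optimization.
(Note the diagnostics recomputed from the published run table differ
from the ones the original authors printed; see `docs/methods.md`.)

Optimizing all three responses at once — small vesicles, high
entrapment, high loading, each scored over its observed range:

```python
fits = {n: fd.ResponseSurface(design, n).fit()
        for n in datasets.RESPONSE_COLUMNS}
goals = datasets.default_goals(design, {"size_nm": "minimize",
                                        "ee_pct": "maximize",
                                        "dl_pct": "maximize"})
opt = fd.optimize(list(fits.values()), goals)
print(opt.actual, round(opt.overall_D, 4))
```

```
[ 5. 10. 50.] 0.7649
```

The optimum sits at 5.0 mM drug, 10.0 mM total lipid and 50.0%
cholesterol (overall desirability 0.76), with predicted responses of
235 nm, 87.6% entrapment and 33.0% loading — matching the formulation
the source study selected (5.0 mM, 10.1 mM, 50.0%).

Release kinetics of a sustained (vesicle-like) profile:

```python
from formudoe import ReleaseCurve, ReleaseKinetics
from formudoe.kinetics import DEFAULT_TIMEPOINTS_H
from formudoe.simulate import emulate_release_profile

rk = ReleaseKinetics(ReleaseCurve(DEFAULT_TIMEPOINTS_H,
                                  emulate_release_profile("sustained")))
print(rk.summary())
```

```
model                   R^2  parameters
first_order          0.9963  k1 = 0.4029
korsmeyer_peppas     0.6822  k_KP = 0.5636, n = 0.1779
higuchi             -0.9938  k_H = 0.2151
zero_order          -5.2370  k0 = 0.03176
```

First-order kinetics dominates (R² ≥ 0.99), as expected for diffusion
out of a vesicle reservoir.

A `formudoe` command-line tool exposes the same pipeline
(`design`, `fit`, `optimize`, `kinetics`, `permeation`, `pii`,
`simulate`); run `formudoe --help`.

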