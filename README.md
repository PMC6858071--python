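# phenodrift

Phenotype-structured population dynamics of heterogeneous formaldehyde
tolerance in *Methylobacterium extorquens*.

## The problem

Clonal *M. extorquens* populations are phenotypically heterogeneous in
formaldehyde tolerance: each cell grows normally up to some maximum
formaldehyde concentration x (its tolerance, 0–8 mM) and dies above it,
and the abundance of cells tolerating ≥ x falls roughly ten-fold per mM.
Exposure to 4 mM formaldehyde kills the sensitive majority and enriches
the tolerant few; transferring the selected population to
formaldehyde-free medium either maintains the tolerant state (methanol)
or reverts it (succinate).  Disentangling how much of these distribution
shifts is selective death versus *active phenotype transitions* —
undirected diversification or directed reversion — requires a
quantitative model of the whole tolerance distribution over time.

`phenodrift` is for quantitative microbiologists analyzing CFU
tolerance-distribution time series (selective plating at a ladder of
toxin concentrations).  It implements:

* the structured-population model
  `∂N/∂t = r_c N − H(x,F) N + D ∂²N/∂x² + v ∂N/∂x`, with death
  `H(x,F) = α (F − b·x)` for x < F, solved by method of lines (LSODA,
  conservative flux-form operators, zero-flux boundaries, 0.01 mM bins);
* data preparation: the cumulative↔density transform
  `N(x) = N̂(x) − N̂(x+h)`, a detection-limit "extension" correction,
  replicate averaging, and monotone cubic-spline (PCHIP) initial
  conditions;
* maximum-likelihood fitting of (α, b, D, v) on the asinh scale with
  Nelder–Mead, Hessian standard errors, pseudo-R², and forward stepwise
  model selection by likelihood-ratio test over a nested variant
  lattice;
* growth/death rate regressions on CFU time series (log2-linear slopes
  × ln 2) and a phenotype-independent α estimate from time-kill curves;
* a fully seeded synthetic-experiment generator with a serial-dilution
  Poisson plating observation model (natural ~34 CFU/mL detection
  limit), plus Monte-Carlo parameter-recovery and model-selection
  studies.

See `docs/methods.md` for model assumptions, numerics, and a candid
account of the method's statistical behaviour under counting noise.

## Worked example

Generate a synthetic 4 mM selection experiment at the best-fit
parameters and re-estimate them through the full pipeline:

```python
from phenodrift import (ModelParameters, ToleranceDynamicsModel, ToleranceGrid,
                        make_dataset, selection_design)

params = ModelParameters(r_c=0.195, alpha=0.202, b=0.770, D=0.019, F=4.0)
dataset = make_dataset(params, selection_design(), seed=17)
model = ToleranceDynamicsModel(
    dataset.observed_series, scenario="selection",
    grid=ToleranceGrid(12.0, 0.02), solver_rtol=1e-6,
)
result = model.fit("F3a")
print(result.summary())
```

prints

```
Tolerance-dynamics fit: variant F3a (selection, methanol)
  F = 4 mM, r_c = 0.195 1/h, n_obs = 55, grid dx = 0.02 mM, L = 12 mM
  log-likelihood = -81.089   pseudo-R2 = 0.929   converged = True
  parameter   estimate      std err       95% CI
  D             0.0340       0.0138   [0.0069, 0.0611]  mM^2/h
  alpha         0.1973       0.0346   [0.1295, 0.2652]  1/(h*mM)
  b             0.8665       0.1227   [0.6261, 1.1070]  -
```

The death coefficient α (0.197 vs the generating 0.202 h⁻¹·mM⁻¹) and
tolerance-sensitivity b (0.87 vs 0.770) come back close to truth from a
single noisy experiment; the diffusion coefficient D is the
hardest-identified parameter (here 0.034 vs 0.019 mM²·h⁻¹, the truth
inside the 95% interval) because it is informed mainly by counts near
the plating detection limit.  On noise-free data the recovery is exact.
Model structure is chosen with `phenodrift.stepwise_select(model)`, and
`phenodrift.recovery_study(...)` repeats this whole exercise over many
seeded datasets.

A thin CLI mirrors the stages: `phenodrift synth | prep | simulate |
fit | select | rates` (see `--help`).

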