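# Methods

## The model

Clonal *Methylobacterium extorquens* populations contain cells whose
maximum tolerated formaldehyde concentration ("tolerance", x, in mM)
varies continuously from 0 to about 8 mM, with abundance falling roughly
one order of magnitude per mM.  `phenodrift` models the population as a
density N(x, t) of CFU/mL over 1-D tolerance space, evolving by

    ∂N/∂t = r_c N − H(x, F) N + D ∂²N/∂x² + v ∂N/∂x

* **Growth** at the substrate-specific per-capita rate r_c (h⁻¹) is
  phenotype-independent; substrate and formaldehyde concentrations are
  effectively constant over the ≤24 h experiments, so neither is a
  dynamic variable.
* **Death** occurs only in medium formaldehyde above a cell's tolerance:
  H(x, F) = α (F − b x) for x < F, 0 otherwise.  α (h⁻¹·mM⁻¹) scales
  death with the formaldehyde concentration F; b ∈ [0, 1] (mM tolerance
  per mM formaldehyde) lets sub-threshold cells with higher tolerance die
  more slowly.
* **Phenotype transitions**: undirected lineage drift in tolerance is
  diffusion with coefficient D (mM²·h⁻¹); directed drift is advection
  with rate v (mM·h⁻¹), *positive v meaning drift toward lower
  tolerance* (the +v ∂N/∂x term translates profiles leftward).

Boundaries are zero-flux at x = 0 (tolerance cannot be negative) and at
x = L, with L above the highest observed tolerance (12 mM by default, 14
mM for succinate regrowth) so the upper boundary does not constrain
upward transitions.

## Numerics

The PDE is semi-discretized (method of lines) on a uniform grid with
dx = 0.01 mM by default.  Diffusion uses conservative flux-form central
differences; advection uses donor-cell (first-order upwind) fluxes with
closed boundary faces, which is unconditionally positivity-preserving and
exactly mass-conserving; growth/death is a diagonal term.  The resulting
constant-coefficient linear system integrates with LSODA and its exact
banded Jacobian (rtol 1e-8 by default; absolute tolerance scaled to
1e-10 of the mean bin occupancy).  Self-convergence: halving dx from
0.02 to 0.01 changes data-resolution binned output by <0.5%, so
Monte-Carlo studies run at dx = 0.02 mM and solver rtol 1e-6; headline
fits use the defaults.  Solver undershoot is clipped to zero on output
only and an error is raised if it ever exceeds 1e-6 of total mass.

## Data preparation

Plating onto agar at concentration x counts all cells with tolerance
≥ x, so raw data are cumulative; N(x) = N̂(x) − N̂(x + h) converts to the
model's non-cumulative density and a right-tail cumulative sum converts
back (exact inverses).  Preparation steps, in order:

1. **Detection-limit extension.**  Plating resolves ≥34 CFU/mL; a
   subpopulation below that reads as zero, and its later growth could
   masquerade as phenotype transitions.  At every (time, level) where all
   replicates observed zero colonies — provided a higher level has a real
   observation, or the level is the first beyond the last real
   observation — one replicate is set to 1 colony (90.9 CFU/mL given the
   10 µL spot scheme; 30.3 CFU/mL after three-replicate averaging).
   Values added by the correction are flagged and never count as
   observations when the rules are re-evaluated, making the operation
   idempotent.
2. **Replicate averaging** (arithmetic mean of CFU/mL per time × level).
3. **Monotonization** by running minimum (plating noise can produce tiny
   inversions; this is the minimal correction).
4. **Initial condition.**  The first sampled distribution (2 h after
   inoculation, avoiding stationary-phase artefacts) is interpolated with
   a monotonicity-preserving cubic spline (PCHIP) at the grid resolution
   and differenced into a density.  Beyond the highest assayed level the
   cumulative curve extends as a constant.  The spline reproduces its
   knots, so total mass equals the 0 mM count exactly.
5. For comparison with data, model densities are summed over each
   [level, next level) bin and re-accumulated to cumulative form.

## Likelihood and model selection

Counts span seven orders of magnitude and include zeros, so both sides
are transformed with asinh(x) = ln(x + √(1+x²)).  The fit criterion is
the Gaussian log-likelihood of an OLS regression of asinh(observed) on
asinh(predicted) with free intercept and slope and MLE residual variance;
an identity-line residual variant is available (`likelihood_mode=
"identity"`) for sensitivity analysis.  Pseudo-R² is the R² of the same
regression.  The residual variance is floored at 1e-12 so numerically
perfect fits return a large finite likelihood.

The initial-condition timepoint is *excluded* from the likelihood by
default: the model passes through it by construction, and counting its
near-zero residuals deflates the variance estimate and makes every
likelihood-ratio test liberal.  (`include_initial_timepoint=True`
restores the alternative.)

Free parameters are optimized by Nelder–Mead on transformed coordinates
(log for α and D, logit for b, identity for v), starting from the best
points of a coarse 3-value-per-parameter grid; nested fits warm-start
from the null model's optimum, which guarantees LR ≥ 0 up to optimizer
tolerance.  Standard errors come from a central finite-difference Hessian
of the negative log-likelihood at the optimum (step 1e-4 × max(|θ|, 1)
on the transformed scale), delta-method-mapped to the natural scale; a
non-positive-definite Hessian flags the SEs as undefined rather than
failing the fit.

Model structure is chosen by forward stepwise likelihood-ratio testing
over a nested lattice.  Selection experiments start from the α-only
model and may add b, D, and v one at a time; regrowth experiments (no
formaldehyde, hence no death) start from the parameter-free growth model
and may add v and D.  At each step all single-parameter expansions are
fitted, the highest-likelihood candidate is kept iff its LR test against
the current model has p < 0.05 (LR = −2(LL₀ − LL₁) against χ² with df =
parameter difference).

## Growth and death rates

Specific rates are OLS slopes of log2(CFU/mL) against time multiplied by
ln 2 (reported in h⁻¹; a 3.5 h doubling time is r ≈ 0.198 h⁻¹).  Zero
CFU observations are dropped from log regressions with a warning.  The
phenotype-independent check of α regresses per-concentration death rates
(negated specific rates of time-kill curves at 3–20 mM formaldehyde)
against concentration; the slope is α.

Fixed growth rates: 0.195 h⁻¹ on methanol, 0.267 h⁻¹ on succinate
(measured on naive populations without formaldehyde); they are design
constants, not fitted.

## Synthetic experiments

The generator emulates the full measurement chain so the pipeline can be
validated end to end without laboratory data.

* **Naive initial population**: cumulative frequency 10^(−x) per mM
  (slope −1 log10/mM, matching ~10⁻⁴ of cells tolerating 4 mM),
  truncated below the plating detection frequency 1.65×10⁻⁷, scaled to
  3×10⁶ CFU/mL (a 1:64 dilution of stationary culture).  **Selected
  population** (regrowth initial): the naive population run through the
  selection dynamics at the best-fit parameters for 18 h, rescaled to
  3×10⁶ CFU/mL.
* **Designs**: selection — 4 mM formaldehyde, methanol, plates 0–10 mM
  at 1 mM steps, samples at 2, 4, 8, 12, 16, 20 h; regrowth — 0 mM,
  plates 0–12 mM at 2 mM steps, samples at 2, 6, 10, 14, 18, 22 h;
  three biological replicates.
* **Observation**: per replicate the serial ten-fold dilution whose
  expected pooled 30 µL spot count is countable (≤300 colonies) is
  chosen, a Poisson colony count drawn, and converted back to CFU/mL.
  The ~34 CFU/mL detection limit and the zeros the extension corrects
  arise naturally; observation noise is counting noise, not Gaussian.
* **Pipeline-consistent truth.**  Two deliberate consistency devices
  make synthetic studies measure the estimator rather than artefacts:
  (i) the generating initial condition is itself the spline
  reconstruction of its plate-resolution coarsening, so a model fitted
  to noise-free data starts from the identical density; (ii) the truth
  carries a 30.3 CFU/mL sub-detection tail at the first plate level
  beyond its detectable range — exactly the abundance the extension rule
  hypothesizes — so the correction is true in the synthetic world.
  Without these, information lost to 1–2 mM plate resolution and the
  extension's invented cells appear as lack of fit that the optimizer
  absorbs into spurious advection.
* **Determinism**: a master seed spawns per-dataset seeds
  (`SeedSequence([seed, index])`); identical seeds reproduce datasets
  bit for bit.

What the generator does **not** emulate: between-biological-replicate
variance beyond counting noise, spot-crowding and counting error on
plates, formaldehyde consumption or substrate depletion, and any real
sub-detection tail structure other than the pegged extension level.
Passing synthetic tests therefore validates the computational pipeline
and the estimator under the model's own assumptions; it cannot certify
those assumptions for laboratory data.

## Statistical behaviour, discovered and documented

Parameter recovery on noise-free synthetic data is exact to optimizer
tolerance for every scenario, and stepwise selection on noise-free data
recovers the generating variant exactly (the spurious extra parameter is
rejected with LR ≈ 0).

Under realistic plating noise, however, the recovery studies show that
the likelihood-ratio machinery is **anticonservative**.  The initial
condition is built from the noisy first sample, so its measurement error
propagates deterministically through the forward model and produces
residuals that are *correlated across timepoints within a tolerance
level*; near the detection limit (Poisson means of order 1) these
per-level offsets are large.  The homoskedastic iid Gaussian likelihood
reads such structure as signal, so a transition parameter is added under
a no-transition truth far more often than the nominal 5%.  Point
estimates of α, b, and D remain accurate (median relative errors well
inside 20%), but stepwise decisions and Wald coverage on noisy data
should be interpreted with this caveat — for laboratory data as much as
for synthetic data, since the published procedure is the same.

## Default parameter summary

| parameter | meaning | unit | default |
|---|---|---|---|
| dx | tolerance grid step | mM | 0.01 (0.02 in MC studies) |
| L | upper boundary | mM | 12 (14 succinate regrowth) |
| r_methanol | growth rate, methanol | h⁻¹ | 0.195 |
| r_succinate | growth rate, succinate | h⁻¹ | 0.267 |
| F | medium formaldehyde | mM | 4 (selection), 0 (regrowth) |
| detection limit | smallest observable abundance | CFU/mL | 34 |
| extension abundance | hypothesized sub-detection count | CFU/mL | 90.9/replicate |
| significance | stepwise acceptance threshold | — | 0.05 |
| solver rtol | LSODA relative tolerance | — | 1e-8 (1e-6 in MC studies) |
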