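"""Maximum-likelihood fitting of tolerance-distribution dynamics.

`ToleranceDynamicsModel` bundles a plating time series with the fixed
experimental design (substrate growth rate, medium formaldehyde
concentration, tolerance grid) and prepares it for fitting: the
detection-limit extension, replicate averaging, and the spline-built
initial condition all happen at construction.  ``fit`` maximizes the
asinh-scale linear-model log-likelihood over a variant's free parameters
(Nelder–Mead on transformed coordinates, multi-start) and returns a
results object carrying estimates, Hessian standard errors, the
log-likelihood, and a pseudo-R²; nested results compare via
``likelihood_ratio_test`` and the forward-stepwise ``stepwise_select``.

Typical use::

    model = ToleranceDynamicsModel(series, scenario="selection")
    res = model.fit("F3a")
    print(res.summary())
    best, trace = stepwise_select(model)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from . import likelihood as lk
from .distributions import (
    DistributionSeries,
    apply_detection_limit_extension,
    average_replicates,
    bin_to_data_resolution,
    interpolate_initial_condition,
    monotonize,
)
from .forward import ModelParameters, simulate
from .grids import ToleranceGrid
from .variants import ModelVariant, candidate_expansions, get_variant

__all__ = [
    "ToleranceDynamicsModel",
    "ToleranceDynamicsResults",
    "LRTResult",
    "likelihood_ratio_test",
    "stepwise_select",
    "METHANOL_GROWTH_RATE",
    "SUCCINATE_GROWTH_RATE",
]

#: Exponential-phase growth rates (h⁻¹) measured on naive populations
#: without formaldehyde; fixed, not fitted.
METHANOL_GROWTH_RATE = 0.195
SUCCINATE_GROWTH_RATE = 0.267

#: Coarse multi-start grids on the natural parameter scale.
_START_GRID = {
    "alpha": (0.05, 0.2, 0.5),
    "b": (0.1, 0.5, 0.9),
    "v": (-0.1, 0.05, 0.3),
    "D": (0.005, 0.03, 0.15),
}

#: Values a newly freed parameter takes when warm-starting from a nested
#: null optimum (≈ the pinned null value, within transform range).
_NULL_START = {"alpha": 0.2, "b": 1e-3, "v": 0.0, "D": 1e-6}

# transforms to an unconstrained optimization scale:
# alpha, D > 0 via log; b in (0,1) via logit; v unconstrained.
_B_EPS = 1e-9


def _to_unconstrained(name: str, value: float) -> float:
    if name in ("alpha", "D"):
        return np.log(max(value, 1e-12))
    if name == "b":
        return float(logit(np.clip(value, _B_EPS, 1 - _B_EPS)))
    return float(value)


def _from_unconstrained(name: str, phi: float) -> float:
    if name in ("alpha", "D"):
        return float(np.exp(phi))
    if name == "b":
        return float(expit(phi))
    return float(phi)


def _jacobian(name: str, theta: float) -> float:
    """|dθ/dφ| at the optimum, for delta-method standard errors."""
    if name in ("alpha", "D"):
        return theta
    if name == "b":
        return theta * (1.0 - theta)
    return 1.0


_DEFAULT_L = {"selection": 12.0, "methanol": 12.0, "succinate": 14.0}


class ToleranceDynamicsModel:
    """Structured-population model bound to one experiment's plating data.

    Parameters
    ----------
    series : DistributionSeries
        Per-replicate cumulative plating counts over time.
    scenario : {"selection", "regrowth"}
        Selection: growth in medium containing formaldehyde (F defaults to
        4 mM, methanol growth rate).  Regrowth: formaldehyde-free medium
        (F = 0), growth rate set by ``substrate``.
    substrate : str, optional
        "methanol" or "succinate"; defaults to the series' substrate label.
    F, r_c : float, optional
        Override the design defaults.
    grid : ToleranceGrid, optional
        Tolerance grid; default dx = 0.01 mM with L = 12 mM (selection and
        methanol regrowth) or 14 mM (succinate regrowth).
    extend : bool
        Apply the detection-limit extension before averaging (default True).
    likelihood_mode : {"regression", "identity"}
        Asinh-scale linear model used for the likelihood (see
        :mod:`phenodrift.likelihood`).
    include_initial_timepoint : bool
        Whether the initial-condition sample's observations also enter the
        likelihood.  Default False: the model reproduces that timepoint by
        construction (the initial condition is splined through it), so
        counting its near-zero residuals would deflate the residual
        variance and make every likelihood-ratio test liberal.
    """

    def __init__(
        self,
        series: DistributionSeries,
        scenario: str,
        substrate: str | None = None,
        F: float | None = None,
        r_c: float | None = None,
        grid: ToleranceGrid | None = None,
        extend: bool = True,
        likelihood_mode: str = "regression",
        include_initial_timepoint: bool = False,
        solver_rtol: float = 1e-8,
    ) -> None:
        if scenario not in ("selection", "regrowth"):
            raise ValueError("scenario must be 'selection' or 'regrowth'")
        self.scenario = scenario
        self.substrate = substrate or series.substrate
        if "succinate" in self.substrate:
            default_rate, default_L = SUCCINATE_GROWTH_RATE, _DEFAULT_L["succinate"]
        else:
            default_rate, default_L = METHANOL_GROWTH_RATE, _DEFAULT_L["methanol"]
        self.F = F if F is not None else (4.0 if scenario == "selection" else 0.0)
        self.r_c = r_c if r_c is not None else default_rate
        self.grid = grid or ToleranceGrid(default_L, 0.01)
        self.likelihood_mode = likelihood_mode
        self.solver_rtol = solver_rtol

        prepared = series
        if extend and len(series.replicates) > 1:
            prepared = apply_detection_limit_extension(prepared)
        if len(prepared.replicates) > 1:
            prepared = average_replicates(prepared)
        self.data = prepared

        self.times = prepared.times  # experiment clock
        self.sim_times = self.times - self.times[0]
        self.levels = prepared.levels
        if not self.grid.covers(self.levels):
            raise ValueError("tolerance grid does not cover the data's plate levels")
        self.initial = interpolate_initial_condition(
            monotonize(prepared.at(self.times[0])), self.grid
        )
        self.include_initial_timepoint = include_initial_timepoint
        self._fit_times = self.sim_times if include_initial_timepoint else self.sim_times[1:]
        obs = [prepared.at(t).counts for t in self.times]
        if not include_initial_timepoint:
            obs = obs[1:]
        self.endog = np.concatenate(obs)  # observed cumulative CFU/mL
        self.nobs = self.endog.size

    # -- forward prediction -------------------------------------------------

    def parameters(self, **free) -> ModelParameters:
        """Full parameter set: fixed design values plus the given free ones."""
        return ModelParameters(
            r_c=self.r_c,
            F=self.F,
            alpha=free.get("alpha", 0.0),
            b=free.get("b", 0.0),
            D=free.get("D", 0.0),
            v=free.get("v", 0.0),
        )

    def predict(self, params: ModelParameters) -> np.ndarray:
        """Model cumulative CFU/mL at every (time, level), data-ordered."""
        result = simulate(self.initial, params, self.sim_times, rtol=self.solver_rtol)
        out = [
            bin_to_data_resolution(result.at(t), self.levels).counts
            for t in self._fit_times
        ]
        return np.concatenate(out)

    def loglike(self, params: ModelParameters) -> float:
        return lk.log_likelihood(self.endog, self.predict(params), self.likelihood_mode)

    # -- fitting ------------------------------------------------------------

    def _objective(self, free_names):
        def negll(phi):
            theta = {n: _from_unconstrained(n, p) for n, p in zip(free_names, phi)}
            try:
                return -self.loglike(self.parameters(**theta))
            except (RuntimeError, ValueError):
                return 1e12
        return negll

    def fit(
        self,
        variant: ModelVariant | str,
        start: dict | None = None,
        n_best_starts: int = 2,
        maxiter: int | None = None,
    ) -> "ToleranceDynamicsResults":
        """Maximize the likelihood over the variant's free parameters.

        Starting points: every combination of a coarse 3-value grid per
        free parameter is scored, and Nelder–Mead polishes the
        ``n_best_starts`` best of them (plus ``start``, if given — used to
        warm-start nested fits).  The best converged polish wins.
        """
        if isinstance(variant, str):
            variant = get_variant(variant)
        if variant.scenario != self.scenario:
            raise ValueError(
                f"variant {variant.name} is for {variant.scenario!r}, "
                f"model is {self.scenario!r}"
            )
        free = sorted(variant.free)
        if not free:  # null regrowth model: nothing to optimize
            params = self.parameters()
            pred = self.predict(params)
            return ToleranceDynamicsResults(
                model=self, variant=variant, params={}, bse={},
                llf=lk.log_likelihood(self.endog, pred, self.likelihood_mode),
                pseudo_r2=lk.pseudo_r2(self.endog, pred, self.likelihood_mode),
                predicted=pred, converged=True, n_starts=0,
            )

        negll = self._objective(free)
        grid_points = [
            np.array([_to_unconstrained(n, v) for n, v in zip(free, combo)])
            for combo in _cartesian([_START_GRID[n] for n in free])
        ]
        scores = [negll(p) for p in grid_points]
        order = np.argsort(scores)
        starts = [grid_points[i] for i in order[:n_best_starts]]
        if start is not None:
            merged = {**{n: _NULL_START[n] for n in free}, **start}
            starts.insert(0, np.array([_to_unconstrained(n, merged[n]) for n in free]))

        best = None
        for x0 in starts:
            res = optimize.minimize(
                negll,
                x0,
                method="Nelder-Mead",
                options={
                    "xatol": 1e-3,
                    "fatol": 1e-7,
                    "maxiter": maxiter or 250 * len(free),
                    "adaptive": len(free) > 2,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise RuntimeError(f"all optimization starts failed for variant {variant.name}")

        phi_hat = best.x
        theta = {n: _from_unconstrained(n, p) for n, p in zip(free, phi_hat)}
        params = self.parameters(**theta)
        pred = self.predict(params)
        bse = self._hessian_se(negll, free, phi_hat, theta)
        return ToleranceDynamicsResults(
            model=self, variant=variant, params=theta, bse=bse,
            llf=-best.fun,
            pseudo_r2=lk.pseudo_r2(self.endog, pred, self.likelihood_mode),
            predicted=pred, converged=bool(best.success), n_starts=len(starts),
        )

    def _hessian_se(self, negll, free, phi_hat, theta) -> dict:
        """Delta-method SEs from a central finite-difference Hessian."""
        p = len(free)
        h = np.array([1e-4 * max(abs(v), 1.0) for v in phi_hat])
        H = np.empty((p, p))
        f0 = negll(phi_hat)
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = h[i]
                ej = np.zeros(p); ej[j] = h[j]
                if i == j:
                    H[i, i] = (negll(phi_hat + ei) - 2 * f0 + negll(phi_hat - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        negll(phi_hat + ei + ej)
                        - negll(phi_hat + ei - ej)
                        - negll(phi_hat - ei + ej)
                        + negll(phi_hat - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            return {n: np.nan for n in free}  # non-PD Hessian: SEs undefined
        return {
            n: float(np.sqrt(d) * abs(_jacobian(n, theta[n])))
            for n, d in zip(free, diag)
        }


def _cartesian(lists):
    out = [()]
    for values in lists:
        out = [c + (v,) for c in out for v in values]
    return out


@dataclass
class ToleranceDynamicsResults:
    """Fit of one model variant: estimates, uncertainty, and diagnostics."""

    model: ToleranceDynamicsModel
    variant: ModelVariant
    params: dict
    bse: dict
    llf: float
    pseudo_r2: float
    predicted: np.ndarray
    converged: bool
    n_starts: int

    @property
    def full_params(self) -> ModelParameters:
        return self.model.parameters(**self.params)

    @property
    def df_model(self) -> int:
        return len(self.params)

    def conf_int(self, alpha: float = 0.05) -> dict:
        """Wald intervals on the natural scale, (lo, hi) per free parameter."""
        z = stats.norm.ppf(1 - alpha / 2)
        return {
            n: (self.params[n] - z * self.bse[n], self.params[n] + z * self.bse[n])
            for n in self.params
        }

    def lrtest(self, null: "ToleranceDynamicsResults") -> "LRTResult":
        return likelihood_ratio_test(null, self)

    def summary(self) -> str:
        lines = [
            f"Tolerance-dynamics fit: variant {self.variant.name} ({self.model.scenario}, "
            f"{self.model.substrate})",
            f"  F = {self.model.F:g} mM, r_c = {self.model.r_c:g} 1/h, "
            f"n_obs = {self.model.nobs}, grid dx = {self.model.grid.dx:g} mM, "
            f"L = {self.model.grid.L:g} mM",
            f"  log-likelihood = {self.llf:.3f}   pseudo-R2 = {self.pseudo_r2:.3f}   "
            f"converged = {self.converged}",
            "  parameter   estimate      std err       95% CI",
        ]
        units = {"alpha": "1/(h*mM)", "b": "-", "v": "mM/h", "D": "mM^2/h"}
        ci = self.conf_int() if self.params else {}
        for n in sorted(self.params):
            lo, hi = ci[n]
            lines.append(
                f"  {n:<9s} {self.params[n]:>10.4f} {self.bse[n]:>12.4f}   "
                f"[{lo:.4f}, {hi:.4f}]  {units[n]}"
            )
        if not self.params:
            lines.append("  (no free parameters)")
        return "\n".join(lines)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a reduced (null) against a fuller model."""

    null_name: str
    alt_name: str
    lr: float
    df: int
    pvalue: float


def likelihood_ratio_test(
    null: ToleranceDynamicsResults, alt: ToleranceDynamicsResults
) -> LRTResult:
    """LR = −2(LL₀ − LL₁) against a χ² with df = parameter-count difference.

    A (slightly) negative LR — possible if the optimizer did worse on the
    fuller model — is reported as-is, with p = 1.
    """
    if not null.variant.nests(alt.variant):
        raise ValueError(
            f"{null.variant.name} is not nested within {alt.variant.name}"
        )
    lr = -2.0 * (null.llf - alt.llf)
    df = alt.df_model - null.df_model
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return LRTResult(null.variant.name, alt.variant.name, float(lr), df, p)


def stepwise_select(
    model: ToleranceDynamicsModel,
    significance: float = 0.05,
    substrate: str | None = None,
    max_steps: int | None = None,
):
    """Forward stepwise model selection over the nested variant lattice.

    Starting from the simplest variant (α-only for selection; the
    parameter-free growth model for regrowth), every single-parameter
    expansion is fitted at each step; the highest-likelihood candidate is
    accepted iff its likelihood-ratio test against the current model is
    significant.  Returns ``(best_results, trace)`` where ``trace`` is a
    list of per-step records (fits of all candidates and the test of the
    chosen one).  ``max_steps`` caps the number of expansion rounds
    (useful when only the first accept/reject decision is of interest).

    Candidate fits are warm-started from the current model's optimum (so
    the likelihood can never fall below the null's) plus the single best
    point of the coarse start grid.
    """
    substrate = substrate or model.substrate
    prefix = "S" if "succinate" in substrate else "M"
    base = "F1" if model.scenario == "selection" else f"{prefix}0"
    current = model.fit(base)
    trace = []
    while max_steps is None or len(trace) < max_steps:
        candidates = candidate_expansions(current.variant, substrate)
        if not candidates:
            break
        fits, errors = [], {}
        for cand in candidates:
            try:
                fits.append(model.fit(cand, start=dict(current.params), n_best_starts=1))
            except RuntimeError as exc:  # selection proceeds with the rest
                errors[cand.name] = str(exc)
        if not fits:
            break
        best_cand = max(fits, key=lambda r: r.llf)
        test = likelihood_ratio_test(current, best_cand)
        trace.append(
            {
                "step": len(trace) + 1,
                "null": current.variant.name,
                "candidates": {r.variant.name: r for r in fits},
                "errors": errors,
                "chosen": best_cand.variant.name,
                "test": test,
                "accepted": test.pvalue < significance,
            }
        )
        if test.pvalue < significance:
            current = best_cand
        else:
            break
    return current, trace
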