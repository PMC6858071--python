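"""Tolerance-distribution data: containers, transforms, and preparation.

Plating a culture onto agar containing x mM formaldehyde counts every cell
whose maximum tolerance is at least x, so the raw data are *cumulative*
distributions N̂(x) (CFU/mL able to grow at ≥ x).  The population model
instead tracks the *non-cumulative* phenotype density N(x): cells whose
maximum tolerance is exactly x.  The two are related by the finite
difference

    N(x) = N̂(x) − N̂(x + h)

where h is the spacing between assayed plate concentrations (1 or 2 mM in
the experiments).  This module implements that transform and its inverse,
the detection-limit "extension" correction, replicate averaging, the
monotone cubic-spline interpolation that builds a fine-grid initial
condition for the model, and the binning of fine model output back to the
coarse resolution of the plating data.

Tolerance bins are left-closed, right-open: a cell "with tolerance x"
grows on every plate with concentration ≤ x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .grids import ToleranceGrid

__all__ = [
    "CumulativeDistribution",
    "PhenotypeDensity",
    "DistributionSeries",
    "cumulative_to_density",
    "density_to_cumulative",
    "apply_detection_limit_extension",
    "average_replicates",
    "monotonize",
    "interpolate_initial_condition",
    "bin_to_data_resolution",
    "read_series_csv",
    "write_series_csv",
    "EXTENSION_CFU_PER_ML",
]

#: CFU/mL equivalent of a single colony in one replicate's lowest-dilution
#: spot series under the plating scheme (10 µL spots, countable counts summed
#: over two adjacent dilutions and scaled by 1.1× the lower dilution factor):
#: 1 colony / 0.011 mL = 90.9 CFU/mL.
EXTENSION_CFU_PER_ML = 1.0 / 0.011

#: Canonical long-format CSV columns.
SERIES_COLUMNS = ["condition", "substrate", "replicate", "time_h", "tolerance_mM", "cfu_per_ml"]


@dataclass(frozen=True)
class CumulativeDistribution:
    """CFU/mL able to grow at plate concentration ≥ each level (N̂)."""

    levels: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if levels.ndim != 1 or levels.shape != counts.shape:
            raise ValueError("levels and counts must be 1-D arrays of equal length")
        if levels.size < 2:
            raise ValueError("need at least two tolerance levels")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("levels must be strictly ascending")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("counts must be finite and non-negative")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "counts", counts)

    @property
    def h(self) -> float:
        """Spacing between assayed levels (mM); requires a uniform ladder."""
        steps = np.diff(self.levels)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("levels are not uniformly spaced; h undefined")
        return float(steps[0])

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.counts) <= 1e-9 * max(1.0, self.counts.max())))

    @property
    def total(self) -> float:
        """Total population (all cells grow at the 0 mM level)."""
        return float(self.counts[0])


@dataclass(frozen=True)
class PhenotypeDensity:
    """Cells per mL whose maximum tolerance falls in each grid bin (N)."""

    grid: ToleranceGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"values shape {values.shape} does not match grid with {self.grid.n_bins} bins"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("density values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def mean_tolerance(self) -> float:
        """Density-weighted mean tolerance (mM)."""
        tot = self.total
        if tot <= 0:
            raise ValueError("mean tolerance undefined for empty population")
        return float(np.dot(self.grid.x, self.values) / tot)


@dataclass
class DistributionSeries:
    """Timepoint- and replicate-indexed collection of plating distributions.

    Backed by a tidy frame with columns ``replicate, time_h, tolerance_mM,
    cfu_per_ml`` (plus an internal ``extended`` flag marking counts added by
    the detection-limit correction).  All records share one ladder of
    tolerance levels.
    """

    condition: str
    substrate: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        needed = {"replicate", "time_h", "tolerance_mM", "cfu_per_ml"}
        missing = needed - set(self.frame.columns)
        if missing:
            raise ValueError(f"series frame missing columns: {sorted(missing)}")
        f = self.frame.copy()
        if "extended" not in f.columns:
            f["extended"] = False
        if (f["time_h"] < 0).any():
            raise ValueError("times must be non-negative")
        if (f["cfu_per_ml"] < 0).any():
            raise ValueError("CFU/mL must be non-negative")
        # every (replicate, time) must carry the full level ladder
        ladder = np.sort(f["tolerance_mM"].unique())
        for (rep, t), grp in f.groupby(["replicate", "time_h"]):
            lv = np.sort(grp["tolerance_mM"].to_numpy())
            if lv.size != ladder.size or not np.allclose(lv, ladder):
                raise ValueError(
                    f"replicate {rep!r} at t={t} h does not cover the common level ladder"
                )
        self.frame = f.sort_values(["replicate", "time_h", "tolerance_mM"]).reset_index(drop=True)

    @property
    def levels(self) -> np.ndarray:
        return np.sort(self.frame["tolerance_mM"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_h"].unique())

    @property
    def replicates(self) -> list:
        return sorted(self.frame["replicate"].unique())

    def at(self, time_h: float, replicate=None) -> CumulativeDistribution:
        """Cumulative distribution at one timepoint (one replicate, or the
        only replicate if the series has been averaged)."""
        f = self.frame[np.isclose(self.frame["time_h"], time_h)]
        if replicate is not None:
            f = f[f["replicate"] == replicate]
        elif len(self.replicates) > 1:
            raise ValueError("series has several replicates; specify one or average first")
        if f.empty:
            raise KeyError(f"no records at t={time_h} h")
        f = f.sort_values("tolerance_mM")
        return CumulativeDistribution(f["tolerance_mM"].to_numpy(), f["cfu_per_ml"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "condition", self.condition)
        out.insert(1, "substrate", self.substrate)
        return out[SERIES_COLUMNS + ["extended"]]


# ---------------------------------------------------------------------------
# cumulative <-> density transforms


def cumulative_to_density(cum: CumulativeDistribution) -> np.ndarray:
    """Difference a cumulative distribution into per-level density.

    ``density[i] = counts[i] − counts[i+1]``; the last level keeps its full
    cumulative count (no cells beyond the ladder).  The input must be
    non-increasing — average replicates and monotonize first if needed.
    """
    c = cum.counts
    if np.any(np.diff(c) > 1e-9 * max(1.0, c.max())):
        raise ValueError("cumulative counts increase with tolerance; monotonize first")
    den = np.empty_like(c)
    den[:-1] = c[:-1] - c[1:]
    den[-1] = c[-1]
    return np.maximum(den, 0.0)  # clip tiny negatives from the tolerance above


def density_to_cumulative(density: np.ndarray, levels: np.ndarray) -> CumulativeDistribution:
    """Accumulate per-level density back into cumulative form (right tail sum).

    Exact right-inverse of :func:`cumulative_to_density`.
    """
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise ValueError("density must be non-negative")
    counts = np.cumsum(density[::-1])[::-1]
    return CumulativeDistribution(levels, counts)


# ---------------------------------------------------------------------------
# detection-limit extension


def apply_detection_limit_extension(series: DistributionSeries) -> DistributionSeries:
    """Add one notional colony at all-zero high-tolerance levels.

    Plating cannot detect subpopulations below ~34 CFU/mL; growth of such
    undetected cells could masquerade as phenotype transitions.  The
    correction adds 1 colony (90.9 CFU/mL) to a single replicate at each
    (time, level) where every replicate observed 0 colonies, provided either

    a. some higher level has an observation of ≥1 colony at that time, or
    b. the level is the first one beyond the last level with an observation
       of ≥1 colony.

    "Observations" are real plate counts: values added by a previous call
    are flagged and ignored when the rules are evaluated, which makes the
    operation idempotent.
    """
    f = series.frame.copy()
    levels = np.sort(f["tolerance_mM"].unique())
    reps = sorted(f["replicate"].unique())

    for t in np.sort(f["time_h"].unique()):
        sel_t = np.isclose(f["time_h"], t)
        observed = f["cfu_per_ml"].where(~f["extended"], 0.0)
        # per-level: any real observation across replicates at this time
        any_obs = {
            lv: bool((observed[sel_t & np.isclose(f["tolerance_mM"], lv)] > 0).any())
            for lv in levels
        }
        nonzero_levels = [lv for lv in levels if any_obs[lv]]
        last_obs = max(nonzero_levels) if nonzero_levels else None
        for i, lv in enumerate(levels):
            if any_obs[lv]:
                continue
            sel = sel_t & np.isclose(f["tolerance_mM"], lv)
            if (f.loc[sel, "cfu_per_ml"] > 0).any():
                continue  # already extended here
            higher_obs = any(any_obs[l2] for l2 in levels[i + 1 :])
            first_beyond = (
                last_obs is not None
                and i > 0
                and levels[i - 1] <= last_obs < lv
            )
            if higher_obs or first_beyond:
                target = sel & (f["replicate"] == reps[0])
                idx = f.index[target][0]
                f.loc[idx, "cfu_per_ml"] = EXTENSION_CFU_PER_ML
                f.loc[idx, "extended"] = True
    return DistributionSeries(series.condition, series.substrate, f)


def average_replicates(series: DistributionSeries) -> DistributionSeries:
    """Arithmetic mean of CFU/mL across replicates at each (time, level)."""
    f = series.frame
    avg = (
        f.groupby(["time_h", "tolerance_mM"], as_index=False)["cfu_per_ml"]
        .mean()
        .assign(replicate="mean", extended=False)
    )
    return DistributionSeries(series.condition, series.substrate, avg)


# ---------------------------------------------------------------------------
# spline interpolation to the model grid and binning back


def monotonize(cum: CumulativeDistribution) -> CumulativeDistribution:
    """Enforce non-increase by a running minimum from the left.

    Plating noise can leave tiny inversions after averaging; the running
    minimum is the smallest correction restoring a valid cumulative curve.
    """
    return CumulativeDistribution(cum.levels, np.minimum.accumulate(cum.counts))


def interpolate_initial_condition(
    cum: CumulativeDistribution, grid: ToleranceGrid
) -> PhenotypeDensity:
    """Build a fine-grid phenotype density from a coarse cumulative curve.

    Fits a monotonicity-preserving cubic spline (PCHIP) through the coarse
    cumulative points, evaluates it at the grid resolution, and differences
    the result into the non-cumulative density.  Beyond the highest assayed
    level the cumulative curve is extended as a constant, so any residual
    count at the top level becomes density there.
    """
    if not cum.is_monotone:
        raise ValueError("cumulative input must be non-increasing; monotonize first")
    if not grid.covers(cum.levels):
        raise ValueError(
            f"grid [0, {grid.L}] does not cover data levels up to {cum.levels.max()} mM"
        )
    x = grid.x
    if cum.levels[0] > 0:
        raise ValueError("cumulative data must include the 0 mM (total population) level")
    spline = PchipInterpolator(cum.levels, cum.counts, extrapolate=False)
    fine = spline(np.clip(x, cum.levels[0], cum.levels[-1]))
    fine = np.minimum.accumulate(fine)  # guard rounding-level wiggles
    density = np.empty_like(fine)
    density[:-1] = fine[:-1] - fine[1:]
    density[-1] = fine[-1]
    return PhenotypeDensity(grid, np.maximum(density, 0.0))


def bin_to_data_resolution(
    den: PhenotypeDensity, levels: np.ndarray
) -> CumulativeDistribution:
    """Sum fine density into coarse data bins and accumulate to cumulative form.

    Coarse bin i spans [level_i, level_{i+1}); the last bin absorbs all mass
    from its level to the top of the grid, so total mass is conserved.
    """
    levels = np.asarray(levels, dtype=float)
    idx = [den.grid.index_of(lv) for lv in levels]  # raises if misaligned
    edges = idx + [den.grid.n_bins]
    coarse = np.array(
        [den.values[edges[i] : edges[i + 1]].sum() for i in range(len(levels))]
    )
    return density_to_cumulative(coarse, levels)


# ---------------------------------------------------------------------------
# CSV I/O (canonical long format)


def read_series_csv(path) -> list[DistributionSeries]:
    """Read tolerance-distribution series from a long-format CSV.

    Expected columns: condition, substrate, replicate, time_h, tolerance_mM,
    cfu_per_ml (extra columns are ignored; an ``extended`` column, if
    present, is honoured).  Returns one series per (condition, substrate).
    """
    df = pd.read_csv(path)
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"input CSV missing columns: {sorted(missing)}")
    keep = SERIES_COLUMNS + (["extended"] if "extended" in df.columns else [])
    out = []
    for (cond, sub), grp in df[keep].groupby(["condition", "substrate"]):
        out.append(
            DistributionSeries(cond, sub, grp.drop(columns=["condition", "substrate"]))
        )
    return out


def write_series_csv(series_list, path) -> None:
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(
        path, index=False
    )
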