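"""Shared fixtures.

Expensive artefacts (PDE fits, Monte-Carlo studies) are session-scoped so
several test modules can assert different properties of one computation.
Fitting fixtures run on a 0.02 mM grid with slightly relaxed solver
tolerance; the self-convergence tests demonstrate this changes binned
model output by well under a percent.
"""

from __future__ import annotations

import pytest
from hypothesis import settings as hypothesis_settings

from phenodrift import (
    ModelParameters,
    ToleranceDynamicsModel,
    ToleranceGrid,
    make_dataset,
    make_initial_distribution,
    make_selected_initial,
    regrowth_design,
    selection_design,
    simulate_experiment,
)
from phenodrift.synthetic import default_grid, plate_resolution_init

hypothesis_settings.register_profile("repeatable", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repeatable")

#: Best-fit parameters of the three experimental scenarios (selection on
#: methanol + 4 mM formaldehyde; formaldehyde-free regrowth on methanol or
#: succinate), used as generating truth throughout the suite.
SELECTION_PARAMS = ModelParameters(r_c=0.195, alpha=0.202, b=0.770, D=0.019, v=0.0, F=4.0)
METHANOL_REGROWTH_PARAMS = ModelParameters(r_c=0.195, v=0.018, F=0.0)
SUCCINATE_REGROWTH_PARAMS = ModelParameters(r_c=0.267, v=0.285, D=0.033, F=0.0)

FIT_DX = 0.02
FIT_RTOL = 1e-6


def fit_kwargs(scenario: str, substrate: str = "methanol") -> dict:
    L = 14.0 if (scenario == "regrowth" and substrate == "succinate") else 12.0
    return {"grid": ToleranceGrid(L, FIT_DX), "solver_rtol": FIT_RTOL}


def noise_free_model(scenario: str, substrate: str = "methanol") -> ToleranceDynamicsModel:
    """Noise-free synthetic experiment fitted with the standard pipeline."""
    if scenario == "selection":
        design, params = selection_design(), SELECTION_PARAMS
    elif substrate == "succinate":
        design, params = regrowth_design("succinate"), SUCCINATE_REGROWTH_PARAMS
    else:
        design, params = regrowth_design("methanol"), METHANOL_REGROWTH_PARAMS
    grid = default_grid(design, FIT_DX)
    raw = (
        make_initial_distribution(grid, N_total=design.N_total)
        if scenario == "selection"
        else make_selected_initial(grid, N_total=design.N_total)
    )
    init = plate_resolution_init(raw, design)
    true_series = simulate_experiment(init, params, design)
    return ToleranceDynamicsModel(
        true_series,
        scenario=scenario,
        substrate=substrate,
        extend=False,
        **fit_kwargs(scenario, substrate),
    )


@pytest.fixture(scope="session")
def selection_noisefree_f3a():
    """F3a fit to noise-free selection data generated at the best-fit values."""
    return noise_free_model("selection").fit("F3a")


@pytest.fixture(scope="session")
def noisy_selection_dataset():
    """One Poisson-noised selection experiment at the best-fit parameters."""
    return make_dataset(SELECTION_PARAMS, selection_design(), seed=20260901, grid_dx=FIT_DX)


@pytest.fixture(scope="session")
def noisy_selection_model(noisy_selection_dataset):
    return ToleranceDynamicsModel(
        noisy_selection_dataset.observed_series,
        scenario="selection",
        **fit_kwargs("selection"),
    )


@pytest.fixture(scope="session")
def noisy_selection_f3a(noisy_selection_model):
    return noisy_selection_model.fit("F3a")


@pytest.fixture(scope="session")
def small_regrowth_model():
    """Small noisy methanol-regrowth model for fast 0/1-parameter fits."""
    ds = make_dataset(
        METHANOL_REGROWTH_PARAMS, regrowth_design("methanol"), seed=42, grid_dx=FIT_DX
    )
    return ToleranceDynamicsModel(
        ds.observed_series, scenario="regrowth", substrate="methanol",
        **fit_kwargs("regrowth", "methanol"),
    )
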