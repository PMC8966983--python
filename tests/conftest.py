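"""Shared fixtures: expensive GP fits are session-scoped and reused."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import comboscreen as cs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sham_setup():
    """Noise-free Loewe sham self-combination (drug A vs drug A, slope 1,
    IC50 0.1 uM) with its fitted GP surface and the true Hill fit."""
    p = cs.HillParams(ic50=0.1, slope=1.0)
    spec = cs.GeneratorSpec(
        seed=2,
        noise_sd=0.0,
        surface_mode="loewe",
        hill_params={"drug_a": p, "drug_b": p},
    )
    axes = (
        cs.build_single_agent_series(1.0, 6, 3.0, drug="A"),
        cs.build_single_agent_series(1.0, 6, 3.0, drug="A-again"),
    )
    grid, truth = cs.gen_combination_grid(spec, axes=axes)
    surface = cs.fit_gp_surface(grid)
    fit = p.as_fit(max_conc=1.0)
    return grid, surface, fit


@pytest.fixture(scope="session")
def bliss_symmetric_setup():
    """Noise-free Bliss grid with identical margins on equal axes (so the
    true surface is symmetric under axis swap) and its fitted GP."""
    p = cs.HillParams(ic50=0.1, slope=1.0)
    spec = cs.GeneratorSpec(
        seed=3,
        noise_sd=0.0,
        surface_mode="bliss",
        hill_params={"drug_a": p, "drug_b": p},
    )
    axes = (
        cs.build_single_agent_series(1.0, 6, 3.0, drug="A"),
        cs.build_single_agent_series(1.0, 6, 3.0, drug="B"),
    )
    grid, truth = cs.gen_combination_grid(spec, axes=axes)
    surface = cs.fit_gp_surface(grid)
    return grid, surface, p


@pytest.fixture(scope="session")
def weak_surface():
    """Surface whose maximum inhibition stays below 50% (both margins
    plateau at viability 0.8), fitted GP included."""
    pa = cs.HillParams(ic50=0.05, slope=1.0, e_inf=0.8)
    pb = cs.HillParams(ic50=0.2, slope=1.0, e_inf=0.8)
    spec = cs.GeneratorSpec(
        seed=4,
        noise_sd=0.0,
        surface_mode="bliss",
        hill_params={"drug_a": pa, "drug_b": pb},
    )
    grid, _ = cs.gen_combination_grid(
        spec,
        axes=(
            cs.build_single_agent_series(1.0, 6, 3.0, drug="wa"),
            cs.build_single_agent_series(1.0, 6, 3.0, drug="wb"),
        ),
    )
    surface = cs.fit_gp_surface(grid)
    return surface, pa, pb


def make_single_agent_curve(params, seed=0, noise_sd=0.0, top=10.0, n=13):
    """Normalized 13-point single-agent curve generated from known truth."""
    spec = cs.GeneratorSpec(seed=seed, noise_sd=noise_sd, hill_params={"d": params})
    series = cs.build_single_agent_series(top, n, 3.0, drug="d")
    wells, _ = cs.gen_single_agent_plate(spec, series=series, drug="d")
    viab = cs.normalize_to_control(wells)
    pts = [(w.conc_a, viab[w]) for w in wells if not w.is_control]
    return cs.DoseResponseCurve("d", "line", pts)
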