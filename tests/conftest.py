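import numpy as np
import pytest

from ecoflux import (
    EfficiencyModel,
    Guild,
    MetabolicCoefficients,
    ReconstructionParams,
    generate_landscape,
)
from ecoflux.community import RESOURCE_CLASSES, STRATA


def make_guild(gid="g", group="soil_arthropod", mass=1.0, sd=None, biomass=1.0,
               occ=None, prefs=None, protection=0.0, n_pct=10.0, hunt=1.0,
               metab="invertebrate"):
    """Small guild factory for toy webs."""
    occupancy = dict.fromkeys(STRATA, 0.0)
    occupancy.update(occ or {"soil": 1.0})
    preferences = dict.fromkeys(RESOURCE_CLASSES, "none")
    preferences.update(prefs or {"litter": "main"})
    return Guild(
        guild_id=gid,
        group=group,
        body_mass_mean=mass,
        body_mass_sd=0.6 * mass if sd is None else sd,
        biomass=biomass,
        density=biomass * 1000.0 / mass,
        stratum_occupancy=occupancy,
        resource_prefs=preferences,
        protection=protection,
        nitrogen_pct=n_pct,
        hunting_modifier=hunt,
        metabolic_group=metab,
    )


@pytest.fixture(scope="session")
def landscape():
    """Default synthetic landscape, 32 plots, fixed seed."""
    return generate_landscape(seed=1)


@pytest.fixture(scope="session")
def rainforest_plot(landscape):
    return next(p for p in landscape.plots if p.system == "rainforest")


@pytest.fixture
def default_params():
    return ReconstructionParams()


@pytest.fixture(scope="session")
def coeffs():
    return MetabolicCoefficients.default()


@pytest.fixture(scope="session")
def eff_model():
    return EfficiencyModel.default()


def random_feasible_web(rng, n_cons=10, n_basal=5):
    """Random column-stochastic diet matrix with guaranteed basal grounding.

    Every consumer gets a substantial basal diet share, which keeps the
    steady-state system diagonally dominant and hence feasible.
    """
    W = np.zeros((n_basal + n_cons, n_cons))
    for j in range(n_cons):
        basal_share = rng.uniform(0.5, 1.0)
        b = rng.dirichlet(np.ones(n_basal)) * basal_share
        prey = rng.dirichlet(np.ones(n_cons)) * (1 - basal_share)
        prey[j] = 0.0
        col = np.concatenate([b, prey])
        W[:, j] = col / col.sum()
    X = rng.uniform(0.1, 5.0, size=n_cons)
    e = rng.uniform(0.15, 1.0, size=n_basal + n_cons)
    return W, X, e


def fixed_point_ingestion(W, X, e, n_basal=5, tol=1e-12, max_iter=100_000):
    """Independent oracle: damped fixed-point iteration G <- (X + P G)/e_bar."""
    e_bar = e @ W
    P = W[n_basal:, :]
    G = X / e_bar
    for _ in range(max_iter):
        G_new = (X + P @ G) / e_bar
        if np.max(np.abs(G_new - G)) < tol:
            return G_new
        G = 0.5 * G + 0.5 * G_new
    raise RuntimeError("fixed point did not converge")
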