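import math

import numpy as np
import pytest

from ecoflux import (
    EfficiencyModel,
    MetabolicCoefficients,
    analyze_plot,
    assimilation_efficiency,
    faeces_production,
    metabolic_loss,
    solve_fluxes,
)
from ecoflux.energetics import BOLTZMANN_EV, celsius_to_kelvin
from ecoflux.errors import ConfigError, EnergeticsError
from ecoflux.reconstruction import FoodWebTopology

from conftest import fixed_point_ingestion, make_guild, random_feasible_web

BASAL = ("plants", "litter", "fungi", "bacteria", "som")


def _topology(W, consumer_ids=None, groups=None):
    W = np.asarray(W, dtype=float)
    n = W.shape[1]
    ids = consumer_ids or [f"c{j}" for j in range(n)]
    return FoodWebTopology(
        basal_nodes=BASAL,
        consumer_ids=ids,
        W=W,
        link_count=int(np.count_nonzero(W)),
        consumer_groups=groups or {cid: "soil_arthropod" for cid in ids},
        plot_id="toy",
    )


def single_link_web(e_resource=0.5):
    """One consumer feeding exclusively on plants."""
    W = np.zeros((6, 1))
    W[0, 0] = 1.0
    e = np.ones(6)
    e[0] = e_resource
    return _topology(W), e


# ---------------------------------------------------------------------------
# metabolic regressions
# ---------------------------------------------------------------------------

def test_mass_scaling_of_ectotherm_rate():
    """With a = 0.75 and E = 0, doubling body mass scales the per-individual
    rate by 2^0.75."""
    coeffs = MetabolicCoefficients(groups={"x": {"kind": "ectotherm_arrhenius", "ln_x0": 0.0, "a": 0.75, "E": 0.0}})
    g1 = make_guild(mass=10.0, metab="x")
    g2 = make_guild(mass=20.0, metab="x")
    g1.density = g2.density = 1.0
    r1 = metabolic_loss(g1, 298.15, coeffs)
    r2 = metabolic_loss(g2, 298.15, coeffs)
    assert r2 / r1 == pytest.approx(2**0.75, rel=1e-12)


def test_rate_increases_with_temperature(coeffs):
    g = make_guild(mass=5.0, metab="invertebrate")
    rates = [metabolic_loss(g, t, coeffs) for t in (278.15, 288.15, 298.15, 308.15)]
    assert all(b > a for a, b in zip(rates, rates[1:]))


def test_ectotherm_rate_matches_closed_form_oracle(coeffs):
    """M = 10 mg at 298.15 K: direct evaluation of the regression, including
    the J/h -> mW conversion and density scaling."""
    g = make_guild(mass=10.0, biomass=0.05, metab="invertebrate")  # density = 5 m^-2
    c = coeffs.groups["invertebrate"]
    expected_per_ind = math.exp(c["ln_x0"] + c["a"] * math.log(10.0) - c["E"] / (BOLTZMANN_EV * 298.15))
    expected = expected_per_ind * (1000.0 / 3600.0) * g.density
    assert metabolic_loss(g, 298.15, coeffs) == pytest.approx(expected, rel=1e-12)


def test_endotherm_rate_is_temperature_independent(coeffs):
    g = make_guild(mass=20_000.0, group="bird", metab="bird", prefs={"invertebrate_prey": "main"})
    assert metabolic_loss(g, 293.15, coeffs) == metabolic_loss(g, 303.15, coeffs)


def test_unknown_metabolic_group_raises(coeffs):
    g = make_guild(metab="plasma_being")
    with pytest.raises(ConfigError, match="plasma_being"):
        metabolic_loss(g, 298.15, coeffs)


def test_temperature_outside_plausible_range_rejected(coeffs):
    with pytest.raises(EnergeticsError):
        metabolic_loss(make_guild(), 250.0, coeffs)


# ---------------------------------------------------------------------------
# assimilation efficiencies
# ---------------------------------------------------------------------------

def test_basal_lookup_defaults(eff_model):
    assert assimilation_efficiency("plants", eff_model) == 0.21
    assert assimilation_efficiency("litter", eff_model) == 0.18
    assert assimilation_efficiency("som", eff_model) == 0.13
    assert assimilation_efficiency("bacteria", eff_model) == 0.96
    assert assimilation_efficiency("fungi", eff_model) == 0.36


def test_animal_efficiency_from_nitrogen(eff_model):
    """The nitrogen equation spans the low-N detritivore to high-N predator
    range: ~0.61 at 6% N (millipede-like) up to ~0.97 at 11% N."""
    millipede = make_guild(n_pct=6.0)
    centipede = make_guild(n_pct=11.0)
    assert assimilation_efficiency(millipede, eff_model) == pytest.approx(0.61, abs=0.01)
    assert assimilation_efficiency(centipede, eff_model) == pytest.approx(0.97, abs=0.01)
    # clipped to (0.01, 1]
    assert assimilation_efficiency(make_guild(n_pct=0.1), eff_model) == 0.01
    assert assimilation_efficiency(make_guild(n_pct=500.0), eff_model) == 1.0


def test_lookup_mode_with_guild_entry_and_fallback():
    model = EfficiencyModel(mode="lookup", lookup={"plants": 0.21, "special": 0.5, "animal": 0.9})
    assert assimilation_efficiency(make_guild("special"), model) == 0.5
    assert assimilation_efficiency(make_guild("other"), model) == 0.9
    with pytest.raises(ConfigError, match="som"):
        assimilation_efficiency("som", model)


# ---------------------------------------------------------------------------
# steady-state solver
# ---------------------------------------------------------------------------

def test_single_consumer_closed_form():
    """One resource at efficiency e: ingestion G = X / e."""
    topo, e = single_link_web(e_resource=0.5)
    res = solve_fluxes(topo, X=[10.0], e_res=e)
    assert res.G[0] == pytest.approx(20.0)
    assert res.F[0, 0] == pytest.approx(20.0)
    assert abs(res.balance_residuals[0]) < 1e-12


def test_two_level_chain_hand_solved():
    """basal -> C -> P with all e = 1 and X = (1, 1): G_P = 1, G_C = 2,
    flux C->P = 1 and basal->C = 2."""
    W = np.zeros((7, 2))
    W[0, 0] = 1.0  # C eats plants
    W[5, 1] = 1.0  # P eats C (row 5 = first consumer row)
    topo = _topology(W, consumer_ids=["C", "P"])
    res = solve_fluxes(topo, X=[1.0, 1.0], e_res=np.ones(7))
    assert res.G[1] == pytest.approx(1.0)
    assert res.G[0] == pytest.approx(2.0)
    assert res.F[5, 1] == pytest.approx(1.0)
    assert res.F[0, 0] == pytest.approx(2.0)


def test_direct_solve_equals_fixed_point_oracle_on_random_webs():
    """>= 200 random feasible webs: the linear solve agrees with the damped
    fixed-point iteration to 1e-10 and balances every consumer to 1e-8
    relative."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(3, 12))
        W, X, e = random_feasible_web(rng, n_cons=n)
        topo = _topology(W)
        res = solve_fluxes(topo, X, e)
        oracle = fixed_point_ingestion(W, X, e, n_basal=5)
        assert np.allclose(res.G, oracle, rtol=1e-10, atol=1e-10)
        scale = np.maximum(res.X, 1e-12)
        assert (np.abs(res.balance_residuals) <= 1e-8 * scale).all()
        assert (res.F >= 0).all()


def test_flux_linearity_in_metabolic_losses():
    rng = np.random.default_rng(11)
    W, X, e = random_feasible_web(rng, n_cons=6)
    topo = _topology(W)
    res1 = solve_fluxes(topo, X, e)
    res3 = solve_fluxes(topo, 3.0 * X, e)
    assert np.allclose(res3.F, 3.0 * res1.F, rtol=1e-12)


def test_removing_a_predator_never_increases_prey_ingestion():
    """Dropping a predator removes its predation losses, so every remaining
    consumer's ingestion can only fall or stay equal (brute force on small webs)."""
    rng = np.random.default_rng(23)
    for _ in range(30):
        n_prey = int(rng.integers(2, 6))
        n = n_prey + 1  # last consumer is the predator
        W = np.zeros((5 + n, n))
        for j in range(n_prey):
            W[:5, j] = rng.dirichlet(np.ones(5))  # prey eat basal only
        W[5:5 + n_prey, n_prey] = rng.dirichlet(np.ones(n_prey))  # predator eats prey
        X = rng.uniform(0.1, 2.0, size=n)
        e = rng.uniform(0.2, 1.0, size=5 + n)
        res = solve_fluxes(_topology(W), X, e)

        W2 = W[:5 + n_prey, :n_prey]
        res2 = solve_fluxes(_topology(W2), X[:n_prey], e[:5 + n_prey])
        assert (res2.G <= res.G[:n_prey] + 1e-9).all()
        # predation losses were strictly positive, so ingestion strictly falls
        assert (res2.G < res.G[:n_prey]).all()


def test_mutual_predation_loop_is_infeasible():
    W = np.zeros((7, 2))
    W[6, 0] = 1.0  # c0 eats c1
    W[5, 1] = 1.0  # c1 eats c0
    e = np.ones(7) * 0.5
    with pytest.raises(EnergeticsError, match="infeasible|singular"):
        solve_fluxes(_topology(W), X=[1.0, 1.0], e_res=e)


def test_zero_mean_efficiency_rejected():
    topo, e = single_link_web()
    e[0] = 0.0
    with pytest.raises(EnergeticsError, match="efficiency"):
        solve_fluxes(topo, X=[1.0], e_res=e)


# ---------------------------------------------------------------------------
# faeces production
# ---------------------------------------------------------------------------

def test_faeces_zero_at_full_assimilation():
    topo, e = single_link_web(e_resource=1.0)
    res = solve_fluxes(topo, X=[10.0], e_res=e)
    assert faeces_production(res) == 0.0


def test_faeces_single_link():
    topo, e = single_link_web(e_resource=0.5)
    res = solve_fluxes(topo, X=[10.0], e_res=e)  # F = 20, e = 0.5
    assert faeces_production(res) == pytest.approx(10.0)


def test_faeces_toy_web_matches_link_sum():
    """Three-node toy web: the faeces total equals the hand-summed
    Σ F_ij (1 − e_i) over its links."""
    W = np.zeros((7, 2))
    W[0, 0] = 0.6
    W[1, 0] = 0.4
    W[5, 1] = 1.0
    topo = _topology(W)
    e = np.ones(7)
    e[0], e[1], e[5] = 0.2, 0.5, 0.8
    res = solve_fluxes(topo, X=[2.0, 1.0], e_res=e)
    expected = res.F[0, 0] * 0.8 + res.F[1, 0] * 0.5 + res.F[5, 1] * 0.2
    assert faeces_production(res) == pytest.approx(expected, rel=1e-12)
    assert faeces_production(res, consumer_subset=["c1"]) == pytest.approx(res.F[5, 1] * 0.2)


def test_analyze_plot_balances_every_consumer(rainforest_plot, coeffs, eff_model):
    topo, res = analyze_plot(rainforest_plot, coeffs=coeffs, eff_model=eff_model)
    scale = np.maximum(res.X, 1e-12)
    assert (np.abs(res.balance_residuals) <= 1e-8 * scale).all()
    assert (res.G >= 0).all()
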