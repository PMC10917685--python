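import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from ecoflux import (
    PlotCommunity,
    ReconstructionParams,
    link_weight,
    mass_suitability,
    preference_weight,
    reconstruct_topology,
    spatial_overlap,
)
from ecoflux.errors import ParameterError, ReconstructionError
from ecoflux.reconstruction import normal_overlap, topology_edge_list

from conftest import make_guild

# Overlapping coefficients frozen from an independent quadrature oracle
# (integral of min of the two normal pdfs over [-20, 20]).
QUADRATURE_CASES = [
    ((0.0, 0.3, 0.5, 0.3), 0.40465676192726163),
    ((0.0, 0.2, 0.4, 0.5), 0.45317553519656356),
    ((1.2, 0.15, 0.3, 0.6), 0.16986423618950125),
]


def _plot(guilds, plot_id="toy"):
    return PlotCommunity(plot_id=plot_id, system="rainforest", region="region1",
                         soil_temperature=25.0, guilds=guilds)


@pytest.mark.parametrize("level,omnivory,expected", [
    ("auxiliary", 0.2, 0.2),
    ("main", 0.0, 1.0),
    ("main", 0.7, 1.0),
    ("none", 0.3, 0.0),
    ("auxiliary", 1.0, 1.0),
    ("auxiliary", 0.0, 0.0),
])
def test_preference_weight(level, omnivory, expected):
    assert preference_weight(level, omnivory) == expected


def test_preference_weight_rejects_bad_omnivory():
    with pytest.raises(ParameterError):
        preference_weight("main", 1.5)


@pytest.mark.parametrize("args,expected", QUADRATURE_CASES)
def test_normal_overlap_matches_quadrature_oracle(args, expected):
    assert float(normal_overlap(*args)) == pytest.approx(expected, abs=1e-9)


@given(
    mu1=st.floats(-3, 3), mu2=st.floats(-3, 3),
    s1=st.floats(0.05, 2), s2=st.floats(0.05, 2),
)
@settings(max_examples=200, derandomize=True)
def test_normal_overlap_properties(mu1, mu2, s1, s2):
    """Symmetric, bounded in [0,1], 1 for identical densities."""
    v = float(normal_overlap(mu1, s1, mu2, s2))
    assert 0.0 <= v <= 1.0
    assert v == pytest.approx(float(normal_overlap(mu2, s2, mu1, s1)), abs=1e-9)
    assert float(normal_overlap(mu1, s1, mu1, s1)) == pytest.approx(1.0)


def test_mass_suitability_identical_distributions_is_one(default_params):
    # predator 100x prey with equal log-scale spreads: preferred-prey
    # distribution coincides with the prey distribution (PPMR optimum 10^2)
    prey = make_guild("prey", mass=1.0, sd=0.6)
    pred = make_guild("pred", mass=100.0, sd=60.0, prefs={"invertebrate_prey": "main"})
    assert mass_suitability(pred, prey, default_params) == pytest.approx(1.0, abs=1e-9)


def test_mass_suitability_distant_distributions_vanish(default_params):
    prey = make_guild("prey", mass=1.0, sd=0.1)  # sigma floored to 0.1 log10 units
    pred = make_guild("pred", mass=100.0, sd=10.0, hunt=-2.0)  # optimum 4 log10 units away
    assert mass_suitability(pred, prey, default_params) < 1e-6


def test_mass_suitability_relaxed_to_one_at_full_relaxation():
    params = ReconstructionParams(size_structure=1.0)
    prey = make_guild("prey", mass=0.01)
    pred = make_guild("pred", mass=1e6)
    assert mass_suitability(pred, prey, params) == pytest.approx(1.0)


def test_spatial_overlap_cases(default_params):
    canopy = make_guild("c", group="canopy_arthropod", occ={"canopy": 1.0})
    soil = make_guild("s", occ={"soil": 1.0})
    assert spatial_overlap(canopy, soil, default_params) == 0.0
    bird = make_guild("b", group="bird", occ={"canopy": 1.0}, prefs={"invertebrate_prey": "main"})
    assert spatial_overlap(bird, canopy, default_params) == 1.0
    a = make_guild("a", occ={"soil": 0.5, "litter": 0.5})
    b = make_guild("d", occ={"soil": 0.2, "litter": 0.8})
    assert spatial_overlap(a, b, default_params) == pytest.approx(0.7)
    assert spatial_overlap(a, b, ReconstructionParams(spatial_structure=1.0)) == 1.0


def test_link_weight_protection_biomass_and_self_predation(default_params):
    pred = make_guild("pred", mass=100.0, prefs={"invertebrate_prey": "main"})
    armoured = make_guild("prey", mass=1.0, protection=1.0)
    assert link_weight(pred, armoured, default_params) == 0.0

    prey1 = make_guild("prey", mass=1.0, biomass=1.0)
    prey2 = make_guild("prey", mass=1.0, biomass=2.0)
    w1 = link_weight(pred, prey1, default_params)
    w2 = link_weight(pred, prey2, default_params)
    assert w1 > 0 and w2 == pytest.approx(2 * w1)

    cannibal = make_guild("pred", mass=100.0, prefs={"invertebrate_prey": "main"})
    assert link_weight(cannibal, cannibal, default_params) == 0.0
    free = ReconstructionParams(self_predation=1.0)
    other = make_guild("other", mass=100.0, prefs={"invertebrate_prey": "main"})
    assert link_weight(cannibal, cannibal, free) == pytest.approx(link_weight(other, cannibal, free))

    herbivore = make_guild("h", prefs={"plants": "main"})
    assert link_weight(herbivore, prey1, default_params) == 0.0  # no animal preference


def test_link_weight_basal_ignores_biomass(default_params):
    g = make_guild("h", prefs={"plants": "main", "litter": "auxiliary"})
    assert link_weight(g, "plants", default_params) == 1.0
    assert link_weight(g, "litter", default_params) == pytest.approx(0.2)
    assert link_weight(g, "som", default_params) == 0.0


def test_single_herbivore_topology(default_params):
    plot = _plot([make_guild("h", prefs={"plants": "main"})])
    topo = reconstruct_topology(plot, default_params)
    assert topo.link_count == 1
    assert topo.W[topo.basal_nodes.index("plants"), 0] == 1.0


def test_three_guild_topology_matches_hand_oracle(default_params):
    """Column shares equal independently hand-composed raw weights.

    The oracle recomputes each rule from its definition: preference level
    weights, the quadrature overlap of the two log10-normal densities, the
    summed minimum stratum occupancy, prey biomass and protection discount,
    then normalizes the predator's column by hand.
    """
    from scipy.integrate import quad

    herb = make_guild("herb", mass=2.0, sd=1.2, biomass=0.5,
                      occ={"litter": 0.5, "ground": 0.5}, prefs={"plants": "main"},
                      protection=0.3)
    detr = make_guild("detr", mass=8.0, sd=4.8, biomass=1.5,
                      occ={"litter": 0.8, "soil": 0.2},
                      prefs={"litter": "main", "som": "auxiliary"}, protection=0.1)
    pred = make_guild("pred", mass=300.0, sd=180.0, biomass=0.2,
                      occ={"litter": 0.6, "ground": 0.4},
                      prefs={"invertebrate_prey": "main"}, protection=0.2, hunt=0.5)
    topo = reconstruct_topology(_plot([herb, detr, pred]),
                                ReconstructionParams(min_diet_fraction=0.0))

    ln10 = np.log(10)
    def sig(g):
        return max(g.body_mass_sd / (g.body_mass_mean * ln10), 0.1)

    def ovl(m1, s1, m2, s2):
        return quad(lambda x: min(norm.pdf(x, m1, s1), norm.pdf(x, m2, s2)), -20, 20, limit=400)[0]

    mu_pref = np.log10(300.0) - 2.0 * 0.5
    w_herb = 1.0 * ovl(mu_pref, sig(pred), np.log10(2.0), sig(herb)) * (0.5 + 0.4) * 0.5 * 0.7
    w_detr = 1.0 * ovl(mu_pref, sig(pred), np.log10(8.0), sig(detr)) * 0.6 * 1.5 * 0.9
    j = topo.consumer_index("pred")
    got_herb = topo.W[topo.node_names.index("herb"), j]
    got_detr = topo.W[topo.node_names.index("detr"), j]
    assert got_herb == pytest.approx(w_herb / (w_herb + w_detr), rel=1e-7)
    assert got_detr == pytest.approx(w_detr / (w_herb + w_detr), rel=1e-7)

    # detritivore column: litter main vs som auxiliary
    jd = topo.consumer_index("detr")
    assert topo.W[topo.node_names.index("litter"), jd] == pytest.approx(1 / 1.2)
    assert topo.W[topo.node_names.index("som"), jd] == pytest.approx(0.2 / 1.2)


def test_columns_are_stochastic_on_synthetic_plot(rainforest_plot, default_params):
    topo = reconstruct_topology(rainforest_plot, default_params)
    sums = topo.W.sum(axis=0)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert (topo.W >= 0).all()
    assert np.allclose(np.diag(topo.W[len(topo.basal_nodes):, :]), 0.0)


def test_raising_prey_biomass_never_lowers_its_diet_share(default_params):
    """Monotonicity of diet shares in prey biomass, on randomized communities."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        guilds = [
            make_guild(f"g{i}", mass=float(rng.lognormal(1, 1)),
                       biomass=float(rng.uniform(0.1, 2)),
                       occ={"soil": 0.5, "litter": 0.5},
                       prefs={"litter": "main", "invertebrate_prey": "main"},
                       protection=float(rng.uniform(0, 0.8)))
            for i in range(5)
        ]
        topo0 = reconstruct_topology(_plot(guilds), ReconstructionParams(min_diet_fraction=0.0))
        k = int(rng.integers(0, 5))
        guilds[k].biomass *= 3.0
        topo1 = reconstruct_topology(_plot(guilds), ReconstructionParams(min_diet_fraction=0.0))
        row = topo0.node_names.index(f"g{k}")
        assert (topo1.W[row, :] >= topo0.W[row, :] - 1e-12).all()


def test_full_relaxation_gives_equal_shares(default_params):
    """All five scalars at 1 neutralize mass, space, protection and the
    auxiliary/main distinction; with equal prey biomasses every permissible
    item gets the same share."""
    relaxed = ReconstructionParams(omnivory=1.0, self_predation=1.0, size_structure=1.0,
                                   spatial_structure=1.0, protection_use=1.0,
                                   min_diet_fraction=0.0)
    a = make_guild("a", mass=0.1, biomass=1.0, occ={"canopy": 1.0},
                   prefs={"plants": "main", "litter": "auxiliary", "invertebrate_prey": "auxiliary"},
                   protection=0.9)
    b = make_guild("b", mass=500.0, biomass=1.0, occ={"soil": 1.0},
                   prefs={"fungi": "auxiliary", "invertebrate_prey": "main"}, protection=0.2)
    topo = reconstruct_topology(_plot([a, b]), relaxed)
    ja = topo.consumer_index("a")
    shares_a = topo.W[:, ja][topo.W[:, ja] > 0]
    assert len(shares_a) == 4  # plants, litter, a itself, b
    assert np.allclose(shares_a, 0.25, atol=1e-12)
    jb = topo.consumer_index("b")
    shares_b = topo.W[:, jb][topo.W[:, jb] > 0]
    assert len(shares_b) == 3  # fungi, a, b
    assert np.allclose(shares_b, 1 / 3, atol=1e-12)


def test_pruning_zero_threshold_is_identity(default_params):
    """With threshold 0 the link set equals the raw permissible link set."""
    guilds = [
        make_guild("h", mass=1.0, biomass=0.5, prefs={"plants": "main", "litter": "auxiliary"}),
        make_guild("d", mass=2.0, biomass=1.0, prefs={"litter": "main", "som": "auxiliary"}),
        make_guild("p", mass=150.0, biomass=0.2, prefs={"invertebrate_prey": "main"}),
    ]
    t0 = reconstruct_topology(_plot(guilds), ReconstructionParams(min_diet_fraction=0.0))
    t1 = reconstruct_topology(_plot(guilds), ReconstructionParams(min_diet_fraction=1e-12))
    # every permissible pair is present: 2+2 basal links + predator's 2 prey
    assert t0.link_count == 6
    assert t0.link_count == t1.link_count
    assert np.allclose(t0.W, t1.W)


def test_pruning_removes_weak_links_and_renormalizes(rainforest_plot):
    pruned = reconstruct_topology(rainforest_plot, ReconstructionParams(min_diet_fraction=0.05))
    full = reconstruct_topology(rainforest_plot, ReconstructionParams(min_diet_fraction=0.0))
    assert pruned.link_count <= full.link_count
    assert np.allclose(pruned.W.sum(axis=0), 1.0, atol=1e-9)
    nonzero = pruned.W[pruned.W > 0]
    # one-pass pruning: surviving raw shares were >= threshold before renormalization
    assert nonzero.min() >= 0.05


def test_impossible_consumer_raises_named_error():
    lonely = make_guild("cave_predator", mass=10.0, occ={"soil": 1.0},
                        prefs={"invertebrate_prey": "main"})
    with pytest.raises(ReconstructionError, match="cave_predator"):
        reconstruct_topology(_plot([lonely]))


def test_zero_biomass_consumers_are_excluded(default_params):
    h = make_guild("h", prefs={"plants": "main"})
    ghost = make_guild("ghost", biomass=0.0, prefs={"plants": "main"})
    topo = reconstruct_topology(_plot([h, ghost]), default_params)
    assert topo.consumer_ids == ["h"]


def test_graphml_export_round_trips_structure(rainforest_plot, default_params, tmp_path):
    import networkx as nx

    from ecoflux import topology_to_graph

    topo = reconstruct_topology(rainforest_plot, default_params)
    g = topology_to_graph(topo)
    assert g.number_of_nodes() == len(topo.node_names)
    assert g.number_of_edges() == topo.link_count
    nx.write_graphml(g, tmp_path / "web.graphml")
    back = nx.read_graphml(tmp_path / "web.graphml")
    assert back.number_of_edges() == topo.link_count


def test_edge_list_matches_matrix(rainforest_plot, default_params):
    topo = reconstruct_topology(rainforest_plot, default_params)
    edges = topology_edge_list(topo)
    assert len(edges) == topo.link_count
    total = edges.groupby("consumer")["diet_share"].sum()
    assert np.allclose(total.to_numpy(), 1.0, atol=1e-9)
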