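"""Trait-based food-web reconstruction.

Builds, for one plot, the weighted and column-normalized diet-share matrix
``W`` (rows = resources, columns = consumers) from five jointly applied rules:

1. *Resource preferences* — inherited feeding preferences to basal resources
   (living plants, leaf litter, fungi, bacteria, soil organic matter) and to
   invertebrate/vertebrate prey, coded as none/auxiliary/main.
2. *Size structure* — predator–prey interactions are filtered by the optimum
   predator–prey mass ratio (PPMR): the overlap between the prey's body-mass
   distribution and the predator's preferred-prey-mass distribution, both
   treated as normal on the log10-mass axis.
3. *Spatial structure* — overlap of vertical-stratum occupancies
   (soil/litter/ground/canopy); canopy-foraging birds fully overlap with
   canopy arthropods.
4. *Biomass dependence* — encounter rates make locally abundant animal prey
   preferred; basal-resource biomass is not used.
5. *Protection* — physically, chemically or behaviourally protected prey are
   consumed less.

Each rule carries a 0–1 relaxation scalar (0 = rule fully applied, 1 = rule
ignored), implemented as linear interpolation between the rule's value and 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .community import BASAL_RESOURCES, STRATA, Guild, PlotCommunity
from .errors import ParameterError, ReconstructionError

__all__ = [
    "ReconstructionParams",
    "FoodWebTopology",
    "preference_weight",
    "mass_suitability",
    "spatial_overlap",
    "link_weight",
    "reconstruct_topology",
    "topology_edge_list",
    "topology_to_graph",
]

#: Floor on the log10-scale body-mass SD used in the overlap rule; avoids
#: degenerate (zero-width) distributions for guilds with tiny measured SDs.
LOG10_SIGMA_FLOOR = 0.1

_LN10 = np.log(10.0)


@dataclass
class ReconstructionParams:
    """Reconstruction settings: five 0–1 relaxation scalars plus constants.

    The five scalars match the sensitivity-sweep semantics: ``omnivory`` is
    the weight of auxiliary resources (0 = full specialization, 1 = full
    generalism; default 0.2, i.e. auxiliary resources five times less
    important than main ones); ``self_predation`` scales cannibalistic links
    (0 = none allowed); ``size_structure``, ``spatial_structure`` and
    ``protection_use`` relax the corresponding filtering rules toward
    "ignored" at 1.
    """

    omnivory: float = 0.2
    self_predation: float = 0.0
    size_structure: float = 0.0
    spatial_structure: float = 0.0
    protection_use: float = 0.0
    ppmr_log10_optimum: float = 2.0  # predator 100x heavier than preferred prey
    min_diet_fraction: float = 0.01

    _SCALARS = ("omnivory", "self_predation", "size_structure", "spatial_structure", "protection_use")

    def __post_init__(self) -> None:
        for name in self._SCALARS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v!r} outside [0, 1]")
        if not 0.0 <= self.min_diet_fraction < 0.5:
            raise ParameterError(f"min_diet_fraction={self.min_diet_fraction!r} outside [0, 0.5)")

    def with_scalar(self, name: str, value: float) -> "ReconstructionParams":
        if name not in self._SCALARS:
            raise ParameterError(f"unknown reconstruction scalar {name!r}")
        return replace(self, **{name: value})


@dataclass
class FoodWebTopology:
    """Reconstructed web for one plot: diet-share matrix over named nodes.

    ``W`` has ``len(basal_nodes) + len(consumer_ids)`` rows and one column per
    consumer; every column of a consumer with positive biomass sums to 1.
    ``consumer_groups`` keeps each consumer's major group so downstream stages
    can scope fluxes without re-reading the plot.
    """

    basal_nodes: tuple[str, ...]
    consumer_ids: list[str]
    W: np.ndarray
    link_count: int
    consumer_groups: dict[str, str] = field(default_factory=dict)
    plot_id: str = ""

    @property
    def node_names(self) -> list[str]:
        return list(self.basal_nodes) + list(self.consumer_ids)

    def consumer_index(self, guild_id: str) -> int:
        return self.consumer_ids.index(guild_id)


def preference_weight(level: str, omnivory: float) -> float:
    """Numeric weight of a preference level: main → 1, none → 0, auxiliary → omnivory."""
    if not 0.0 <= omnivory <= 1.0:
        raise ParameterError(f"omnivory={omnivory!r} outside [0, 1]")
    if level == "main":
        return 1.0
    if level == "none":
        return 0.0
    if level == "auxiliary":
        return omnivory
    raise ParameterError(f"unknown preference level {level!r}")


def normal_overlap(mu1, sigma1, mu2, sigma2):
    """Overlapping coefficient ∫ min(f1, f2) of two normal densities.

    Closed form via the crossing points of the two densities; symmetric,
    bounded in [0, 1], equal to 1 iff the densities coincide.  Accepts scalars
    or broadcastable arrays.
    """
    mu1, sigma1, mu2, sigma2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (mu1, sigma1, mu2, sigma2))
    )
    # Order so distribution 1 is the narrower one.
    swap = sigma1 > sigma2
    m1 = np.where(swap, mu2, mu1)
    s1 = np.where(swap, sigma2, sigma1)
    m2 = np.where(swap, mu1, mu2)
    s2 = np.where(swap, sigma1, sigma2)

    equal_s = np.isclose(s1, s2, rtol=1e-12, atol=1e-15)
    # Equal spreads: one crossing at the midpoint.
    d = np.abs(m1 - m2)
    ovl_equal = 2.0 * norm.cdf(-d / np.where(equal_s, 2.0 * s1, 1.0))

    # Unequal spreads: two crossings x1 < x2; the narrower density dominates
    # between them, so OVL = F2(x2) - F2(x1) + F1(x1) + 1 - F1(x2).
    s1u = np.where(equal_s, 1.0, s1)
    s2u = np.where(equal_s, 2.0, s2)
    a = 1.0 / s1u**2 - 1.0 / s2u**2
    b = -2.0 * (m1 / s1u**2 - m2 / s2u**2)
    c = m1**2 / s1u**2 - m2**2 / s2u**2 + 2.0 * np.log(s1u / s2u)
    disc = np.maximum(b**2 - 4.0 * a * c, 0.0)
    sq = np.sqrt(disc)
    x1 = (-b - sq) / (2.0 * a)
    x2 = (-b + sq) / (2.0 * a)
    lo = np.minimum(x1, x2)
    hi = np.maximum(x1, x2)
    ovl_unequal = (
        norm.cdf((hi - m2) / s2u)
        - norm.cdf((lo - m2) / s2u)
        + norm.cdf((lo - m1) / s1u)
        + 1.0
        - norm.cdf((hi - m1) / s1u)
    )
    out = np.where(equal_s, ovl_equal, ovl_unequal)
    return np.clip(out, 0.0, 1.0)


def log10_mass_sigma(guild: Guild) -> float:
    """Log10-scale SD of a guild's body-mass distribution (delta method, floored)."""
    if guild.body_mass_mean <= 0:
        raise ReconstructionError(f"guild {guild.guild_id!r}: nonpositive body mass")
    sigma = guild.body_mass_sd / (guild.body_mass_mean * _LN10)
    return max(float(sigma), LOG10_SIGMA_FLOOR)


def mass_suitability(predator: Guild, prey: Guild, params: ReconstructionParams) -> float:
    """Size-structure rule: body-mass distribution overlap on the log10 axis.

    The prey's distribution N(log10 m_prey, σ_prey) is compared with the
    predator's preferred-prey distribution, centred the (possibly
    hunting-modified) optimum PPMR below the predator's own mass.  The result
    is relaxed toward 1 by ``size_structure``.
    """
    if predator.body_mass_mean <= 0 or prey.body_mass_mean <= 0:
        raise ReconstructionError("mass_suitability requires positive body masses")
    mu_prey = np.log10(prey.body_mass_mean)
    mu_pref = np.log10(predator.body_mass_mean) - params.ppmr_log10_optimum * predator.hunting_modifier
    s = float(normal_overlap(mu_pref, log10_mass_sigma(predator), mu_prey, log10_mass_sigma(prey)))
    return (1.0 - params.size_structure) * s + params.size_structure


def spatial_overlap(predator: Guild, prey: Guild, params: ReconstructionParams) -> float:
    """Spatial-structure rule: Σ over strata of min occupancy, relaxed toward 1.

    Canopy-foraging birds get full overlap with canopy arthropods regardless
    of their own stratum split (canopy fogging samples the birds' entire
    foraging space).
    """
    if predator.group == "bird" and prey.group == "canopy_arthropod" and predator.stratum_occupancy["canopy"] > 0:
        v = 1.0
    else:
        v = sum(
            min(predator.stratum_occupancy[s], prey.stratum_occupancy[s]) for s in STRATA
        )
    return (1.0 - params.spatial_structure) * v + params.spatial_structure


def _protection_discount(prey: Guild, params: ReconstructionParams) -> float:
    base = 1.0 - prey.protection
    return (1.0 - params.protection_use) * base + params.protection_use


def link_weight(predator: Guild, prey_node, params: ReconstructionParams) -> float:
    """Raw (unnormalized) diet weight of one predator–resource pair.

    ``prey_node`` is a basal-resource name or a prey :class:`Guild`.  Basal
    weights use the preference level only (basal biomass is deliberately not
    used).  Animal-prey weights combine preference, mass suitability, spatial
    overlap, prey biomass and the protection discount; same-guild prey is
    additionally scaled by ``self_predation``.
    """
    if isinstance(prey_node, str):
        if prey_node not in BASAL_RESOURCES:
            raise ParameterError(f"unknown basal resource {prey_node!r}")
        return preference_weight(predator.resource_prefs[prey_node], params.omnivory)
    prey: Guild = prey_node
    pref_class = "vertebrate_prey" if prey.group == "bird" else "invertebrate_prey"
    p = preference_weight(predator.resource_prefs[pref_class], params.omnivory)
    if p == 0.0:
        return 0.0
    w = (
        p
        * mass_suitability(predator, prey, params)
        * spatial_overlap(predator, prey, params)
        * prey.biomass
        * _protection_discount(prey, params)
    )
    if prey.guild_id == predator.guild_id:
        w *= params.self_predation
    return w


# ---------------------------------------------------------------------------
# Plot-level assembly (vectorized over all pairs)
# ---------------------------------------------------------------------------

def _raw_weight_matrix(consumers: Sequence[Guild], params: ReconstructionParams) -> np.ndarray:
    """Raw weights, rows = 5 basal + consumers-as-prey, columns = consumers."""
    n = len(consumers)
    nb = len(BASAL_RESOURCES)
    W = np.zeros((nb + n, n))

    pref = {lvl: preference_weight(lvl, params.omnivory) for lvl in ("none", "auxiliary", "main")}
    for j, pred in enumerate(consumers):
        for i, res in enumerate(BASAL_RESOURCES):
            W[i, j] = pref[pred.resource_prefs[res]]

    if n == 0:
        return W

    mu = np.log10([g.body_mass_mean for g in consumers])
    sig = np.array([log10_mass_sigma(g) for g in consumers])
    hunt = np.array([g.hunting_modifier for g in consumers])
    occ = np.array([[g.stratum_occupancy[s] for s in STRATA] for g in consumers])
    biomass = np.array([g.biomass for g in consumers])
    protect = np.array([g.protection for g in consumers])
    is_bird = np.array([g.group == "bird" for g in consumers])
    is_canopy_arth = np.array([g.group == "canopy_arthropod" for g in consumers])
    canopy_forager = is_bird & (occ[:, STRATA.index("canopy")] > 0)

    # prey i (rows) x predator j (columns)
    mu_pref = mu[None, :] - params.ppmr_log10_optimum * hunt[None, :]
    mass_s = normal_overlap(mu_pref, sig[None, :], mu[:, None], sig[:, None])
    mass_s = (1.0 - params.size_structure) * mass_s + params.size_structure

    # spatial overlap[i_prey, j_pred] = sum over strata of min occupancy
    space = np.minimum(occ[:, None, :], occ[None, :, :]).sum(axis=2)
    space[np.ix_(is_canopy_arth, canopy_forager)] = 1.0
    space = (1.0 - params.spatial_structure) * space + params.spatial_structure

    disc = (1.0 - params.protection_use) * (1.0 - protect) + params.protection_use

    pref_invert = np.array([pref[g.resource_prefs["invertebrate_prey"]] for g in consumers])
    pref_vert = np.array([pref[g.resource_prefs["vertebrate_prey"]] for g in consumers])
    # preference of predator j for prey i depends on prey i's class
    pref_ij = np.where(is_bird[:, None], pref_vert[None, :], pref_invert[None, :])

    animal = pref_ij * mass_s * space * biomass[:, None] * disc[:, None]
    np.fill_diagonal(animal, np.diag(animal) * params.self_predation)
    W[nb:, :] = animal
    return W


def reconstruct_topology(plot: PlotCommunity, params: ReconstructionParams | None = None) -> FoodWebTopology:
    """Assemble the column-normalized, pruned diet matrix for one plot.

    Consumers with zero biomass are excluded from the web.  After
    normalization, diet shares below ``min_diet_fraction`` are removed in a
    single pass and each column is renormalized.  A consumer whose permissible
    diet weights are all zero signals inconsistent traits and raises
    :class:`ReconstructionError`.
    """
    params = params or ReconstructionParams()
    consumers = [g for g in plot.guilds if g.biomass > 0]
    if not consumers:
        raise ReconstructionError(f"plot {plot.plot_id!r}: no guild with positive biomass")

    W = _raw_weight_matrix(consumers, params)
    sums = W.sum(axis=0)
    dead = np.flatnonzero(sums <= 0)
    if dead.size:
        names = [consumers[j].guild_id for j in dead]
        raise ReconstructionError(
            f"plot {plot.plot_id!r}: consumer(s) {names} have no permissible diet (all weights zero)"
        )
    W = W / sums

    if params.min_diet_fraction > 0:
        W[W < params.min_diet_fraction] = 0.0
        sums = W.sum(axis=0)
        dead = np.flatnonzero(sums <= 0)
        if dead.size:
            names = [consumers[j].guild_id for j in dead]
            raise ReconstructionError(f"plot {plot.plot_id!r}: pruning removed the entire diet of {names}")
        W = W / sums

    return FoodWebTopology(
        basal_nodes=BASAL_RESOURCES,
        consumer_ids=[g.guild_id for g in consumers],
        W=W,
        link_count=int(np.count_nonzero(W)),
        consumer_groups={g.guild_id: g.group for g in consumers},
        plot_id=plot.plot_id,
    )


def topology_edge_list(topology: FoodWebTopology) -> pd.DataFrame:
    """Nonzero diet shares as a long table (plot_id, resource, consumer, diet_share)."""
    names = topology.node_names
    rows = []
    for j, cons in enumerate(topology.consumer_ids):
        col = topology.W[:, j]
        for i in np.flatnonzero(col):
            rows.append(
                {
                    "plot_id": topology.plot_id,
                    "resource": names[i],
                    "consumer": cons,
                    "diet_share": float(col[i]),
                }
            )
    return pd.DataFrame(rows, columns=["plot_id", "resource", "consumer", "diet_share"])


def topology_to_graph(topology: FoodWebTopology):
    """Directed resource→consumer graph (networkx) with diet-share edge weights."""
    import networkx as nx

    g = nx.DiGraph(plot_id=topology.plot_id)
    for name in topology.basal_nodes:
        g.add_node(name, kind="basal")
    for cons in topology.consumer_ids:
        g.add_node(cons, kind="consumer", group=topology.consumer_groups.get(cons, ""))
    for _, row in topology_edge_list(topology).iterrows():
        g.add_edge(row["resource"], row["consumer"], diet_share=row["diet_share"])
    return g
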