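"""Metabolic losses, assimilation efficiencies and the steady-state flux solver.

The steady-state assumption: each consumer's assimilated energy intake exactly
covers its metabolic loss plus its losses to predation,

    ē_j G_j = X_j + Σ_k W_jk G_k

where G_j is consumer j's total ingestion (mW m⁻²), X_j its community-level
metabolic loss, W_jk the diet share of node j in predator k's diet and
ē_j = Σ_i W_ij e_i the diet-weighted mean assimilation efficiency.  Basal
nodes are unconstrained sources.  The system is linear in G and solved
directly; per-link fluxes follow as F_ij = W_ij G_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .community import BASAL_RESOURCES, Guild, PlotCommunity
from .errors import ConfigError, EnergeticsError
from .reconstruction import FoodWebTopology, ReconstructionParams, reconstruct_topology

__all__ = [
    "BOLTZMANN_EV",
    "MetabolicCoefficients",
    "EfficiencyModel",
    "FluxResult",
    "metabolic_loss",
    "assimilation_efficiency",
    "solve_fluxes",
    "faeces_production",
    "analyze_plot",
    "celsius_to_kelvin",
]

#: Boltzmann constant in eV per Kelvin.
BOLTZMANN_EV = 8.617333e-5

#: 1 J h⁻¹ expressed in mW.
_JPH_TO_MW = 1000.0 / 3600.0


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


@dataclass
class MetabolicCoefficients:
    """Per-group metabolic regression coefficients.

    Each group maps to ``{"kind": ..., "ln_x0": ..., "a": ..., "E": ...}``
    with ``kind`` either ``ectotherm_arrhenius`` (mass + Arrhenius
    temperature dependence) or ``endotherm_power`` (mass power law,
    temperature-independent).  Rates are per individual in J h⁻¹ with body
    mass in mg; they are converted to mW here.
    """

    groups: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "MetabolicCoefficients":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw, str(path))

    @classmethod
    def default(cls) -> "MetabolicCoefficients":
        raw = yaml.safe_load(resources.files("ecoflux.data").joinpath("metabolic_coeffs.yaml").read_text())
        return cls._from_mapping(raw, "package default metabolic_coeffs.yaml")

    @classmethod
    def _from_mapping(cls, raw: Mapping, source: str) -> "MetabolicCoefficients":
        if not isinstance(raw, Mapping) or "groups" not in raw:
            raise ConfigError(f"{source}: expected a top-level 'groups' mapping")
        groups = {}
        for name, entry in raw["groups"].items():
            kind = entry.get("kind")
            if kind not in ("ectotherm_arrhenius", "endotherm_power"):
                raise ConfigError(f"{source}: group {name!r} has unknown kind {kind!r}")
            a = float(entry["a"])
            E = float(entry.get("E", 0.0))
            if not 0.0 < a < 1.5:
                raise ConfigError(f"{source}: group {name!r} mass exponent a={a} outside (0, 1.5)")
            if kind == "ectotherm_arrhenius" and not 0.0 <= E <= 1.5:
                raise ConfigError(f"{source}: group {name!r} activation energy E={E} outside [0, 1.5] eV")
            groups[name] = {"kind": kind, "ln_x0": float(entry["ln_x0"]), "a": a, "E": E}
        return cls(groups=groups)

    def resolve(self, metabolic_group: str) -> dict:
        try:
            return self.groups[metabolic_group]
        except KeyError:
            raise ConfigError(f"unresolvable metabolic_group {metabolic_group!r}") from None


def metabolic_loss(guild: Guild, temperature: float, coeffs: MetabolicCoefficients) -> float:
    """Community-level metabolic loss of one guild, mW m⁻².

    ``temperature`` is in Kelvin.  The per-individual regression rate is
    scaled by the guild's density; endotherm rates ignore temperature.
    """
    if guild.body_mass_mean <= 0 or guild.density < 0:
        raise EnergeticsError(f"guild {guild.guild_id!r}: mass must be > 0 and density >= 0")
    if not 273.0 <= temperature <= 320.0:
        raise EnergeticsError(f"temperature {temperature!r} K outside the plausible range [273, 320]")
    c = coeffs.resolve(guild.metabolic_group)
    ln_m = np.log(guild.body_mass_mean)
    if c["kind"] == "ectotherm_arrhenius":
        ln_rate = c["ln_x0"] + c["a"] * ln_m - c["E"] / (BOLTZMANN_EV * temperature)
    else:
        ln_rate = c["ln_x0"] + c["a"] * ln_m
    per_individual_mw = float(np.exp(ln_rate)) * _JPH_TO_MW
    return per_individual_mw * guild.density


@dataclass
class EfficiencyModel:
    """Diet-specific assimilation efficiencies.

    Basal resources always come from ``lookup``.  Animal prey use either the
    lookup (guild_id, then the ``animal`` fallback) or, in
    ``nitrogen_equation`` mode, ``clip(slope·ln(%N) + intercept, 0.01, 1)``
    on the prey's nitrogen content.
    """

    mode: str = "nitrogen_equation"
    lookup: dict[str, float] = field(default_factory=dict)
    slope: float = 0.594
    intercept: float = -0.454

    def __post_init__(self) -> None:
        if self.mode not in ("lookup", "nitrogen_equation"):
            raise ConfigError(f"unknown efficiency mode {self.mode!r}")
        for key, e in self.lookup.items():
            if not 0.0 < e <= 1.0:
                raise ConfigError(f"efficiency lookup[{key!r}]={e!r} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "EfficiencyModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        eq = raw.get("equation", {})
        return cls(
            mode=raw.get("mode", "nitrogen_equation"),
            lookup={str(k): float(v) for k, v in raw.get("lookup", {}).items()},
            slope=float(eq.get("slope", 0.594)),
            intercept=float(eq.get("intercept", -0.454)),
        )

    @classmethod
    def default(cls) -> "EfficiencyModel":
        text = resources.files("ecoflux.data").joinpath("efficiencies.yaml").read_text()
        raw = yaml.safe_load(text)
        eq = raw.get("equation", {})
        return cls(
            mode=raw.get("mode", "nitrogen_equation"),
            lookup={str(k): float(v) for k, v in raw.get("lookup", {}).items()},
            slope=float(eq.get("slope", 0.594)),
            intercept=float(eq.get("intercept", -0.454)),
        )


def assimilation_efficiency(node, model: EfficiencyModel) -> float:
    """Efficiency of one resource node (basal name or prey :class:`Guild`)."""
    if isinstance(node, str):
        if node not in model.lookup:
            raise ConfigError(f"no efficiency configured for basal resource {node!r}")
        return model.lookup[node]
    guild: Guild = node
    if model.mode == "lookup":
        if guild.guild_id in model.lookup:
            return model.lookup[guild.guild_id]
        if "animal" in model.lookup:
            return model.lookup["animal"]
        raise ConfigError(f"no efficiency configured for animal node {guild.guild_id!r}")
    if guild.nitrogen_pct <= 0:
        raise ConfigError(f"guild {guild.guild_id!r}: %N required for nitrogen-equation efficiencies")
    e = model.slope * float(np.log(guild.nitrogen_pct)) + model.intercept
    return float(np.clip(e, 0.01, 1.0))


@dataclass
class FluxResult:
    """Solved steady-state fluxes for one plot.

    ``F`` is the per-link flux matrix aligned with the topology's ``W``
    (rows = resources, columns = consumers, mW m⁻²); ``e_res`` the per-resource
    efficiencies; ``X`` and ``G`` the per-consumer metabolic losses and total
    ingestion.
    """

    topology: FoodWebTopology
    X: np.ndarray
    G: np.ndarray
    F: np.ndarray
    e_res: np.ndarray
    balance_residuals: np.ndarray

    @property
    def consumer_ids(self) -> list[str]:
        return self.topology.consumer_ids


def solve_fluxes(topology: FoodWebTopology, X, e_res) -> FluxResult:
    """Solve the steady-state system for the ingestion vector G and link fluxes.

    ``X`` is the per-consumer metabolic-loss vector (mW m⁻²) and ``e_res`` the
    per-resource-row efficiency vector (length = number of rows of ``W``).
    Raises :class:`EnergeticsError` when the system is singular, a mean
    efficiency is zero, or any ingestion comes out negative (an energetically
    infeasible web).
    """
    W = topology.W
    nb = len(topology.basal_nodes)
    n = len(topology.consumer_ids)
    X = np.asarray(X, dtype=float)
    e_res = np.asarray(e_res, dtype=float)
    if X.shape != (n,):
        raise EnergeticsError(f"X has shape {X.shape}, expected ({n},)")
    if e_res.shape != (nb + n,):
        raise EnergeticsError(f"e_res has shape {e_res.shape}, expected ({nb + n},)")
    if np.any(X < 0):
        raise EnergeticsError("metabolic losses must be non-negative")

    e_bar = e_res @ W  # diet-weighted mean efficiency per consumer
    if np.any(e_bar <= 0):
        bad = [topology.consumer_ids[j] for j in np.flatnonzero(e_bar <= 0)]
        raise EnergeticsError(f"zero mean assimilation efficiency for consumer(s) {bad}")

    # Predation-loss matrix: P[j, k] = diet share of consumer j in predator k.
    P = W[nb:, :]
    A = np.diag(e_bar) - P
    try:
        G = np.linalg.solve(A, X)
    except np.linalg.LinAlgError as exc:
        raise EnergeticsError(f"singular steady-state system: {exc}") from exc
    if np.any(G < -1e-9):
        raise EnergeticsError("energetically infeasible web: negative ingestion in the steady-state solution")
    G = np.maximum(G, 0.0)

    F = W * G[None, :]
    assimilated_in = (e_res[:, None] * F).sum(axis=0)
    predation_out = F[nb:, :].sum(axis=1)
    residuals = assimilated_in - X - predation_out
    return FluxResult(topology=topology, X=X, G=G, F=F, e_res=e_res, balance_residuals=residuals)


def faeces_production(result: FluxResult, consumer_subset=None) -> float:
    """Total unassimilated food, Σ over links of F_ij (1 − e_i), mW m⁻².

    ``consumer_subset`` optionally restricts the sum to links whose consumer
    (recipient) is in the given collection of guild ids — e.g. the
    belowground compartment.
    """
    unassimilated = result.F * (1.0 - result.e_res)[:, None]
    if consumer_subset is None:
        return float(unassimilated.sum())
    idx = [j for j, cid in enumerate(result.consumer_ids) if cid in set(consumer_subset)]
    return float(unassimilated[:, idx].sum())


def efficiency_vector(plot: PlotCommunity, topology: FoodWebTopology, model: EfficiencyModel) -> np.ndarray:
    """Per-resource-row efficiencies aligned with the topology's ``W``."""
    e = [assimilation_efficiency(res, model) for res in topology.basal_nodes]
    for cid in topology.consumer_ids:
        e.append(assimilation_efficiency(plot.guild(cid), model))
    return np.array(e)


def analyze_plot(
    plot: PlotCommunity,
    params: ReconstructionParams | None = None,
    coeffs: MetabolicCoefficients | None = None,
    eff_model: EfficiencyModel | None = None,
) -> tuple[FoodWebTopology, FluxResult]:
    """Reconstruct one plot's web and solve its steady-state fluxes."""
    params = params or ReconstructionParams()
    coeffs = coeffs or MetabolicCoefficients.default()
    eff_model = eff_model or EfficiencyModel.default()
    topology = reconstruct_topology(plot, params)
    t_kelvin = celsius_to_kelvin(plot.soil_temperature)
    X = np.array([metabolic_loss(plot.guild(cid), t_kelvin, coeffs) for cid in topology.consumer_ids])
    e_res = efficiency_vector(plot, topology, eff_model)
    return topology, solve_fluxes(topology, X, e_res)
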