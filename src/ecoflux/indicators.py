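"""Trophic functions and bulk food-web indicators.

Fluxes are classified by their donor node into six trophic functions
(herbivory, litter feeding, fungivory, bacterivory, soil feeding, predation)
and summarized into six bulk parameters per (sub-)web: total biomass, total
energy flux, number of trophic links, trophic hierarchy (predation ÷ basal
consumption), bacteria:fungi flux ratio and the faeces-production ÷
soil-organic-matter-consumption ratio.

Scopes: the whole web, the 'green' aboveground compartment (canopy arthropods
and birds), the 'brown' belowground compartment (soil arthropods and
earthworms), or a single major group (``group:<name>``).  Undefined ratios
(zero denominator) are reported as missing values, never as infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import GROUPS, PlotCommunity
from .energetics import FluxResult, faeces_production
from .errors import ParameterError
from .reconstruction import FoodWebTopology

__all__ = [
    "ABOVEGROUND_GROUPS",
    "BELOWGROUND_GROUPS",
    "TROPHIC_FUNCTIONS",
    "TrophicFunctionBreakdown",
    "IndicatorSet",
    "classify_trophic_functions",
    "bulk_indicators",
    "predation_to_herbivory",
    "aggregate_by_system",
    "plot_indicator_table",
]

#: Compartment membership is fixed by major group: birds are always
#: aboveground and earthworms always belowground, regardless of foraging strata.
ABOVEGROUND_GROUPS = frozenset({"canopy_arthropod", "bird"})
BELOWGROUND_GROUPS = frozenset({"soil_arthropod", "earthworm"})

#: Donor basal node → trophic function name.
_BASAL_FUNCTION = {
    "plants": "herbivory",
    "litter": "litter_feeding",
    "fungi": "fungivory",
    "bacteria": "bacterivory",
    "som": "soil_feeding",
}

TROPHIC_FUNCTIONS = ("herbivory", "litter_feeding", "fungivory", "bacterivory", "soil_feeding", "predation")

COMPARTMENTS = ("whole", "aboveground", "belowground") + tuple(f"group:{g}" for g in GROUPS)


def _scope_consumer_mask(topology: FoodWebTopology, compartment: str) -> np.ndarray:
    groups = [topology.consumer_groups[cid] for cid in topology.consumer_ids]
    if compartment == "whole":
        return np.ones(len(groups), dtype=bool)
    if compartment == "aboveground":
        return np.array([g in ABOVEGROUND_GROUPS for g in groups])
    if compartment == "belowground":
        return np.array([g in BELOWGROUND_GROUPS for g in groups])
    if compartment.startswith("group:"):
        name = compartment.split(":", 1)[1]
        if name not in GROUPS:
            raise ParameterError(f"unknown group scope {compartment!r}")
        return np.array([g == name for g in groups])
    raise ParameterError(f"unknown scope {compartment!r}")


@dataclass
class TrophicFunctionBreakdown:
    """Flux totals (mW m⁻²) per trophic function, for one scope."""

    herbivory: float
    litter_feeding: float
    fungivory: float
    bacterivory: float
    soil_feeding: float
    predation: float
    scope: str = "whole"

    def total(self) -> float:
        return sum(getattr(self, f) for f in TROPHIC_FUNCTIONS)

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in TROPHIC_FUNCTIONS}


def classify_trophic_functions(result: FluxResult, scope: str = "whole") -> TrophicFunctionBreakdown:
    """Sum fluxes by donor class, restricted to recipients in ``scope``."""
    topology = result.topology
    mask = _scope_consumer_mask(topology, scope)
    nb = len(topology.basal_nodes)
    F_scope = result.F[:, mask]
    values = {}
    for i, basal in enumerate(topology.basal_nodes):
        values[_BASAL_FUNCTION[basal]] = float(F_scope[i, :].sum())
    values["predation"] = float(F_scope[nb:, :].sum())
    return TrophicFunctionBreakdown(scope=scope, **values)


@dataclass
class IndicatorSet:
    """The six bulk parameters plus the trophic-function breakdown for one scope.

    ``bf_ratio`` and ``faeces_to_som`` are computed only for the whole-web and
    belowground scopes; ratios with a zero denominator are ``None``.
    """

    compartment: str
    total_biomass: float  # g m^-2
    total_flux: float  # mW m^-2
    n_links: int
    trophic_hierarchy: float | None
    bf_ratio: float | None
    faeces_to_som: float | None
    functions: TrophicFunctionBreakdown

    def as_rows(self, plot_id: str = "") -> list[dict]:
        rows = []
        scalars = {
            "total_biomass": self.total_biomass,
            "total_flux": self.total_flux,
            "n_links": self.n_links,
            "trophic_hierarchy": self.trophic_hierarchy,
            "bf_ratio": self.bf_ratio,
            "faeces_to_som": self.faeces_to_som,
            **{f"function_{k}": v for k, v in self.functions.as_dict().items()},
        }
        for name, value in scalars.items():
            rows.append(
                {
                    "plot_id": plot_id,
                    "compartment": self.compartment,
                    "indicator": name,
                    "value": float("nan") if value is None else float(value),
                }
            )
        return rows


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def bulk_indicators(
    plot: PlotCommunity,
    topology: FoodWebTopology,
    result: FluxResult,
    compartment: str = "whole",
) -> IndicatorSet:
    """Compute the bulk parameters for one scope of a solved plot."""
    mask = _scope_consumer_mask(topology, compartment)
    scope_ids = {cid for cid, m in zip(topology.consumer_ids, mask) if m}
    functions = classify_trophic_functions(result, compartment)

    total_biomass = sum(g.biomass for g in plot.guilds if g.guild_id in scope_ids)
    total_flux = float(result.G[mask].sum())
    n_links = int(np.count_nonzero(topology.W[:, mask]))

    basal_consumption = sum(v for k, v in functions.as_dict().items() if k != "predation")
    trophic_hierarchy = _ratio(functions.predation, basal_consumption)

    bf_ratio = None
    faeces_to_som = None
    if compartment in ("whole", "belowground"):
        bf_ratio = _ratio(functions.bacterivory, functions.fungivory)
        faeces = faeces_production(result, consumer_subset=scope_ids)
        faeces_to_som = _ratio(faeces, functions.soil_feeding)

    return IndicatorSet(
        compartment=compartment,
        total_biomass=total_biomass,
        total_flux=total_flux,
        n_links=n_links,
        trophic_hierarchy=trophic_hierarchy,
        bf_ratio=bf_ratio,
        faeces_to_som=faeces_to_som,
        functions=functions,
    )


def predation_to_herbivory(result: FluxResult, group: str) -> float | None:
    """Predation flux into a major group divided by its plant-feeding flux.

    ``None`` when the group receives no herbivory flux (undefined ratio).
    """
    if group not in ("bird", "canopy_arthropod", "soil_arthropod"):
        raise ParameterError(f"predation_to_herbivory not defined for group {group!r}")
    breakdown = classify_trophic_functions(result, f"group:{group}")
    return _ratio(breakdown.predation, breakdown.herbivory)


def plot_indicator_table(
    plot: PlotCommunity,
    topology: FoodWebTopology,
    result: FluxResult,
    compartments=("whole", "aboveground", "belowground") + tuple(f"group:{g}" for g in GROUPS),
) -> pd.DataFrame:
    """Long indicator table (plot_id, compartment, indicator, value) for one plot."""
    rows: list[dict] = []
    for comp in compartments:
        rows.extend(bulk_indicators(plot, topology, result, comp).as_rows(plot_id=plot.plot_id))
    return pd.DataFrame(rows, columns=["plot_id", "compartment", "indicator", "value"])


def aggregate_by_system(
    indicator_table: pd.DataFrame,
    plot_systems: pd.DataFrame | dict,
    baseline_system: str = "rainforest",
) -> pd.DataFrame:
    """Descriptive per-system summary of per-plot indicators.

    ``indicator_table`` is the long per-plot table; ``plot_systems`` maps
    plot_id → land-use system (dict or a frame with plot_id/system columns).
    Returns, per (system, compartment, indicator): mean, SD (n−1 denominator),
    n, the count of excluded undefined values and the percent change of the
    mean vs the baseline system,  (x̄_sys − x̄_base)/x̄_base × 100.
    """
    if isinstance(plot_systems, pd.DataFrame):
        mapping = dict(zip(plot_systems["plot_id"].astype(str), plot_systems["system"]))
    else:
        mapping = dict(plot_systems)
    df = indicator_table.copy()
    df["system"] = df["plot_id"].map(mapping)
    if df["system"].isna().any():
        missing = sorted(df.loc[df["system"].isna(), "plot_id"].unique())
        raise ParameterError(f"no land-use system known for plot(s) {missing}")

    rows = []
    grouped = df.groupby(["system", "compartment", "indicator"], sort=False)
    for (system, comp, ind), grp in grouped:
        vals = grp["value"].to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        rows.append(
            {
                "system": system,
                "compartment": comp,
                "indicator": ind,
                "mean": float(np.mean(defined)) if defined.size else math.nan,
                "sd": float(np.std(defined, ddof=1)) if defined.size > 1 else (0.0 if defined.size == 1 else math.nan),
                "n": int(defined.size),
                "n_undefined": int(vals.size - defined.size),
            }
        )
    out = pd.DataFrame(rows)

    base = out[out["system"] == baseline_system].set_index(["compartment", "indicator"])["mean"]
    pct = []
    for _, row in out.iterrows():
        b = base.get((row["compartment"], row["indicator"]), math.nan)
        if b is None or (isinstance(b, float) and (math.isnan(b) or b == 0)):
            pct.append(math.nan)
        else:
            pct.append((row["mean"] - b) / b * 100.0)
    out["pct_change_vs_rainforest"] = pct
    return out
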