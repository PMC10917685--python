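"""Community data model: trophic guilds, plots, datasets, readers/writers, validation.

A *trophic guild* is the node unit of the food web: a set of taxa aggregated by
shared feeding preferences, body size and habitat stratum.  A plot holds one
local community (all guilds observed at a site) together with the site metadata
needed downstream (land-use system, region, soil temperature, tree heights).

Canonical units are fixed at this boundary and used everywhere downstream:

* body mass — mg fresh weight per individual,
* biomass — g fresh weight per m²,
* density — individuals per m²,
* temperature — °C in files, converted to Kelvin inside the energetics stage,
* energy flux — mW per m².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError

__all__ = [
    "STRATA",
    "BASAL_RESOURCES",
    "RESOURCE_CLASSES",
    "PREF_LEVELS",
    "GROUPS",
    "SYSTEMS",
    "REGIONS",
    "Guild",
    "PlotCommunity",
    "CommunityDataset",
    "ValidationReport",
    "read_community_tables",
    "write_community_tables",
    "validate_dataset",
    "merge_soil_litter_layers",
]

#: Vertical strata a guild can occupy (occupancies sum to 1).
STRATA = ("soil", "litter", "ground", "canopy")

#: Basal resource nodes: the five entry points of energy into the animal web.
BASAL_RESOURCES = ("plants", "litter", "fungi", "bacteria", "som")

#: Resource-preference classes a guild can hold (basal classes + animal prey).
RESOURCE_CLASSES = BASAL_RESOURCES + ("invertebrate_prey", "vertebrate_prey")

PREF_LEVELS = ("none", "auxiliary", "main")
GROUPS = ("bird", "canopy_arthropod", "soil_arthropod", "earthworm")
SYSTEMS = ("rainforest", "jungle_rubber", "rubber", "oil_palm")
REGIONS = ("region1", "region2")

_OCC_SUM_TOL = 1e-9
_OCC_RENORM_TOL = 1e-6


@dataclass
class Guild:
    """One consumer node: traits of a trophic guild in one plot.

    ``resource_prefs`` maps every resource class to ``none``/``auxiliary``/
    ``main``; the numeric weighting of these levels happens only in the
    reconstruction stage.  ``protection`` aggregates physical, chemical and
    behavioural defences on a 0–1 scale (1 = fully protected).
    ``hunting_modifier`` multiplicatively shifts the guild's optimum
    predator–prey mass ratio on the log10 scale (1 = no shift).
    """

    guild_id: str
    group: str
    body_mass_mean: float  # mg fresh weight per individual
    body_mass_sd: float  # mg, SD of individual masses
    biomass: float  # g fresh weight per m^2
    density: float  # individuals per m^2
    stratum_occupancy: dict[str, float]
    resource_prefs: dict[str, str]
    protection: float = 0.0
    nitrogen_pct: float = 10.0  # % dry mass N
    carbon_pct: float = 47.0  # % dry mass C
    hunting_modifier: float = 1.0
    metabolic_group: str = "invertebrate"

    def invariant_violations(self) -> list[tuple[str, str]]:
        """Return ``(rule, message)`` pairs for every violated invariant."""
        out: list[tuple[str, str]] = []
        if not self.body_mass_mean > 0:
            out.append(("body_mass_positive", f"body_mass_mean={self.body_mass_mean!r} must be > 0"))
        if self.body_mass_sd < 0:
            out.append(("body_mass_sd_nonneg", f"body_mass_sd={self.body_mass_sd!r} must be >= 0"))
        if self.biomass < 0:
            out.append(("biomass_nonneg", f"biomass={self.biomass!r} must be >= 0"))
        if self.density < 0:
            out.append(("density_nonneg", f"density={self.density!r} must be >= 0"))
        if self.group not in GROUPS:
            out.append(("group_enum", f"unknown group {self.group!r}"))
        occ = self.stratum_occupancy
        if set(occ) != set(STRATA):
            out.append(("occupancy_keys", f"occupancy keys {sorted(occ)} != {sorted(STRATA)}"))
        else:
            if any(v < 0 for v in occ.values()):
                out.append(("occupancy_nonneg", "stratum occupancies must be >= 0"))
            total = sum(occ.values())
            if abs(total - 1.0) > _OCC_SUM_TOL:
                out.append(("occupancy_sum", f"stratum occupancies sum to {total!r}, not 1"))
        if not 0.0 <= self.protection <= 1.0:
            out.append(("protection_range", f"protection={self.protection!r} outside [0, 1]"))
        prefs = self.resource_prefs
        if set(prefs) != set(RESOURCE_CLASSES):
            out.append(("prefs_keys", f"preference keys {sorted(prefs)} != {sorted(RESOURCE_CLASSES)}"))
        else:
            if any(v not in PREF_LEVELS for v in prefs.values()):
                out.append(("prefs_levels", "preference levels must be none/auxiliary/main"))
            elif all(v == "none" for v in prefs.values()):
                out.append(("no_resources", "all resource preferences are 'none'"))
        if not self.nitrogen_pct > 0:
            out.append(("nitrogen_positive", f"nitrogen_pct={self.nitrogen_pct!r} must be > 0"))
        return out


@dataclass
class PlotCommunity:
    """All guilds plus site metadata for one plot; the unit of reconstruction."""

    plot_id: str
    system: str
    region: str
    soil_temperature: float  # deg C
    guilds: list[Guild] = field(default_factory=list)
    tree_heights: list[float] = field(default_factory=list)  # m, trees >= 10 cm DBH

    def invariant_violations(self) -> list[tuple[str, str, str]]:
        """Return ``(guild_id, rule, message)`` triples ('' for plot-level rules)."""
        out: list[tuple[str, str, str]] = []
        if self.system not in SYSTEMS:
            out.append(("", "system_enum", f"unknown system {self.system!r}"))
        if self.region not in REGIONS:
            out.append(("", "region_enum", f"unknown region {self.region!r}"))
        if not 0.0 < self.soil_temperature < 45.0:
            out.append(("", "temperature_range", f"soil_temperature={self.soil_temperature!r} outside (0, 45) degC"))
        if any(h <= 0 for h in self.tree_heights):
            out.append(("", "tree_height_positive", "tree heights must be > 0"))
        seen: set[str] = set()
        for g in self.guilds:
            if g.guild_id in seen:
                out.append((g.guild_id, "guild_id_unique", f"duplicate guild_id {g.guild_id!r}"))
            seen.add(g.guild_id)
            for rule, msg in g.invariant_violations():
                out.append((g.guild_id, rule, msg))
        return out

    def guild(self, guild_id: str) -> Guild:
        for g in self.guilds:
            if g.guild_id == guild_id:
                return g
        raise KeyError(guild_id)


@dataclass
class CommunityDataset:
    """A collection of plots sharing one provenance (a survey or a simulation)."""

    plots: list[PlotCommunity] = field(default_factory=list)
    provenance: str = ""

    def plot(self, plot_id: str) -> PlotCommunity:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)


@dataclass
class ValidationReport:
    """Invariant violations collected over a dataset.

    Entries are ``(plot_id, guild_id, rule, message)``; ``guild_id`` is ``""``
    for plot- or dataset-level rules.  An empty ``errors`` list means the
    dataset is accepted.
    """

    errors: list[tuple[str, str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(ds: CommunityDataset) -> ValidationReport:
    """Check every type invariant; violations become report entries, not exceptions.

    Ordering is deterministic: plots in dataset order, guilds in plot order,
    rules in declaration order.
    """
    report = ValidationReport()
    seen_plots: set[str] = set()
    for plot in ds.plots:
        if plot.plot_id in seen_plots:
            report.errors.append((plot.plot_id, "", "plot_id_unique", f"duplicate plot_id {plot.plot_id!r}"))
        seen_plots.add(plot.plot_id)
        for guild_id, rule, msg in plot.invariant_violations():
            report.errors.append((plot.plot_id, guild_id, rule, msg))
    return report


# ---------------------------------------------------------------------------
# Layer merging (litter/soil extracted separately, analysed as one guild)
# ---------------------------------------------------------------------------

#: Extraction layers and the stratum their abundance maps to.  Litter-layer
#: extractions cover both the litter and ground strata; they are assigned to
#: the litter stratum here.
_LAYER_TO_STRATUM = {"litter": "litter", "soil": "soil"}

_SHARED_TRAITS = (
    "group",
    "resource_prefs",
    "protection",
    "nitrogen_pct",
    "carbon_pct",
    "hunting_modifier",
    "metabolic_group",
)


def merge_soil_litter_layers(raw_rows: Sequence[Mapping]) -> Guild:
    """Merge layer-resolved extraction rows of one guild into a single node.

    Each row is a mapping with keys ``guild_id``, ``plot_id``, ``layer``
    (``soil`` or ``litter``), ``abundance`` (individuals m⁻²), ``biomass``
    (g m⁻²), ``body_mass_mean`` and ``body_mass_sd`` (mg), plus the shared
    trait fields of :class:`Guild`.  Biomass and abundance are summed exactly;
    stratum occupancy is set to the layer-wise abundance proportions; body-mass
    mean and SD are pooled by abundance weighting (total variance = within- +
    between-layer components).
    """
    if not raw_rows:
        raise IntegrityError("merge_soil_litter_layers: no rows given")
    ids = {(r["guild_id"], r["plot_id"]) for r in raw_rows}
    if len(ids) > 1:
        raise IntegrityError(f"rows span several (plot, guild) pairs: {sorted(ids)}")
    for key in _SHARED_TRAITS:
        values = [r[key] for r in raw_rows if key in r]
        if len({repr(v) for v in values}) > 1:
            raise IntegrityError(f"conflicting values for shared trait {key!r}: {values!r}")

    total_abund = sum(float(r["abundance"]) for r in raw_rows)
    total_biomass = sum(float(r["biomass"]) for r in raw_rows)
    occ = dict.fromkeys(STRATA, 0.0)
    for r in raw_rows:
        layer = r["layer"]
        if layer not in _LAYER_TO_STRATUM:
            raise IntegrityError(f"unknown extraction layer {layer!r}")
        occ[_LAYER_TO_STRATUM[layer]] += float(r["abundance"])
    if total_abund > 0:
        occ = {k: v / total_abund for k, v in occ.items()}
    else:
        occ = dict.fromkeys(STRATA, 0.0)
        occ["soil"] = 1.0

    # Abundance-weighted pooled mean and total SD across layers.
    if total_abund > 0:
        mean = sum(float(r["abundance"]) * float(r["body_mass_mean"]) for r in raw_rows) / total_abund
        second_moment = sum(
            float(r["abundance"]) * (float(r["body_mass_sd"]) ** 2 + float(r["body_mass_mean"]) ** 2)
            for r in raw_rows
        ) / total_abund
        sd = math.sqrt(max(second_moment - mean**2, 0.0))
    else:
        mean = float(raw_rows[0]["body_mass_mean"])
        sd = float(raw_rows[0]["body_mass_sd"])

    first = raw_rows[0]
    return Guild(
        guild_id=first["guild_id"],
        group=first["group"],
        body_mass_mean=mean,
        body_mass_sd=sd,
        biomass=total_biomass,
        density=total_abund,
        stratum_occupancy=occ,
        resource_prefs=dict(first["resource_prefs"]),
        protection=float(first.get("protection", 0.0)),
        nitrogen_pct=float(first.get("nitrogen_pct", 10.0)),
        carbon_pct=float(first.get("carbon_pct", 47.0)),
        hunting_modifier=float(first.get("hunting_modifier", 1.0)),
        metabolic_group=first.get("metabolic_group", "invertebrate"),
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

GUILD_COLUMNS = (
    "plot_id",
    "guild_id",
    "group",
    "metabolic_group",
    "body_mass_mean_mg",
    "body_mass_sd_mg",
    "biomass_g_m2",
    "density_ind_m2",
    "occ_soil",
    "occ_litter",
    "occ_ground",
    "occ_canopy",
    "pref_plants",
    "pref_litter",
    "pref_fungi",
    "pref_bacteria",
    "pref_som",
    "pref_invert",
    "pref_vert",
    "protection",
    "nitrogen_pct",
    "carbon_pct",
    "hunting_modifier",
)

PLOT_COLUMNS = ("plot_id", "system", "region", "soil_temperature_c")
TREE_COLUMNS = ("plot_id", "tree_id", "height_m")

_PREF_COLUMN = {
    "plants": "pref_plants",
    "litter": "pref_litter",
    "fungi": "pref_fungi",
    "bacteria": "pref_bacteria",
    "som": "pref_som",
    "invertebrate_prey": "pref_invert",
    "vertebrate_prey": "pref_vert",
}


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _guild_from_row(row: pd.Series, rownum: int, warnings: list) -> Guild:
    def enum(col: str, allowed: tuple) -> str:
        val = str(row[col])
        if val not in allowed:
            raise IntegrityError(f"guilds.csv row {rownum}: unknown value {val!r} in column {col!r}")
        return val

    occ = {s: float(row[f"occ_{s}"]) for s in STRATA}
    total = sum(occ.values())
    # Renormalize small rounding slack from serialized files; reject bigger gaps.
    if total > 0 and abs(total - 1.0) <= _OCC_RENORM_TOL:
        occ = {k: v / total for k, v in occ.items()}
    mass_mean = float(row["body_mass_mean_mg"])
    sd_raw = row["body_mass_sd_mg"]
    if pd.isna(sd_raw):
        # SD is required by the mass-overlap rule; default to half the mean.
        mass_sd = 0.5 * mass_mean
        warnings.append(
            (str(row["plot_id"]), str(row["guild_id"]), "body_mass_sd_default",
             "missing body_mass_sd_mg; defaulted to 0.5 x mean")
        )
    else:
        mass_sd = float(sd_raw)
    if float(row["biomass_g_m2"]) < 0:
        raise IntegrityError(f"guilds.csv row {rownum}: negative biomass {row['biomass_g_m2']!r}")
    return Guild(
        guild_id=str(row["guild_id"]),
        group=enum("group", GROUPS),
        body_mass_mean=mass_mean,
        body_mass_sd=mass_sd,
        biomass=float(row["biomass_g_m2"]),
        density=float(row["density_ind_m2"]),
        stratum_occupancy=occ,
        resource_prefs={cls: enum(col, PREF_LEVELS) for cls, col in _PREF_COLUMN.items()},
        protection=float(row["protection"]),
        nitrogen_pct=float(row["nitrogen_pct"]),
        carbon_pct=float(row["carbon_pct"]),
        hunting_modifier=float(row["hunting_modifier"]),
        metabolic_group=str(row["metabolic_group"]),
    )


def read_community_tables(
    guild_table_path,
    plot_table_path,
    tree_table_path=None,
    provenance: str = "",
) -> CommunityDataset:
    """Read the long-format guild table and plot metadata into a dataset.

    One :class:`PlotCommunity` is built per row of ``plots.csv``; guild rows
    are joined by ``plot_id``.  ``trees.csv`` (optional) supplies per-tree
    heights used by the canopy-undersampling analysis.
    """
    guilds_df = pd.read_csv(guild_table_path)
    plots_df = pd.read_csv(plot_table_path)
    _require_columns(guilds_df, GUILD_COLUMNS, guild_table_path)
    _require_columns(plots_df, PLOT_COLUMNS, plot_table_path)

    dupes = guilds_df.duplicated(subset=["plot_id", "guild_id"])
    if dupes.any():
        first = guilds_df[dupes].iloc[0]
        raise IntegrityError(
            f"{guild_table_path}: duplicate (plot_id, guild_id) = ({first['plot_id']!r}, {first['guild_id']!r})"
        )

    trees: dict[str, list[float]] = {}
    if tree_table_path is not None:
        trees_df = pd.read_csv(tree_table_path)
        _require_columns(trees_df, TREE_COLUMNS, tree_table_path)
        for pid, grp in trees_df.groupby("plot_id", sort=False):
            trees[str(pid)] = [float(h) for h in grp["height_m"]]

    warnings: list = []
    by_plot: dict[str, list[Guild]] = {}
    for i, row in guilds_df.iterrows():
        by_plot.setdefault(str(row["plot_id"]), []).append(_guild_from_row(row, int(i) + 2, warnings))

    plots = []
    for _, row in plots_df.iterrows():
        pid = str(row["plot_id"])
        system = str(row["system"])
        region = str(row["region"])
        if system not in SYSTEMS:
            raise IntegrityError(f"{plot_table_path}: unknown system {system!r} for plot {pid!r}")
        if region not in REGIONS:
            raise IntegrityError(f"{plot_table_path}: unknown region {region!r} for plot {pid!r}")
        plots.append(
            PlotCommunity(
                plot_id=pid,
                system=system,
                region=region,
                soil_temperature=float(row["soil_temperature_c"]),
                guilds=by_plot.get(pid, []),
                tree_heights=trees.get(pid, []),
            )
        )
    ds = CommunityDataset(plots=plots, provenance=provenance or str(guild_table_path))
    return ds


def dataset_to_frames(ds: CommunityDataset) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Serialize a dataset to the (guilds, plots, trees) frame triple."""
    guild_rows = []
    plot_rows = []
    tree_rows = []
    for plot in ds.plots:
        plot_rows.append(
            {
                "plot_id": plot.plot_id,
                "system": plot.system,
                "region": plot.region,
                "soil_temperature_c": plot.soil_temperature,
            }
        )
        for i, h in enumerate(plot.tree_heights):
            tree_rows.append({"plot_id": plot.plot_id, "tree_id": f"{plot.plot_id}_t{i + 1}", "height_m": h})
        for g in plot.guilds:
            row = {
                "plot_id": plot.plot_id,
                "guild_id": g.guild_id,
                "group": g.group,
                "metabolic_group": g.metabolic_group,
                "body_mass_mean_mg": g.body_mass_mean,
                "body_mass_sd_mg": g.body_mass_sd,
                "biomass_g_m2": g.biomass,
                "density_ind_m2": g.density,
                "protection": g.protection,
                "nitrogen_pct": g.nitrogen_pct,
                "carbon_pct": g.carbon_pct,
                "hunting_modifier": g.hunting_modifier,
            }
            for s in STRATA:
                row[f"occ_{s}"] = g.stratum_occupancy[s]
            for cls, col in _PREF_COLUMN.items():
                row[col] = g.resource_prefs[cls]
            guild_rows.append(row)
    guilds_df = pd.DataFrame(guild_rows, columns=list(GUILD_COLUMNS))
    plots_df = pd.DataFrame(plot_rows, columns=list(PLOT_COLUMNS))
    trees_df = pd.DataFrame(tree_rows, columns=list(TREE_COLUMNS))
    return guilds_df, plots_df, trees_df


def write_community_tables(ds: CommunityDataset, guild_table_path, plot_table_path, tree_table_path=None) -> None:
    """Write ``guilds.csv`` / ``plots.csv`` (and optionally ``trees.csv``)."""
    guilds_df, plots_df, trees_df = dataset_to_frames(ds)
    Path(guild_table_path).parent.mkdir(parents=True, exist_ok=True)
    guilds_df.to_csv(guild_table_path, index=False)
    plots_df.to_csv(plot_table_path, index=False)
    if tree_table_path is not None:
        trees_df.to_csv(tree_table_path, index=False)


def copy_dataset(ds: CommunityDataset) -> CommunityDataset:
    """Deep-enough copy: guild dicts and lists are fresh objects."""
    plots = []
    for p in ds.plots:
        guilds = [
            replace(g, stratum_occupancy=dict(g.stratum_occupancy), resource_prefs=dict(g.resource_prefs))
            for g in p.guilds
        ]
        plots.append(replace(p, guilds=guilds, tree_heights=list(p.tree_heights)))
    return CommunityDataset(plots=plots, provenance=ds.provenance)
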