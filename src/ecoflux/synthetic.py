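"""Seeded synthetic community generator.

Emulates the structure of a 32-site tropical land-use survey: four land-use
systems (rainforest, jungle rubber agroforest, rubber and oil-palm
monocultures) × 8 replicate plots split over two regions, each plot holding
62 trophic guilds (11 bird, 17 canopy-arthropod, 33 soil-arthropod, 1
earthworm).  Template biomasses are order-of-magnitude anchored to field
magnitudes (rainforest belowground ≈ 10 g fresh mass m⁻² vs aboveground
≈ 0.9 g m⁻²) and are then shifted per system (earthworm dominance and canopy
biomass collapse in plantations) and jittered per plot with lognormal noise.

The template trait values are invented calibration, not field data; see the
package methods note for what they do and do not emulate.

Randomness: one master seed; per-plot generators are spawned from
``numpy.random.SeedSequence`` children keyed by (system, plot index), so
adding plots or systems never perturbs existing plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .community import (
    CommunityDataset,
    Guild,
    PlotCommunity,
    RESOURCE_CLASSES,
    STRATA,
    SYSTEMS,
    write_community_tables,
)
from .errors import ParameterError

__all__ = ["GeneratorConfig", "guild_template", "generate_plot", "generate_landscape"]


def _occ(soil=0.0, litter=0.0, ground=0.0, canopy=0.0) -> dict[str, float]:
    occ = {"soil": soil, "litter": litter, "ground": ground, "canopy": canopy}
    total = sum(occ.values())
    return {k: v / total for k, v in occ.items()}


def _prefs(**kwargs: str) -> dict[str, str]:
    prefs = dict.fromkeys(RESOURCE_CLASSES, "none")
    alias = {"invert": "invertebrate_prey", "vert": "vertebrate_prey"}
    for key, level in kwargs.items():
        prefs[alias.get(key, key)] = level
    return prefs


def _guild(gid, group, mass, biomass, occ, prefs, protection, n_pct, hunt=1.0, metab=None, c_pct=47.0) -> Guild:
    metab = metab or {"bird": "bird", "earthworm": "earthworm"}.get(group, "invertebrate")
    return Guild(
        guild_id=gid,
        group=group,
        body_mass_mean=mass,
        body_mass_sd=0.6 * mass,
        biomass=biomass,
        density=biomass * 1000.0 / mass,  # g m^-2 over mg per individual
        stratum_occupancy=occ,
        resource_prefs=prefs,
        protection=protection,
        nitrogen_pct=n_pct,
        carbon_pct=c_pct,
        hunting_modifier=hunt,
        metabolic_group=metab,
    )


def guild_template() -> list[Guild]:
    """The 62 guild prototypes: 11 birds, 17 canopy arthropods, 33 soil arthropods, 1 earthworm.

    Body masses are mg fresh weight per individual; biomasses are the
    rainforest-template values in g fresh weight m⁻².  Birds carry a raised
    hunting modifier (they take prey far below their own mass); parasitoids a
    negative one (hosts larger than themselves); specialist canopy and soil
    arthropods are strictly separated in their stratum occupancies.
    """
    g: list[Guild] = []

    # --- birds (11) ------------------------------------------------------
    canopy = _occ(canopy=1)
    ground = _occ(ground=1)
    g += [
        _guild("bird_canopy_insectivore_small", "bird", 10_000, 0.050, canopy, _prefs(invert="main"), 0.5, 11, hunt=1.5),
        _guild("bird_canopy_insectivore_large", "bird", 35_000, 0.030, canopy, _prefs(invert="main"), 0.5, 11, hunt=1.6),
        _guild("bird_ground_insectivore", "bird", 28_000, 0.030, ground, _prefs(invert="main"), 0.5, 11, hunt=1.6),
        _guild("bird_canopy_frugivore", "bird", 45_000, 0.050, canopy, _prefs(plants="main"), 0.5, 11),
        _guild("bird_ground_granivore", "bird", 22_000, 0.030, ground, _prefs(plants="main"), 0.5, 11),
        _guild("bird_nectarivore", "bird", 8_000, 0.020, canopy, _prefs(plants="main", invert="auxiliary"), 0.5, 11, hunt=1.5),
        _guild("bird_canopy_omnivore", "bird", 40_000, 0.040, canopy, _prefs(plants="main", invert="main"), 0.5, 11, hunt=1.6),
        _guild("bird_ground_omnivore", "bird", 60_000, 0.020, ground, _prefs(plants="main", invert="main"), 0.5, 11, hunt=1.7),
        _guild("bird_understory_insectivore", "bird", 15_000, 0.015, _occ(ground=0.5, canopy=0.5), _prefs(invert="main"), 0.5, 11, hunt=1.5),
        _guild("bird_raptor", "bird", 150_000, 0.010, canopy, _prefs(vert="main", invert="auxiliary"), 0.5, 11, hunt=0.5),
        _guild("bird_scavenger_omnivore", "bird", 80_000, 0.005, ground, _prefs(vert="main", plants="auxiliary"), 0.5, 11, hunt=0.6),
    ]

    # --- canopy arthropods (17): strict canopy specialists ---------------
    c = _occ(canopy=1)
    g += [
        _guild("can_acarina", "canopy_arthropod", 0.03, 0.005, c, _prefs(fungi="main", invert="auxiliary"), 0.2, 9, hunt=0.3, metab="arachnid"),
        _guild("can_araneae", "canopy_arthropod", 8.0, 0.050, c, _prefs(invert="main"), 0.3, 11, hunt=0.5, metab="arachnid"),
        _guild("can_blattodea", "canopy_arthropod", 40.0, 0.040, c, _prefs(litter="main", plants="auxiliary", fungi="auxiliary"), 0.2, 7, metab="insect"),
        _guild("can_coleoptera_other", "canopy_arthropod", 10.0, 0.040, c, _prefs(plants="main", fungi="auxiliary", invert="auxiliary"), 0.5, 8, hunt=0.4, metab="insect"),
        _guild("can_chrysomelidae", "canopy_arthropod", 4.0, 0.030, c, _prefs(plants="main"), 0.5, 8, metab="insect"),
        _guild("can_curculionidae", "canopy_arthropod", 5.0, 0.030, c, _prefs(plants="main"), 0.6, 8, metab="insect"),
        _guild("can_elateridae", "canopy_arthropod", 6.0, 0.015, c, _prefs(plants="main", invert="auxiliary"), 0.5, 8, hunt=0.4, metab="insect"),
        _guild("can_staphylinidae", "canopy_arthropod", 2.0, 0.015, c, _prefs(invert="main"), 0.4, 10, hunt=0.4, metab="insect"),
        _guild("can_collembola", "canopy_arthropod", 0.05, 0.010, c, _prefs(fungi="main", plants="auxiliary"), 0.1, 9, metab="insect"),
        _guild("can_diptera", "canopy_arthropod", 1.5, 0.030, c, _prefs(plants="main", fungi="auxiliary"), 0.2, 9, metab="insect"),
        _guild("can_hemiptera", "canopy_arthropod", 3.0, 0.060, c, _prefs(plants="main"), 0.3, 8, metab="insect"),
        _guild("can_formicidae", "canopy_arthropod", 1.5, 0.120, c, _prefs(invert="main", plants="auxiliary"), 0.6, 10, hunt=0.3, metab="insect"),
        _guild("can_braconidae", "canopy_arthropod", 0.5, 0.005, c, _prefs(invert="main"), 0.2, 10, hunt=-0.5, metab="insect"),
        _guild("can_lepidoptera_larvae", "canopy_arthropod", 60.0, 0.060, c, _prefs(plants="main"), 0.3, 8, metab="insect"),
        _guild("can_orthoptera", "canopy_arthropod", 80.0, 0.050, c, _prefs(plants="main"), 0.3, 8, metab="insect"),
        _guild("can_psocoptera", "canopy_arthropod", 0.3, 0.010, c, _prefs(fungi="main", litter="auxiliary"), 0.1, 9, metab="insect"),
        _guild("can_thysanoptera", "canopy_arthropod", 0.05, 0.005, c, _prefs(plants="main", fungi="auxiliary"), 0.1, 8, metab="insect"),
    ]

    # --- soil arthropods (33): soil/litter/ground only -------------------
    g += [
        _guild("soil_collembola_epigeic", "soil_arthropod", 0.05, 0.35, _occ(litter=0.7, ground=0.3), _prefs(fungi="main", litter="auxiliary"), 0.1, 9, metab="insect"),
        _guild("soil_collembola_euedaphic", "soil_arthropod", 0.02, 0.25, _occ(soil=1), _prefs(fungi="main", bacteria="auxiliary", som="auxiliary"), 0.1, 9, metab="insect"),
        _guild("soil_collembola_hemiedaphic", "soil_arthropod", 0.03, 0.30, _occ(soil=0.5, litter=0.5), _prefs(fungi="main", litter="auxiliary"), 0.1, 9, metab="insect"),
        _guild("soil_oribatida", "soil_arthropod", 0.02, 0.45, _occ(soil=0.6, litter=0.4), _prefs(litter="main", fungi="auxiliary"), 0.7, 7, metab="arachnid"),
        _guild("soil_mesostigmata", "soil_arthropod", 0.03, 0.12, _occ(soil=0.5, litter=0.5), _prefs(invert="main"), 0.2, 11, hunt=0.25, metab="arachnid"),
        _guild("soil_prostigmata", "soil_arthropod", 0.01, 0.06, _occ(soil=0.7, litter=0.3), _prefs(bacteria="main", fungi="auxiliary"), 0.1, 9, metab="arachnid"),
        _guild("soil_astigmata", "soil_arthropod", 0.015, 0.04, _occ(soil=1), _prefs(bacteria="main", som="auxiliary"), 0.1, 9, metab="arachnid"),
        _guild("soil_uropodina", "soil_arthropod", 0.03, 0.05, _occ(soil=0.8, litter=0.2), _prefs(fungi="main", invert="auxiliary"), 0.3, 9, hunt=0.25, metab="arachnid"),
        _guild("soil_araneae", "soil_arthropod", 6.0, 0.25, _occ(litter=0.6, ground=0.4), _prefs(invert="main"), 0.3, 11, hunt=0.5, metab="arachnid"),
        _guild("soil_pseudoscorpiones", "soil_arthropod", 1.0, 0.05, _occ(litter=0.8, soil=0.2), _prefs(invert="main"), 0.3, 11, hunt=0.4, metab="arachnid"),
        _guild("soil_opiliones", "soil_arthropod", 8.0, 0.08, _occ(ground=0.7, litter=0.3), _prefs(invert="main", litter="auxiliary"), 0.2, 10, hunt=0.5, metab="arachnid"),
        _guild("soil_chilopoda_lithobiida", "soil_arthropod", 15.0, 0.20, _occ(litter=0.7, soil=0.3), _prefs(invert="main"), 0.3, 11, hunt=0.5),
        _guild("soil_chilopoda_geophilida", "soil_arthropod", 10.0, 0.15, _occ(soil=0.9, litter=0.1), _prefs(invert="main"), 0.3, 11, hunt=0.5),
        _guild("soil_diplopoda", "soil_arthropod", 25.0, 0.35, _occ(litter=0.6, soil=0.4), _prefs(litter="main", som="auxiliary"), 0.6, 6),
        _guild("soil_symphyla", "soil_arthropod", 0.8, 0.06, _occ(soil=1), _prefs(plants="main", fungi="auxiliary"), 0.1, 8),
        _guild("soil_pauropoda", "soil_arthropod", 0.05, 0.02, _occ(soil=1), _prefs(fungi="main"), 0.1, 9),
        _guild("soil_protura", "soil_arthropod", 0.05, 0.02, _occ(soil=1), _prefs(fungi="main"), 0.1, 9, metab="insect"),
        _guild("soil_diplura", "soil_arthropod", 0.5, 0.03, _occ(soil=1), _prefs(invert="main", fungi="auxiliary"), 0.1, 10, hunt=0.25, metab="insect"),
        _guild("soil_isopoda", "soil_arthropod", 20.0, 0.25, _occ(litter=0.8, ground=0.2), _prefs(litter="main", som="auxiliary"), 0.5, 6),
        _guild("soil_termites", "soil_arthropod", 2.5, 0.80, _occ(soil=0.5, litter=0.5), _prefs(litter="main", som="auxiliary", fungi="auxiliary"), 0.3, 7, metab="insect"),
        _guild("soil_formicidae", "soil_arthropod", 1.5, 0.80, _occ(litter=0.4, ground=0.3, soil=0.3), _prefs(invert="main", plants="auxiliary"), 0.6, 10, hunt=0.3, metab="insect"),
        _guild("soil_carabidae", "soil_arthropod", 30.0, 0.15, _occ(ground=0.6, litter=0.4), _prefs(invert="main", plants="auxiliary"), 0.5, 10, hunt=0.5, metab="insect"),
        _guild("soil_staphylinidae", "soil_arthropod", 4.0, 0.12, _occ(litter=0.6, soil=0.4), _prefs(invert="main"), 0.4, 10, hunt=0.4, metab="insect"),
        _guild("soil_coleoptera_larvae_pred", "soil_arthropod", 8.0, 0.08, _occ(soil=0.7, litter=0.3), _prefs(invert="main"), 0.2, 10, hunt=0.4, metab="insect"),
        _guild("soil_elateridae_larvae", "soil_arthropod", 12.0, 0.20, _occ(soil=0.9, litter=0.1), _prefs(plants="main", som="auxiliary", invert="auxiliary"), 0.3, 8, hunt=0.3, metab="insect"),
        _guild("soil_scarabaeidae_larvae", "soil_arthropod", 80.0, 0.40, _occ(soil=1), _prefs(som="main", litter="auxiliary", plants="auxiliary"), 0.3, 6, metab="insect"),
        _guild("soil_curculionidae_larvae", "soil_arthropod", 10.0, 0.15, _occ(soil=0.8, litter=0.2), _prefs(plants="main"), 0.3, 8, metab="insect"),
        _guild("soil_diptera_larvae", "soil_arthropod", 3.0, 0.45, _occ(soil=0.6, litter=0.4), _prefs(litter="main", som="auxiliary", fungi="auxiliary", bacteria="auxiliary"), 0.1, 8, metab="insect"),
        _guild("soil_lepidoptera_larvae", "soil_arthropod", 40.0, 0.10, _occ(litter=0.5, ground=0.5), _prefs(plants="main", litter="auxiliary"), 0.2, 8, metab="insect"),
        _guild("soil_hemiptera", "soil_arthropod", 2.0, 0.12, _occ(soil=0.5, litter=0.3, ground=0.2), _prefs(plants="main"), 0.2, 8, metab="insect"),
        _guild("soil_thysanoptera", "soil_arthropod", 0.05, 0.02, _occ(litter=0.6, soil=0.4), _prefs(fungi="main", plants="auxiliary"), 0.1, 8, metab="insect"),
        _guild("soil_blattodea", "soil_arthropod", 35.0, 0.12, _occ(litter=0.7, ground=0.3), _prefs(litter="main", fungi="auxiliary"), 0.2, 7, metab="insect"),
        _guild("soil_orthoptera", "soil_arthropod", 50.0, 0.10, _occ(ground=0.8, litter=0.2), _prefs(plants="main", litter="auxiliary"), 0.3, 8, metab="insect"),
    ]

    # --- earthworms (1) ---------------------------------------------------
    g.append(
        _guild(
            "earthworms", "earthworm", 400.0, 4.0, _occ(soil=0.8, litter=0.2),
            _prefs(som="main", litter="auxiliary", bacteria="auxiliary"), 0.2, 10.5,
        )
    )
    return g


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic landscape.

    Defaults encode the emulated survey: 4 systems × 8 plots split over two
    regions; per-system biomass multipliers for the four major groups
    (earthworm dominance and canopy/soil-arthropod decline in plantations);
    lognormal plot-to-plot biomass noise; mean annual soil temperatures per
    system; and per-system tree-height distributions whose 90th percentiles
    match the emulated stands (≈29.5, 21.0, 17.0 and 12.7 m).
    """

    n_plots_per_system: int = 8
    systems: tuple[str, ...] = SYSTEMS
    regions: tuple[str, ...] = ("region1", "region2")
    biomass_sigma: float = 0.6  # lognormal sigma of plot-to-plot biomass noise
    mass_jitter: float = 0.10  # uniform +/- fraction on body masses
    effect_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "rainforest": {"bird": 1.0, "canopy_arthropod": 1.0, "soil_arthropod": 1.0, "earthworm": 1.0},
            "jungle_rubber": {"bird": 0.8, "canopy_arthropod": 0.55, "soil_arthropod": 0.75, "earthworm": 6.0},
            "rubber": {"bird": 0.6, "canopy_arthropod": 0.25, "soil_arthropod": 0.55, "earthworm": 6.5},
            "oil_palm": {"bird": 0.5, "canopy_arthropod": 0.2, "soil_arthropod": 0.5, "earthworm": 8.0},
        }
    )
    temperature_c: dict[str, float] = field(
        default_factory=lambda: {"rainforest": 25.0, "jungle_rubber": 25.6, "rubber": 26.1, "oil_palm": 26.1}
    )
    # (mean m, sd m, n trees per 0.25 ha plot); 90th pct = mean + 1.2816 sd
    tree_heights: dict[str, tuple[float, float, int]] = field(
        default_factory=lambda: {
            "rainforest": (22.0, 5.9, 139),
            "jungle_rubber": (16.0, 3.9, 145),
            "rubber": (13.5, 2.7, 117),
            "oil_palm": (10.1, 2.0, 35),
        }
    )

    def validate(self) -> None:
        if self.n_plots_per_system < 1:
            raise ParameterError("n_plots_per_system must be >= 1")
        if self.biomass_sigma < 0:
            raise ParameterError("biomass_sigma must be >= 0")
        for system in self.systems:
            mult = self.effect_multipliers.get(system)
            if mult is None or any(v <= 0 for v in mult.values()):
                raise ParameterError(f"system {system!r} needs positive effect multipliers")
            if system not in self.temperature_c or system not in self.tree_heights:
                raise ParameterError(f"system {system!r} needs temperature and tree-height settings")


_SYSTEM_CODE = {"rainforest": "F", "jungle_rubber": "J", "rubber": "R", "oil_palm": "O"}


def generate_plot(system: str, region: str, plot_index: int, config: GeneratorConfig, seed: int) -> PlotCommunity:
    """One synthetic plot; fully determined by (system, plot_index, config, seed)."""
    config.validate()
    if system not in config.systems:
        raise ParameterError(f"unknown system {system!r}")
    sys_idx = SYSTEMS.index(system)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(sys_idx, plot_index)))

    mult = config.effect_multipliers[system]
    guilds = []
    for proto in guild_template():
        noise = rng.lognormal(mean=0.0, sigma=config.biomass_sigma) if config.biomass_sigma > 0 else 1.0
        jitter = 1.0 + rng.uniform(-config.mass_jitter, config.mass_jitter) if config.mass_jitter > 0 else 1.0
        mass = proto.body_mass_mean * jitter
        biomass = proto.biomass * mult[proto.group] * noise
        guilds.append(
            replace(
                proto,
                body_mass_mean=mass,
                body_mass_sd=proto.body_mass_sd * jitter,
                biomass=biomass,
                density=biomass * 1000.0 / mass,
                stratum_occupancy=dict(proto.stratum_occupancy),
                resource_prefs=dict(proto.resource_prefs),
            )
        )

    h_mean, h_sd, n_trees = config.tree_heights[system]
    heights = np.clip(rng.normal(h_mean, h_sd, size=n_trees), 1.5, None).tolist()

    code = _SYSTEM_CODE.get(system, system[:1].upper())
    return PlotCommunity(
        plot_id=f"{code}{plot_index + 1}",
        system=system,
        region=region,
        soil_temperature=config.temperature_c[system],
        guilds=guilds,
        tree_heights=heights,
    )


def generate_landscape(config: GeneratorConfig | None = None, seed: int = 0) -> CommunityDataset:
    """The full synthetic landscape: n_systems × n_plots_per_system plots.

    Replicates alternate between the two regions in blocks (the first half of
    each system's plots in region 1, the second half in region 2, mirroring a
    balanced two-region design).
    """
    config = config or GeneratorConfig()
    config.validate()
    plots = []
    for system in config.systems:
        for i in range(config.n_plots_per_system):
            region = config.regions[0] if i < config.n_plots_per_system / 2 else config.regions[-1]
            plots.append(generate_plot(system, region, i, config, seed))
    return CommunityDataset(plots=plots, provenance=f"synthetic landscape, seed={seed}")


def write_landscape(ds: CommunityDataset, outdir, config: GeneratorConfig | None = None) -> None:
    """Emit guilds.csv / plots.csv / trees.csv (and the generator config as YAML)."""
    from dataclasses import asdict
    from pathlib import Path

    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_community_tables(ds, out / "guilds.csv", out / "plots.csv", out / "trees.csv")
    if config is not None:
        with open(out / "generator_config.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=False)
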