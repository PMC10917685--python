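"""End-to-end runs: input (files or generator) → webs → fluxes → indicators → sweeps.

All outputs are plain CSV plus a JSON manifest recording the configuration
hash, seed, package version and the completion status of every plot, so a run
can be reproduced and partial failures audited.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import CommunityDataset, dataset_to_frames, read_community_tables, validate_dataset
from .energetics import EfficiencyModel, MetabolicCoefficients, analyze_plot
from .errors import ConfigError, EcofluxError
from .indicators import aggregate_by_system, plot_indicator_table
from .reconstruction import ReconstructionParams, topology_edge_list
from .sensitivity import SweepSpec, UndersamplingScenario, apply_undersampling, sweep_parameter
from .synthetic import GeneratorConfig, generate_landscape

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Settings of one pipeline run.

    Exactly one of ``input_paths`` (mapping with guilds/plots and optionally
    trees CSV paths) or ``generator`` (a :class:`GeneratorConfig`) selects the
    input.  Optional stages: parameter sweeps (list of scalar names) and
    undersampling scenarios (list of h_max values in metres).
    """

    output_dir: str = "ecoflux_out"
    seed: int = 0
    input_paths: dict | None = None
    generator: GeneratorConfig | None = None
    params: ReconstructionParams = field(default_factory=ReconstructionParams)
    metabolic_coeffs_path: str | None = None
    efficiencies_path: str | None = None
    sweep_parameters: list[str] = field(default_factory=list)
    h_max_list: list[float] = field(default_factory=list)

    def validate(self) -> None:
        if (self.input_paths is None) == (self.generator is None):
            raise ConfigError("exactly one of input_paths / generator must be set")


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file (see examples/run_config.yaml)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = ReconstructionParams(**raw.get("params", {}))
    generator = None
    if "generator" in raw:
        generator = GeneratorConfig(**{
            k: v for k, v in (raw["generator"] or {}).items()
        })
    cfg = RunConfig(
        output_dir=raw.get("output_dir", "ecoflux_out"),
        seed=int(raw.get("seed", 0)),
        input_paths=raw.get("input_paths"),
        generator=generator,
        params=params,
        metabolic_coeffs_path=raw.get("metabolic_coeffs_path"),
        efficiencies_path=raw.get("efficiencies_path"),
        sweep_parameters=list(raw.get("sweep_parameters", [])),
        h_max_list=[float(h) for h in raw.get("h_max_list", [])],
    )
    cfg.validate()
    return cfg


def _config_hash(config: RunConfig) -> str:
    def default(o):
        return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_dataset(config: RunConfig) -> CommunityDataset:
    if config.generator is not None:
        return generate_landscape(config.generator, seed=config.seed)
    paths = config.input_paths
    for key in ("guilds", "plots"):
        if key not in paths:
            raise ConfigError(f"input_paths missing {key!r}")
    return read_community_tables(paths["guilds"], paths["plots"], paths.get("trees"))


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the results bundle.

    Returns the manifest dict.  Per-plot reconstruction/flux failures are
    recorded in the manifest (status ``failed: ...``) rather than aborting the
    whole run; a dataset-validation failure aborts.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    ds = _load_dataset(config)
    report = validate_dataset(ds)
    if not report.ok:
        raise EcofluxError(f"input dataset failed validation with {len(report.errors)} error(s): {report.errors[:5]}")

    coeffs = (
        MetabolicCoefficients.from_yaml(config.metabolic_coeffs_path)
        if config.metabolic_coeffs_path
        else MetabolicCoefficients.default()
    )
    eff = (
        EfficiencyModel.from_yaml(config.efficiencies_path)
        if config.efficiencies_path
        else EfficiencyModel.default()
    )

    guilds_df, plots_df, trees_df = dataset_to_frames(ds)
    guilds_df.to_csv(outdir / "guilds.csv", index=False)
    plots_df.to_csv(outdir / "plots.csv", index=False)
    trees_df.to_csv(outdir / "trees.csv", index=False)

    plot_status: dict[str, str] = {}
    edge_tables, flux_tables, indicator_tables = [], [], []
    for plot in ds.plots:
        try:
            topology, result = analyze_plot(plot, config.params, coeffs, eff)
        except EcofluxError as exc:
            plot_status[plot.plot_id] = f"failed: {exc}"
            continue
        plot_status[plot.plot_id] = "completed"
        edge_tables.append(topology_edge_list(topology))
        names = topology.node_names
        rows = []
        for j, cons in enumerate(topology.consumer_ids):
            col = result.F[:, j]
            for i in np.flatnonzero(col):
                rows.append(
                    {
                        "plot_id": plot.plot_id,
                        "resource": names[i],
                        "consumer": cons,
                        "flux_mw_m2": float(col[i]),
                        "efficiency": float(result.e_res[i]),
                    }
                )
        flux_tables.append(pd.DataFrame(rows))
        indicator_tables.append(plot_indicator_table(plot, topology, result))

    if not indicator_tables:
        raise EcofluxError("no plot completed successfully")

    pd.concat(edge_tables, ignore_index=True).to_csv(outdir / "edges.csv", index=False)
    pd.concat(flux_tables, ignore_index=True).to_csv(outdir / "fluxes.csv", index=False)
    indicators = pd.concat(indicator_tables, ignore_index=True)
    indicators.to_csv(outdir / "indicators.csv", index=False)
    summary = aggregate_by_system(indicators, plots_df)
    summary.to_csv(outdir / "summary.csv", index=False)

    outputs = ["guilds.csv", "plots.csv", "trees.csv", "edges.csv", "fluxes.csv", "indicators.csv", "summary.csv"]

    if config.sweep_parameters:
        sweeps = [
            sweep_parameter(ds, SweepSpec(parameter=p), config.params, coeffs, eff)
            for p in config.sweep_parameters
        ]
        pd.concat(sweeps, ignore_index=True).to_csv(outdir / "sweep.csv", index=False)
        outputs.append("sweep.csv")

    if config.h_max_list:
        rows = []
        for h_max in config.h_max_list:
            corrected = apply_undersampling(ds, UndersamplingScenario(h_max=h_max))
            for plot in corrected.plots:
                try:
                    topology, result = analyze_plot(plot, config.params, coeffs, eff)
                except EcofluxError as exc:
                    rows.append({"h_max": h_max, "plot_id": plot.plot_id, "compartment": "", "indicator": "",
                                 "value": float("nan"), "status": f"failed: {exc}"})
                    continue
                tab = plot_indicator_table(plot, topology, result, compartments=("whole", "aboveground", "belowground"))
                tab = tab[tab["indicator"].isin(("total_flux", "total_biomass"))]
                for _, r in tab.iterrows():
                    rows.append({"h_max": h_max, "plot_id": r["plot_id"], "compartment": r["compartment"],
                                 "indicator": r["indicator"], "value": r["value"], "status": "ok"})
        pd.DataFrame(rows).to_csv(outdir / "undersampling.csv", index=False)
        outputs.append("undersampling.csv")

    manifest = {
        "package": "ecoflux",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_plots": len(ds.plots),
        "plots": plot_status,
        "outputs": outputs,
        "partial": any(s != "completed" for s in plot_status.values()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
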