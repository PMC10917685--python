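"""Optional benchmark adapter for a locally downloaded field-survey deposit.

This module is deliberately separate from the core pipeline: it expects a
directory holding the deposited survey tables converted to the package's
community-table dialect (guilds.csv / plots.csv / trees.csv, see
:mod:`ecoflux.community`), plus optionally the deposit's own metabolic and
efficiency coefficient files.  Nothing here downloads data; reproducing the
published per-system numbers additionally requires reconciling the
reconstruction constants (PPMR optimum, metabolic regressions, the
nitrogen→efficiency equation) with the deposited analysis script, for which
the shipped YAML defaults are editable stand-ins.
"""

from __future__ import annotations

from pathlib import Path

from .errors import ConfigError
from .pipeline import RunConfig, run_pipeline
from .reconstruction import ReconstructionParams

__all__ = ["run_benchmark"]

REQUIRED_FILES = ("guilds.csv", "plots.csv")


def run_benchmark(
    data_dir,
    output_dir="benchmark_out",
    params: ReconstructionParams | None = None,
    metabolic_coeffs_path=None,
    efficiencies_path=None,
) -> dict:
    """Run the full pipeline on a local copy of the survey deposit.

    Raises :class:`ConfigError` with download/conversion instructions when
    the data directory or its required tables are absent.
    """
    data_dir = Path(data_dir)
    missing = [f for f in REQUIRED_FILES if not (data_dir / f).exists()]
    if not data_dir.is_dir() or missing:
        raise ConfigError(
            f"benchmark data not found under {data_dir} (missing: {missing or 'directory'}). "
            "Download the survey deposit, convert its tables to the community-table dialect "
            "(guilds.csv / plots.csv / trees.csv) and point data_dir at that directory."
        )
    trees = data_dir / "trees.csv"
    cfg = RunConfig(
        output_dir=str(output_dir),
        input_paths={
            "guilds": str(data_dir / "guilds.csv"),
            "plots": str(data_dir / "plots.csv"),
            **({"trees": str(trees)} if trees.exists() else {}),
        },
        params=params or ReconstructionParams(),
        metabolic_coeffs_path=metabolic_coeffs_path,
        efficiencies_path=efficiencies_path,
    )
    return run_pipeline(cfg)
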