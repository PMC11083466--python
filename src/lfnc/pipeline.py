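"""End-to-end pipeline: grid -> simulated dataset -> fits, bias, charts.

Stages mirror the bench protocol and its analysis: enumerate the breathing
grid, simulate every scenario x flow in replicate, fit the FiO2(MV) power
law per flow, quantify the closed-form formulas' bias, and build the
predictive charts.  All outputs are CSV plus a JSON manifest sufficient to
reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from lfnc._version import __version__ as _version
from lfnc.charts import ChartSpec, build_chart, write_chart
from lfnc.config import PipelineConfig
from lfnc.evaluation import FORMULAS, bias_threshold_summary, formula_differences
from lfnc.fitting import fit_per_flow
from lfnc.scenarios import enumerate_grid, scenarios_to_frame
from lfnc.simulator import generate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Execute all stages and write the artifact bundle under ``out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) listing the
    configuration echo, effective seed and produced files.  Idempotent for a
    fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    effective_seed = config.seed if seed is None else seed
    files: list[str] = []

    # --- scenario grid ---
    try:
        scenarios = enumerate_grid(
            config.vt_values,
            config.rr_values,
            config.ti_values,
            config.ratio_lo,
            config.ratio_hi,
        )
        grid_path = out / "scenarios.csv"
        scenarios_to_frame(scenarios).to_csv(grid_path, index=False)
        files.append(grid_path.name)
        logger.info("grid: %d feasible scenarios", len(scenarios))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("grid", str(e)) from e

    # --- simulated dataset ---
    try:
        if not config.flows:
            raise ValueError("no cannula flows configured; nothing to simulate")
        if not scenarios:
            raise ValueError("empty scenario grid; nothing to simulate")
        dataset = generate_dataset(
            scenarios,
            config.flows,
            config.geometry(),
            config.waveform_spec(),
            noise_sd_pp=config.noise_sd_pp,
            replicates=config.replicates,
            seed=effective_seed,
            supply_o2_fraction=config.supply_o2_percent / 100.0,
            tol_pp=config.tol_pp,
            max_breaths=config.max_breaths,
        )
        ds_path = out / "dataset.csv"
        dataset.to_csv(ds_path, index=False)
        files.append(ds_path.name)
        logger.info("dataset: %d rows", len(dataset))
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("dataset", str(e)) from e

    # --- power-law fits per flow ---
    try:
        fits = fit_per_flow(dataset)
        fits_path = out / "power_fits.csv"
        fits.to_csv(fits_path, index=False)
        files.append(fits_path.name)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit-power", str(e)) from e

    # --- formula bias ---
    try:
        for formula in FORMULAS:
            diffs = formula_differences(dataset, formula, config.supply_o2_percent)
            dpath = out / f"bias_{formula}.csv"
            diffs.to_csv(dpath, index=False)
            files.append(dpath.name)
            summary = bias_threshold_summary(diffs, config.bias_thresholds_pp)
            spath = out / f"bias_summary_{formula}.csv"
            summary.to_csv(spath, index=False, na_rep="none")
            files.append(spath.name)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("compare-formulas", str(e)) from e

    # --- predictive charts ---
    try:
        for flow in config.flows:
            for vt_per_kg in config.vt_per_kg_values:
                spec = ChartSpec(
                    flow_l_min=flow,
                    vt_per_kg=vt_per_kg,
                    weight_grid=tuple(config.weight_grid),
                    rr_grid=tuple(config.chart_rr_values),
                    vt_cap_ml=config.vt_cap_ml,
                    ti_grid=tuple(config.ti_values),
                    ratio_window=(config.ratio_lo, config.ratio_hi),
                    supply_o2_fraction=config.supply_o2_percent / 100.0,
                )
                table = build_chart(
                    spec,
                    config.geometry(),
                    config.waveform_spec(),
                    tol_pp=config.tol_pp,
                    max_breaths=config.max_breaths,
                )
                name = f"chart_flow{flow:g}_vt{vt_per_kg:g}.csv"
                write_chart(table, out / name)
                files.append(name)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("build-charts", str(e)) from e

    manifest = {
        "package": "lfnc",
        "version": _version,
        "seed": effective_seed,
        "config": config.model_dump(),
        "n_scenarios": len(scenarios),
        "n_dataset_rows": len(dataset),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
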