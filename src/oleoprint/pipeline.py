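"""End-to-end printability pipeline.

Binds the stages into one flow: gelation-temperature extraction from
temperature sweeps, viscosity interpolation at the nozzle shear rates and
nozzle temperature, the shear-rate table, the layer-by-layer cooling
simulation, operational-map classification and the thermal shape-stability
assessment.  Produces a single versioned JSON report plus per-layer CSV
artifacts; fixed inputs give byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as oio
from .errors import ConfigError, OutOfRangeError
from .nozzle import shear_rate_table
from .printability import (
    MU_RANGE_PA_S,
    TG_RANGE_C,
    OperationalPoint,
    classify_operational_point,
)
from .rheology import gelation_report, interpolate_viscosity
from .thermal import simulate_print

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Inputs and options of one pipeline run."""

    sweep_paths: tuple[str, ...]
    flow_paths: tuple[str, ...]
    sim_config_path: str | None = None  # None -> packaged reference scenario
    output_dir: str = "."
    tg_range_C: tuple[float, float] = TG_RANGE_C
    mu_range_Pa_s: tuple[float, float] = MU_RANGE_PA_S
    speeds_mm_s: tuple[float, ...] | None = None  # None -> all in scenario
    allow_extrapolation: bool = False
    dry_run: bool = False

    def __post_init__(self) -> None:
        if not self.sweep_paths:
            raise ConfigError("need at least one sweep CSV")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full flow and write ``report.json`` plus CSV artifacts.

    Returns the report dict.  With ``dry_run`` the inputs are read and
    validated but nothing is computed or written.
    """
    for p in (*config.sweep_paths, *config.flow_paths):
        if not Path(p).exists():
            raise ConfigError(f"input does not exist: {p}")
    out_dir = Path(config.output_dir)

    try:
        sweeps = [oio.read_sweep_csv(p) for p in config.sweep_paths]
        flows = {f.sample_id: f for p in config.flow_paths
                 for f in [oio.read_flowcurves_csv(p)]}
        scenario = (
            oio.load_packaged_scenario()
            if config.sim_config_path is None
            else oio.load_print_scenario(config.sim_config_path)
        )
    except Exception as exc:
        raise type(exc)(f"[stage: read-inputs] {exc}") from exc

    if config.dry_run:
        return {
            "dry_run": True,
            "samples": [s.sample_id for s in sweeps],
            "flow_samples": sorted(flows),
            "speeds_mm_s": scenario.speeds_mm_s,
        }
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- nozzle shear rates -------------------------------------------
    table = shear_rate_table(scenario.nozzle_specs, scenario.nozzle_speeds_mm_s)
    table.to_csv(out_dir / "shear_rate_table.csv", index=False)
    shear_rates = list(table["shear_rate_per_s"])

    # --- thermal simulation per speed ---------------------------------
    speeds = (
        scenario.speeds_mm_s
        if config.speeds_mm_s is None
        else [v for v in scenario.speeds_mm_s if v in config.speeds_mm_s]
    )
    simulations: dict[float, list] = {}
    for v in speeds:
        try:
            histories = simulate_print(scenario.configs[v])
        except Exception as exc:
            raise type(exc)(f"[stage: thermal-sim v={v} mm/s] {exc}") from exc
        simulations[v] = histories
        for h in histories:
            oio.write_history_csv(
                h, out_dir / f"layers_v{v:g}_layer{h.layer_index}.csv"
            )

    # histories used for the stability verdict: slowest simulated speed
    # (most cooling time; the scenario's most conservative print)
    verdict_histories = simulations[min(simulations)] if simulations else None

    # --- per-sample rheology + classification -------------------------
    t0 = scenario.nozzle_temperature_C
    samples: dict[str, dict] = {}
    for sweep in sweeps:
        try:
            entry = gelation_report(sweep)
        except Exception as exc:
            raise type(exc)(f"[stage: gelation {sweep.sample_id}] {exc}") from exc

        visc_entries = []
        if sweep.sample_id in flows:
            fc = flows[sweep.sample_id]
            for gd in shear_rates:
                try:
                    mu = interpolate_viscosity(
                        fc, t0, gd, allow_extrapolation=config.allow_extrapolation
                    )
                except OutOfRangeError as exc:
                    logger.warning(
                        "sample %s: skipping viscosity at %.3g 1/s: %s",
                        sweep.sample_id, gd, exc,
                    )
                    continue
                visc_entries.append((t0, float(gd), mu))
        if visc_entries:
            point = OperationalPoint(
                sample_id=sweep.sample_id,
                tg_C=entry["tg_C"],
                viscosities=tuple(visc_entries),
                nozzle_temperature_C=t0,
            )
            verdict = classify_operational_point(
                point,
                tg_range_C=config.tg_range_C,
                mu_range_Pa_s=config.mu_range_Pa_s,
                histories=verdict_histories,
            )
            entry["viscosities_at_nozzle"] = [
                {"temperature_C": t, "shear_rate_per_s": g, "mu_Pa_s": m}
                for (t, g, m) in visc_entries
            ]
            entry["verdict"] = {
                "zone": verdict.zone,
                "extrudable": verdict.extrudable,
                "shape_stable": verdict.shape_stable,
                "reasons": [r.value for r in verdict.reasons],
            }
        samples[sweep.sample_id] = entry

    report = {
        "samples": samples,
        "shear_rate_table": table.to_dict(orient="records"),
        "nozzle_temperature_C": t0,
        "zone_bounds": {
            "tg_C": list(config.tg_range_C),
            "mu_Pa_s": list(config.mu_range_Pa_s),
        },
        "simulation": {
            f"{v:g}": [
                {
                    "layer_index": h.layer_index,
                    "base_temperature_C": h.base_temperature_C,
                    "final_t_upper_C": h.final_t_upper_C,
                    "final_t_side_C": h.final_t_side_C,
                    "energy_residual_rel": h.energy.residual_rel,
                }
                for h in hists
            ]
            for v, hists in simulations.items()
        },
    }
    oio.write_report(report, out_dir / "report.json")
    return report
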