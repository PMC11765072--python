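"""Canonical readers and writers.

CSV schemas (comma-separated, dot decimal, one header row; ``# key: value``
comment lines before the header carry metadata):

* temperature sweep: ``temperature_C, g_prime_Pa, g_double_prime_Pa``
* flow curves (long): ``temperature_C, shear_rate_per_s, viscosity_Pa_s``
* map points (long): ``sample_id, tg_C, temperature_C, shear_rate_per_s,
  viscosity_Pa_s``

YAML print configuration::

    material:   {k, rho, cp}
    boundaries: {Tp, Tinf, h, T0}
    grid:       {Nx, Ny, Nz}
    layers:     {count}
    dt: ...
    output_stride_s: ...
    speeds:
      - {v_mm_s, Lx, Ly, Lz, layer_time_s}
    nozzle:
      mass_g: ...
      radius_um: ...
      density_gcm3: ...
      jobs:
        - {v_mm_s, time_s}

The packaged ``data/print_scenario.yaml`` reproduces the reference print
scenario (cooled platform at 8.5 deg C, ambient 22.1 deg C, nozzle exit
79.7 deg C, natural convection 2 W/m^2 K, seven layers, 20 x 20 x 10 nodes,
dt = 0.01 s, four extrusion speeds with their slab dimensions and layer
times, and the nozzle shear-rate jobs).
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .nozzle import NozzleFlowSpec
from .printability import OperationalPoint
from .rheology import FlowCurveSet, RheologySweep
from .thermal import (
    BoundaryConditions,
    LayerGeometry,
    LayerThermalHistory,
    MaterialThermalProps,
    PrintSimConfig,
)

SWEEP_COLUMNS = ["temperature_C", "g_prime_Pa", "g_double_prime_Pa"]
FLOW_COLUMNS = ["temperature_C", "shear_rate_per_s", "viscosity_Pa_s"]
POINT_COLUMNS = ["sample_id", "tg_C", "temperature_C", "shear_rate_per_s",
                 "viscosity_Pa_s"]

REPORT_SCHEMA_VERSION = 1


def _read_csv_with_metadata(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    meta: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise SchemaError(f"empty file: {path}")
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
        elif line.strip():
            break
    df = pd.read_csv(_stdio.StringIO(text), comment="#",
                     float_precision="round_trip")
    return df, meta


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    for col in required:
        bad = df[df[col].isna()]
        if len(bad):
            raise SchemaError(
                f"{path}: column {col!r} has missing values at row(s) "
                f"{list(bad.index[:5])}"
            )


def _fmt(x: float) -> str:
    return repr(float(x))


def read_sweep_csv(path) -> RheologySweep:
    """Read a temperature-sweep CSV (with optional ``#`` metadata lines)."""
    df, meta = _read_csv_with_metadata(path)
    _require_columns(df, SWEEP_COLUMNS, path)

    def fmeta(key):
        return float(meta[key]) if key in meta else None

    return RheologySweep(
        sample_id=meta.get("sample_id", Path(path).stem),
        temperature_C=df["temperature_C"].to_numpy(float),
        g_prime_Pa=df["g_prime_Pa"].to_numpy(float),
        g_double_prime_Pa=df["g_double_prime_Pa"].to_numpy(float),
        strain_pct=fmeta("strain_pct"),
        angular_frequency_rad_s=fmeta("angular_frequency_rad_s"),
        cooling_rate_C_min=fmeta("cooling_rate_C_min"),
    )


def write_sweep_csv(sweep: RheologySweep, path) -> None:
    """Write a sweep at full precision; round-trips through read_sweep_csv."""
    lines = [f"# sample_id: {sweep.sample_id}"]
    for key in ("strain_pct", "angular_frequency_rad_s", "cooling_rate_C_min"):
        val = getattr(sweep, key)
        if val is not None:
            lines.append(f"# {key}: {_fmt(val)}")
    lines.append(",".join(SWEEP_COLUMNS))
    for t, gp, gpp in zip(
        sweep.temperature_C, sweep.g_prime_Pa, sweep.g_double_prime_Pa
    ):
        lines.append(f"{_fmt(t)},{_fmt(gp)},{_fmt(gpp)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_flowcurves_csv(path, sample_id: str | None = None) -> FlowCurveSet:
    """Read long-format flow curves; one file may hold several temperatures."""
    df, meta = _read_csv_with_metadata(path)
    _require_columns(df, FLOW_COLUMNS, path)
    curves = {}
    for temp, grp in df.groupby("temperature_C"):
        grp = grp.sort_values("shear_rate_per_s")
        curves[float(temp)] = (
            grp["shear_rate_per_s"].to_numpy(float),
            grp["viscosity_Pa_s"].to_numpy(float),
        )
    sid = sample_id or meta.get("sample_id", Path(path).stem)
    return FlowCurveSet(sample_id=sid, curves=curves)


def write_flowcurves_csv(flowcurves: FlowCurveSet, path) -> None:
    lines = [f"# sample_id: {flowcurves.sample_id}", ",".join(FLOW_COLUMNS)]
    for temp in sorted(flowcurves.curves):
        sr, mu = flowcurves.curves[temp]
        for s, m in zip(sr, mu):
            lines.append(f"{_fmt(temp)},{_fmt(s)},{_fmt(m)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_points_csv(path) -> list[OperationalPoint]:
    """Read operational-map points (long format, grouped by sample_id)."""
    df, _ = _read_csv_with_metadata(path)
    _require_columns(df, POINT_COLUMNS, path)
    points = []
    for sid, grp in df.groupby("sample_id", sort=False):
        tg = grp["tg_C"].to_numpy(float)
        if not (tg == tg[0]).all():
            raise SchemaError(f"{path}: sample {sid!r} has inconsistent tg_C values")
        points.append(
            OperationalPoint(
                sample_id=str(sid),
                tg_C=float(tg[0]),
                viscosities=tuple(
                    (float(r.temperature_C), float(r.shear_rate_per_s),
                     float(r.viscosity_Pa_s))
                    for r in grp.itertuples()
                ),
            )
        )
    return points


def write_history_csv(history: LayerThermalHistory, path) -> None:
    """Per-layer surface-temperature time series: ``t_s, T_upper_C, T_side_C``."""
    lines = [f"# layer_index: {history.layer_index}",
             f"# base_temperature_C: {_fmt(history.base_temperature_C)}",
             "t_s,T_upper_C,T_side_C"]
    for t, tu, ts in zip(history.times_s, history.t_upper_C, history.t_side_C):
        lines.append(f"{_fmt(t)},{_fmt(tu)},{_fmt(ts)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(report: dict, path) -> None:
    """Serialize a report as versioned JSON."""
    payload = {"schema": REPORT_SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# print-scenario configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrintScenario:
    """A full print scenario: one thermal config per extrusion speed plus the
    nozzle shear-rate jobs."""

    configs: dict[float, PrintSimConfig]          # keyed by speed, mm/s
    nozzle_specs: list[NozzleFlowSpec]
    nozzle_speeds_mm_s: list[float]
    nozzle_temperature_C: float

    @property
    def speeds_mm_s(self) -> list[float]:
        return sorted(self.configs)


def load_print_scenario(source) -> PrintScenario:
    """Build a PrintScenario from a YAML/JSON path or an equivalent dict."""
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("print scenario config must be a mapping")

    def section(name):
        if name not in raw:
            raise ConfigError(f"config is missing section {name!r}")
        return raw[name]

    mat = section("material")
    try:
        material = MaterialThermalProps(
            conductivity_W_mK=float(mat["k"]),
            density_kg_m3=float(mat["rho"]),
            heat_capacity_J_kgK=float(mat["cp"]),
        )
        bnd = section("boundaries")
        boundaries = BoundaryConditions(
            base_temperature_C=float(bnd["Tp"]),
            ambient_temperature_C=float(bnd["Tinf"]),
            convection_W_m2K=float(bnd["h"]),
            initial_temperature_C=float(bnd["T0"]),
        )
        grid = raw.get("grid", {})
        nx, ny, nz = (int(grid.get(k, d)) for k, d in
                      (("Nx", 20), ("Ny", 20), ("Nz", 10)))
        n_layers = int(raw.get("layers", {}).get("count", 7))
        dt = float(raw.get("dt", 0.01))
        stride = float(raw.get("output_stride_s", 1.0))

        configs = {}
        for spd in section("speeds"):
            geometry = LayerGeometry(
                Lx_m=float(spd["Lx"]), Ly_m=float(spd["Ly"]), Lz_m=float(spd["Lz"]),
                Nx=nx, Ny=ny, Nz=nz,
            )
            configs[float(spd["v_mm_s"])] = PrintSimConfig(
                geometry=geometry,
                material=material,
                boundaries=boundaries,
                layer_duration_s=float(spd["layer_time_s"]),
                n_layers=n_layers,
                dt_s=dt,
                output_stride_s=stride,
            )

        nozzle_specs, nozzle_speeds = [], []
        for job in raw.get("nozzle", {}).get("jobs", []):
            nozzle_specs.append(
                NozzleFlowSpec(
                    printed_mass_g=float(raw["nozzle"].get("mass_g", 1.0)),
                    nozzle_radius_um=float(raw["nozzle"].get("radius_um", 415.0)),
                    print_time_s=float(job["time_s"]),
                    melt_density_g_cm3=float(raw["nozzle"].get("density_gcm3", 0.8793)),
                )
            )
            nozzle_speeds.append(float(job["v_mm_s"]))
    except KeyError as exc:
        raise ConfigError(f"config is missing key {exc.args[0]!r}") from exc

    return PrintScenario(
        configs=configs,
        nozzle_specs=nozzle_specs,
        nozzle_speeds_mm_s=nozzle_speeds,
        nozzle_temperature_C=boundaries.initial_temperature_C,
    )


def packaged_scenario_path() -> Path:
    """Path of the bundled reference print-scenario YAML."""
    return Path(resources.files("oleoprint").joinpath("data/print_scenario.yaml"))


def load_packaged_scenario() -> PrintScenario:
    """The bundled reference scenario (four speeds, seven layers)."""
    return load_print_scenario(packaged_scenario_path())
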