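"""Nozzle-wall shear rate during extrusion.

For laminar flow in a tube the Hagen-Poiseuille relation gives the wall shear
rate as gamma_dot = 4 Q / (pi r^3), with Q the volumetric flow rate.  For a
print job the flow rate is estimated from the mass of the printed form and
the print time, Q = m / (t rho), so

    gamma_dot = 4 m / (pi r^3 t rho)

with m the average printed mass, r the nozzle radius, t the print time and
rho the melt density at the extrusion temperature.  This is the Newtonian
estimate; no shear-thinning (Rabinowitsch) correction is applied.

Inputs carry the bench units the numbers are usually quoted in (g, um, s,
g/cm^3); the computation converts everything to SI first.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)

#: default melt density, g/cm^3, of the high-oleic sunflower-oil base at 70 C
DEFAULT_MELT_DENSITY_G_CM3 = 0.8793


@dataclass(frozen=True)
class NozzleFlowSpec:
    """Inputs for the shear-rate estimate; all strictly positive.

    printed_mass_g : average weight of the printed solid form (g)
    nozzle_radius_um : nozzle radius (micrometres)
    print_time_s : total printing time (s)
    melt_density_g_cm3 : melt density at the extrusion temperature (g/cm^3)
    """

    printed_mass_g: float
    nozzle_radius_um: float
    print_time_s: float
    melt_density_g_cm3: float = DEFAULT_MELT_DENSITY_G_CM3

    def __post_init__(self) -> None:
        for name in (
            "printed_mass_g",
            "nozzle_radius_um",
            "print_time_s",
            "melt_density_g_cm3",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be a finite positive number, got {v!r}")


def nozzle_shear_rate(spec: NozzleFlowSpec) -> float:
    """Wall shear rate (1/s) via the mass-flow Hagen-Poiseuille estimate.

    All quantities are converted to SI (kg, m, s, kg/m^3) before evaluating
    4 m / (pi r^3 t rho).
    """
    m_kg = spec.printed_mass_g * 1e-3
    r_m = spec.nozzle_radius_um * 1e-6
    rho_kg_m3 = spec.melt_density_g_cm3 * 1e3
    return 4.0 * m_kg / (math.pi * r_m**3 * spec.print_time_s * rho_kg_m3)


def shear_rate_table(
    specs: list[NozzleFlowSpec], speeds_mm_s: list[float]
) -> pd.DataFrame:
    """Tabulate shear rates for a set of print jobs at labelled extrusion speeds.

    Returns a DataFrame with columns ``speed_mm_s, time_s, shear_rate_per_s``
    (raw) and ``shear_rate_rounded`` (nearest integer, the form such tables
    are usually printed in).
    """
    if len(specs) != len(speeds_mm_s):
        raise ValueError(
            f"specs and speed labels differ in length: {len(specs)} vs {len(speeds_mm_s)}"
        )
    rows = []
    for spec, v in zip(specs, speeds_mm_s):
        gd = nozzle_shear_rate(spec)
        rows.append(
            {
                "speed_mm_s": v,
                "time_s": spec.print_time_s,
                "shear_rate_per_s": gd,
                "shear_rate_rounded": int(round(gd)),
            }
        )
    return pd.DataFrame(
        rows, columns=["speed_mm_s", "time_s", "shear_rate_per_s", "shear_rate_rounded"]
    )
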