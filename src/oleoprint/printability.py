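"""Operational-map classification and printability verdicts.

A formulation is summarized by its gelation temperature Tg and the
viscosities it shows at printing-relevant (temperature, shear-rate)
conditions.  On the Tg-viscosity plane the printable ("green") zone is the
rectangle Tg in [50, 80] deg C and mu in [0.01, 0.05] Pa s: below 50 deg C
the ink gels too fast for interlayer adhesion, above 80 deg C it needs
extrusion temperatures past common hardware limits; mu below 0.01 Pa s flows
uncontrolled, above 0.05 Pa s it clogs.  Independently of the zone, an ink
whose Tg is at or above the nozzle temperature T0 gels inside the syringe
and cannot be extruded at all.  Shape stability after deposition is judged
from the thermal simulation: every layer's final top and side surface
temperatures must drop below Tg.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .thermal import LayerThermalHistory

#: printable zone defaults: closed intervals
TG_RANGE_C = (50.0, 80.0)
MU_RANGE_PA_S = (0.01, 0.05)

#: default shear-rate symbol classes used on the map (1/s)
DEFAULT_SHEAR_CLASSES = (9.0, 27.0, 40.0, 52.0)


class Reason(str, Enum):
    TG_BELOW_RANGE = "tg_below_range"
    TG_ABOVE_RANGE = "tg_above_range"
    VISCOSITY_TOO_LOW = "viscosity_too_low"
    VISCOSITY_TOO_HIGH = "viscosity_too_high"
    GELS_IN_SYRINGE = "gels_in_syringe"
    INSUFFICIENT_COOLING = "insufficient_cooling"


#: reasons that decide the map zone (extrudability is a separate axis)
ZONE_REASONS = frozenset(
    {
        Reason.TG_BELOW_RANGE,
        Reason.TG_ABOVE_RANGE,
        Reason.VISCOSITY_TOO_LOW,
        Reason.VISCOSITY_TOO_HIGH,
    }
)


@dataclass(frozen=True)
class OperationalPoint:
    """One formulation's coordinates on the operational map.

    ``viscosities`` lists (temperature_C, shear_rate_per_s, mu_Pa_s) entries
    at printing conditions; all of them must fall in the viscosity window for
    the point to be green (conservative all-must-pass rule).
    """

    sample_id: str
    tg_C: float
    viscosities: tuple[tuple[float, float, float], ...]
    nozzle_temperature_C: float | None = None

    def __post_init__(self) -> None:
        import math

        if not self.viscosities:
            raise ValueError("need at least one viscosity entry")
        if not math.isfinite(self.tg_C):
            raise ValueError("tg must be finite")
        object.__setattr__(self, "viscosities", tuple(map(tuple, self.viscosities)))


@dataclass(frozen=True)
class PrintabilityVerdict:
    zone: str  # "green" | "red"
    extrudable: bool
    shape_stable: bool | None  # None = indeterminate (no thermal histories)
    reasons: tuple[Reason, ...]

    def __post_init__(self) -> None:
        zone_violations = [r for r in self.reasons if r in ZONE_REASONS]
        if (self.zone == "green") != (not zone_violations):
            raise ValueError("zone must be green iff no zone reasons")
        if Reason.GELS_IN_SYRINGE in self.reasons and self.extrudable:
            raise ValueError("gels_in_syringe implies not extrudable")


@dataclass
class StabilityReportItem:
    layer_index: int
    final_t_upper_C: float
    final_t_side_C: float
    upper_below_tg: bool
    side_below_tg: bool
    margin_upper_C: float
    margin_side_C: float


@dataclass
class ThermalStabilityReport:
    tg_C: float
    layers: list[StabilityReportItem]
    shape_stable: bool


def classify_operational_point(
    point: OperationalPoint,
    tg_range_C: tuple[float, float] = TG_RANGE_C,
    mu_range_Pa_s: tuple[float, float] = MU_RANGE_PA_S,
    any_viscosity_passes: bool = False,
    histories: list[LayerThermalHistory] | None = None,
) -> PrintabilityVerdict:
    """Verdict for one formulation.

    Green iff Tg lies in ``tg_range_C`` (closed) and the viscosity entries
    lie in ``mu_range_Pa_s`` (closed; all entries by default, any one entry
    with ``any_viscosity_passes``).  Extrudability additionally requires
    Tg strictly below the nozzle temperature; equality counts as gelling in
    the syringe.  Shape stability is judged from thermal histories when
    supplied, otherwise left indeterminate.
    """
    reasons: list[Reason] = []
    tg_lo, tg_hi = tg_range_C
    mu_lo, mu_hi = mu_range_Pa_s

    if point.tg_C < tg_lo:
        reasons.append(Reason.TG_BELOW_RANGE)
    elif point.tg_C > tg_hi:
        reasons.append(Reason.TG_ABOVE_RANGE)

    mus = [mu for (_, _, mu) in point.viscosities]
    if any_viscosity_passes:
        if not any(mu_lo <= mu <= mu_hi for mu in mus):
            reasons.append(
                Reason.VISCOSITY_TOO_LOW if all(mu < mu_lo for mu in mus)
                else Reason.VISCOSITY_TOO_HIGH
            )
    else:
        if any(mu < mu_lo for mu in mus):
            reasons.append(Reason.VISCOSITY_TOO_LOW)
        if any(mu > mu_hi for mu in mus):
            reasons.append(Reason.VISCOSITY_TOO_HIGH)

    extrudable = True
    if point.nozzle_temperature_C is not None and point.tg_C >= point.nozzle_temperature_C:
        reasons.append(Reason.GELS_IN_SYRINGE)
        extrudable = False

    shape_stable: bool | None = None
    if histories:
        report = assess_thermal_stability(histories, point.tg_C)
        shape_stable = report.shape_stable
        if not report.shape_stable:
            reasons.append(Reason.INSUFFICIENT_COOLING)

    zone = "green" if not any(r in ZONE_REASONS for r in reasons) else "red"
    return PrintabilityVerdict(
        zone=zone,
        extrudable=extrudable,
        shape_stable=shape_stable,
        reasons=tuple(reasons),
    )


def assess_thermal_stability(
    histories: list[LayerThermalHistory], tg_C: float
) -> ThermalStabilityReport:
    """Per-layer check that final top and side surface temperatures dropped
    below Tg; overall shape stability requires both for every layer."""
    if not histories:
        raise ValueError("need at least one layer history")
    items = []
    for h in histories:
        tu, ts = h.final_t_upper_C, h.final_t_side_C
        items.append(
            StabilityReportItem(
                layer_index=h.layer_index,
                final_t_upper_C=tu,
                final_t_side_C=ts,
                upper_below_tg=tu < tg_C,
                side_below_tg=ts < tg_C,
                margin_upper_C=tg_C - tu,
                margin_side_C=tg_C - ts,
            )
        )
    stable = all(i.upper_below_tg and i.side_below_tg for i in items)
    return ThermalStabilityReport(tg_C=tg_C, layers=items, shape_stable=stable)


def build_operational_map(
    points: list[OperationalPoint],
    tg_range_C: tuple[float, float] = TG_RANGE_C,
    mu_range_Pa_s: tuple[float, float] = MU_RANGE_PA_S,
    shear_classes: tuple[float, ...] = DEFAULT_SHEAR_CLASSES,
) -> dict:
    """Plot-ready dataset for the Tg-viscosity operational map.

    Each (Tg, mu) pair is tagged with its zone and the nearest shear-rate
    symbol class; the green-zone rectangle bounds are included so callers can
    draw the shaded regions.
    """
    if not points:
        raise ValueError("need at least one point")
    rows = []
    tg_lo, tg_hi = tg_range_C
    mu_lo, mu_hi = mu_range_Pa_s
    for p in points:
        for (temp, shear, mu) in p.viscosities:
            in_zone = (tg_lo <= p.tg_C <= tg_hi) and (mu_lo <= mu <= mu_hi)
            cls = min(shear_classes, key=lambda c: abs(c - shear)) if shear_classes else shear
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "tg_C": p.tg_C,
                    "temperature_C": temp,
                    "shear_rate_per_s": shear,
                    "shear_class_per_s": cls,
                    "mu_Pa_s": mu,
                    "zone": "green" if in_zone else "red",
                }
            )
    return {
        "points": rows,
        "zone_bounds": {"tg_C": list(tg_range_C), "mu_Pa_s": list(mu_range_Pa_s)},
    }


def plot_operational_map(map_dataset: dict, path: str) -> None:
    """Render the operational map to an image file (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    (tg_lo, tg_hi) = map_dataset["zone_bounds"]["tg_C"]
    (mu_lo, mu_hi) = map_dataset["zone_bounds"]["mu_Pa_s"]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.set_yscale("log")
    ax.add_patch(
        Rectangle((tg_lo, mu_lo), tg_hi - tg_lo, mu_hi - mu_lo,
                  facecolor="green", alpha=0.2, zorder=0)
    )
    markers = {9.0: "o", 27.0: "x", 40.0: "^", 52.0: "_"}
    for row in map_dataset["points"]:
        ax.scatter(
            row["tg_C"], row["mu_Pa_s"],
            marker=markers.get(row["shear_class_per_s"], "s"),
            c="tab:green" if row["zone"] == "green" else "tab:red",
        )
    ax.set_xlabel("gelation temperature Tg (deg C)")
    ax.set_ylabel("viscosity mu (Pa s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
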