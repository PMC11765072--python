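"""Oscillatory temperature sweeps and rotational flow curves.

Small-amplitude oscillatory shear during a cooling ramp yields the storage
modulus G' (elastic part) and loss modulus G'' (viscous part) as functions of
temperature.  The gelation temperature Tg is the point where the two moduli
intersect, i.e. where the loss factor tan(delta) = G''/G' passes through
unity: above Tg the melt is liquid-like (tan(delta) > 1), below it a gel
network dominates (tan(delta) < 1).  Rotational flow curves give the apparent
viscosity mu(shear_rate) at a set of fixed temperatures; the printing
calculations need mu at arbitrary (temperature, shear-rate) queries, which is
done by bilinear interpolation in (T, log shear_rate) of log mu.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum


import numpy as np

from .errors import DomainError, MalformedSweepError, NoCrossingError, OutOfRangeError

logger = logging.getLogger(__name__)

#: default reference temperature (deg C) for gel classification; storage-relevant
CLASSIFICATION_TEMPERATURE_C = 5.0

#: shear-rate window (1/s) a rotational flow curve is expected to cover
FLOW_CURVE_SHEAR_RANGE = (0.01, 100.0)


@dataclass(frozen=True)
class RheologySweep:
    """A G'/G'' temperature sweep, normally recorded while cooling.

    Parameters
    ----------
    sample_id : str
        Formulation label (e.g. ``"M20"``).
    temperature_C, g_prime_Pa, g_double_prime_Pa : array-like
        Equal-length columns; temperatures strictly monotone (descending for
        a cooling sweep), both moduli strictly positive, at least 3 rows.
    strain_pct, angular_frequency_rad_s, cooling_rate_C_min : float, optional
        Instrument metadata carried through to reports.
    """

    sample_id: str
    temperature_C: np.ndarray
    g_prime_Pa: np.ndarray
    g_double_prime_Pa: np.ndarray
    strain_pct: float | None = None
    angular_frequency_rad_s: float | None = None
    cooling_rate_C_min: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_C, dtype=float)
        gp = np.asarray(self.g_prime_Pa, dtype=float)
        gpp = np.asarray(self.g_double_prime_Pa, dtype=float)
        if not (t.ndim == gp.ndim == gpp.ndim == 1):
            raise MalformedSweepError("sweep columns must be 1-D")
        if not (t.size == gp.size == gpp.size):
            raise MalformedSweepError(
                f"column lengths differ: {t.size}, {gp.size}, {gpp.size}"
            )
        if t.size < 3:
            raise MalformedSweepError(f"sweep needs at least 3 rows, got {t.size}")
        dt = np.diff(t)
        if not (np.all(dt > 0) or np.all(dt < 0)):
            raise MalformedSweepError("temperatures must be strictly monotone")
        if not (np.all(np.isfinite(gp)) and np.all(gp > 0)):
            raise MalformedSweepError("G' must be finite and > 0 for every row")
        if not (np.all(np.isfinite(gpp)) and np.all(gpp > 0)):
            raise MalformedSweepError("G'' must be finite and > 0 for every row")
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "g_prime_Pa", gp)
        object.__setattr__(self, "g_double_prime_Pa", gpp)

    @property
    def n_rows(self) -> int:
        return int(self.temperature_C.size)

    def reversed(self) -> "RheologySweep":
        """Same sweep with row order flipped (re-validated)."""
        return RheologySweep(
            self.sample_id,
            self.temperature_C[::-1].copy(),
            self.g_prime_Pa[::-1].copy(),
            self.g_double_prime_Pa[::-1].copy(),
            self.strain_pct,
            self.angular_frequency_rad_s,
            self.cooling_rate_C_min,
        )


@dataclass(frozen=True)
class GelationResult:
    """Outcome of the G'/G'' crossover search.

    ``tg_C`` is the highest-temperature crossing (the liquid-to-gel transition
    on a cooling sweep); ``crossings_C`` lists every crossing found, descending.
    ``bracketing_rows`` holds the two (T, G', G'') rows between which the
    reported crossing lies.
    """

    tg_C: float
    bracketing_rows: tuple[tuple[float, float, float], tuple[float, float, float]]
    method: str
    crossings_C: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        lo = min(self.bracketing_rows[0][0], self.bracketing_rows[1][0])
        hi = max(self.bracketing_rows[0][0], self.bracketing_rows[1][0])
        if not (lo <= self.tg_C <= hi):
            raise ValueError("tg must lie within the bracketing temperature interval")


class GelClassValue(str, Enum):
    STRONG_GEL = "strong_gel"
    WEAK_GEL = "weak_gel"
    VISCOUS_LIQUID = "viscous_liquid"


@dataclass(frozen=True)
class GelClass:
    value: GelClassValue
    tan_delta: float


@dataclass(frozen=True)
class FlowCurveSet:
    """Viscosity-vs-shear-rate curves at several fixed temperatures.

    ``curves`` maps temperature (deg C) to a ``(shear_rate_per_s,
    viscosity_Pa_s)`` pair of 1-D arrays with strictly increasing shear rates
    and positive viscosities.  Shear rates are expected inside
    ``FLOW_CURVE_SHEAR_RANGE`` unless ``allow_wide_shear_range`` is set.
    """

    sample_id: str
    curves: dict[float, tuple[np.ndarray, np.ndarray]]
    allow_wide_shear_range: bool = False

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("FlowCurveSet needs at least one curve")
        clean: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        lo, hi = FLOW_CURVE_SHEAR_RANGE
        for temp, (sr, mu) in self.curves.items():
            sr = np.asarray(sr, dtype=float)
            mu = np.asarray(mu, dtype=float)
            if sr.size != mu.size or sr.size == 0:
                raise ValueError(f"curve at {temp} C: mismatched or empty columns")
            if not np.all(np.diff(sr) > 0):
                raise ValueError(
                    f"curve at {temp} C: shear rates must be strictly increasing"
                )
            if not self.allow_wide_shear_range and (sr[0] < lo * (1 - 1e-12) or sr[-1] > hi * (1 + 1e-12)):
                raise ValueError(
                    f"curve at {temp} C: shear rates outside [{lo}, {hi}] 1/s "
                    "(pass allow_wide_shear_range=True to override)"
                )
            if not np.all(mu > 0):
                raise ValueError(f"curve at {temp} C: viscosities must be > 0")
            clean[float(temp)] = (sr, mu)
        object.__setattr__(self, "curves", clean)

    @property
    def temperatures_C(self) -> np.ndarray:
        return np.array(sorted(self.curves), dtype=float)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

CROSSOVER_METHOD = "linear in (T, log G' - log G'')"


def loss_factor(g_prime: float, g_double_prime: float) -> float:
    """tan(delta) = G''/G'.  Both moduli must be strictly positive (Pa)."""
    if not (g_prime > 0 and g_double_prime > 0):
        raise DomainError(
            f"moduli must be > 0, got G'={g_prime!r}, G''={g_double_prime!r}"
        )
    return g_double_prime / g_prime


def classify_gel(tan_delta: float) -> GelClass:
    """Classify a material from its loss factor.

    tan(delta) < 0.1 -> strong gel; 0.1 <= tan(delta) < 1 -> weak gel;
    tan(delta) >= 1 -> viscous liquid.  The boundary 0.1 is assigned to the
    weak-gel class so the strong-gel definition stays strict.
    """
    if not (isinstance(tan_delta, (int, float)) and math.isfinite(tan_delta) and tan_delta > 0):
        raise DomainError(f"tan(delta) must be a finite positive number, got {tan_delta!r}")
    if tan_delta < 0.1:
        value = GelClassValue.STRONG_GEL
    elif tan_delta < 1.0:
        value = GelClassValue.WEAK_GEL
    else:
        value = GelClassValue.VISCOUS_LIQUID
    return GelClass(value=value, tan_delta=float(tan_delta))


def loss_factor_at(
    sweep: RheologySweep, temperature_C: float = CLASSIFICATION_TEMPERATURE_C
) -> float:
    """tan(delta) read at the sweep row nearest the given temperature.

    Defaults to 5 deg C, the storage-relevant reference; a single nearest-row
    read, no averaging window.
    """
    i = int(np.argmin(np.abs(sweep.temperature_C - temperature_C)))
    return loss_factor(float(sweep.g_prime_Pa[i]), float(sweep.g_double_prime_Pa[i]))


def classify_sweep(
    sweep: RheologySweep, temperature_C: float = CLASSIFICATION_TEMPERATURE_C
) -> GelClass:
    """Gel class of a sweep, evaluated at the row nearest ``temperature_C``."""
    return classify_gel(loss_factor_at(sweep, temperature_C))


def find_gelation_temperature(sweep: RheologySweep) -> GelationResult:
    """Locate the G'/G'' crossover (tan(delta) = 1) of a temperature sweep.

    The signed log-modulus gap d(T) = log G'(T) - log G''(T) is zero exactly
    at the crossover; between bracketing rows the crossing is interpolated
    linearly in (T, d), which is exact when both moduli are exponential in T.
    If several crossings exist the highest-temperature one is reported (the
    liquid-to-gel transition on a cooling sweep) and all are recorded.

    Raises
    ------
    NoCrossingError
        If d keeps one sign over the whole sweep.
    """
    t = sweep.temperature_C
    d = np.log(sweep.g_prime_Pa) - np.log(sweep.g_double_prime_Pa)

    crossings: list[tuple[float, int, int]] = []  # (T*, i, j) bracketing indices
    for i in range(t.size - 1):
        di, dj = d[i], d[i + 1]
        if di == 0.0:
            crossings.append((float(t[i]), i, i))
            continue
        if di * dj < 0.0:
            frac = di / (di - dj)
            crossings.append((float(t[i] + (t[i + 1] - t[i]) * frac), i, i + 1))
    if d[-1] == 0.0:
        crossings.append((float(t[-1]), t.size - 1, t.size - 1))

    if not crossings:
        raise NoCrossingError(
            f"sample {sweep.sample_id!r}: G' - G'' has one sign over the whole "
            "sweep; no tan(delta) = 1 crossover in the measured range"
        )

    crossings.sort(key=lambda c: -c[0])
    tg, i, j = crossings[0]
    row = lambda k: (
        float(t[k]),
        float(sweep.g_prime_Pa[k]),
        float(sweep.g_double_prime_Pa[k]),
    )
    return GelationResult(
        tg_C=tg,
        bracketing_rows=(row(i), row(j)),
        method=CROSSOVER_METHOD,
        crossings_C=tuple(c[0] for c in crossings),
    )


def _interp_log(x: float, xs: np.ndarray, ys: np.ndarray, extrapolate: bool) -> float:
    """Piecewise-linear interpolation with optional linear end extension."""
    if xs.size == 1:
        return float(ys[0])
    if x < xs[0]:
        if not extrapolate:
            raise OutOfRangeError(f"query {x} below grid start {xs[0]}")
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        return float(ys[0] + slope * (x - xs[0]))
    if x > xs[-1]:
        if not extrapolate:
            raise OutOfRangeError(f"query {x} above grid end {xs[-1]}")
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + slope * (x - xs[-1]))
    return float(np.interp(x, xs, ys))


def interpolate_viscosity(
    flowcurves: FlowCurveSet,
    temperature_C: float,
    shear_rate_per_s: float,
    allow_extrapolation: bool = False,
) -> float:
    """Viscosity (Pa s) at an arbitrary (temperature, shear-rate) query.

    Bilinear in (temperature, log shear_rate) of log viscosity between the
    two nearest measured curves; exact (bit-identical) at measured grid
    points.  Out-of-range queries raise ``OutOfRangeError`` unless
    ``allow_extrapolation`` is set, in which case the edge segments are
    extended linearly (in the same log coordinates) and a warning is logged.
    """
    if shear_rate_per_s <= 0:
        raise DomainError(f"shear rate must be > 0, got {shear_rate_per_s}")
    temps = flowcurves.temperatures_C

    # bit-exact short-circuit at measured grid points
    if temperature_C in flowcurves.curves:
        sr, mu = flowcurves.curves[temperature_C]
        hit = np.nonzero(sr == shear_rate_per_s)[0]
        if hit.size:
            return float(mu[hit[0]])

    def at_temp(temp: float) -> float:
        sr, mu = flowcurves.curves[temp]
        return _interp_log(
            math.log(shear_rate_per_s), np.log(sr), np.log(mu), allow_extrapolation
        )

    if temperature_C < temps[0] or temperature_C > temps[-1]:
        if not allow_extrapolation:
            raise OutOfRangeError(
                f"temperature {temperature_C} C outside measured span "
                f"[{temps[0]}, {temps[-1]}] C"
            )
        logger.warning(
            "extrapolating viscosity outside measured temperature span "
            "(%s C not in [%s, %s] C)", temperature_C, temps[0], temps[-1]
        )
    if allow_extrapolation and (
        temperature_C < temps[0]
        or temperature_C > temps[-1]
        or _needs_shear_extrapolation(flowcurves, temperature_C, shear_rate_per_s)
    ):
        logger.warning(
            "viscosity extrapolation active for query T=%s C, shear=%s 1/s",
            temperature_C, shear_rate_per_s,
        )

    if temps.size == 1 or temperature_C in flowcurves.curves:
        key = float(temps[np.argmin(np.abs(temps - temperature_C))]) \
            if temperature_C not in flowcurves.curves else temperature_C
        return math.exp(at_temp(key))

    j = int(np.searchsorted(temps, temperature_C))
    j = min(max(j, 1), temps.size - 1)
    t_lo, t_hi = float(temps[j - 1]), float(temps[j])
    log_lo, log_hi = at_temp(t_lo), at_temp(t_hi)
    w = (temperature_C - t_lo) / (t_hi - t_lo)
    return math.exp(log_lo * (1.0 - w) + log_hi * w)


def _needs_shear_extrapolation(
    flowcurves: FlowCurveSet, temperature_C: float, shear_rate_per_s: float
) -> bool:
    for sr, _ in flowcurves.curves.values():
        if not (sr[0] <= shear_rate_per_s <= sr[-1]):
            return True
    return False


def gelation_report(
    sweep: RheologySweep,
    classification_temperature_C: float = CLASSIFICATION_TEMPERATURE_C,
) -> dict:
    """JSON-ready summary: Tg, all crossings, tan(delta) at the reference
    temperature and the gel class."""
    res = find_gelation_temperature(sweep)
    td = loss_factor_at(sweep, classification_temperature_C)
    cls = classify_gel(td)
    return {
        "sample_id": sweep.sample_id,
        "tg_C": res.tg_C,
        "crossings": list(res.crossings_C),
        "tan_delta_at_5C": td,
        "gel_class": cls.value.value,
    }
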