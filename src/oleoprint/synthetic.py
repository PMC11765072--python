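"""Synthetic rheometer data with exact ground truth.

No public dataset of oleogel temperature sweeps or flow curves ships with
this package, so every analysis stage is exercised against generated data
whose ground truth is known by construction:

* ``generate_sweep`` builds a cooling sweep whose storage modulus follows a
  logistic sigmoid between a liquid and a solid plateau (in log space, since
  moduli span decades) and whose loss factor tan(delta) interpolates
  logistically from a liquid value > 1 down to a solid value < 1 — with the
  tan(delta) = 1 crossover pinned *exactly* at the requested gelation
  temperature by solving the logistic pin analytically, not by root-finding.

* ``generate_flow_curves`` builds shear-thinning flow curves from a
  temperature-dependent power law mu = mu_inf + K(T) shear^(n-1) with an
  Arrhenius-type consistency K(T) = K0 exp(E / T_kelvin).

Optional multiplicative lognormal noise (coefficient of variation
``noise_cv``) emulates instrument scatter; generation is deterministic for a
given seed.  The bundled presets mimic the qualitative character of a
monoglyceride oleogel series with increasing phytosterol content (rising Tg
ladder, strong vs weak gels, one near-Newtonian member); they are synthetic
mimics, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .rheology import FlowCurveSet, RheologySweep


def _logit(u: float) -> float:
    return math.log(u / (1.0 - u))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-median multiplicative noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


@dataclass(frozen=True)
class SweepGeneratorParams:
    """Ground-truth description of a synthetic cooling sweep.

    The crossover tan(delta) = 1 occurs exactly at ``target_tg_C``.
    ``transition_width_C`` is the logistic scale of both the modulus ramp and
    the loss-factor ramp; ``noise_cv`` the multiplicative noise level.
    """

    target_tg_C: float
    solid_plateau_g_prime_Pa: float = 3.0e6
    liquid_g_prime_Pa: float = 0.5
    transition_width_C: float = 2.0
    tan_delta_solid: float = 0.08
    tan_delta_liquid: float = 2.5
    sampling_step_C: float = 0.5
    temperature_range_C: tuple[float, float] = (5.0, 95.0)
    noise_cv: float = 0.0
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not (self.tan_delta_solid < 1.0 < self.tan_delta_liquid):
            raise ValueError("need tan_delta_solid < 1 < tan_delta_liquid")
        lo, hi = self.temperature_range_C
        if not (lo < self.target_tg_C < hi):
            raise ValueError("target Tg must lie inside the temperature range")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.sampling_step_C <= 0 or self.transition_width_C <= 0:
            raise ValueError("sampling step and transition width must be > 0")
        if min(self.solid_plateau_g_prime_Pa, self.liquid_g_prime_Pa) <= 0:
            raise ValueError("modulus plateaus must be > 0")

    # --- noise-free ground-truth curves -------------------------------
    def true_tan_delta(self, temperature_C):
        """Exact tan(delta) of the generating model (vectorized)."""
        t = np.asarray(temperature_C, dtype=float)
        ls = math.log(self.tan_delta_solid)
        ll = math.log(self.tan_delta_liquid)
        u_star = -ls / (ll - ls)          # logistic value where tan(delta)=1
        t_mid = self.target_tg_C - self.transition_width_C * _logit(u_star)
        u = _sigmoid((t - t_mid) / self.transition_width_C)
        return np.exp(ls + (ll - ls) * u)

    def true_g_prime(self, temperature_C):
        t = np.asarray(temperature_C, dtype=float)
        ls = math.log(self.solid_plateau_g_prime_Pa)
        ll = math.log(self.liquid_g_prime_Pa)
        u = _sigmoid((self.target_tg_C - t) / self.transition_width_C)
        return np.exp(ll + (ls - ll) * u)


def generate_sweep(params: SweepGeneratorParams) -> RheologySweep:
    """Synthesize a cooling sweep (descending temperatures) from the model."""
    lo, hi = params.temperature_range_C
    temps = np.arange(hi, lo - 1e-9, -params.sampling_step_C)
    gp = params.true_g_prime(temps)
    gpp = gp * params.true_tan_delta(temps)
    rng = np.random.default_rng(params.seed)
    gp = gp * _lognormal_factor(rng, params.noise_cv, temps.size)
    gpp = gpp * _lognormal_factor(rng, params.noise_cv, temps.size)
    return RheologySweep(
        sample_id=params.sample_id,
        temperature_C=temps,
        g_prime_Pa=gp,
        g_double_prime_Pa=gpp,
        strain_pct=0.01,
        angular_frequency_rad_s=1.0,
        cooling_rate_C_min=2.0,
    )


@dataclass(frozen=True)
class FlowGeneratorParams:
    """Ground truth for synthetic flow curves.

    mu(shear, T) = mu_inf + K(T) shear^(n-1),
    K(T) = consistency_prefactor * exp(activation_scale_K / T_kelvin).
    Flow index n in (0, 1]: 1 is Newtonian, smaller is more shear-thinning.
    """

    consistency_prefactor_Pa_sn: float
    flow_index_n: float = 1.0
    activation_scale_K: float = 0.0
    infinite_shear_viscosity_Pa_s: float = 0.0
    temperatures_C: tuple[float, ...] = (60.0, 70.0, 80.0, 90.0)
    shear_rate_grid_per_s: tuple[float, ...] = tuple(np.logspace(-2, 2, 21))
    noise_cv: float = 0.0
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.0 < self.flow_index_n <= 1.0):
            raise ValueError("flow index must satisfy 0 < n <= 1")
        if not self.temperatures_C or not len(self.shear_rate_grid_per_s):
            raise ValueError("temperature and shear-rate grids must be non-empty")
        if self.consistency_prefactor_Pa_sn <= 0:
            raise ValueError("consistency prefactor must be > 0")
        if self.infinite_shear_viscosity_Pa_s < 0 or self.noise_cv < 0:
            raise ValueError("mu_inf and noise_cv must be >= 0")

    def true_viscosity(self, shear_rate_per_s, temperature_C):
        """Closed-form viscosity of the generating model (Pa s)."""
        sr = np.asarray(shear_rate_per_s, dtype=float)
        k = self.consistency_prefactor_Pa_sn * math.exp(
            self.activation_scale_K / (temperature_C + 273.15)
        )
        return self.infinite_shear_viscosity_Pa_s + k * sr ** (self.flow_index_n - 1.0)


def generate_flow_curves(params: FlowGeneratorParams) -> FlowCurveSet:
    """Synthesize a FlowCurveSet from the power-law model."""
    rng = np.random.default_rng(params.seed)
    curves = {}
    for temp in params.temperatures_C:
        sr = np.asarray(params.shear_rate_grid_per_s, dtype=float)
        mu = params.true_viscosity(sr, temp)
        mu = mu * _lognormal_factor(rng, params.noise_cv, sr.size)
        curves[float(temp)] = (sr, mu)
    return FlowCurveSet(sample_id=params.sample_id, curves=curves)


# ---------------------------------------------------------------------------
# presets: synthetic mimics of a phytosterol-in-oleogel formulation ladder
# ---------------------------------------------------------------------------

#: Sweep presets. Tg ladder rises with co-gelator content except for the
#: low-ratio members, which gel later than the plain oleogel; tan(delta)
#: plateaus distinguish weak (0.1..1) from strong (<0.1) gels.  Synthetic
#: mimics for demos and tests, not measurements.
SWEEP_PRESETS: dict[str, SweepGeneratorParams] = {
    "M0": SweepGeneratorParams(target_tg_C=65.0, tan_delta_solid=0.255,
                               solid_plateau_g_prime_Pa=5.0e5, sample_id="M0"),
    "M5": SweepGeneratorParams(target_tg_C=55.0, tan_delta_solid=0.343,
                               solid_plateau_g_prime_Pa=3.0e5, sample_id="M5"),
    "M10": SweepGeneratorParams(target_tg_C=50.0, tan_delta_solid=0.024,
                                solid_plateau_g_prime_Pa=1.5e6, sample_id="M10"),
    "M20": SweepGeneratorParams(target_tg_C=78.37, tan_delta_solid=0.079,
                                solid_plateau_g_prime_Pa=3.07e6, sample_id="M20"),
    "M30": SweepGeneratorParams(target_tg_C=90.0, tan_delta_solid=0.034,
                                solid_plateau_g_prime_Pa=4.0e6,
                                temperature_range_C=(5.0, 105.0), sample_id="M30"),
    "M40": SweepGeneratorParams(target_tg_C=100.0, tan_delta_solid=0.055,
                                solid_plateau_g_prime_Pa=6.0e6,
                                temperature_range_C=(5.0, 115.0), sample_id="M40"),
}

#: Flow-curve presets.  The optimal member is near-Newtonian with mu around
#: 0.013-0.032 Pa s between 90 and 60 deg C; high co-gelator members are
#: strongly shear-thinning with viscosities reaching 0.5 / 36 Pa s.
FLOW_PRESETS: dict[str, FlowGeneratorParams] = {
    "M0": FlowGeneratorParams(consistency_prefactor_Pa_sn=2.0e-6,
                              flow_index_n=0.85, activation_scale_K=3300.0,
                              sample_id="M0"),
    "M5": FlowGeneratorParams(consistency_prefactor_Pa_sn=1.5e-6,
                              flow_index_n=0.80, activation_scale_K=3300.0,
                              sample_id="M5"),
    "M10": FlowGeneratorParams(consistency_prefactor_Pa_sn=1.8e-6,
                               flow_index_n=0.82, activation_scale_K=3300.0,
                               sample_id="M10"),
    "M20": FlowGeneratorParams(consistency_prefactor_Pa_sn=5.9e-7,
                               flow_index_n=1.0, activation_scale_K=3630.0,
                               sample_id="M20"),
    "M30": FlowGeneratorParams(consistency_prefactor_Pa_sn=3.0e-5,
                               flow_index_n=0.60, activation_scale_K=3300.0,
                               temperatures_C=(60.0, 70.0, 80.0, 90.0, 100.0),
                               sample_id="M30"),
    "M40": FlowGeneratorParams(consistency_prefactor_Pa_sn=3.0e-4,
                               flow_index_n=0.40, activation_scale_K=3300.0,
                               temperatures_C=(60.0, 70.0, 80.0, 90.0, 100.0),
                               sample_id="M40"),
}
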