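"""Transient 3D cooling of a printed layer, stacked layer by layer.

Each deposited layer is a rectangular slab of molten oleogel, initially at
the nozzle exit temperature T0, cooling by conduction to the build platform
(Dirichlet base at Tp) and by natural convection to ambient air on the four
side walls and the top face (Robin condition -k dT/dn = h (T - Tinf)).
Latent heat of gelator crystallization is neglected (it is a few percent of
the sensible heat exchanged).

The heat equation dT/dt = alpha laplacian(T), alpha = k / (rho Cp), is
discretized forward-time centred-space (FTCS) on a node-centred grid with
spacing Delta_i = L_i / (N_i - 1).  Robin faces use second-order ghost
nodes; the explicit scheme is stable when

    r = alpha dt (1/dx^2 + 1/dy^2 + 1/dz^2) <= 1/2.

A print of n layers is simulated as n independent slab problems: layer 1
sits on the platform (base fixed at Tp); layer j >= 2 starts uniform at T0
with its base held at the final top-surface temperature of layer j-1 (the
handoff is exact, the recorded value is reused bit-for-bit).  The mean top
(T_upper) and side (T_side) surface temperatures of each layer are recorded
on an output stride and compared downstream against the gelation
temperature to judge shape stability.

An energy audit accumulates the discrete boundary fluxes the FTCS stencil
itself exchanges (base conduction plus ghost-node Robin fluxes), so the
enthalpy balance closes to round-off; this is the bookkeeping used by the
conservation checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, StabilityError

logger = logging.getLogger(__name__)

STABILITY_LIMIT = 0.5


@dataclass(frozen=True)
class MaterialThermalProps:
    """Thermal properties of the melt; diffusivity is always derived.

    conductivity_W_mK : thermal conductivity k, W/(m K)
    density_kg_m3 : density rho, kg/m^3
    heat_capacity_J_kgK : specific heat Cp, J/(kg K)
    """

    conductivity_W_mK: float
    density_kg_m3: float
    heat_capacity_J_kgK: float

    def __post_init__(self) -> None:
        for name in ("conductivity_W_mK", "density_kg_m3", "heat_capacity_J_kgK"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")

    @property
    def diffusivity_m2_s(self) -> float:
        """alpha = k / (rho Cp), m^2/s."""
        return self.conductivity_W_mK / (self.density_kg_m3 * self.heat_capacity_J_kgK)


@dataclass(frozen=True)
class LayerGeometry:
    """One layer's slab dimensions (m) and node counts per direction."""

    Lx_m: float
    Ly_m: float
    Lz_m: float
    Nx: int = 20
    Ny: int = 20
    Nz: int = 10

    def __post_init__(self) -> None:
        if min(self.Lx_m, self.Ly_m, self.Lz_m) <= 0:
            raise ConfigError("layer lengths must be > 0")
        if min(self.Nx, self.Ny, self.Nz) < 3:
            raise ConfigError("need at least 3 nodes per direction")

    @property
    def spacings_m(self) -> tuple[float, float, float]:
        """(dx, dy, dz) with Delta_i = L_i / (N_i - 1)."""
        return (
            self.Lx_m / (self.Nx - 1),
            self.Ly_m / (self.Ny - 1),
            self.Lz_m / (self.Nz - 1),
        )


@dataclass(frozen=True)
class BoundaryConditions:
    """Platform (Dirichlet), ambient (Robin) and nozzle-exit temperatures, deg C."""

    base_temperature_C: float
    ambient_temperature_C: float
    convection_W_m2K: float
    initial_temperature_C: float

    def __post_init__(self) -> None:
        if self.convection_W_m2K < 0:
            raise ConfigError("convection coefficient must be >= 0")


@dataclass
class ThermalField:
    """Node temperatures (deg C), shape (Nx, Ny, Nz) with iz = 0 at the base,
    plus the simulation clock (s)."""

    temperatures_C: np.ndarray
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        if self.temperatures_C.ndim != 3:
            raise ConfigError("temperature field must be 3-D")


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the explicit-scheme stability check."""

    r: float
    limit: float
    passed: bool
    dt_s: float
    diffusivity_m2_s: float
    spacings_m: tuple[float, float, float]


@dataclass
class EnergyAudit:
    """Discrete boundary-flux bookkeeping over one layer's run (J).

    ``base_in_J`` is heat conducted in through the Dirichlet base (negative
    when the base removes heat), ``robin_out_J`` heat lost through the
    ghost-node Robin faces; ``enthalpy_change_J`` is rho Cp V dT summed over
    the updated nodes.  ``residual_rel`` is |dH - (in - out)| relative to the
    largest of the three magnitudes.
    """

    base_in_J: float = 0.0
    robin_out_J: float = 0.0
    enthalpy_change_J: float = 0.0

    @property
    def residual_rel(self) -> float:
        net = self.base_in_J - self.robin_out_J
        scale = max(abs(self.enthalpy_change_J), abs(self.base_in_J),
                    abs(self.robin_out_J), 1e-300)
        return abs(self.enthalpy_change_J - net) / scale


@dataclass
class LayerThermalHistory:
    """Recorded surface temperatures of one printed layer (1-based index)."""

    layer_index: int
    times_s: np.ndarray
    t_upper_C: np.ndarray
    t_side_C: np.ndarray
    final_field: ThermalField
    base_temperature_C: float
    energy: EnergyAudit
    observed_min_C: float
    observed_max_C: float

    @property
    def final_t_upper_C(self) -> float:
        return float(self.t_upper_C[-1])

    @property
    def final_t_side_C(self) -> float:
        return float(self.t_side_C[-1])


@dataclass(frozen=True)
class PrintSimConfig:
    """Everything one layer-by-layer print simulation needs."""

    geometry: LayerGeometry
    material: MaterialThermalProps
    boundaries: BoundaryConditions
    layer_duration_s: float
    n_layers: int = 7
    dt_s: float = 0.01
    output_stride_s: float = 1.0
    robin_order: int = 2
    override_stability: bool = False

    def __post_init__(self) -> None:
        if self.layer_duration_s < 0:
            raise ConfigError("layer duration must be >= 0")
        if self.n_layers < 1:
            raise ConfigError("need at least one layer")
        if self.dt_s <= 0 or self.output_stride_s <= 0:
            raise ConfigError("dt and output stride must be > 0")
        if self.robin_order not in (1, 2):
            raise ConfigError("robin_order must be 1 or 2")


def stability_check(config: PrintSimConfig) -> StabilityReport:
    """Evaluate r = alpha dt sum(1/Delta_i^2) against the FTCS bound 1/2."""
    alpha = config.material.diffusivity_m2_s
    dx, dy, dz = config.geometry.spacings_m
    r = alpha * config.dt_s * (1.0 / dx**2 + 1.0 / dy**2 + 1.0 / dz**2)
    return StabilityReport(
        r=r,
        limit=STABILITY_LIMIT,
        passed=r <= STABILITY_LIMIT,
        dt_s=config.dt_s,
        diffusivity_m2_s=alpha,
        spacings_m=(dx, dy, dz),
    )


class _Stepper:
    """Preallocated FTCS stepper for one layer; mutates its field in place."""

    def __init__(self, config: PrintSimConfig, base_temperature_C: float,
                 initial: np.ndarray):
        g, m, b = config.geometry, config.material, config.boundaries
        self.cfg = config
        self.base_T = float(base_temperature_C)
        self.Tinf = b.ambient_temperature_C
        self.h = b.convection_W_m2K
        self.k = m.conductivity_W_mK
        self.dx, self.dy, self.dz = g.spacings_m
        alpha = m.diffusivity_m2_s
        dt = config.dt_s
        self.cx = alpha * dt / self.dx**2
        self.cy = alpha * dt / self.dy**2
        self.cz = alpha * dt / self.dz**2
        # ghost-node factor 2 Delta h / k per direction
        self.gx = 2.0 * self.dx * self.h / self.k
        self.gy = 2.0 * self.dy * self.h / self.k
        self.gz = 2.0 * self.dz * self.h / self.k

        self.P = np.zeros((g.Nx + 2, g.Ny + 2, g.Nz + 2))
        self.I = self.P[1:-1, 1:-1, 1:-1]  # interior view = physical field
        self.I[...] = initial
        self.I[:, :, 0] = self.base_T
        self.new = np.empty_like(self.I)

        # per-node face areas (full, scheme-consistent) and cell volume
        self.Ax = self.dy * self.dz
        self.Ay = self.dx * self.dz
        self.Az = self.dx * self.dy
        self.cell_heat = m.density_kg_m3 * m.heat_capacity_J_kgK * \
            self.dx * self.dy * self.dz  # J/K per node

        # trapezoid weights for surface aggregation
        wx = np.ones(g.Nx); wx[0] = wx[-1] = 0.5
        wy = np.ones(g.Ny); wy[0] = wy[-1] = 0.5
        wz = np.ones(g.Nz - 1); wz[0] = wz[-1] = 0.5  # iz = 1 .. Nz-1
        self._w_top = np.outer(wx, wy)
        self._w_top_sum = self._w_top.sum()
        self._wy_z = np.outer(wy, wz) * self.dy * self.dz   # x-faces
        self._wx_z = np.outer(wx, wz) * self.dx * self.dz   # y-faces
        self._w_side_sum = 2.0 * self._wy_z.sum() + 2.0 * self._wx_z.sum()

        self.energy = EnergyAudit()
        self._H0 = self.cell_heat * float(self.I[:, :, 1:].sum())
        self.min_seen = float(self.I.min())
        self.max_seen = float(self.I.max())

    def _set_ghosts(self) -> None:
        P, I = self.P, self.I
        Tinf = self.Tinf
        P[0, 1:-1, 1:-1] = I[1, :, :] - self.gx * (I[0, :, :] - Tinf)
        P[-1, 1:-1, 1:-1] = I[-2, :, :] - self.gx * (I[-1, :, :] - Tinf)
        P[1:-1, 0, 1:-1] = I[:, 1, :] - self.gy * (I[:, 0, :] - Tinf)
        P[1:-1, -1, 1:-1] = I[:, -2, :] - self.gy * (I[:, -1, :] - Tinf)
        P[1:-1, 1:-1, -1] = I[:, :, -2] - self.gz * (I[:, :, -1] - Tinf)
        P[1:-1, 1:-1, 0] = I[:, :, 1]  # below the Dirichlet plane; plane is reset

    def _account_fluxes(self) -> None:
        """Accumulate the stencil's own boundary fluxes for the pre-step field."""
        I, dt = self.I, self.cfg.dt_s
        k, h, Tinf = self.k, self.h, self.Tinf
        base_W = k * self.Az / self.dz * float((self.base_T - I[:, :, 1]).sum())

        def ghost_out(T_b: np.ndarray, T_in: np.ndarray, A: float, d: float) -> float:
            return float((2.0 * h * (T_b - Tinf) - k * (T_in - T_b) / d).sum()) * A

        out_W = (
            ghost_out(I[0, :, 1:], I[1, :, 1:], self.Ax, self.dx)
            + ghost_out(I[-1, :, 1:], I[-2, :, 1:], self.Ax, self.dx)
            + ghost_out(I[:, 0, 1:], I[:, 1, 1:], self.Ay, self.dy)
            + ghost_out(I[:, -1, 1:], I[:, -2, 1:], self.Ay, self.dy)
            + ghost_out(I[:, :, -1], I[:, :, -2], self.Az, self.dz)
        )
        self.energy.base_in_J += base_W * dt
        self.energy.robin_out_J += out_W * dt

    def step(self) -> None:
        self._account_fluxes()
        self._set_ghosts()
        P, I = self.P, self.I
        lap = self.cx * (P[2:, 1:-1, 1:-1] - 2.0 * I + P[:-2, 1:-1, 1:-1])
        lap += self.cy * (P[1:-1, 2:, 1:-1] - 2.0 * I + P[1:-1, :-2, 1:-1])
        lap += self.cz * (P[1:-1, 1:-1, 2:] - 2.0 * I + P[1:-1, 1:-1, :-2])
        np.add(I, lap, out=self.new)
        I[...] = self.new
        if self.cfg.robin_order == 1:
            self._first_order_robin()
        I[:, :, 0] = self.base_T
        self.min_seen = min(self.min_seen, float(I.min()))
        self.max_seen = max(self.max_seen, float(I.max()))

    def _first_order_robin(self) -> None:
        """Quasi-steady one-sided surface balance (optional lower-order mode)."""
        I = self.I
        for d, (face, inner) in zip(
            (self.dx, self.dx, self.dy, self.dy, self.dz),
            (
                ((0, Ellipsis), (1, Ellipsis)),
                ((-1, Ellipsis), (-2, Ellipsis)),
                ((slice(None), 0), (slice(None), 1)),
                ((slice(None), -1), (slice(None), -2)),
                ((Ellipsis, -1), (Ellipsis, -2)),
            ),
        ):
            a = self.k / d
            I[face] = (a * I[inner] + self.h * self.Tinf) / (a + self.h)

    def surface_means(self) -> tuple[float, float]:
        """Area-weighted mean top and side temperatures.

        Sides exclude the base-contact row (iz = 0), which is pinned to the
        platform temperature rather than exposed to air.
        """
        I = self.I
        t_upper = float((I[:, :, -1] * self._w_top).sum() / self._w_top_sum)
        side = (
            (I[0, :, 1:] * self._wy_z).sum()
            + (I[-1, :, 1:] * self._wy_z).sum()
            + (I[:, 0, 1:] * self._wx_z).sum()
            + (I[:, -1, 1:] * self._wx_z).sum()
        )
        t_side = float(side / self._w_side_sum)
        return t_upper, t_side

    def close_energy(self) -> None:
        H1 = self.cell_heat * float(self.I[:, :, 1:].sum())
        self.energy.enthalpy_change_J = H1 - self._H0


def step_field(
    field: ThermalField, config: PrintSimConfig, base_temperature_C: float | None = None
) -> ThermalField:
    """One FTCS update of a field; returns a new ThermalField.

    Convenience wrapper over the internal stepper; ``solve_layer`` should be
    used for whole-layer runs.
    """
    rep = stability_check(config)
    if not rep.passed and not config.override_stability:
        raise StabilityError(
            f"r = {rep.r:.3g} exceeds {rep.limit}; shrink dt or set override_stability"
        )
    base = config.boundaries.base_temperature_C if base_temperature_C is None \
        else base_temperature_C
    st = _Stepper(config, base, field.temperatures_C)
    st.step()
    return ThermalField(st.I.copy(), field.time_s + config.dt_s)


def solve_layer(
    config: PrintSimConfig,
    duration_s: float | None = None,
    initial: ThermalField | float | None = None,
    base_temperature_C: float | None = None,
    layer_index: int = 1,
) -> LayerThermalHistory:
    """Advance one layer for its duration, recording surface temperatures.

    ``initial`` may be a ThermalField, a uniform temperature, or None (uses
    the configured nozzle-exit temperature T0).  ``base_temperature_C``
    overrides the platform temperature — used for the layer-to-layer handoff.
    """
    g, b = config.geometry, config.boundaries
    duration = config.layer_duration_s if duration_s is None else duration_s
    if duration < 0:
        raise ConfigError("duration must be >= 0")
    rep = stability_check(config)
    if not rep.passed:
        if not config.override_stability:
            raise StabilityError(
                f"r = {rep.r:.3g} exceeds {rep.limit}; shrink dt or set "
                "override_stability=True"
            )
        logger.warning("running with violated stability bound r = %.3g", rep.r)

    if initial is None:
        init = np.full((g.Nx, g.Ny, g.Nz), float(b.initial_temperature_C))
    elif isinstance(initial, ThermalField):
        init = initial.temperatures_C
    else:
        init = np.full((g.Nx, g.Ny, g.Nz), float(initial))
    base = b.base_temperature_C if base_temperature_C is None else base_temperature_C

    st = _Stepper(config, base, init)
    n_steps = int(round(duration / config.dt_s))
    stride = max(1, int(round(config.output_stride_s / config.dt_s)))

    times, uppers, sides = [], [], []

    def record(t: float) -> None:
        tu, ts = st.surface_means()
        times.append(t)
        uppers.append(tu)
        sides.append(ts)

    record(0.0)
    for n in range(1, n_steps + 1):
        st.step()
        if n % stride == 0 or n == n_steps:
            record(n * config.dt_s)
    st.close_energy()

    return LayerThermalHistory(
        layer_index=layer_index,
        times_s=np.asarray(times),
        t_upper_C=np.asarray(uppers),
        t_side_C=np.asarray(sides),
        final_field=ThermalField(st.I.copy(), n_steps * config.dt_s),
        base_temperature_C=base,
        energy=st.energy,
        observed_min_C=st.min_seen,
        observed_max_C=st.max_seen,
    )


def simulate_print(config: PrintSimConfig) -> list[LayerThermalHistory]:
    """Layer-by-layer print simulation with base-temperature handoff.

    Layer 1 starts uniform at T0 on the platform (base at Tp); each later
    layer starts uniform at T0 on its own slab-thick grid with the base held
    at the previous layer's final mean top-surface temperature.
    """
    histories: list[LayerThermalHistory] = []
    base = config.boundaries.base_temperature_C
    for j in range(1, config.n_layers + 1):
        hist = solve_layer(config, base_temperature_C=base, layer_index=j)
        histories.append(hist)
        base = hist.final_t_upper_C
    return histories


def analytic_slab_solution(
    z_m,
    t_s: float,
    Lz_m: float,
    diffusivity_m2_s: float,
    base_temperature_C: float,
    initial_temperature_C: float,
    n_terms: int = 100,
):
    """Fourier-series solution of the 1D slab: base fixed at Tp, top insulated.

    T(z, t) = Tp + (T0 - Tp) * sum_k (4 / ((2k+1) pi))
              sin((2k+1) pi z / (2 Lz)) exp(-alpha ((2k+1) pi / (2 Lz))^2 t)

    Valid for 0 <= z <= Lz; used as the independent oracle for the 3D solver
    with lateral/top convection switched off.
    """
    if n_terms < 1:
        raise ValueError("need at least one series term")
    z = np.asarray(z_m, dtype=float)
    if np.any(z < 0) or np.any(z > Lz_m):
        raise ValueError("z outside [0, Lz]")
    n = np.arange(n_terms)
    lam = (2 * n + 1) * math.pi / (2.0 * Lz_m)          # (n_terms,)
    amp = 4.0 / ((2 * n + 1) * math.pi)
    decay = np.exp(-diffusivity_m2_s * lam**2 * t_s)
    series = (amp * decay * np.sin(np.outer(z, lam))).sum(axis=-1)
    out = base_temperature_C + (initial_temperature_C - base_temperature_C) * series
    return float(out[0]) if np.ndim(z_m) == 0 else out
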