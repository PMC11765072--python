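import numpy as np
import pytest
from hypothesis import settings

import oleoprint as op
from oleoprint.io import load_packaged_scenario

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def packaged_scenario():
    return load_packaged_scenario()


@pytest.fixture(scope="session")
def full_print_runs(packaged_scenario):
    """Layer-by-layer cooling runs at all four extrusion speeds of the
    packaged reference scenario (7 layers each).  Computed once per session;
    this is the expensive simulation shared by the thermal acceptance
    checks."""
    return {
        v: op.simulate_print(cfg)
        for v, cfg in sorted(packaged_scenario.configs.items())
    }


@pytest.fixture()
def small_sim_config():
    """A light-weight thermal config for fast unit tests."""
    return op.PrintSimConfig(
        geometry=op.LayerGeometry(0.01, 0.01, 0.001, Nx=6, Ny=6, Nz=5),
        material=op.MaterialThermalProps(0.16, 880.0, 2400.0),
        boundaries=op.BoundaryConditions(8.5, 22.1, 2.0, 79.7),
        layer_duration_s=5.0,
        n_layers=2,
        dt_s=0.01,
        output_stride_s=1.0,
    )


@pytest.fixture()
def m20_sweep():
    """Noise-free synthetic sweep mimicking the optimal formulation."""
    return op.generate_sweep(op.SWEEP_PRESETS["M20"])


def exponential_sweep(t_cross=80.0):
    """Sweep with G' = exp(t_cross - T), G'' = 1: log-linear interpolation of
    the crossover is exact, Tg = t_cross."""
    temps = np.arange(90.0, 69.0, -1.0)
    return op.RheologySweep(
        sample_id="exp",
        temperature_C=temps,
        g_prime_Pa=np.exp(t_cross - temps),
        g_double_prime_Pa=np.ones_like(temps),
    )
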