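"""Gelation-temperature extraction, gel classification, viscosity interpolation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oleoprint as op
from oleoprint.errors import (
    DomainError,
    MalformedSweepError,
    NoCrossingError,
    OutOfRangeError,
)
from oleoprint.rheology import loss_factor_at

from conftest import exponential_sweep


class TestFindGelationTemperature:
    def test_exact_for_exponential_moduli(self):
        # log-linear interpolation is exact when G' is exponential in T
        res = op.find_gelation_temperature(exponential_sweep(80.0))
        assert res.tg_C == pytest.approx(80.0, abs=1e-12)
        lo = min(r[0] for r in res.bracketing_rows)
        hi = max(r[0] for r in res.bracketing_rows)
        assert lo <= res.tg_C <= hi

    def test_no_crossing_raises(self):
        temps = np.array([90.0, 80.0, 70.0])
        gpp = np.array([1.0, 2.0, 3.0])
        sweep = op.RheologySweep("x", temps, 2.0 * gpp, gpp)
        with pytest.raises(NoCrossingError):
            op.find_gelation_temperature(sweep)

    def test_non_monotone_temperatures_rejected(self):
        with pytest.raises(MalformedSweepError):
            op.RheologySweep("x", [90.0, 70.0, 80.0], [1, 1, 1], [2, 2, 2])

    def test_recovers_pinned_crossover_within_tolerance(self):
        # bisection on the generator's exact tan(delta) is the oracle
        params = op.SweepGeneratorParams(target_tg_C=78.37, sampling_step_C=0.5)
        sweep = op.generate_sweep(params)
        res = op.find_gelation_temperature(sweep)

        lo, hi = 70.0, 90.0
        f = lambda t: math.log(float(params.true_tan_delta(t)))
        assert f(lo) < 0 < f(hi)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        oracle_tg = 0.5 * (lo + hi)
        assert oracle_tg == pytest.approx(78.37, abs=1e-9)
        assert abs(res.tg_C - oracle_tg) < 0.1

    def test_multiple_crossings_returns_highest_and_records_all(self):
        # tan(delta) dips below 1 twice on the way down
        temps = np.array([90.0, 80.0, 70.0, 60.0, 50.0])
        gp = np.ones(5)
        gpp = np.array([2.0, 0.5, 2.0, 0.5, 0.25])
        res = op.find_gelation_temperature(op.RheologySweep("w", temps, gp, gpp))
        assert len(res.crossings_C) == 3
        assert res.tg_C == max(res.crossings_C)
        assert 80.0 <= res.tg_C <= 90.0

    @given(scale=st.floats(1e-6, 1e6))
    def test_invariant_to_uniform_modulus_rescaling(self, scale):
        sweep = exponential_sweep(80.0)
        scaled = op.RheologySweep(
            "s",
            sweep.temperature_C,
            sweep.g_prime_Pa * scale,
            sweep.g_double_prime_Pa * scale,
        )
        a = op.find_gelation_temperature(sweep).tg_C
        b = op.find_gelation_temperature(scaled).tg_C
        assert b == pytest.approx(a, rel=1e-9)

    def test_row_reversal_gives_same_tg(self, m20_sweep):
        a = op.find_gelation_temperature(m20_sweep).tg_C
        b = op.find_gelation_temperature(m20_sweep.reversed()).tg_C
        assert b == pytest.approx(a, abs=1e-9)

    def test_error_shrinks_with_sampling_density(self):
        errs = []
        for step in (2.0, 1.0, 0.5):
            params = op.SweepGeneratorParams(target_tg_C=78.37, sampling_step_C=step)
            res = op.find_gelation_temperature(op.generate_sweep(params))
            errs.append(abs(res.tg_C - 78.37))
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] < 0.1


class TestLossFactorAndClassification:
    @pytest.mark.parametrize(
        "gp,gpp,expected", [(1.0, 0.255, 0.255), (2.0, 2.0, 1.0), (1e6, 2.4e4, 0.024)]
    )
    def test_loss_factor_definition(self, gp, gpp, expected):
        assert op.loss_factor(gp, gpp) == pytest.approx(expected)

    def test_loss_factor_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            op.loss_factor(-1.0, 1.0)
        with pytest.raises(DomainError):
            op.loss_factor(1.0, 0.0)

    @pytest.mark.parametrize(
        "td,expected",
        [
            (0.255, op.GelClassValue.WEAK_GEL),       # weak gel, tan(delta)=0.255
            (0.024, op.GelClassValue.STRONG_GEL),     # strong gel, tan(delta)=0.024
            (1.0, op.GelClassValue.VISCOUS_LIQUID),   # boundary tan(delta) >= 1
            (0.1, op.GelClassValue.WEAK_GEL),         # boundary 0.1 closed upward
        ],
    )
    def test_classification_thresholds(self, td, expected):
        assert op.classify_gel(td).value == expected

    @given(td=st.floats(1e-12, 1e12))
    def test_classification_partitions_positive_reals(self, td):
        cls = op.classify_gel(td)
        assert cls.value in set(op.GelClassValue)
        n_matches = sum(
            [td < 0.1, 0.1 <= td < 1.0, td >= 1.0]
        )
        assert n_matches == 1

    def test_classify_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            op.classify_gel(0.0)

    def test_tan_delta_read_at_nearest_row_to_5C(self, m20_sweep):
        td = loss_factor_at(m20_sweep)  # defaults to 5 deg C
        i = np.argmin(np.abs(m20_sweep.temperature_C - 5.0))
        assert td == m20_sweep.g_double_prime_Pa[i] / m20_sweep.g_prime_Pa[i]
        assert op.classify_gel(td).value == op.GelClassValue.STRONG_GEL


class TestInterpolateViscosity:
    @pytest.fixture()
    def two_constant_curves(self):
        sr = np.array([0.01, 0.1, 1.0, 10.0, 100.0])
        return op.FlowCurveSet(
            "c",
            {
                60.0: (sr, np.full(5, 0.01)),
                80.0: (sr, np.full(5, 0.04)),
            },
        )

    def test_grid_points_are_bit_exact(self, two_constant_curves):
        assert op.interpolate_viscosity(two_constant_curves, 60.0, 1.0) == 0.01
        assert op.interpolate_viscosity(two_constant_curves, 80.0, 100.0) == 0.04

    def test_midpoint_is_geometric_mean_in_log_space(self, two_constant_curves):
        mu = op.interpolate_viscosity(two_constant_curves, 70.0, 1.0)
        assert mu == pytest.approx(0.02, rel=1e-12)

    def test_power_law_recovered_off_grid(self):
        params = op.FlowGeneratorParams(
            consistency_prefactor_Pa_sn=5e-7,
            flow_index_n=0.6,
            activation_scale_K=3300.0,
        )
        fc = op.generate_flow_curves(params)
        rng = np.random.default_rng(11)
        for _ in range(50):
            t = rng.uniform(60.0, 90.0)
            sr = 10 ** rng.uniform(-2, 2)
            mu = op.interpolate_viscosity(fc, t, sr)
            assert mu == pytest.approx(float(params.true_viscosity(sr, t)), rel=0.02)

    def test_monotone_between_grid_points(self):
        sr = np.array([0.01, 0.1, 1.0, 10.0, 100.0])
        mu60 = np.array([5.0, 2.0, 1.0, 0.5, 0.2])
        mu80 = mu60 / 4.0
        fc = op.FlowCurveSet("m", {60.0: (sr, mu60), 80.0: (sr, mu80)})
        # decreasing in shear rate at fixed T
        q = [op.interpolate_viscosity(fc, 70.0, s) for s in np.logspace(-2, 2, 33)]
        assert np.all(np.diff(q) < 0)
        # decreasing in T at fixed shear rate
        q = [op.interpolate_viscosity(fc, t, 3.0) for t in np.linspace(60, 80, 21)]
        assert np.all(np.diff(q) < 0)

    def test_out_of_range_raises_unless_flagged(self, two_constant_curves):
        with pytest.raises(OutOfRangeError):
            op.interpolate_viscosity(two_constant_curves, 95.0, 1.0)
        with pytest.raises(OutOfRangeError):
            op.interpolate_viscosity(two_constant_curves, 70.0, 1000.0)
        # flagged: linear extension, still positive and finite
        mu = op.interpolate_viscosity(
            two_constant_curves, 95.0, 1.0, allow_extrapolation=True
        )
        assert math.isfinite(mu) and mu > 0
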