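"""Bloch-McConnell propagation: exact solver vs oracles and physical limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cestmrf.physics import (GAMMA_HZ_PER_UT, InvalidParameterError,
                             MagnetizationState, PoolParameters,
                             TissueParameters, apply_semisolid_lineshape,
                             normalize_trajectory, propagate_interval,
                             propagate_interval_rk4, simulate_schedule,
                             simulate_trajectories, superlorentzian_lineshape)


def _single_pool(t1=2.5, t2=0.8):
    return TissueParameters(
        water=PoolParameters(t1=t1, t2=t2),
        solute=PoolParameters(t1=1.0, t2=0.04, chemical_shift=3.0,
                              exchange_rate=400.0, volume_fraction=0.0))


class TestPropagateInterval:
    def test_equilibrium_is_stationary(self, larg_tissue):
        state = MagnetizationState.equilibrium(larg_tissue)
        out = propagate_interval(state, larg_tissue, 0.0, 3.0, 1.7)
        np.testing.assert_allclose(out.as_vector(), state.as_vector(),
                                   atol=1e-12)

    def test_free_relaxation_closed_form(self):
        """b1 = 0 on a decoupled water pool follows the analytic solution."""
        tissue = _single_pool()
        mxy0, mz0, t = 0.3, 0.5, 0.7
        state = MagnetizationState(np.array([mxy0, 0.0, mz0]), np.zeros(3))
        out = propagate_interval(state, tissue, 0.0, 3.0, t)
        assert out.water_xyz[2] == pytest.approx(
            1 - (1 - mz0) * math.exp(-t / 2.5), rel=1e-12)
        # transverse decays as exp(-t/T2) regardless of precession phase
        assert np.hypot(*out.water_xyz[:2]) == pytest.approx(
            mxy0 * math.exp(-t / 0.8), rel=1e-12)

    def test_matches_rk4_oracle_one_pulse(self, larg_tissue):
        state = MagnetizationState.equilibrium(larg_tissue)
        a = propagate_interval(state, larg_tissue, 2.0, 3.0, 0.1)
        b = propagate_interval_rk4(state, larg_tissue, 2.0, 3.0, 0.1,
                                   max_step=1e-5)
        err = np.abs(a.water_xyz[2] - b.water_xyz[2]) / abs(b.water_xyz[2])
        assert err <= 1e-6

    def test_fast_rk4_equals_literal_stepping(self, larg_tissue):
        """The matrix-power RK4 form is the literal four-stage loop."""
        state = MagnetizationState.equilibrium(larg_tissue)
        lit = propagate_interval_rk4(state, larg_tissue, 2.0, 3.0, 0.1,
                                     max_step=1e-4, literal=True)
        fast = propagate_interval_rk4(state, larg_tissue, 2.0, 3.0, 0.1,
                                      max_step=1e-4, literal=False)
        np.testing.assert_allclose(lit.as_vector(), fast.as_vector(),
                                   rtol=0, atol=1e-12)

    def test_contract_errors(self, larg_tissue):
        state = MagnetizationState.equilibrium(larg_tissue)
        with pytest.raises(ValueError):
            propagate_interval(state, larg_tissue, 2.0, 3.0, -0.1)
        with pytest.raises((InvalidParameterError, ValueError)):
            propagate_interval(state, larg_tissue, math.nan, 3.0, 0.1)
        with pytest.raises(InvalidParameterError):
            PoolParameters(t1=-1.0, t2=0.1)
        with pytest.raises(InvalidParameterError):
            PoolParameters(t1=1.0, t2=0.1, volume_fraction=1.5)


class TestLineshapes:
    def test_zero_b1_gives_zero_rate(self):
        pool = PoolParameters(t1=1.0, t2=1e-5, lineshape="lorentzian")
        assert apply_semisolid_lineshape(pool, 0.0, 10.0) == 0.0

    def test_lorentzian_peak_value(self):
        """On resonance the rate is omega1^2 * T2s."""
        t2s = 1e-5
        pool = PoolParameters(t1=1.0, t2=t2s, lineshape="lorentzian")
        b1 = 2.0
        omega1 = 2 * math.pi * GAMMA_HZ_PER_UT * b1
        assert apply_semisolid_lineshape(pool, b1, 0.0) == pytest.approx(
            omega1 ** 2 * t2s, rel=1e-12)

    def test_superlorentzian_matches_quadrature(self):
        """Fiber-angle integral at 10 ppm vs adaptive scipy quadrature."""
        t2s, b1, offset = 1e-5, 2.0, 10.0
        dw = 2 * math.pi * GAMMA_HZ_PER_UT * 3.0 * offset

        def integrand(theta):
            u = abs(3 * math.cos(theta) ** 2 - 1)
            return (math.sin(theta) * math.sqrt(2 / math.pi) * (t2s / u)
                    * math.exp(-2 * (dw * t2s / u) ** 2))

        expected, _ = quad(integrand, 0, math.pi / 2, limit=200)
        got = superlorentzian_lineshape(dw, t2s)
        assert got == pytest.approx(expected, rel=1e-4)

    def test_unknown_lineshape_rejected(self):
        with pytest.raises(InvalidParameterError):
            PoolParameters(t1=1.0, t2=1e-5, lineshape="gaussian")
        pool = PoolParameters(t1=1.0, t2=1e-5)
        with pytest.raises(InvalidParameterError):
            apply_semisolid_lineshape(pool, 1.0, 5.0)


class TestSimulateSchedule:
    def test_zero_power_entry_from_equilibrium(self):
        from cestmrf.schedule import AcquisitionSchedule, ScheduleEntry
        sched = AcquisitionSchedule([ScheduleEntry(sat_power=0.0,
                                                   sat_offset=3.0)])
        sig = simulate_schedule(_single_pool(), sched)
        assert sig[0] == pytest.approx(math.sin(math.radians(15.0)), rel=1e-12)

    def test_decoupled_pool_limit(self, schedule30):
        """f_s = 0 reproduces the pure single-pool water trajectory."""
        base = dict(t1w=2.5, t2w=0.8, t1s=1.0, t2s=0.04, fs=0.0, ksw=400.0,
                    shift_ppm=3.0)
        two_pool = simulate_trajectories(
            {k: np.array([v]) for k, v in base.items()}, schedule30)
        single = simulate_trajectories(
            {k: np.array([v]) for k, v in {**base, "ksw": 0.0}.items()},
            schedule30)
        np.testing.assert_allclose(two_pool, single, rtol=0, atol=1e-10)

    def test_full_schedule_matches_rk4(self, larg_tissue, schedule30):
        sig = simulate_schedule(larg_tissue, schedule30)
        oracle = simulate_schedule(larg_tissue, schedule30, propagator="rk4",
                                   rk4_step=1e-5)
        assert np.max(np.abs(sig - oracle)) / np.max(np.abs(oracle)) <= 1e-5

    def test_batch_equals_scalar_path(self, larg_tissue, schedule6):
        sig = simulate_schedule(larg_tissue, schedule6)
        batch = simulate_trajectories(
            dict(t1w=np.array([2.5]), t2w=np.array([0.8]), t1s=np.array([1.0]),
                 t2s=np.array([0.04]), fs=np.array([1.35e-3]),
                 ksw=np.array([400.0]), shift_ppm=np.array([3.0])), schedule6)
        np.testing.assert_allclose(batch[0], sig, rtol=0, atol=1e-12)

    def test_z_monotone_in_volume_fraction(self, schedule6):
        """More exchangeable protons always means more saturation."""
        from cestmrf.schedule import AcquisitionSchedule, ScheduleEntry
        fs = np.linspace(1e-4, 1e-2, 12)
        for b1 in (1.0, 2.0, 3.0):
            sched = AcquisitionSchedule([ScheduleEntry(sat_power=b1,
                                                       sat_offset=3.0)])
            sig = simulate_trajectories(
                dict(t1w=2.5 * np.ones_like(fs), t2w=0.8 * np.ones_like(fs),
                     t1s=np.ones_like(fs), t2s=0.04 * np.ones_like(fs),
                     fs=fs, ksw=400.0 * np.ones_like(fs),
                     shift_ppm=3.0 * np.ones_like(fs)), sched)
            z = sig[:, 0] / math.sin(math.radians(15.0))
            assert np.all(np.diff(z) < 0)
            assert np.all((z >= -1) & (z <= 1))

    def test_trajectory_z_bounded(self, larg_tissue, schedule30):
        z = simulate_schedule(larg_tissue, schedule30) \
            / math.sin(math.radians(15.0))
        assert np.all((z >= -1) & (z <= 1))


class TestNormalizeTrajectory:
    def test_three_four_five(self):
        np.testing.assert_allclose(normalize_trajectory([3.0, 4.0]),
                                   [0.6, 0.8])

    def test_idempotent_on_unit_vectors(self):
        v = normalize_trajectory(np.array([1.0, 2.0, 2.0]))
        np.testing.assert_allclose(normalize_trajectory(v), v, atol=1e-15)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_trajectory(np.zeros(5))

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_unit_norm_property(self, seed):
        v = np.random.default_rng(seed).normal(size=17)
        assert np.linalg.norm(normalize_trajectory(v)) == pytest.approx(1.0)


class TestSemisolidMT:
    def _mt_tissue(self, fss=0.15, kssw=40.0):
        return TissueParameters(
            water=PoolParameters(t1=0.85, t2=0.07),
            solute=PoolParameters(t1=1.0, t2=1e-5, chemical_shift=0.0,
                                  exchange_rate=kssw, volume_fraction=fss,
                                  lineshape="lorentzian"))

    def test_batch_equals_scalar_path(self):
        from cestmrf.schedule import generate_pseudorandom_schedule
        sched = generate_pseudorandom_schedule(5, "mt_sweep", seed=11)
        tissue = self._mt_tissue()
        sig = simulate_schedule(tissue, sched)
        batch = simulate_trajectories(
            dict(t1w=np.array([0.85]), t2w=np.array([0.07]),
                 t1s=np.array([1.0]), t2s=np.array([1e-5]),
                 fs=np.array([0.15]), ksw=np.array([40.0]),
                 shift_ppm=np.array([0.0])), sched, lineshape="lorentzian")
        np.testing.assert_allclose(batch[0], sig, rtol=0, atol=1e-12)

    def test_mt_pool_attenuates_water(self):
        """A semisolid pool saturated off-resonance lowers the water signal."""
        from cestmrf.schedule import generate_pseudorandom_schedule
        sched = generate_pseudorandom_schedule(5, "mt_sweep", seed=11)
        with_mt = simulate_schedule(self._mt_tissue(), sched)
        without = simulate_schedule(self._mt_tissue(fss=1e-9), sched)
        assert np.all(with_mt < without)

    def test_matches_rk4_oracle(self):
        from cestmrf.schedule import generate_pseudorandom_schedule
        sched = generate_pseudorandom_schedule(5, "mt_sweep", seed=11)
        tissue = self._mt_tissue()
        sig = simulate_schedule(tissue, sched)
        oracle = simulate_schedule(tissue, sched, propagator="rk4",
                                   rk4_step=1e-5)
        assert np.max(np.abs(sig - oracle)) / np.max(np.abs(oracle)) <= 1e-5
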