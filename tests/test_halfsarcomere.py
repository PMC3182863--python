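"""Unit tests for single half-sarcomere mechanics and kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sarcsim as ss
from sarcsim.halfsarcomere import (AxisRangeError, InvalidInputError,
                                   StepSizeError, hs_kinetics_step)


# ---------------------------------------------------------------------------
# overlap and available heads
# ---------------------------------------------------------------------------

class TestOverlap:
    @pytest.mark.parametrize("length, expected", [
        (1210.0, 1.0),            # plateau
        (1296.0, 1.0),            # plateau
        (1700.0, 0.0),            # zero-overlap breakpoint
        (2000.0, 0.0),            # far beyond overlap
        (800.0, 0.0),             # ascending-limb foot
    ])
    def test_values(self, params, length, expected):
        assert ss.overlap_fraction(length, params.overlap) == expected

    def test_ascending_below_plateau(self, params):
        v = ss.overlap_fraction(1134.0, params.overlap)
        assert 0.0 < v < 1.0

    def test_continuity_at_breakpoints(self, params):
        for b in params.overlap.breakpoints:
            lo = ss.overlap_fraction(b - 1e-9, params.overlap)
            hi = ss.overlap_fraction(b + 1e-9, params.overlap)
            assert hi == pytest.approx(lo, abs=1e-8)

    def test_invalid_length(self, params):
        with pytest.raises(InvalidInputError):
            ss.overlap_fraction(float("nan"), params.overlap)
        with pytest.raises(InvalidInputError):
            ss.overlap_fraction(-5.0, params.overlap)


class TestAvailableHeads:
    def test_zero_activation(self, params):
        assert ss.n_available(1210.0, 0.0, params) == 0.0

    def test_plateau_full_activation(self, params):
        assert ss.n_available(1210.0, 1.0, params) == pytest.approx(1.15e17)

    def test_zeta_scaling(self, params):
        half = ss.n_available(1210.0, 1.0, params, zeta=0.5)
        assert half == pytest.approx(5.75e16)

    def test_activation_out_of_range(self, params):
        with pytest.raises(InvalidInputError):
            ss.n_available(1210.0, 1.5, params)


# ---------------------------------------------------------------------------
# passive force
# ---------------------------------------------------------------------------

class TestPassive:
    def test_zero_at_offset(self, params):
        assert ss.passive_force(params.passive_offset, params) == 0.0

    def test_xi_is_multiplier(self, params):
        f1 = ss.passive_force(1300.0, params, xi=1.0)
        f2 = ss.passive_force(1300.0, params, xi=2.0)
        assert f2 == pytest.approx(2.0 * f1)

    def test_strictly_increasing(self, params):
        lengths = np.linspace(400.0, 1700.0, 200)
        f = ss.passive_force(lengths, params)
        assert np.all(np.diff(f) > 0)
        assert ss.passive_force(1404.0, params) > ss.passive_force(
            1296.0, params)

    def test_stiffness_matches_slope(self, params):
        for L in (500.0, 900.0, 1404.0):
            fd = (ss.passive_force(L + 0.005, params)
                  - ss.passive_force(L - 0.005, params)) / 0.01
            assert ss.passive_stiffness(L, params) == pytest.approx(
                fd, rel=1e-5)


# ---------------------------------------------------------------------------
# active force
# ---------------------------------------------------------------------------

class TestActiveForce:
    def test_all_detached_is_zero(self, params):
        dist = ss.XbDistribution.all_detached(params.axis, 1e17)
        assert ss.active_force(dist, params) == 0.0

    def test_zero_strain_pre_powerstroke_bin(self, params):
        dist = ss.XbDistribution.all_detached(params.axis, 0.0)
        i0 = int(np.argmin(np.abs(params.axis.centers())))
        dist.a1[i0] = 5e15
        assert ss.active_force(dist, params) == 0.0

    def test_symmetric_a2_occupancy(self, params):
        # strain terms cancel; force reduces to k_cb * x_ps * total a2
        dist = ss.XbDistribution.all_detached(params.axis, 0.0)
        dist.a2[:] = 3e14
        expected = params.k_cb * params.x_ps * dist.a2.sum()
        assert ss.active_force(dist, params) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_axis_mismatch_raises(self, params):
        from sarcsim.halfsarcomere import StructureError
        bad = ss.XbDistribution(a1=np.zeros(10), a2=np.zeros(10), d=0.0)
        with pytest.raises(StructureError):
            ss.active_force(bad, params)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _rates(**kw):
    base = dict(f0=0.0, sigma_f=1.0, k3_0=0.0, x_k3=1.0, k_minus3=0.0,
                g_a1=0.0, g0=0.0, g_det=0.0, x_det=6.0, g_slip=0.0,
                x_slip=-0.3, w_slip=0.3, g_cap=900.0, x_ps=10.0)
    base.update(kw)
    return ss.RateLaws(**base)


class TestKinetics:
    def test_zero_rates_identity(self, params):
        tb = _rates().tables(params.axis)
        dist = ss.XbDistribution.all_detached(params.axis, 1e17)
        dist.a1[:] = 1e14
        out = ss.kinetics_step(dist, 1e-3, tb)
        np.testing.assert_allclose(out.a1, dist.a1)
        assert out.d == pytest.approx(dist.d)

    def test_exponential_decay_oracle(self, params):
        # only A2 -> D at constant rate g: total a2 decays as e^{-g t}
        g, dt, t_end = 10.0, 2.5e-4, 0.5
        tb = _rates(g0=g).tables(params.axis)
        dist = ss.XbDistribution.all_detached(params.axis, 0.0)
        dist.a2[:] = 1e15
        n0 = dist.a2.sum()
        n = int(round(t_end / dt))
        for _ in range(n):
            dist = ss.kinetics_step(dist, dt, tb)
        # exact discrete limit ...
        assert dist.a2.sum() == pytest.approx(n0 * (1 - g * dt) ** n,
                                              rel=1e-9)
        # ... approaching the continuous exponential
        assert dist.a2.sum() == pytest.approx(n0 * np.exp(-g * t_end),
                                              rel=0.01)

    def test_steady_state_unique_and_matches_closed_form(self, params):
        tb = params.rates.tables(params.axis)
        n = ss.n_available(1210.0, 1.0, params)
        forces = []
        for init in ("detached", "bound"):
            dist = ss.XbDistribution.all_detached(params.axis, n)
            if init == "bound":
                dist.a1[:] = n / (3 * params.axis.n_bins)
                dist.a2[:] = n / (3 * params.axis.n_bins)
                dist.d = n - dist.total_bound()
            prev = None
            for _ in range(12000):
                dist = ss.kinetics_step(dist, 1e-3, tb)
            forces.append(ss.active_force(dist, params))
        assert forces[0] == pytest.approx(forces[1], rel=1e-3)
        analytic = ss.isometric_steady_state(params, 1210.0)
        assert forces[0] == pytest.approx(ss.active_force(analytic, params),
                                          rel=1e-3)

    def test_stability_guard(self, params):
        tb = params.rates.tables(params.axis)
        with pytest.raises(StepSizeError):
            ss.kinetics_step(ss.XbDistribution.all_detached(params.axis, 1.0),
                             1.0, tb)

    def test_pool_rescale_proportional(self, params):
        dist = ss.XbDistribution.all_detached(params.axis, 0.0)
        dist.a1[:] = 1e14
        dist.a2[:] = 2e14
        dist.d = 1e16
        tot = dist.total()
        out = ss.set_available(dist, 0.5 * tot)
        assert out.total() == pytest.approx(0.5 * tot, rel=1e-12)
        np.testing.assert_allclose(out.a1, 0.5 * dist.a1)

    def test_available_pool_follows_activation(self, params):
        st = ss.HalfSarcomereState(length=1210.0,
                                   dist=ss.XbDistribution.all_detached(
                                       params.axis, 0.0))
        out = hs_kinetics_step(st, 0.5, 1e-3, params)
        assert out.total() == pytest.approx(0.5 * 1.15e17, rel=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10 ** 6), dt=st.floats(1e-4, 1e-3))
def test_kinetics_mass_conservation_property(seed, dt):
    """Total head count is invariant under the kinetic exchange."""
    params = ss.HalfSarcomereParams()
    rng = np.random.default_rng(seed)
    tb = params.rates.tables(params.axis)
    B = params.axis.n_bins
    dist = ss.XbDistribution(a1=rng.uniform(0, 1e15, B),
                             a2=rng.uniform(0, 1e15, B),
                             d=float(rng.uniform(0, 1e17)))
    tot0 = dist.total()
    for _ in range(5):
        dist = ss.kinetics_step(dist, dt, tb)
    assert dist.total() == pytest.approx(tot0, rel=1e-9)
    assert np.all(dist.a1 >= 0) and np.all(dist.a2 >= 0)


# ---------------------------------------------------------------------------
# strain advection
# ---------------------------------------------------------------------------

class TestShift:
    def test_zero_shift_identity(self, params):
        dist = ss.XbDistribution.all_detached(params.axis, 1e16)
        dist.a1[:] = np.linspace(0, 1e15, params.axis.n_bins)
        out = ss.shift_distribution(dist, 0.0, params.axis)
        np.testing.assert_allclose(out.a1, dist.a1)

    def test_exact_one_bin_translation(self, params):
        axis = params.axis
        dist = ss.XbDistribution.all_detached(axis, 0.0)
        i0 = axis.n_bins // 2
        dist.a2[i0] = 7e14
        out = ss.shift_distribution(dist, axis.bin_width, axis)
        assert out.a2[i0 + 1] == pytest.approx(7e14, rel=1e-12)
        assert out.total_bound() == pytest.approx(7e14, rel=1e-12)

    def test_gaussian_round_trip(self, params):
        """Shift +h then -h: mass conserved exactly; profile blurred by
        no more than the interpolation-diffusion bound."""
        axis = params.axis
        x = axis.centers()
        prof = 1e15 * np.exp(-0.5 * ((x - 1.0) / 1.5) ** 2)
        dist = ss.XbDistribution(a1=prof.copy(), a2=np.zeros_like(prof),
                                 d=0.0)
        h = 0.3 * axis.bin_width
        out = ss.shift_distribution(dist, h, axis)
        out = ss.shift_distribution(out, -h, axis)
        assert out.total_bound() == pytest.approx(prof.sum(), rel=1e-9)
        # first moment restored exactly by the conservative interpolation
        assert (out.a1 @ x) == pytest.approx(prof @ x, rel=1e-9)
        l2 = np.linalg.norm(out.a1 - prof) / np.linalg.norm(prof)
        assert l2 < 0.05

    def test_first_moment_advected_exactly(self, params):
        axis = params.axis
        x = axis.centers()
        rng = np.random.default_rng(3)
        prof = rng.uniform(0, 1e15, axis.n_bins)
        prof[:8] = prof[-8:] = 0.0
        dist = ss.XbDistribution(a1=prof, a2=np.zeros_like(prof), d=0.0)
        delta = 0.77
        out = ss.shift_distribution(dist, delta, axis)
        m0, m1 = prof.sum(), prof @ x
        assert (out.a1 @ x) == pytest.approx(m1 + delta * m0, rel=1e-12)

    def test_oversized_shift_raises(self, params):
        dist = ss.XbDistribution.all_detached(params.axis, 1e16)
        with pytest.raises(AxisRangeError):
            ss.shift_distribution(dist, 13.0, params.axis)

    def test_mass_leaving_axis_rejected(self, params):
        axis = params.axis
        dist = ss.XbDistribution.all_detached(axis, 0.0)
        dist.a1[-1] = 1e15  # at the +x boundary
        with pytest.raises(AxisRangeError):
            ss.shift_distribution(dist, 1.0, axis)


# ---------------------------------------------------------------------------
# stiffness
# ---------------------------------------------------------------------------

class TestStiffness:
    def test_matches_finite_difference(self, params):
        dist = ss.isometric_steady_state(params, 1250.0)
        st = ss.HalfSarcomereState(length=1250.0, dist=dist)
        k = ss.instantaneous_stiffness(st, params)
        h = 0.01
        up = ss.shift_distribution(dist, h, params.axis)
        dn = ss.shift_distribution(dist, -h, params.axis)
        f_up = ss.active_force(up, params) + ss.passive_force(1250.0 + h,
                                                              params)
        f_dn = ss.active_force(dn, params) + ss.passive_force(1250.0 - h,
                                                              params)
        assert k == pytest.approx((f_up - f_dn) / (2 * h), rel=1e-3)

    def test_linear_in_bound_population(self, params):
        dist = ss.isometric_steady_state(params, 1250.0)
        st1 = ss.HalfSarcomereState(length=1250.0, dist=dist)
        dbl = dist.copy()
        dbl.a1 *= 2
        dbl.a2 *= 2
        st2 = ss.HalfSarcomereState(length=1250.0, dist=dbl)
        pk = ss.passive_stiffness(1250.0, params)
        k1 = ss.instantaneous_stiffness(st1, params) - pk
        k2 = ss.instantaneous_stiffness(st2, params) - pk
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_positive_with_no_bound_heads(self, params):
        dist = ss.XbDistribution.all_detached(params.axis, 0.0)
        st = ss.HalfSarcomereState(length=500.0, dist=dist)
        assert ss.instantaneous_stiffness(st, params) > 0
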