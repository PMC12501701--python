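"""Closed-form relaxation model chain: identities, limits, cross-checks."""

import math

import numpy as np
import pytest

from mpfpsl import PulseTrainParams, RfSetting, analytic
from mpfpsl.params import TwoPoolParams


def random_pools(rng) -> TwoPoolParams:
    return TwoPoolParams(
        R1a=rng.uniform(0.5, 2.5),
        R2a=rng.uniform(10.0, 60.0),
        R1b=rng.uniform(0.5, 2.5),
        T2b=rng.uniform(5e-6, 12e-6),
        fb=rng.uniform(0.005, 0.2),
        kba=rng.uniform(15.0, 90.0),
        lineshape="gaussian",
    )


class TestRWater:
    def test_limits(self, liver):
        on_axis = RfSetting(omega1=0.0, delta=1.0)
        assert analytic.r_water(liver, on_axis) == pytest.approx(liver.R1a)
        transverse = RfSetting(omega1=1e9, delta=1e-3)
        assert analytic.r_water(liver, transverse) == pytest.approx(
            liver.R2a, rel=1e-6
        )

    def test_liver_low_rf_value(self, liver):
        rf = RfSetting.from_hz(100.0, 1000.0)
        # R1a*cos^2 + R2a*sin^2 at theta = atan(0.1)
        assert analytic.r_water(liver, rf) == pytest.approx(1.455, abs=1e-3)


class TestRMt:
    def test_no_pool_no_rate(self, free_water, rf_hi):
        assert analytic.r_mt(free_water, rf_hi) == 0.0

    def test_saturating_limit(self, liver):
        # Rrfb -> infinity: full semisolid saturation, the water pool loses
        # longitudinal magnetization at the forward exchange rate fb*kba
        strong = RfSetting(omega1=2e6, delta=2 * math.pi * 3500.0)
        assert analytic.r_mt(liver, strong) == pytest.approx(
            liver.fb * liver.kba, rel=1e-2
        )

    def test_pairwise_difference_identity(self, rf_lo, rf_hi):
        """Rmt(hi) - Rmt(lo) must equal the MT-difference closed form
        kba^2 fb (1+fb) [1/D_lo - 1/D_hi] exactly."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_pools(rng)
            r1, r2 = analytic.rrfb(p, rf_lo), analytic.rrfb(p, rf_hi)
            direct = analytic.r_mt(p, rf_hi) - analytic.r_mt(p, rf_lo)
            d1 = (1 + p.fb) * p.kba + r1
            d2 = (1 + p.fb) * p.kba + r2
            identity = p.kba**2 * p.fb * (1 + p.fb) * (1 / d1 - 1 / d2)
            assert direct == pytest.approx(identity, abs=1e-12)


class TestBetaTransient:
    def test_steady_state_limit(self, liver, rf_hi):
        rb = analytic.rrfb(liver, rf_hi)
        assert analytic.beta_transient(liver, rf_hi, 100.0) == pytest.approx(
            rb / (liver.kba + rb), rel=1e-12
        )

    def test_no_saturation_no_transfer(self, liver):
        off = RfSetting(omega1=0.0, delta=2 * math.pi * 3500.0)
        assert analytic.beta_transient(liver, off, 0.01) == 0.0

    def test_bounds(self, liver, rf_lo, rf_hi):
        for rf in (rf_lo, rf_hi):
            b = analytic.beta_transient(liver, rf, 0.01)
            assert 0.0 < b < 1.0


class TestFreePrecession:
    def test_biexp_boundary_values(self, liver):
        mza0, mzb0 = 0.4, 0.02
        assert analytic.mza_free_biexp(mza0, mzb0, liver, 0.0) == pytest.approx(mza0)
        assert analytic.mza_free_biexp(mza0, mzb0, liver, 100.0) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_biexp_undefined_without_pool(self, free_water):
        with pytest.raises(ValueError, match="mzb0"):
            analytic.mza_free_biexp(0.5, 0.01, free_water, 0.01)

    def test_reduced_matches_biexp_after_spin_lock(self, liver, rf_hi):
        """The per-gap reduction tracks the full bi-exponential recovery
        from post-spin-lock initial conditions once the transfer completes."""
        Tp, t = 0.01, 0.05
        beta = analytic.beta_transient(liver, rf_hi, Tp)
        mza0 = 0.8
        mzb0 = liver.fb * (1.0 - beta) * mza0
        full = analytic.mza_free_biexp(mza0, mzb0, liver, t)
        red = analytic.mza_free_reduced(mza0, liver, rf_hi, Tp, t)
        assert red == pytest.approx(full, rel=0.01)

    def test_transient_model_exact_at_zero_gap(self, liver, rf_hi):
        assert analytic.mza_free_transient(0.8, liver, rf_hi, 0.01, 0.0) == pytest.approx(0.8)

    def test_transient_model_reaches_reduced_form(self, liver, rf_hi):
        """Once the exchange transient has died out (t >> 1/kba) the
        transient-state and lumped per-gap models coincide."""
        t = 0.2
        a = analytic.mza_free_transient(0.8, liver, rf_hi, 0.01, t)
        b = analytic.mza_free_reduced(0.8, liver, rf_hi, 0.01, t)
        assert a == pytest.approx(b, abs=1e-3)

    def test_reduced_limits(self, liver, free_water, rf_hi):
        t = 0.05
        pure = 0.8 * math.exp(-free_water.R1a * t) + 1 - math.exp(-free_water.R1a * t)
        assert analytic.mza_free_reduced(0.8, free_water, rf_hi, 0.01, t) == pytest.approx(pure)
        # per-gap log-decrement consistent with the train's gap factor
        beta = analytic.beta_transient(liver, rf_hi, 0.01)
        gap = analytic.mza_free_reduced(1.0, liver, rf_hi, 0.01, t) - (
            1 - math.exp(-liver.R1a * t)
        )
        assert gap == pytest.approx(math.exp(-liver.fb * beta - liver.R1a * t))


class TestTrainMagnetization:
    def test_single_module_mono_exponential(self, liver, rf_hi):
        train = PulseTrainParams(0.05, 0.05, 1)
        r1rho = analytic.r1rho(liver, rf_hi)
        mss = analytic.mza_ss(liver, rf_hi)
        e = math.exp(-r1rho * train.Tp)
        for m0 in (1.0, -1.0, 0.3):
            expected = m0 * e + mss * (1 - e)
            assert analytic.train_magnetization(m0, liver, rf_hi, train) == pytest.approx(
                expected, abs=1e-14
            )

    def test_closed_form_equals_recursion(self, rf_lo, rf_hi):
        """Geometric-series closed form vs explicit recursion, random draws."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = random_pools(rng)
            rf = rf_lo if rng.random() < 0.5 else rf_hi
            train = PulseTrainParams(
                rng.uniform(0.002, 0.05), rng.uniform(0.01, 0.1), int(rng.integers(1, 25))
            )
            m0 = rng.uniform(-1.0, 1.0)
            closed = analytic.train_magnetization(m0, p, rf, train)
            recursive = analytic.train_magnetization_recursive(m0, p, rf, train)
            assert closed == pytest.approx(recursive, abs=1e-12)

    def test_long_train_reaches_fixed_point(self, liver, rf_hi):
        train = PulseTrainParams(0.01, 0.05, 4000)
        from mpfpsl.analytic import _train_constants

        *_, mss_b = _train_constants(liver, rf_hi, train)
        assert analytic.train_magnetization(1.0, liver, rf_hi, train) == pytest.approx(
            mss_b, abs=1e-12
        )


class TestR1RhoPul:
    def test_single_module_is_cw_rate(self, liver, rf_hi):
        train = PulseTrainParams(0.1, 0.0, 1)
        assert analytic.r1rho_pul(liver, rf_hi, train) == analytic.r1rho(liver, rf_hi)

    def test_water_only(self, free_water, rf_lo, train10):
        expected = analytic.r_water(free_water, rf_lo) + train10.idr * free_water.R1a
        assert analytic.r1rho_pul(free_water, rf_lo, train10) == pytest.approx(expected)

    def test_zero_gap_multi_module_rejected(self, liver, rf_hi):
        with pytest.raises(ValueError, match="Tf"):
            analytic.r1rho_pul(liver, rf_hi, PulseTrainParams(0.01, 0.0, 5))


class TestRmpfslPul:
    def test_no_pool_exactly_zero(self, free_water, pair_study1, train10):
        assert analytic.rmpfsl_pul(free_water, pair_study1, train10) == 0.0

    def test_equals_rate_difference(self, liver, pair_study1, train10):
        """The water terms cancel exactly (shared effective-field angle), so
        the closed form equals the difference of the two pulsed rates."""
        diff = analytic.r1rho_pul(liver, pair_study1.setting2, train10) - analytic.r1rho_pul(
            liver, pair_study1.setting1, train10
        )
        assert analytic.rmpfsl_pul(liver, pair_study1, train10) == pytest.approx(
            diff, abs=1e-12
        )

    def test_independent_of_water_parameters(self, liver, pair_study1, train10):
        base = analytic.rmpfsl_pul(liver, pair_study1, train10)
        perturbed = liver.with_(R1a=3.3, R2a=77.0)
        assert analytic.rmpfsl_pul(perturbed, pair_study1, train10) == base

    def test_positive_for_stronger_high_rf(self, liver, pair_study1, pair_fig4, train10):
        for pair in (pair_study1, pair_fig4):
            assert analytic.rmpfsl_pul(liver, pair, train10) > 0.0

    def test_near_linear_in_fb(self, liver, pair_study1, train10):
        fbs = np.linspace(0.01, 0.10, 10)
        ratios = [
            analytic.rmpfsl_pul(liver.with_(fb=f), pair_study1, train10) / f for f in fbs
        ]
        spread = (max(ratios) - min(ratios)) / np.mean(ratios)
        assert spread < 0.15

    def test_r1b_extension_reduces_to_base(self, liver, pair_study1, train10):
        base = analytic.rmpfsl_pul(liver, pair_study1, train10)
        assert analytic.rmpfsl_pul(liver, pair_study1, train10, r1b=0.0) == base
        assert analytic.rmpfsl_pul(liver, pair_study1, train10, r1b=3.0) != base


def test_decomposition_invariants(liver, rf_hi, train10):
    dec = analytic.decompose(liver, rf_hi, train10)
    assert dec.r1rho == pytest.approx(dec.r_water + dec.r_mt)
    assert dec.r1rho_pul == pytest.approx(
        dec.r1rho + train10.idr * liver.R1a + dec.free_precession_mt_term
    )
    assert all(
        v >= 0
        for v in (dec.r_water, dec.r_mt, dec.r1rho, dec.r1rho_pul, dec.free_precession_mt_term)
    )
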