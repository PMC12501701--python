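"""Bloch-McConnell simulator: structure, exactness, and model cross-checks."""

import math

import numpy as np
import pytest

from mpfpsl import PulseTrainParams, RfSetting, analytic, bm


class TestGeneratorStructure:
    def test_no_pool_decouples_semisolid(self, free_water, rf_hi):
        A, b = bm.cw_generator(free_water, rf_hi)
        assert A[2, 3] == 0.0 and A[3, 2] == 0.0 and b[3] == 0.0

    def test_free_precession_decouples_transverse(self, liver):
        A, _ = bm.free_generator(liver)
        assert np.all(A[:2, 2:] == 0.0) and np.all(A[2:, :2] == 0.0)

    def test_equilibrium_is_fixed_point_without_rf(self, liver):
        A, b = bm.free_generator(liver)
        eq = bm.equilibrium_state(liver.fb)
        assert np.allclose(A @ eq + b, 0.0, atol=1e-14)

    def test_no_cross_coupling_without_exchange_or_saturation(self):
        from mpfpsl.params import TwoPoolParams

        p = TwoPoolParams(R1a=1.0, R2a=20.0, R1b=1.0, T2b=8e-6, fb=0.05, kba=1e-9,
                          lineshape="gaussian")
        rf = RfSetting(omega1=0.0, delta=0.0)
        A, _ = bm.cw_generator(p, rf)
        assert abs(A[2, 3]) < 1e-7 and abs(A[3, 2]) < 1e-7


class TestPropagation:
    def test_zero_duration_is_identity(self, liver, rf_hi):
        gen = bm.cw_generator(liver, rf_hi)
        s = np.array([0.1, -0.2, 0.7, 0.03])
        assert np.allclose(bm.propagate(s, gen, 0.0), s, atol=1e-15)

    def test_semigroup_property(self, liver, rf_hi):
        gen = bm.cw_generator(liver, rf_hi)
        s = np.array([0.1, -0.2, 0.7, 0.03])
        whole = bm.propagate(s, gen, 0.02)
        halves = bm.propagate(bm.propagate(s, gen, 0.01), gen, 0.01)
        assert np.allclose(whole, halves, atol=1e-12)

    def test_single_pool_longitudinal_closed_form(self, free_water):
        gen = bm.cw_generator(free_water, RfSetting(omega1=0.0, delta=0.0))
        s0 = np.array([0.0, 0.0, -1.0, 0.0])
        t = 0.3
        out = bm.propagate(s0, gen, t)
        expected = 1.0 + (-1.0 - 1.0) * math.exp(-free_water.R1a * t)
        assert out[2] == pytest.approx(expected, abs=1e-12)

    def test_equilibrium_conserved_under_free_evolution(self, liver):
        eq = bm.equilibrium_state(liver.fb)
        out = bm.propagate(eq, bm.free_generator(liver), 0.5)
        assert np.allclose(out, eq, atol=1e-12)

    def test_non_finite_generator_rejected(self, liver):
        A, b = bm.free_generator(liver)
        A = A.copy()
        A[0, 0] = np.nan
        with pytest.raises(ValueError):
            bm.propagate(np.zeros(4), (A, b), 0.01)


class TestCrusher:
    def test_definition(self):
        out = bm.apply_crusher((0.3, -0.2, 0.8, 0.05))
        assert np.allclose(out, [0.0, 0.0, 0.8, 0.05])

    def test_idempotent(self):
        once = bm.apply_crusher((0.3, -0.2, 0.8, 0.05))
        assert np.allclose(bm.apply_crusher(once), once)

    def test_equilibrium_unchanged(self, liver):
        eq = bm.equilibrium_state(liver.fb)
        assert np.allclose(bm.apply_crusher(eq), eq)


class TestPulseTrain:
    def test_single_block_matches_mono_exponential(self, liver, rf_hi):
        """A single CW block decays mono-exponentially at the analytic
        R1rho to within 2% for liver at the high-RF setting."""
        for tp in (0.02, 0.05, 0.1):
            train = PulseTrainParams(tp, 0.0, 1)
            sim = bm.simulate_pulse_train(liver, rf_hi, train, 1.0)[-1]
            model = analytic.train_magnetization(1.0, liver, rf_hi, train)
            assert sim == pytest.approx(model, rel=0.02)

    def test_no_pool_matches_water_oracle(self, free_water, train10):
        """fb=0 at near-zero tilt: per-module Rwater decay plus R1a recovery
        in the gaps, composed in closed form."""
        rf = RfSetting.from_hz(5.0, 5000.0)  # theta ~ 0.001
        sims = bm.simulate_pulse_train(free_water, rf, train10, 1.0)
        rw = analytic.r_water(free_water, rf)
        m = 1.0
        for j in range(train10.n):
            m = m * math.exp(-rw * train10.Tp) + analytic.mza_ss(free_water, rf) * (
                1 - math.exp(-rw * train10.Tp)
            )
            assert sims[j] == pytest.approx(m, abs=2e-6)
            if j < train10.n - 1:
                m = m * math.exp(-free_water.R1a * train10.Tf) + (
                    1 - math.exp(-free_water.R1a * train10.Tf)
                )

    def test_toggled_traces_bracket_symmetrically(self, liver, rf_hi):
        """With negligible recovery (Tp << 1/R1rho) the +-1 toggles are
        mirror images around the small steady-state offset."""
        train = PulseTrainParams(0.002, 0.0, 1)
        sp = bm.simulate_pulse_train(liver, rf_hi, train, 1.0)[-1]
        sm = bm.simulate_pulse_train(liver, rf_hi, train, -1.0)[-1]
        assert sp + sm == pytest.approx(0.0, abs=0.01)

    def test_returns_one_signal_per_module(self, liver, rf_lo, train10):
        assert bm.simulate_pulse_train(liver, rf_lo, train10, 1.0).shape == (10,)


class TestNumericR1RhoPul:
    def test_noiseless_fit_quality(self, liver, rf_lo, rf_hi, train10):
        for rf in (rf_lo, rf_hi):
            fit = bm.numeric_r1rho_pul(liver, rf, train10, range(1, 11))
            assert fit.r_squared > 0.999

    def test_water_only_rate(self, free_water, rf_lo, train10):
        fit = bm.numeric_r1rho_pul(free_water, rf_lo, train10, range(1, 11))
        expected = analytic.r_water(free_water, rf_lo) + train10.idr * free_water.R1a
        assert fit.rate == pytest.approx(expected, rel=0.01)

    def test_invariant_to_module_count_selection(self, liver, rf_hi, train10):
        a = bm.numeric_r1rho_pul(liver, rf_hi, train10, range(1, 11)).rate
        b = bm.numeric_r1rho_pul(liver, rf_hi, train10, range(2, 21, 2)).rate
        assert abs(a - b) / a < 0.005

    def test_requires_three_module_counts(self, liver, rf_hi, train10):
        with pytest.raises(ValueError):
            bm.numeric_r1rho_pul(liver, rf_hi, train10, [1, 5])


class TestNumericRmpfsl:
    def test_no_pool_near_zero(self, free_water, pair_study1, train10):
        for method in ("four_image", "fit"):
            assert abs(bm.numeric_rmpfsl(free_water, pair_study1, train10, method)) < 1e-3

    def test_monotone_in_fb(self, liver, pair_study1, train10):
        vals = [
            bm.numeric_rmpfsl(liver.with_(fb=f), pair_study1, train10, "four_image")
            for f in np.linspace(0.01, 0.15, 6)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_four_image_and_fit_methods_agree(self, liver, pair_fig4, train10):
        a = bm.numeric_rmpfsl(liver, pair_fig4, train10, "four_image")
        b = bm.numeric_rmpfsl(liver, pair_fig4, train10, "fit")
        assert a == pytest.approx(b, rel=0.02)

    def test_cw_fit_reference_matches_closed_form(self, liver, pair_fig4, train10):
        """The figure-level reference (CW R1rho fitted from simulation plus
        analytic pulsed terms) reproduces the closed form to ~1%."""
        ref = bm.numeric_rmpfsl(liver, pair_fig4, train10, "cw_fit")
        a = analytic.rmpfsl_pul(liver, pair_fig4, train10)
        assert ref == pytest.approx(a, rel=0.02)

    def test_four_image_converges_to_closed_form_with_pulse_length(
        self, liver, pair_fig4
    ):
        """The end-to-end simulated rate sits below the asymptotic closed
        form at short Tp (per-pulse saturation transient) and converges to
        it as Tp grows at fixed TSL."""
        errs = []
        for tp_ms, n in ((10, 10), (20, 5), (100, 1)):
            tr = PulseTrainParams.from_ms(tp_ms, 50.0, n)
            sim = bm.numeric_rmpfsl(liver, pair_fig4, tr, "four_image")
            a = analytic.rmpfsl_pul(liver, pair_fig4, tr)
            errs.append((a - sim) / sim)
        assert all(e > 0 for e in errs)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01


class TestTransientAndFreePrecession:
    def test_pool_ratio_follows_transient_relationship(self, liver, rf_lo, rf_hi):
        """During CW spin-lock the simulated Mzb/Mza tracks fb*(1-beta(t))
        within 5% for both validation protocols."""
        t_grid = np.linspace(0.0005, 0.1, 50)
        for rf in (rf_lo, rf_hi):
            traj = bm.cw_trajectory(liver, rf, t_grid)
            ratio = traj[:, 3] / traj[:, 2]
            predicted = np.array(
                [liver.fb * (1 - analytic.beta_transient(liver, rf, t)) for t in t_grid]
            )
            rel = np.abs(ratio - predicted) / predicted
            assert rel.max() < 0.05

    def test_transient_free_model_beats_pure_recovery(self, liver, rf_lo, rf_hi):
        """After a CW block, the transferred-saturation recovery model
        tracks the simulation more closely than pure R1a recovery."""
        Tp = 0.01
        t_grid = np.linspace(0.0, 0.2, 41)
        for rf in (rf_lo, rf_hi):
            start = bm.end_of_cw_state(liver, rf, Tp)
            mza0 = start[2]
            sim = bm.free_trajectory(start, liver, t_grid)[:, 2]
            model = np.array(
                [analytic.mza_free_transient(mza0, liver, rf, Tp, t) for t in t_grid]
            )
            naive = mza0 * np.exp(-liver.R1a * t_grid) + (
                1 - np.exp(-liver.R1a * t_grid)
            )
            assert np.abs(model - sim).max() < np.abs(naive - sim).max()
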