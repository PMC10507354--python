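"""Forward-physics tests: population AIF, Tofts convolution, FLASH signal."""

import numpy as np
import pytest
from dataclasses import replace

from roqdce.core import DynamicCurve, FlashParams, PKParams, TimeGrid
from roqdce.pk import (
    AIFModelParams,
    _aif_closed_form,
    flash_signal,
    population_aif,
    signal_to_concentration,
    tofts_forward,
    tofts_forward_batch,
    ve_from_rates,
)


class TestPopulationAIF:
    def test_zero_scale_gives_zero_curve(self, grid):
        p = AIFModelParams(scale=0.0)
        assert np.all(population_aif(p, grid).values == 0)

    def test_causal_before_bolus_arrival(self, grid, aif_params, aif):
        pre = grid.times < aif_params.bolus_arrival_s
        assert pre.sum() >= 5  # a pre-contrast segment exists on the default grid
        assert np.all(aif.values[pre] == 0)

    def test_peak_matches_dense_closed_form_evaluation(self, aif_params):
        # oracle: evaluate the closed form on a 1-ms grid and locate its max
        t_dense = np.arange(0, 120_000) * 1e-3 / 60.0  # minutes, 1 ms steps
        dense = _aif_closed_form(t_dense, aif_params)
        peak_val, peak_t_s = dense.max(), t_dense[dense.argmax()] * 60.0
        fine = TimeGrid(n_steps=120_000, dt=1e-3, t0=aif_params.bolus_arrival_s)
        curve = population_aif(aif_params, fine)
        assert curve.peak == pytest.approx(peak_val, rel=1e-12)
        t_at_max = fine.times[np.argmax(curve.values)] - aif_params.bolus_arrival_s
        assert t_at_max == pytest.approx(peak_t_s, abs=2e-3)

    def test_single_global_maximum_after_bolus(self, grid, aif):
        # the bolus-passage peak is the unique global maximum (the second
        # Gaussian only produces a lower shoulder)
        post = aif.values[grid.times >= 30.0]
        assert np.sum(post == post.max()) == 1
        assert np.argmax(post) < len(post) / 4  # early first-pass peak

    def test_scaling_is_multiplicative(self, grid, aif_params, aif):
        scaled = population_aif(replace(aif_params, scale=2.5), grid)
        np.testing.assert_allclose(scaled.values, 2.5 * aif.values, rtol=1e-12)

    def test_trapezoid_integral_scales_with_scale(self, grid, aif_params, aif):
        base = np.trapezoid(aif.values, grid.times)
        scaled = population_aif(replace(aif_params, scale=3.0), grid)
        assert np.trapezoid(scaled.values, grid.times) == pytest.approx(
            3.0 * base, rel=1e-6
        )

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            AIFModelParams(sigma1=-0.1)
        with pytest.raises(ValueError):
            AIFModelParams(beta=0.0)


class TestToftsForward:
    def test_zero_ktrans_gives_zero(self, aif):
        assert np.all(tofts_forward(aif, 0.0, 1.0).values == 0)

    def test_impulse_response_is_exponential(self):
        # a sampled impulse at t=0 (piecewise-linear: a half-tent of area
        # cp_0*dt/2) yields a pure exponential decay from the first step on
        grid = TimeGrid(n_steps=200, dt=2.0)
        dt_min = grid.dt / 60.0
        kt, kep = 0.8, 3.0
        cp = DynamicCurve(grid, np.r_[1.0 / dt_min, np.zeros(199)])
        ct = tofts_forward(cp, ktrans=kt, kep=kep)
        ratio = ct.values[1:] / np.exp(-kep * grid.times_min[1:])
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)
        # amplitude approaches half the impulse area x ktrans as dt -> 0
        assert ratio[0] == pytest.approx(0.5 * kt, rel=0.05)

    def test_step_response_closed_form_is_exact(self):
        # constant Cp is its own piecewise-linear interpolant, so the
        # exponential-integrator convolution matches the closed form exactly
        grid = TimeGrid(n_steps=400, dt=0.25)
        cp = DynamicCurve(grid, np.full(400, 2.0))
        kt, kep = 0.5, 4.0
        ct = tofts_forward(cp, kt, kep)
        expected = (kt * 2.0 / kep) * (1.0 - np.exp(-kep * grid.times_min))
        np.testing.assert_allclose(ct.values, expected, rtol=1e-10, atol=1e-14)

    def test_linear_in_cp_and_ktrans(self, aif):
        ct = tofts_forward(aif, 0.7, 2.0)
        ct_scaled_cp = tofts_forward(aif.with_values(3.0 * aif.values), 0.7, 2.0)
        ct_scaled_kt = tofts_forward(aif, 1.4, 2.0)
        np.testing.assert_allclose(ct_scaled_cp.values, 3.0 * ct.values, rtol=1e-12)
        np.testing.assert_allclose(ct_scaled_kt.values, 2.0 * ct.values, rtol=1e-12)

    def test_grid_mismatch_raises(self, aif):
        other = TimeGrid(n_steps=64, dt=2.0)
        with pytest.raises(ValueError):
            tofts_forward(aif, 0.5, 1.0, grid=other)

    def test_matches_fine_grid_quadrature_oracle(self, grid, aif_params, rng):
        """Discrete convolution vs trapezoid quadrature on a 100x finer grid,
        100 random draws inside the physiologic ranges, <= 1e-3 relative."""
        fine = TimeGrid(n_steps=(grid.n_steps - 1) * 100 + 1, dt=grid.dt / 100)
        # continuous input: the piecewise-linear interpolant of the sampled Cp
        cp_coarse = population_aif(aif_params, grid).values
        cp_fine = np.interp(fine.times, grid.times, cp_coarse)
        t_fine_min = fine.times_min
        coarse_idx = np.arange(grid.n_steps) * 100
        cp = population_aif(aif_params, grid)
        for _ in range(100):
            kt = rng.uniform(0.01, 12.0)
            kep = rng.uniform(0.01, 24.0)
            ct = tofts_forward(cp, kt, kep).values
            # oracle: direct quadrature of the convolution integral
            kernel = np.exp(-kep * t_fine_min)
            conv = np.convolve(cp_fine, kernel)[: fine.n_steps]
            conv -= 0.5 * (cp_fine * kernel[0] + cp_fine[0] * kernel)  # trapezoid ends
            oracle = kt * conv * (fine.dt / 60.0)
            scale = np.abs(oracle).max()
            assert np.abs(ct - oracle[coarse_idx]).max() <= 1e-3 * scale

    def test_batch_agrees_with_scalar(self, grid, aif, rng):
        kt = rng.uniform(0.1, 5.0, size=8)
        kep = rng.uniform(0.5, 10.0, size=8)
        batch = tofts_forward_batch(aif.values, kt, kep, grid.dt)
        for i in range(8):
            np.testing.assert_allclose(
                batch[i], tofts_forward(aif, kt[i], kep[i]).values, rtol=1e-12
            )


class TestFlashSignal:
    def test_zero_r1_gives_zero_signal(self, grid):
        r1 = DynamicCurve(grid, np.zeros(grid.n_steps), kind="R1")
        assert np.all(flash_signal(r1, FlashParams()).values == 0)

    def test_saturation_limit(self, grid):
        fp = FlashParams(m0=2.0)
        r1 = DynamicCurve(grid, np.full(grid.n_steps, 1e7), kind="R1")
        np.testing.assert_allclose(
            flash_signal(r1, fp).values,
            fp.m0 * np.sin(np.deg2rad(fp.flip_angle_deg)),
            rtol=1e-12,
        )

    def test_value_matches_arbitrary_precision_oracle(self):
        # oracle: sympy evaluation of the closed form at 50 digits
        import sympy as sp

        tr, r1v, alpha = sp.Rational(56, 10) / 1000, 1, sp.rad(10)
        e = sp.exp(-tr * r1v)
        expected = float(
            (sp.sin(alpha) * (1 - e) / (1 - sp.cos(alpha) * e)).evalf(50)
        )
        grid = TimeGrid(n_steps=1, dt=1.0)
        r1 = DynamicCurve(grid, np.array([1.0]), kind="R1")
        got = flash_signal(r1, FlashParams(tr_ms=5.6, flip_angle_deg=10.0, m0=1.0))
        assert got.values[0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_r1_and_bounded(self, rng):
        fp = FlashParams()
        grid = TimeGrid(n_steps=50, dt=1.0)
        r1 = DynamicCurve(grid, np.sort(rng.uniform(0, 20, 50)), kind="R1")
        s = flash_signal(r1, fp).values
        assert np.all(np.diff(s) > 0)
        assert np.all(s < fp.m0 * np.sin(np.deg2rad(fp.flip_angle_deg)))

    def test_negative_r1_rejected(self, grid):
        r1 = DynamicCurve(grid, np.full(grid.n_steps, -0.1), kind="R1")
        with pytest.raises(ValueError):
            flash_signal(r1, FlashParams())


class TestSignalNormalization:
    def test_baseline_identity_and_doubling(self, grid):
        s0 = 3.0
        vals = np.full(grid.n_steps, s0)
        vals[50] = 2 * s0
        out = signal_to_concentration(DynamicCurve(grid, vals, kind="raw_signal"), s0)
        assert out.values[0] == 0.0
        assert out.values[50] == pytest.approx(1.0)

    def test_nonpositive_baseline_rejected(self, grid):
        s = DynamicCurve(grid, np.ones(grid.n_steps), kind="raw_signal")
        with pytest.raises(ValueError):
            signal_to_concentration(s, 0.0)

    def test_roundtrip_linearized_signal_recovers_concentration_shape(self, grid, aif):
        """Low-concentration FLASH signals, baseline-normalized, stay
        proportional to the underlying concentration curve."""
        ct = tofts_forward(aif, 0.2, 1.0).values
        r1_0, r1_coef = 0.7, 0.02  # small enhancement regime
        r1 = DynamicCurve(grid, r1_0 + r1_coef * ct, kind="R1")
        fp = FlashParams()
        s = flash_signal(r1, fp)
        s0 = s.values[0]
        enh = signal_to_concentration(s, s0).values
        ratio = enh[ct > 0.5 * ct.max()] / ct[ct > 0.5 * ct.max()]
        assert ratio.std() / ratio.mean() < 0.02  # proportional within 2%


class TestPKParams:
    @pytest.mark.parametrize(
        "kt,kep,expected", [(1.0, 2.0, 0.5), (0.0, 5.0, 0.0), (0.3, 0.6, 0.5)]
    )
    def test_ve_from_rates(self, kt, kep, expected):
        assert ve_from_rates(kt, kep) == pytest.approx(expected)

    def test_ve_domain_error(self):
        with pytest.raises(ValueError):
            ve_from_rates(1.0, 0.0)

    def test_triple_consistency_enforced(self):
        assert PKParams(1.0, 2.0).ve == 0.5
        with pytest.raises(ValueError):
            PKParams(1.0, 2.0, ve=0.7)
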