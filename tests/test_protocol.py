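"""Clinical-protocol synthesis: downsampling, displacement, interpolation,
screening, and the simulation / phantom-cohort generators."""

import numpy as np
import pytest
from scipy import stats

from roqdce.core import DynamicCurve, TimeGrid
from roqdce.pk import AIFModelParams, population_aif, tofts_forward
from roqdce.protocol import (
    GROUP_PRIORS,
    ClinicalProtocol,
    MultiPhasicSample,
    apply_displacement,
    constant_interpolate,
    downsample,
    generate_phantom_cohort,
    linear_interpolate,
    screen_voxel,
    simulate_training_set,
)


@pytest.fixture(scope="module")
def protocol():
    return ClinicalProtocol()


@pytest.fixture(scope="module")
def small_cohort():
    return generate_phantom_cohort(
        {"control": 2, "pdac": 2, "cp": 1}, voxels_per_subject=30, rng_seed=11
    )


class TestDownsample:
    def test_linear_ramp_returns_phase_center_times(self, grid, protocol):
        curve = DynamicCurve(grid, grid.times.astype(float))
        sample = downsample(curve, protocol, aif_peak_time_s=40.0)
        np.testing.assert_allclose(sample.phase_values, sample.phase_times_s)
        np.testing.assert_allclose(sample.phase_times_s, [10.0, 40.0, 70.0, 100.0])

    def test_constant_curve_gives_equal_phases(self, grid, protocol):
        sample = downsample(DynamicCurve(grid, np.full(130, 3.3)), protocol, 40.0)
        assert np.all(sample.phase_values == 3.3)

    def test_arterial_phase_hits_curve_argmax(self, grid, aif, protocol):
        peak_t = grid.times[np.argmax(aif.values)]
        sample = downsample(aif, protocol, peak_t)
        assert sample.phase_values[1] == aif.values.max()

    def test_out_of_span_phase_center_raises(self, grid, protocol):
        curve = DynamicCurve(grid, np.zeros(130))
        with pytest.raises(ValueError, match="span"):
            downsample(curve, protocol, aif_peak_time_s=250.0)


class TestDisplacement:
    def test_zero_displacement_is_identity(self, protocol):
        assert apply_displacement(protocol, 0.0) == protocol

    def test_positive_shift_moves_all_post_contrast_centers(self, protocol):
        base = protocol.phase_centers(40.0)
        shifted = apply_displacement(protocol, 4.0).phase_centers(40.0)
        np.testing.assert_allclose(shifted[1:], base[1:] + 4.0)
        assert shifted[0] == base[0]  # pre-contrast phase unchanged

    @pytest.mark.parametrize("delta", [-10.5, 8.4, 100.0])
    def test_out_of_span_delta_rejected(self, protocol, delta):
        with pytest.raises(ValueError, match="span"):
            apply_displacement(protocol, delta)

    def test_displaced_arterial_center_before_grid_start_raises(self, grid):
        proto = apply_displacement(ClinicalProtocol(precontrast_time_s=0.0), -10.0)
        curve = DynamicCurve(grid, np.zeros(130))
        with pytest.raises(ValueError, match="span"):
            downsample(curve, proto, aif_peak_time_s=8.0)


class TestInterpolation:
    @pytest.fixture
    def sample(self):
        return MultiPhasicSample(
            np.array([0.0, 2.0, 1.0, 0.5]), np.array([10.0, 40.0, 70.0, 100.0])
        )

    def test_constant_on_equal_phases(self, grid):
        s = MultiPhasicSample(np.full(4, 7.0), np.array([10.0, 40.0, 70.0, 100.0]))
        assert np.all(constant_interpolate(s, grid).values == 7.0)

    def test_constant_left_closed_and_distinct_steps(self, grid, sample):
        out = constant_interpolate(sample, grid)
        assert out.values[grid.nearest_index(40.0)] == 2.0  # value at phase time
        assert out.values[grid.nearest_index(38.0)] == 0.0  # just before
        assert len(np.unique(out.values)) == 4
        assert np.all(out.values[grid.times >= 100.0] == 0.5)  # hold last

    def test_linear_midpoint_is_mean(self, grid):
        s = MultiPhasicSample(
            np.array([0.0, 2.0, 1.0, 0.5]), np.array([10.0, 40.0, 72.0, 100.0])
        )
        out = linear_interpolate(s, grid)
        i = grid.nearest_index(56.0)  # midpoint of the 40 s and 72 s phases
        assert out.values[i] == pytest.approx((2.0 + 1.0) / 2)

    def test_linear_exact_on_collinear_phases(self, grid):
        s = MultiPhasicSample(
            np.array([10.0, 40.0, 70.0, 100.0]) * 0.1,
            np.array([10.0, 40.0, 70.0, 100.0]),
        )
        out = linear_interpolate(s, grid)
        inside = (grid.times >= 10.0) & (grid.times <= 100.0)
        np.testing.assert_allclose(out.values[inside], 0.1 * grid.times[inside])

    def test_linear_beats_constant_on_smooth_tofts_curves(self, grid, aif, rng):
        # within the sampled span (both methods merely hold the last phase
        # beyond it), averaged over 100 random physiologic draws
        from roqdce.evaluation import nrmse

        protocol = ClinicalProtocol()
        peak_t = grid.times[np.argmax(aif.values)]
        wins = []
        for _ in range(100):
            ct = tofts_forward(aif, rng.uniform(0.1, 2.0), rng.uniform(0.5, 6.0))
            s = downsample(ct, protocol, peak_t)
            mask = grid.times <= s.phase_times_s[-1]
            wins.append(
                nrmse(linear_interpolate(s, grid).values, ct.values, mask=mask)
                - nrmse(constant_interpolate(s, grid).values, ct.values, mask=mask)
            )
        assert np.mean(wins) < 0

    def test_omega_after_constant_interpolation_is_identity(self, grid, aif, protocol):
        """Omega(constant_interp(Omega(curve))) == Omega(curve) exactly."""
        peak_t = grid.times[np.argmax(aif.values)]
        for interp in (constant_interpolate, linear_interpolate):
            sample = downsample(aif, protocol, peak_t)
            rebuilt = downsample(interp(sample, grid), protocol, peak_t)
            np.testing.assert_array_equal(rebuilt.phase_values, sample.phase_values)


class TestScreening:
    def test_noiseless_tofts_voxel_is_kept(self, grid, aif):
        ct = tofts_forward(aif, 0.6, 2.0)
        res = screen_voxel(ct, aif)
        assert res.keep and res.norm_error < 1e-6

    def test_sign_noise_voxel_is_dropped(self, grid, aif, rng):
        # +/-1 random-sign noise: peak exactly 1, and no smooth Tofts curve
        # can absorb it, so norm_error ~ RMSE(curve)/1 = 1 > 0.7
        curve = DynamicCurve(grid, rng.choice([-1.0, 1.0], grid.n_steps))
        res = screen_voxel(curve, aif)
        assert res.norm_error > 0.7 and not res.keep
        assert res.norm_error == pytest.approx(1.0, abs=0.15)

    def test_boundary_is_inclusive(self, grid, aif, monkeypatch):
        from roqdce import protocol as protomod
        from roqdce.fitters import FitResult

        fake = FitResult(1, 1, 1, 0.7, 0.7, True, 1)
        monkeypatch.setattr("roqdce.fitters.nlls_fit", lambda *a, **k: fake)
        ct = tofts_forward(aif, 0.6, 2.0)
        assert protomod.screen_voxel(ct, aif, threshold=0.7).keep

    def test_all_zero_curve_is_degenerate(self, grid, aif):
        with pytest.raises(ValueError, match="degenerate"):
            screen_voxel(DynamicCurve(grid, np.zeros(130)), aif)


class TestSimulateTrainingSet:
    def test_zero_noise_reproduces_forward_model(self, grid):
        sim = simulate_training_set(3, noise_sigma_range=(0.0, 0.0), rng_seed=5)
        for pair in sim:
            expected = tofts_forward(pair.aif, pair.ktrans, pair.kep)
            np.testing.assert_allclose(pair.ct.values, expected.values, atol=1e-12)

    def test_fixed_seed_is_deterministic(self):
        a = simulate_training_set(50, rng_seed=3)
        b = simulate_training_set(50, rng_seed=3)
        np.testing.assert_array_equal(a.ct, b.ct)
        np.testing.assert_array_equal(a.truth_matrix(), b.truth_matrix())

    def test_empty_noise_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_training_set(5, noise_sigma_range=(0.1, 0.01))

    def test_parameter_marginals_match_conditional_law(self):
        """KS test of the Ktrans marginal against the exact post-rejection
        conditional density (uniform draws restricted to 0.1 <= kt/kep <= 0.8)."""
        sim = simulate_training_set(10_000, rng_seed=21)
        kt_lo, kt_hi, kep_lo, kep_hi = 0.01, 12.0, 0.01, 24.0

        def accept_measure(kt):
            lo = np.maximum(kep_lo, kt / 0.8)
            hi = np.minimum(kep_hi, kt / 0.1)
            return np.maximum(hi - lo, 0.0)

        xs = np.linspace(kt_lo, kt_hi, 20_001)
        dens = accept_measure(xs)
        cdf_vals = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2)])
        cdf_vals /= cdf_vals[-1]
        stat, p = stats.kstest(sim.ktrans, lambda x: np.interp(x, xs, cdf_vals))
        assert p > 0.01
        # ve constraint honored exactly
        assert sim.ve.min() >= 0.1 and sim.ve.max() <= 0.8


class TestPhantomCohort:
    def test_group_median_orderings(self):
        # enforced by construction of the priors, verified on draws
        cohort = generate_phantom_cohort(
            {"control": 4, "pdac": 4, "cp": 3}, voxels_per_subject=200, rng_seed=2
        )
        med = {
            g: np.median(cohort.group_truth(g), axis=0)
            for g in ("control", "non_tumor", "tumor", "cp")
        }
        assert med["control"][0] > med["non_tumor"][0] > med["tumor"][0]  # ktrans
        assert med["control"][1] > med["non_tumor"][1] > med["tumor"][1]  # kep
        assert med["control"][2] < med["non_tumor"][2] < med["tumor"][2]  # ve
        assert med["cp"][0] < med["control"][0] and med["cp"][1] < med["control"][1]
        assert med["cp"][2] > med["control"][2]

    def test_zero_noise_voxels_pass_screening(self):
        from roqdce.fitters import varpro_norm_error_batch

        cohort = generate_phantom_cohort(
            {"control": 1, "pdac": 1, "cp": 1},
            voxels_per_subject=20,
            noise_sigma=0.0,
            rng_seed=4,
        )
        for s in cohort.subjects:
            # exact fit via the NLLS screen on a couple of voxels
            aif = DynamicCurve(cohort.grid, s.aif_values)
            for v in (0, s.n_voxels - 1):
                res = screen_voxel(DynamicCurve(cohort.grid, s.ref_curves[v]), aif)
                assert res.keep and res.norm_error < 1e-6
            # coarse-grid batch screen stays far below the 0.7 threshold
            err = varpro_norm_error_batch(s.ref_curves, s.aif_values, cohort.grid.dt)
            assert np.all(err < 0.05)

    def test_fixed_seed_reproducible(self, small_cohort):
        again = generate_phantom_cohort(
            {"control": 2, "pdac": 2, "cp": 1}, voxels_per_subject=30, rng_seed=11
        )
        for a, b in zip(small_cohort.subjects, again.subjects):
            np.testing.assert_array_equal(a.ref_curves, b.ref_curves)
            np.testing.assert_array_equal(a.truth, b.truth)
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_subject_aif_shared_and_sample_consistent(self, small_cohort):
        s = small_cohort.subjects[0]
        grid = small_cohort.grid
        idx = [grid.nearest_index(t) for t in s.phase_times_s]
        np.testing.assert_allclose(s.aif_sample.phase_values, s.aif_values[idx])
        # tissue samples are the clinical restriction of the noisy reference
        np.testing.assert_allclose(s.samples, s.ref_curves[:, idx])

    def test_pdac_subjects_have_both_rois(self, small_cohort):
        pdac = [s for s in small_cohort.subjects if s.group == "pdac"]
        for s in pdac:
            assert set(np.unique(s.roi)) == {"tumor", "non_tumor"}
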