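import numpy as np
import pytest

from conjmap.conjunction import (
    SCENARIOS,
    OverlapCurve,
    ZMapPair,
    build_threshold_grid,
    scenario_overlap_curves,
)
from conjmap.null_model import (
    SmoothnessEstimate,
    average_smoothness,
    decide_significance,
    estimate_fwhm,
    monte_carlo_null,
    permutation_null,
)
from conjmap.synthetic_data import FieldSpec, generate_smooth_field
from conjmap.volume_io import MaskedVolume


def null_template(shape=(24, 24, 24)):
    spec = FieldSpec(shape=shape, fwhm_mm=0.0, seed=0)
    return MaskedVolume(np.zeros(shape), spec.affine, spec.make_mask())


class TestSmoothnessEstimator:
    def test_known_6mm_recovered_within_10pct(self):
        ests = [
            estimate_fwhm(
                generate_smooth_field(FieldSpec(shape=(48, 48, 48), fwhm_mm=6.0, seed=s))
            ).combined_fwhm_mm
            for s in range(20)
        ]
        assert np.mean(ests) == pytest.approx(6.0, rel=0.10)

    def test_white_noise_reported_below_resolution(self):
        vol = generate_smooth_field(FieldSpec(shape=(32, 32, 32), fwhm_mm=0.0, seed=1))
        est = estimate_fwhm(vol)
        # unsmoothed noise: neighbor diff variance ~ 2 var -> rho <= 0
        assert all(np.isnan(f) or f < 3.0 for f in est.fwhm_mm)

    def test_scale_invariance(self):
        vol = generate_smooth_field(FieldSpec(shape=(32, 32, 32), fwhm_mm=6.0, seed=2))
        a = estimate_fwhm(vol)
        b = estimate_fwhm(vol.with_data(vol.data * 10.0))
        np.testing.assert_allclose(a.fwhm_mm, b.fwhm_mm, rtol=1e-10)

    def test_too_few_voxels_rejected(self):
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[:3, :3, :3] = True
        vol = MaskedVolume(
            np.random.default_rng(0).standard_normal((16, 16, 16)),
            np.diag([3.0, 3, 3, 1]),
            mask,
        )
        with pytest.raises(ValueError, match="100"):
            estimate_fwhm(vol)


class TestAverageSmoothness:
    def test_identical_estimates_unchanged(self):
        a = SmoothnessEstimate((6.0, 6.0, 6.0), 6.0)
        out = average_smoothness(a, a)
        assert out.fwhm_mm == (6.0, 6.0, 6.0)

    def test_arithmetic_mean(self):
        a = SmoothnessEstimate((4.0, 4.0, 4.0), 4.0)
        b = SmoothnessEstimate((8.0, 8.0, 8.0), 8.0)
        assert average_smoothness(a, b).fwhm_mm == (6.0, 6.0, 6.0)

    def test_asymmetric_axes_average_elementwise(self):
        a = SmoothnessEstimate((4.0, 6.0, 8.0), 5.8)
        b = SmoothnessEstimate((6.0, 6.0, 6.0), 6.0)
        expected = tuple((x + y) / 2 for x, y in zip(a.fwhm_mm, b.fwhm_mm))
        assert average_smoothness(a, b).fwhm_mm == expected


class TestMonteCarloNull:
    def test_same_seed_reproduces_matrix(self):
        template = null_template()
        grid = build_threshold_grid(0.05, 0.005, 0.005)
        n1 = monte_carlo_null(template, 6.0, grid, iterations=50, seed=5)
        n2 = monte_carlo_null(template, 6.0, grid, iterations=50, seed=5)
        np.testing.assert_array_equal(n1.overlaps, n2.overlaps)

    def test_bands_ordered_by_percentile(self):
        template = null_template()
        grid = build_threshold_grid(0.05, 0.01, 0.005)
        null = monte_carlo_null(template, 6.0, grid, iterations=120, seed=1)
        assert np.all(null.band(0.5) <= null.band(50.0))
        assert np.all(null.band(50.0) <= null.band(99.5))

    def test_upper_band_nondecreasing_in_smoothness(self):
        # smoother fields make random overlap more variable: fewer
        # independent resels means occasional much larger chance overlaps,
        # so the 99.5th-percentile band widens with FWHM
        template = null_template((32, 32, 32))
        grid = build_threshold_grid(0.05, 0.01, 0.01)
        uppers = []
        for fwhm in (0.0, 6.0, 12.0):
            null = monte_carlo_null(template, fwhm, grid, iterations=200, seed=3)
            uppers.append(null.band(99.5)[0])  # most lenient threshold
        assert uppers[0] <= uppers[1] <= uppers[2]
        assert uppers[2] > uppers[0]

    def test_low_iteration_warning(self, caplog):
        template = null_template((16, 16, 16))
        grid = build_threshold_grid(0.05, 0.05, 0.01)
        import logging

        with caplog.at_level(logging.WARNING):
            monte_carlo_null(template, 3.0, grid, iterations=20, seed=0)
        assert any("100" in r.message for r in caplog.records)


class TestDecision:
    @staticmethod
    def _result_with_exceedances(k, n=500):
        grid = build_threshold_grid()
        curve = OverlapCurve(
            scenario=SCENARIOS["EMB1"],
            grid=grid,
            overlap_percent=np.where(np.arange(n) < k, 10.0, 0.0),
            count_a=np.ones(n, int),
            count_b=np.ones(n, int),
            count_intersection=np.ones(n, int),
        )
        from conjmap.null_model import NullDistribution

        null = NullDistribution(
            overlaps=np.zeros((10, n)),
            grid=grid,
            bands={0.5: np.zeros(n), 50.0: np.zeros(n), 99.5: np.zeros(n)},
            iterations=10,
            seed=0,
            target_fwhm_mm=6.0,
        )
        return decide_significance(curve, null)

    def test_all_thresholds_above_is_significant(self):
        assert self._result_with_exceedances(500).significant

    def test_boundary_flips_between_350_and_349(self):
        at_350 = self._result_with_exceedances(350)
        at_349 = self._result_with_exceedances(349)
        assert at_350.required_count == 350
        assert at_350.significant
        assert not at_349.significant

    def test_ties_with_band_do_not_count(self):
        # observed exactly equal to the band everywhere -> 0 exceedances
        res = self._result_with_exceedances(0)
        assert res.exceedance_count == 0 and not res.significant

    def test_grid_mismatch_rejected(self):
        grid_a = build_threshold_grid()
        grid_b = build_threshold_grid(0.05, 0.001, 0.001)
        curve = OverlapCurve(
            SCENARIOS["EMB1"], grid_b, np.zeros(len(grid_b)),
            np.zeros(len(grid_b)), np.zeros(len(grid_b)), np.zeros(len(grid_b)),
        )
        from conjmap.null_model import NullDistribution

        null = NullDistribution(
            np.zeros((5, len(grid_a))), grid_a,
            {0.5: np.zeros(500), 50.0: np.zeros(500), 99.5: np.zeros(500)},
            5, 0, 6.0,
        )
        with pytest.raises(ValueError, match="grid"):
            decide_significance(curve, null)


class TestPermutationNull:
    @staticmethod
    def _cohort_maps(seed):
        from conjmap.synthetic_data import (
            CohortSpec,
            cohort_derivative_maps,
            simulate_cohort,
        )

        ds = simulate_cohort(
            CohortSpec(n_per_group=6, n_timepoints=32, shape=(10, 10, 10), seed=seed)
        )
        return cohort_derivative_maps(ds), ds.phenotype

    def test_requires_subject_level_inputs(self):
        grid = build_threshold_grid(0.05, 0.01, 0.01)
        with pytest.raises(ValueError, match="subject-level"):
            permutation_null(None, None, None, None, grid)

    def test_same_seed_reproduces(self):
        maps_a, pheno_a = self._cohort_maps(1)
        maps_b, pheno_b = self._cohort_maps(2)
        grid = build_threshold_grid(0.05, 0.025, 0.025)
        n1 = permutation_null(maps_a, pheno_a, maps_b, pheno_b, grid, n_perm=5, seed=9)
        n2 = permutation_null(maps_a, pheno_a, maps_b, pheno_b, grid, n_perm=5, seed=9)
        for name in SCENARIOS:
            np.testing.assert_array_equal(n1[name].overlaps, n2[name].overlaps)

    def test_agrees_with_monte_carlo_under_null_cohorts(self):
        # both null constructions should put the 99.5th band in the same
        # range at a mid-grid threshold for effect-free cohorts
        maps_a, pheno_a = self._cohort_maps(3)
        maps_b, pheno_b = self._cohort_maps(4)
        grid = build_threshold_grid(0.02, 0.02, 0.01)  # single mid-grid threshold
        perm = permutation_null(maps_a, pheno_a, maps_b, pheno_b, grid, n_perm=60, seed=2)
        from conjmap.group_zmaps import fit_voxelwise_glm
        from conjmap.null_model import estimate_fwhm, average_smoothness

        za = fit_voxelwise_glm(maps_a, pheno_a)
        zb = fit_voxelwise_glm(maps_b, pheno_b)
        sm = average_smoothness(estimate_fwhm(za.volume), estimate_fwhm(zb.volume))
        template = MaskedVolume(
            np.zeros(za.volume.shape), za.volume.affine, za.volume.mask & zb.volume.mask
        )
        mc = monte_carlo_null(template, sm.combined_fwhm_mm, grid, iterations=60, seed=2)
        p_band = np.mean([perm[name].band(99.5)[0] for name in SCENARIOS])
        # loose agreement: both are small-sample 99.5th estimates
        assert abs(p_band - mc.band(99.5)[0]) < 12.0
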