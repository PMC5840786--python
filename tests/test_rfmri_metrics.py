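import numpy as np
import pytest

from conjmap.rfmri_metrics import (
    MetricConfig,
    degree_centrality,
    falff,
    reho,
    seed_ifc,
    smooth_volume,
    vmhc,
)
from conjmap.rfmri_metrics import _neighborhood_offsets
from conjmap.volume_io import MaskedVolume

from oracles import (
    brute_dc,
    brute_falff,
    brute_kendall_w,
    brute_reho,
    brute_seed_ifc,
    brute_vmhc,
)

AFF = np.diag([3.0, 3.0, 3.0, 1.0])


def template_for(shape):
    return MaskedVolume(np.zeros(shape), AFF)


class TestReHo:
    def test_identical_neighborhood_series_give_w_of_1(self, rng):
        shape = (5, 5, 5)
        base = rng.standard_normal(20)
        ts = np.broadcast_to(base, shape + (20,)).copy()
        out = reho(ts, template_for(shape), MetricConfig(metric="ReHo"))
        assert out.volume.data[2, 2, 2] == pytest.approx(1.0)

    def test_two_reversed_rank_series_give_w_of_0(self):
        # m=2 exactly reversed rank sequences: every per-timepoint rank sum
        # equals n+1, so S = 0 and W = 12*0 / (m^2 (n^3 - n)) = 0
        shape = (3, 3, 3)
        mask = np.zeros(shape, dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        ts = np.zeros(shape + (8,))
        ts[1, 1, 1] = np.arange(1.0, 9.0)
        ts[1, 1, 2] = np.arange(8.0, 0.0, -1.0)
        template = MaskedVolume(np.zeros(shape), AFF, mask)
        out = reho(ts, template, MetricConfig(metric="ReHo", reho_neighborhood=7))
        assert out.volume.data[1, 1, 1] == pytest.approx(0.0, abs=1e-12)
        assert brute_kendall_w(np.array(ts[1, 1, 1:3, :])) == pytest.approx(0.0)

    @pytest.mark.parametrize("neighborhood", [7, 19, 27])
    def test_matches_brute_force_on_random_data(self, rng, neighborhood):
        shape = (6, 6, 6)
        ts = rng.standard_normal(shape + (24,))
        mask = rng.random(shape) < 0.9
        template = MaskedVolume(np.zeros(shape), AFF, mask)
        cfg = MetricConfig(metric="ReHo", reho_neighborhood=neighborhood)
        out = reho(ts, template, cfg)
        expected = brute_reho(ts, mask, _neighborhood_offsets(neighborhood))
        np.testing.assert_allclose(out.volume.data, expected, atol=1e-10)

    def test_bounded_in_unit_interval_and_scale_invariant(self, rng):
        shape = (6, 6, 6)
        ts = rng.standard_normal(shape + (30,))
        template = template_for(shape)
        cfg = MetricConfig(metric="ReHo")
        w1 = reho(ts, template, cfg).volume.data
        w2 = reho(ts * 7.3 + 2.0, template, cfg).volume.data
        assert w1.min() >= 0 and w1.max() <= 1
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_constant_series_zeroed(self, rng):
        shape = (5, 5, 5)
        ts = rng.standard_normal(shape + (16,))
        ts[2, 2, 2, :] = 3.0
        out = reho(ts, template_for(shape), MetricConfig(metric="ReHo"))
        assert out.volume.data[2, 2, 2] == 0.0

    def test_too_few_timepoints_rejected(self, rng):
        ts = rng.standard_normal((5, 5, 5, 4))
        with pytest.raises(ValueError, match="8 timepoints"):
            reho(ts, template_for((5, 5, 5)), MetricConfig(metric="ReHo"))


class TestVMHC:
    def test_mirror_symmetric_data_gives_r_of_1(self, rng):
        shape = (6, 5, 5)
        half = rng.standard_normal((3, 5, 5, 30))
        ts = np.concatenate([half, half[::-1]], axis=0)
        out = vmhc(ts, template_for(shape), MetricConfig(metric="VMHC"))
        clip = np.arctanh(1 - 1e-7)
        np.testing.assert_allclose(out.volume.values(), clip, atol=1e-6)

    def test_negated_mirror_gives_r_of_minus_1(self, rng):
        shape = (6, 5, 5)
        half = rng.standard_normal((3, 5, 5, 30))
        ts = np.concatenate([half, -half[::-1]], axis=0)
        out = vmhc(ts, template_for(shape), MetricConfig(metric="VMHC"))
        np.testing.assert_allclose(out.volume.values(), -np.arctanh(1 - 1e-7), atol=1e-6)

    def test_odd_axis_midline_maps_to_itself(self, rng):
        shape = (5, 4, 4)
        ts = rng.standard_normal(shape + (20,))
        out = vmhc(ts, template_for(shape), MetricConfig(metric="VMHC"))
        np.testing.assert_allclose(
            out.volume.data[2], np.arctanh(1 - 1e-7), atol=1e-6
        )

    def test_independent_noise_mean_z_near_zero(self, rng):
        shape = (8, 8, 8)
        ts = rng.standard_normal(shape + (200,))
        out = vmhc(ts, template_for(shape), MetricConfig(metric="VMHC"))
        vals = out.volume.values()
        vals = vals[np.abs(vals) < np.arctanh(1 - 1e-7) - 1]  # drop midline self-pairs
        se = 1.0 / np.sqrt(197) / np.sqrt(len(vals) / 2)  # pairs share values
        assert abs(vals.mean()) < 3 * se + 0.01

    def test_matches_brute_force(self, rng):
        shape = (6, 4, 4)
        ts = rng.standard_normal(shape + (24,))
        mask = rng.random(shape) < 0.85
        template = MaskedVolume(np.zeros(shape), AFF, mask)
        out = vmhc(ts, template, MetricConfig(metric="VMHC"))
        expected, exp_mask = brute_vmhc(ts, mask)
        np.testing.assert_array_equal(out.volume.mask, exp_mask)
        np.testing.assert_allclose(out.volume.data, expected, atol=1e-10)


class TestDegreeCentrality:
    def test_identical_series_give_n_minus_1_binary(self, rng):
        shape = (4, 4, 4)
        base = rng.standard_normal(20)
        ts = np.broadcast_to(base, shape + (20,)).copy()
        cfg = MetricConfig(metric="DC", dc_mode="binary")
        out = degree_centrality(ts, template_for(shape), cfg)
        np.testing.assert_allclose(out.volume.values(), 63.0)

    @pytest.mark.parametrize("mode", ["binary", "weighted"])
    def test_matches_brute_force(self, rng, mode):
        shape = (5, 5, 5)
        ts = rng.standard_normal(shape + (30,))
        mask = rng.random(shape) < 0.7
        mask[2, 2, 2] = True
        template = MaskedVolume(np.zeros(shape), AFF, mask)
        cfg = MetricConfig(metric="DC", dc_mode=mode)
        out = degree_centrality(ts, template, cfg)
        expected = brute_dc(ts, mask, 0.25, mode)
        np.testing.assert_allclose(out.volume.data, expected, atol=1e-8)

    def test_chunked_pass_equals_full_matrix(self, rng):
        shape = (8, 8, 8)
        ts = rng.standard_normal(shape + (40,))
        template = template_for(shape)
        full = degree_centrality(ts, template, MetricConfig(metric="DC"))
        chunked = degree_centrality(
            ts, template, MetricConfig(metric="DC", dc_voxel_budget=100)
        )
        np.testing.assert_allclose(full.volume.data, chunked.volume.data, atol=1e-9)

    def test_binary_null_mean_matches_analytic_tail(self, rng):
        # exact null of the sample correlation of n iid normals:
        # r*sqrt(n-2)/sqrt(1-r^2) ~ t(n-2)
        from scipy import stats

        shape = (8, 8, 8)
        n_t = 500
        ts = rng.standard_normal(shape + (n_t,))
        cfg = MetricConfig(metric="DC", dc_mode="binary", dc_r_threshold=0.25)
        out = degree_centrality(ts, template_for(shape), cfg)
        n_vox = out.volume.mask.sum()
        df = n_t - 2  # detrending costs ~1 more df; negligible at n=500
        t_cut = 0.25 * np.sqrt(df) / np.sqrt(1 - 0.25**2)
        p_exceed = stats.t.sf(t_cut, df)
        expected = (n_vox - 1) * p_exceed
        sd = np.sqrt((n_vox - 1) * p_exceed * (1 - p_exceed))
        assert abs(out.volume.values().mean() - expected) < 4 * sd / np.sqrt(n_vox) + 0.05 * expected


class TestFALFF:
    @staticmethod
    def _pure_tone(freq_hz, n=160, tr=2.0):
        # n=160 at TR=2 puts multiples of 1/320 Hz exactly on Fourier bins;
        # the phase is chosen orthogonal to the detrend ramp so linear
        # detrending leaves the tone untouched (a discrete tone generally
        # has nonzero covariance with a ramp at arbitrary phase)
        t = np.arange(n) * tr
        ramp = np.arange(n) - (n - 1) / 2
        theta = 2 * np.pi * freq_hz * t
        s_s = (ramp * np.sin(theta)).sum()
        s_c = (ramp * np.cos(theta)).sum()
        phi = np.arctan2(-s_s, s_c)
        return np.sin(theta + phi)

    def test_in_band_sinusoid_gives_fraction_near_1(self):
        shape = (4, 4, 4)
        tone = self._pure_tone(0.05)
        ts = np.broadcast_to(tone, shape + (160,)).copy()
        out = falff(ts, template_for(shape), MetricConfig(metric="fALFF", tr_seconds=2.0))
        assert out.volume.values().min() >= 0.99

    def test_out_of_band_sinusoid_gives_fraction_near_0(self):
        shape = (4, 4, 4)
        tone = self._pure_tone(0.2)
        ts = np.broadcast_to(tone, shape + (160,)).copy()
        out = falff(ts, template_for(shape), MetricConfig(metric="fALFF", tr_seconds=2.0))
        assert out.volume.values().max() <= 0.05

    def test_white_noise_matches_periodogram_oracle(self, rng):
        shape = (6, 6, 6)
        ts = rng.standard_normal(shape + (256,))
        cfg = MetricConfig(metric="fALFF", tr_seconds=2.0)
        out = falff(ts, template_for(shape), cfg)
        expected = brute_falff(ts, np.ones(shape, dtype=bool), 2.0, (0.01, 0.1))
        np.testing.assert_allclose(out.volume.data, expected, atol=1e-10)
        # mean against an independent simulation oracle at matched n
        sim = np.abs(np.fft.rfft(rng.standard_normal((2000, 256)), axis=1))
        freqs = np.fft.rfftfreq(256, d=2.0)
        pos, band = freqs > 0, (freqs > 0) & (freqs >= 0.01) & (freqs <= 0.1)
        sim_mean = (sim[:, band].sum(1) / sim[:, pos].sum(1)).mean()
        assert abs(out.volume.values().mean() - sim_mean) < 0.02

    def test_band_beyond_nyquist_rejected(self, rng):
        ts = rng.standard_normal((4, 4, 4, 64))
        cfg = MetricConfig(metric="fALFF", tr_seconds=2.0, falff_band_hz=(0.01, 0.3))
        with pytest.raises(ValueError, match="Nyquist"):
            falff(ts, template_for((4, 4, 4)), cfg)

    def test_offset_invariance_after_detrend(self, rng):
        shape = (4, 4, 4)
        ts = rng.standard_normal(shape + (64,))
        cfg = MetricConfig(metric="fALFF", tr_seconds=2.0)
        a = falff(ts, template_for(shape), cfg).volume.data
        b = falff(ts + 100.0, template_for(shape), cfg).volume.data
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestSeedIFC:
    def test_seed_voxel_correlates_perfectly_with_itself(self, rng):
        shape = (5, 5, 5)
        ts = rng.standard_normal(shape + (40,))
        seed = np.zeros(shape, dtype=bool)
        seed[2, 2, 2] = True
        cfg = MetricConfig(metric="PCC_iFC", seed_mask=seed)
        out = seed_ifc(ts, template_for(shape), cfg)
        assert out.volume.data[2, 2, 2] == pytest.approx(np.arctanh(1 - 1e-7), abs=1e-6)

    def test_matches_brute_force(self, rng):
        shape = (6, 6, 6)
        ts = rng.standard_normal(shape + (32,))
        seed = np.zeros(shape, dtype=bool)
        seed[2:4, 2:4, 2:4] = True
        cfg = MetricConfig(metric="PCC_iFC", seed_mask=seed)
        out = seed_ifc(ts, template_for(shape), cfg)
        expected = brute_seed_ifc(ts, np.ones(shape, dtype=bool), seed)
        np.testing.assert_allclose(out.volume.data, expected, atol=1e-10)

    def test_independent_noise_mean_z_near_zero(self, rng):
        shape = (8, 8, 8)
        ts = rng.standard_normal(shape + (200,))
        seed = np.zeros(shape, dtype=bool)
        seed[4, 4, 4] = True
        cfg = MetricConfig(metric="PCC_iFC", seed_mask=seed)
        out = seed_ifc(ts, template_for(shape), cfg)
        vals = out.volume.values()
        vals = vals[vals < 3]  # exclude the seed voxel itself
        assert abs(vals.mean()) < 3.0 / np.sqrt(197) / np.sqrt(len(vals)) + 0.005

    def test_constant_seed_rejected(self):
        shape = (5, 5, 5)
        ts = np.zeros(shape + (20,))
        seed = np.zeros(shape, dtype=bool)
        seed[2, 2, 2] = True
        cfg = MetricConfig(metric="PCC_iFC", seed_mask=seed)
        with pytest.raises(ValueError, match="constant"):
            seed_ifc(ts, template_for(shape), cfg)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, small_volume):
        out = smooth_volume(small_volume, 0.0)
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_impulse_response_half_maximum_diameter(self):
        # 6 mm FWHM on 3 mm voxels: half-max contour diameter ~ 2 voxels
        shape = (21, 21, 21)
        data = np.zeros(shape)
        data[10, 10, 10] = 1.0
        vol = MaskedVolume(data, AFF)
        sm = smooth_volume(vol, 6.0)
        profile = sm.data[:, 10, 10]
        half = profile.max() / 2
        above = np.nonzero(profile >= half)[0]
        # linear interpolation of the crossing points
        lo = above[0] - (profile[above[0]] - half) / (profile[above[0]] - profile[above[0] - 1])
        hi = above[-1] + (profile[above[-1]] - half) / (profile[above[-1]] - profile[above[-1] + 1])
        assert (hi - lo) == pytest.approx(2.0, rel=0.10)

    def test_interior_mean_preserved(self, rng):
        shape = (24, 24, 24)
        data = rng.random(shape) + 1.0
        vol = MaskedVolume(data, AFF)
        sm = smooth_volume(vol, 6.0)
        interior = np.zeros(shape, dtype=bool)
        interior[6:-6, 6:-6, 6:-6] = True
        assert sm.data[interior].mean() == pytest.approx(
            data[interior].mean(), rel=0.01
        )

    def test_negative_fwhm_rejected(self, small_volume):
        with pytest.raises(ValueError, match="non-negative"):
            smooth_volume(small_volume, -1.0)
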