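import numpy as np
import pytest
import pywt

from lcmcs.lcm import (
    CorrelationProfile,
    LCMDenoiser,
    apply_level_map,
    band_correlations,
    build_occ_osp,
    decompose_stack,
    smooth_to_level,
)
from lcmcs.spectra_io import SpectrumSet, TargetVector


def _specset(values, start=350.0):
    values = np.atleast_2d(values)
    wl = start + np.arange(values.shape[1], dtype=float)
    ids = [f"s{i}" for i in range(values.shape[0])]
    return SpectrumSet(wl, values, ids)


class TestSmoothing:
    def test_constant_reproduced_at_every_level(self):
        s = _specset(np.full((3, 512), 0.37))
        stack = decompose_stack(s, "sym8", 5)
        for k in range(6):
            np.testing.assert_allclose(stack.level(k).values, 0.37, atol=1e-10)

    def test_perfect_reconstruction_without_zeroing(self, rng):
        x = rng.uniform(0.1, 0.9, size=(5, 300))
        coeffs = pywt.wavedec(x, "sym8", mode="symmetric", level=5, axis=1)
        rec = pywt.waverec(coeffs, "sym8", mode="symmetric", axis=1)[:, :300]
        np.testing.assert_allclose(rec, x, atol=1e-10)

    def test_level_zero_is_identity(self, rng):
        x = rng.uniform(0.1, 0.9, size=(2, 64))
        np.testing.assert_array_equal(smooth_to_level(x, 0), x)

    def test_smoothing_recovers_clean_signal_correlation(self, rng):
        # smooth clean signal + alternating fine noise: correlation of each
        # band with the clean band value must increase with smoothing level
        n, nb = 60, 512
        t = np.linspace(0, 1, nb)
        amp = rng.uniform(0.5, 1.5, n)
        clean = amp[:, None] * (0.3 + 0.2 * t + 0.1 * t**2)[None, :]
        noise = 0.1 * rng.standard_normal((n, nb)) * np.tile([1, -1], nb // 2)[None, :]
        x = clean + noise
        j = nb // 2

        def corr(level):
            v = smooth_to_level(x, level)[:, j]
            return abs(np.corrcoef(v, clean[:, j])[0, 1])

        assert corr(5) > corr(2) > corr(0)

    def test_excessive_level_raises_with_feasible_depth(self):
        s = _specset(np.full((1, 40), 0.5))
        with pytest.raises(ValueError, match="maximum feasible"):
            decompose_stack(s, "sym8", 12)


class TestBandCorrelations:
    def test_self_correlation_is_one(self, rng):
        x = rng.uniform(0.1, 0.9, size=(20, 64))
        s = _specset(x)
        y = TargetVector(10 + x[:, 7], s.sample_ids)
        profiles = band_correlations(decompose_stack(s, "sym8", 2), y)
        assert profiles[0].r[7] == pytest.approx(1.0, abs=1e-12)

    def test_affine_target_invariance(self, tiny_data):
        s, y = tiny_data[0], tiny_data[1]
        stack = decompose_stack(s, "sym8", 2)
        p1 = band_correlations(stack, y)
        y2 = TargetVector(3.0 * y.values + 1.0, list(y.sample_ids))
        p2 = band_correlations(stack, y2)
        for a, b in zip(p1, p2):
            np.testing.assert_allclose(a.r, b.r, atol=1e-12)

    def test_requires_three_samples(self):
        s = _specset(np.full((2, 64), 0.5) + np.arange(64) * 1e-3)
        y = TargetVector([1.0, 2.0], s.sample_ids)
        with pytest.raises(ValueError, match="3 samples"):
            band_correlations(decompose_stack(s, "sym8", 1), y)

    def test_null_correlations_below_critical_value(self, rng):
        # independent target: |r| should rarely exceed the p<0.01 critical r
        n = 150
        x = rng.uniform(0.1, 0.9, size=(n, 200))
        s = _specset(x)
        y = TargetVector(rng.uniform(7, 19, n), s.sample_ids)
        profiles = band_correlations(decompose_stack(s, "sym8", 1), y)
        frac = np.mean(np.abs(profiles[0].r) > 0.2097)
        assert frac < 0.05  # nominal 1%; generous bound on one draw


class TestOCC:
    def _profiles(self, R, computable=None):
        L, nb = R.shape
        if computable is None:
            computable = np.ones((L, nb), dtype=bool)
        return [
            CorrelationProfile(r=R[k], computable=computable[k], n=50, level=k)
            for k in range(L)
        ]

    def test_argmax_against_brute_force(self, rng):
        x = rng.uniform(0.1, 0.9, size=(4, 64))
        stack = decompose_stack(_specset(x), "sym8", 2)
        R = rng.uniform(-1, 1, size=(3, 64))
        occ = build_occ_osp(stack, self._profiles(R))
        for j in range(64):
            best = max(range(3), key=lambda k: (abs(R[k, j]), -k))
            assert occ.level_map[j] == best
            assert occ.occ_r[j] == R[best, j]
            np.testing.assert_array_equal(
                occ.osp.values[:, j], stack.level(best).values[:, j]
            )

    def test_tie_breaks_to_lowest_level(self, rng):
        x = rng.uniform(0.1, 0.9, size=(3, 64))
        stack = decompose_stack(_specset(x), "sym8", 2)
        R = np.vstack([np.full(64, 0.5), np.full(64, -0.5), np.full(64, 0.5)])
        occ = build_occ_osp(stack, self._profiles(R))
        assert (occ.level_map == 0).all()

    def test_level0_dominant_returns_base(self, rng):
        x = rng.uniform(0.1, 0.9, size=(3, 64))
        stack = decompose_stack(_specset(x), "sym8", 2)
        R = np.vstack([np.full(64, 0.9), np.full(64, 0.1), np.full(64, 0.2)])
        occ = build_occ_osp(stack, self._profiles(R))
        assert (occ.level_map == 0).all()
        np.testing.assert_array_equal(occ.osp.values, stack.base.values)

    def test_occ_dominates_every_fixed_level(self, tiny_data):
        s, y = tiny_data[0], tiny_data[1]
        stack = decompose_stack(s, "sym8", 2)
        profiles = band_correlations(stack, y)
        occ = build_occ_osp(stack, profiles)
        for p in profiles:
            assert np.mean(np.abs(occ.occ_r)) >= np.mean(np.abs(p.r)) - 1e-12
            assert (np.abs(occ.occ_r) >= np.abs(p.r) - 1e-12).all()


class TestApplyLevelMap:
    def test_training_idempotence(self, tiny_data):
        s, y = tiny_data[0], tiny_data[1]
        stack = decompose_stack(s, "sym8", 2)
        occ = build_occ_osp(stack, band_correlations(stack, y))
        re = apply_level_map(s, occ.level_map, "sym8", 2)
        np.testing.assert_array_equal(re.values, occ.osp.values)

    def test_zero_map_is_identity(self, tiny_data):
        s = tiny_data[0]
        out = apply_level_map(s, np.zeros(s.n_bands, dtype=int))
        np.testing.assert_array_equal(out.values, s.values)

    def test_constant_map_equals_direct_smoothing(self, tiny_data):
        s = tiny_data[0]
        out = apply_level_map(s, np.full(s.n_bands, 2), "sym8", 2)
        np.testing.assert_array_equal(out.values, smooth_to_level(s.values, 2, "sym8"))

    def test_grid_mismatch_rejected(self, tiny_data):
        with pytest.raises(ValueError, match="bands"):
            apply_level_map(tiny_data[0], np.zeros(10, dtype=int))


class TestLCMDenoiser:
    def test_matches_functional_path(self, tiny_data):
        s, y = tiny_data[0], tiny_data[1]
        yv = y.aligned_to(s)
        den = LCMDenoiser(max_level=2).fit(s.values, yv)
        stack = decompose_stack(s, "sym8", 2)
        occ = build_occ_osp(stack, band_correlations(stack, y))
        np.testing.assert_array_equal(den.level_map_, occ.level_map)
        np.testing.assert_array_equal(den.transform(s.values), occ.osp.values)

    def test_noise_scale_recovered_at_signal_bands(self, study_data):
        spectra, targets, _, gt = study_data
        den = LCMDenoiser().fit(spectra.values, targets.aligned_to(spectra))
        sb, k = gt["signal_bands"], gt["noise_scale"]
        assert np.mean(den.level_map_[sb] >= k) >= 0.9

    def test_sharp_bands_kept_at_low_levels(self, study_data):
        # informative narrow features must not be over-smoothed away
        spectra, targets, _, gt = study_data
        from lcmcs.transforms import apply_transform

        t = apply_transform(spectra, "FDR_LOG_INV")
        den = LCMDenoiser().fit(t.values, targets.aligned_to(spectra))
        assert np.median(den.level_map_[gt["sharp_bands"]]) <= 3
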