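import numpy as np
import pytest

from theranost import (
    PreprocessConfig,
    Spectrum,
    SpectrumCollection,
    StageError,
    ValidationError,
    asls_baseline,
    crop,
    despike,
    mean_center,
    normalize_auc,
    preprocess_collection,
    savgol,
    whittaker_baseline,
)
from theranost.preprocess import find_spikes
from theranost.synthetic import RamanGenConfig, class_template, generate_spectrum


def dense_weighted_whittaker_oracle(y, w, lam):
    """Independent dense-matrix solve of the weighted Whittaker normal
    equations (W + lam D'D) z = W y with explicit second-difference D.

    One refinement solve keeps the dense solution accurate at large lam,
    where the normal equations are badly conditioned.
    """
    y = np.asarray(y, float)
    n = len(y)
    D = np.diff(np.eye(n), 2, axis=0)
    A = np.diag(w) + lam * D.T @ D
    z = np.linalg.solve(A, w * y)
    for _ in range(3):  # refinement; residual evaluated without cancellation
        z = z + np.linalg.solve(A, stable_whittaker_residual(y, w, lam, z))
    return z


def stable_whittaker_residual(y, w, lam, z):
    """w*y - (W + lam D'D) z evaluated as lam*D'(Dz) in extended precision,
    avoiding the catastrophic cancellation of forming the matrix product."""
    zl = z.astype(np.longdouble)
    d2 = zl[2:] - 2.0 * zl[1:-1] + zl[:-2]
    back = np.zeros_like(zl)
    back[2:] += d2
    back[1:-1] -= 2.0 * d2
    back[:-2] += d2
    r = w * y.astype(np.longdouble) - (w * zl + np.longdouble(lam) * back)
    return r.astype(float)


class TestCrop:
    def test_fingerprint_crop_channel_count(self):
        s = Spectrum(axis=np.arange(400.0, 2001.0), intensity=np.ones(1601))
        out = crop(s, 510.0, 1825.0)
        assert len(out) == 1316
        assert out.axis[0] == 510.0 and out.axis[-1] == 1825.0

    def test_lo_below_axis_min_keeps_low_end(self):
        s = Spectrum(axis=np.arange(400.0, 500.0), intensity=np.ones(100))
        out = crop(s, 100.0, 450.0)
        assert out.axis[0] == 400.0

    def test_empty_window_errors(self):
        s = Spectrum(axis=np.arange(400.0, 1826.0), intensity=np.ones(1426))
        with pytest.raises(ValidationError, match="excludes all channels"):
            crop(s, 2000.0, 2100.0)

    def test_metadata_copied(self):
        s = Spectrum(axis=np.arange(400.0, 500.0), intensity=np.ones(100),
                     meta={"subject_id": "m1"})
        assert crop(s, 420, 480).meta["subject_id"] == "m1"


class TestWhittakerBaseline:
    def test_constant_signal_is_its_own_baseline(self):
        s = Spectrum(axis=np.arange(50.0), intensity=np.full(50, 7.3))
        base, corrected = whittaker_baseline(s)
        np.testing.assert_allclose(base.intensity, 7.3, atol=1e-8)
        np.testing.assert_allclose(corrected.intensity, 0.0, atol=1e-8)

    def test_linear_ramp_in_penalty_null_space(self):
        x = np.arange(80.0)
        s = Spectrum(axis=x, intensity=3.0 + 0.5 * x)
        base, corrected = whittaker_baseline(s)
        # exact in theory; tolerance covers conditioning at lam = 1e5
        np.testing.assert_allclose(base.intensity, s.intensity, atol=1e-6)
        np.testing.assert_allclose(corrected.intensity, 0.0, atol=1e-6)

    @pytest.mark.parametrize("n,lam,seed", [(200, 1e5, 0), (350, 1e5, 1),
                                            (120, 10.0, 2), (500, 1e3, 3)])
    def test_matches_dense_oracle(self, n, lam, seed):
        """The banded solve agrees with an independent dense solve of the
        same asymmetric normal equations (identical final weights)."""
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, n).cumsum() + 100
        z, w = asls_baseline(y, lam=lam, asym_p=1e-3, iters=10,
                             return_weights=True)
        z_oracle = dense_weighted_whittaker_oracle(y, w, lam)
        scale = np.max(np.abs(z_oracle))
        assert np.max(np.abs(z - z_oracle)) / scale <= 1e-8

    def test_large_lambda_limit_is_ols_line(self):
        rng = np.random.default_rng(4)
        x = np.arange(150.0)
        y = 5 + 0.2 * x + np.sin(x / 7) + rng.normal(0, 0.3, 150)
        z = asls_baseline(y, lam=1e12, asym_p=0.5, iters=1)
        A = np.vstack([np.ones_like(x), x]).T
        line = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.max(np.abs(z - line)) <= 1e-4 * (y.max() - y.min())

    def test_small_lambda_limit_is_identity(self):
        rng = np.random.default_rng(5)
        y = rng.normal(10, 2, 90)
        z = asls_baseline(y, lam=1e-8, asym_p=0.5, iters=1)
        assert np.max(np.abs(z - y)) <= 1e-6

    def test_too_few_channels(self):
        with pytest.raises(ValidationError, match="at least 4"):
            asls_baseline(np.array([1.0, 2.0, 3.0]))


class TestDespike:
    @staticmethod
    def _gentle():
        """Spike-free spectrum whose first differences vary slowly relative
        to their own spread, so no channel is anomalous."""
        x = np.arange(1500.0)
        return Spectrum(axis=x, intensity=100.0 + 10.0 * np.sin(x / 40.0))

    def test_single_spike_locality(self):
        base = self._gentle()
        y = base.intensity.copy()
        y[800] += 5000.0
        out = despike(base.copy_with(intensity=y), 8.0)
        changed = np.flatnonzero(out.intensity != y)
        assert list(changed) == [800]
        # interpolated value close to the underlying smooth signal
        assert abs(out.intensity[800] - base.intensity[800]) < 1.0

    def test_spike_free_spectrum_untouched(self):
        base = self._gentle()
        out = despike(base, 8.0)
        assert np.array_equal(out.intensity, base.intensity)

    def test_adjacent_spikes_flagged_as_block(self):
        base = self._gentle()
        y = base.intensity.copy()
        y[600] += 4000.0
        y[601] += 5200.0
        out = despike(base.copy_with(intensity=y), 8.0)
        changed = set(np.flatnonzero(out.intensity != y))
        assert changed == {600, 601}

    def test_flags_match_bruteforce_oracle(self):
        """Brute-force re-derivation of the flag set: explicit python loops
        over the z-scored diff series with the same pairing rule."""
        y = self._gentle().intensity.copy()
        for ch, amp in [(200, 3000.0), (900, -2500.0), (1200, 6000.0)]:
            y[ch] += amp
        flags = find_spikes(y, 8.0)

        d = np.diff(y)
        med = float(np.median(d))
        dev = np.abs(d - med)
        mad = float(np.median(dev))
        z = 0.6745 * dev / mad
        hot = [j for j in range(len(d)) if z[j] > 8.0]
        expected = np.zeros(len(y), bool)
        used = set()
        for a, j in enumerate(hot):
            if a in used:
                continue
            sj = d[j] >= med
            for b in range(a + 1, len(hot)):
                k = hot[b]
                if k - j > 4:
                    break
                if b in used:
                    continue
                if (d[k] >= med) != sj:
                    expected[j + 1:k + 1] = True
                    used.update((a, b))
                    break
        hotset = set(hot)
        for a, j in enumerate(hot):
            if a not in used and (j - 1) not in hotset and (j + 1) not in hotset:
                expected[j] = expected[j + 1] = True
        np.testing.assert_array_equal(flags, expected)
        assert flags[200] and flags[900] and flags[1200]

    def test_majority_flagged_is_degenerate(self):
        # wide spike blocks covering most channels: interpolation meaningless
        y = np.zeros(20)
        for start in (1, 6, 11, 16):
            y[start:start + 3] = 1e6
        with pytest.raises(ValidationError, match="degenerate"):
            despike(Spectrum(axis=np.arange(20.0), intensity=y), 0.5)


class TestSavgol:
    def test_affine_signal_reproduced_exactly(self):
        x = np.arange(200.0)
        s = Spectrum(axis=x, intensity=4.0 - 0.3 * x)
        out = savgol(s, order=1, frame=7)
        np.testing.assert_allclose(out.intensity, s.intensity, atol=1e-10)

    def test_constant_signal_unchanged(self):
        s = Spectrum(axis=np.arange(50.0), intensity=np.full(50, 2.5))
        np.testing.assert_allclose(savgol(s).intensity, 2.5, atol=1e-12)

    def test_interior_matches_windowed_ols_oracle(self, rng):
        y = rng.normal(0, 1, 60)
        s = Spectrum(axis=np.arange(60.0), intensity=y)
        out = savgol(s, order=1, frame=7)
        for i in (10, 30, 49):
            idx = np.arange(i - 3, i + 4)
            A = np.vstack([np.ones(7), idx]).T
            coef = np.linalg.lstsq(A, y[idx], rcond=None)[0]
            assert abs(out.intensity[i] - (coef[0] + coef[1] * i)) < 1e-10

    def test_edges_match_truncated_window_ols(self, rng):
        y = rng.normal(0, 1, 40)
        s = Spectrum(axis=np.arange(40.0), intensity=y)
        out = savgol(s, order=1, frame=7)
        for i in (0, 1, 2):
            idx = np.arange(0, i + 4)
            A = np.vstack([np.ones(idx.size), idx]).T
            coef = np.linalg.lstsq(A, y[idx], rcond=None)[0]
            assert abs(out.intensity[i] - (coef[0] + coef[1] * i)) < 1e-10

    def test_frame_longer_than_spectrum_errors(self):
        s = Spectrum(axis=np.arange(8.0), intensity=np.ones(8))
        with pytest.raises(ValidationError):
            savgol(s, order=1, frame=9)


class TestNormalizeAuc:
    def test_area_one_after(self, smooth_spectrum):
        out = normalize_auc(smooth_spectrum)
        assert abs(np.trapezoid(out.intensity, out.axis) - 1.0) <= 1e-12

    def test_idempotent(self, smooth_spectrum):
        once = normalize_auc(smooth_spectrum)
        twice = normalize_auc(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-12)

    def test_scale_invariant(self, smooth_spectrum):
        scaled = smooth_spectrum.copy_with(intensity=7.0 * smooth_spectrum.intensity)
        np.testing.assert_allclose(
            normalize_auc(scaled).intensity,
            normalize_auc(smooth_spectrum).intensity,
            atol=1e-12,
        )

    def test_nonpositive_area_errors(self):
        s = Spectrum(axis=np.arange(10.0), intensity=np.zeros(10))
        with pytest.raises(ValidationError, match="nonpositive"):
            normalize_auc(s)


class TestMeanCenter:
    def test_identical_spectra_center_to_zero(self):
        x = np.arange(20.0)
        s = Spectrum(axis=x, intensity=np.sin(x))
        coll = SpectrumCollection([s.copy_with(), s.copy_with()])
        centered, mean = mean_center(coll)
        for c in centered:
            np.testing.assert_allclose(c.intensity, 0.0, atol=1e-12)
        np.testing.assert_allclose(mean.intensity, np.sin(x), atol=1e-12)

    def test_column_sums_zero_and_reconstruction(self, small_collection):
        centered, mean = mean_center(small_collection)
        X = centered.to_matrix()
        np.testing.assert_allclose(X.sum(axis=0), 0.0, atol=1e-10)
        for orig, c in zip(small_collection, centered):
            np.testing.assert_allclose(c.intensity + mean.intensity,
                                       orig.intensity, atol=1e-12)

    def test_heterogeneous_axes_error(self):
        a = Spectrum(axis=np.arange(10.0), intensity=np.ones(10))
        b = Spectrum(axis=np.arange(10.0) + 0.5, intensity=np.ones(10))
        with pytest.raises(ValidationError, match="shared axis"):
            mean_center(SpectrumCollection([a, b]))


class TestFullChain:
    def test_peak_positions_and_baseline_removal(self):
        """Generator ground truth: the chain must keep the band positions,
        remove the injected spike, and reproduce the noiseless peaks-only
        template to within a few percent of the tallest band."""
        cfg = RamanGenConfig(seed=3, spike_rate=1.0)  # force a cosmic spike
        rng = np.random.default_rng(3)
        spec, truth = generate_spectrum("control", cfg, rng)
        pre = PreprocessConfig(normalize="none")
        out = preprocess_collection(SpectrumCollection([spec]), pre)[0]
        # strongest channel near the strongest template band (1445)
        assert abs(out.axis[np.argmax(out.intensity)] - 1445.0) <= 5.0
        # residual against the known template, on the template's own scale
        keep = (cfg.axis >= pre.crop_lo) & (cfg.axis <= pre.crop_hi)
        template = truth["template"][keep]
        resid = out.intensity - template
        assert np.sqrt(np.mean(resid**2)) < 0.05 * template.max()
        # the cosmic spike is gone: its channel sits near the template too
        for ch in truth["spike_channels"]:
            idx = np.flatnonzero(np.isclose(out.axis, cfg.axis[ch]))
            if idx.size:  # spike may fall outside the crop window
                assert abs(resid[idx[0]]) < 0.15 * template.max()

    def test_peak_area_ratio_recovered(self, default_gen_config):
        """Area ratio of the 1655/1445 bands survives the chain within 10%."""
        rng = np.random.default_rng(11)
        cfg = default_gen_config
        spec, truth = generate_spectrum("tumour", cfg, rng)
        out = preprocess_collection(SpectrumCollection([spec]))[0]

        def band_area(x, y, c):
            m = (x >= c - 30) & (x <= c + 30)
            return np.trapezoid(y[m], x[m])

        template = truth["template"]
        x0 = cfg.axis
        truth_ratio = band_area(x0, template, 1655) / band_area(x0, template, 1445)
        got_ratio = (band_area(out.axis, out.intensity, 1655)
                     / band_area(out.axis, out.intensity, 1445))
        assert abs(got_ratio - truth_ratio) / truth_ratio < 0.10

    def test_normalize_none_honoured(self, small_collection):
        cfg = PreprocessConfig(normalize="none")
        out = preprocess_collection(small_collection, cfg)
        areas = [np.trapezoid(s.intensity, s.axis) for s in out]
        assert not np.allclose(areas, 1.0)

    def test_empty_collection_passes_through(self):
        out = preprocess_collection(SpectrumCollection([]))
        assert len(out) == 0

    def test_stage_error_names_stage(self):
        s = Spectrum(axis=np.arange(400.0, 500.0), intensity=np.ones(100))
        cfg = PreprocessConfig(crop_lo=1900.0, crop_hi=1950.0)
        with pytest.raises(StageError, match="crop"):
            preprocess_collection(SpectrumCollection([s]), cfg)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            PreprocessConfig(crop_lo=1000, crop_hi=500)
        with pytest.raises(ValidationError):
            PreprocessConfig(sg_frame=6)
        with pytest.raises(ValidationError):
            PreprocessConfig(asym_p=1.5)
        with pytest.raises(ValidationError):
            PreprocessConfig(lam=-1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = PreprocessConfig(lam=42.0, sg_frame=9)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = PreprocessConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
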