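"""Welch PSD, relative band powers, differential entropy, and the two
derived feature containers."""

import numpy as np
import pytest

from frontaleeg.features import (
    DEFAULT_BANDS,
    RATIO_DEFS,
    compute_bundles,
    differential_entropy,
    global_vector,
    per_channel_map,
    relative_band_powers,
    welch_psd,
)

FS = 250.0
L = 3840


def _tone(freq, L=L, fs=FS, amp=1.0):
    t = np.arange(L) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestWelch:
    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(L)
        freqs, psd = welch_psd(x, FS)
        df = freqs[1] - freqs[0]
        assert df == pytest.approx(0.5)
        assert np.sum(psd) * df == pytest.approx(np.var(x), rel=0.05)

    def test_tone_concentrates_at_10hz(self):
        freqs, psd = welch_psd(_tone(10.0), FS)
        assert freqs[np.argmax(psd)] == pytest.approx(10.0)
        inband = (freqs >= 9) & (freqs <= 11)
        assert psd[inband].sum() / psd.sum() > 0.99

    def test_constant_signal_zero_psd(self):
        _, psd = welch_psd(np.full(L, 3.7), FS)
        np.testing.assert_allclose(psd, 0.0, atol=1e-20)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            welch_psd(np.zeros(499), FS)

    def test_nonnegative(self, rng):
        _, psd = welch_psd(rng.standard_normal(L), FS)
        assert np.all(psd >= 0)


class TestRelativeBandPowers:
    def test_tone_in_alpha(self):
        freqs, psd = welch_psd(_tone(10.0), FS)
        rel = relative_band_powers(freqs, psd)
        assert rel[DEFAULT_BANDS.index("alpha")] > 0.99
        assert np.all(np.delete(rel, DEFAULT_BANDS.index("alpha")) < 0.01)

    def test_sum_to_one(self, rng):
        freqs, psd = welch_psd(rng.standard_normal(L), FS)
        assert relative_band_powers(freqs, psd).sum() == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_bandwidth_fractions(self, rng):
        """Flat spectrum: each band's share approaches its bin-count share
        of the 0.5-100 Hz grid (theta ~ 4/99.5 ~ 0.040)."""
        acc = np.zeros(7)
        n_avg = 40
        for _ in range(n_avg):
            freqs, psd = welch_psd(rng.standard_normal(L), FS)
            acc += relative_band_powers(freqs, psd)
        acc /= n_avg
        df = 0.5
        n_bins = np.array(
            [
                np.sum((freqs >= lo) & (freqs < hi)) if name != "gamma_high"
                else np.sum((freqs >= lo) & (freqs <= 100.0))
                for name, lo, hi in DEFAULT_BANDS.bands
            ]
        )
        expected = n_bins / n_bins.sum()
        assert expected[DEFAULT_BANDS.index("theta")] == pytest.approx(4 / 99.5, abs=2e-3)
        np.testing.assert_allclose(acc, expected, rtol=0.12)

    def test_zero_power_rejected(self):
        freqs = np.arange(0, 125.5, 0.5)
        with pytest.raises(ValueError, match="QC"):
            relative_band_powers(freqs, np.zeros_like(freqs))


class TestDifferentialEntropy:
    UNIT = 0.5 * np.log(2 * np.pi * np.e)

    def test_unit_variance_closed_form(self, rng):
        x = rng.standard_normal(100000)
        x = (x - x.mean()) / x.std()
        assert differential_entropy(x) == pytest.approx(self.UNIT, abs=1e-9)

    def test_log_linearity(self, rng):
        x = rng.standard_normal(5000)
        x = (x - x.mean()) / x.std()
        assert differential_entropy(np.e * x) == pytest.approx(
            differential_entropy(x) + 1.0, abs=1e-9
        )

    def test_matches_formula_oracle(self, rng):
        x = rng.standard_normal(3840) * 1.7 + 0.3
        assert differential_entropy(x) == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e * np.var(x)), abs=1e-12
        )

    def test_monotone_in_variance(self, rng):
        x = rng.standard_normal(3840)
        des = [differential_entropy(s * x) for s in (0.5, 1.0, 2.0, 4.0)]
        assert des == sorted(des)

    def test_degenerate_floored(self):
        assert np.isfinite(differential_entropy(np.zeros(100)))


class TestPerChannelMap:
    def test_identical_channels_identical_rows(self, rng):
        ch = rng.standard_normal(L)
        m = per_channel_map(np.tile(ch[:, None], (1, 3)), FS)
        assert m.shape == (3, 8)
        np.testing.assert_array_equal(m[0], m[1])
        np.testing.assert_array_equal(m[0], m[2])

    def test_row_sums(self, rng):
        m = per_channel_map(rng.standard_normal((L, 3)), FS)
        np.testing.assert_allclose(m[:, :7].sum(axis=1), 1.0, atol=1e-12)

    def test_theta_dominant_window(self, rng):
        w = np.stack([_tone(6.0) + 0.05 * rng.standard_normal(L) for _ in range(3)], axis=1)
        m = per_channel_map(w, FS)
        assert np.all(np.argmax(m[:, :7], axis=1) == DEFAULT_BANDS.index("theta"))

    def test_deterministic(self, rng):
        w = rng.standard_normal((L, 3))
        np.testing.assert_array_equal(per_channel_map(w, FS), per_channel_map(w, FS))


class TestGlobalVector:
    def test_symmetric_signal_zero_skew(self):
        w = np.stack([_tone(10.0), _tone(6.0), _tone(21.0)], axis=1)
        rel = per_channel_map(w, FS)[:, :7]
        g = global_vector(w, rel)
        assert g.shape == (17,)
        skews = g[[2, 6, 10]]
        # tones are symmetric up to the fractional final cycle in the window
        np.testing.assert_allclose(skews, 0.0, atol=5e-3)

    def test_identity_ratio(self):
        rel = np.tile(np.array([[0.2, 0.1, 0.2, 0.1, 0.2, 0.1, 0.1]]), (3, 1))
        g = global_vector(np.random.default_rng(0).standard_normal((L, 3)), rel)
        # delta/gamma_low = 0.2/0.2 = 1
        assert g[12] == pytest.approx(1.0)

    def test_moments_match_bruteforce(self, rng):
        w = rng.standard_normal((L, 3)) * 1.4 + 0.2
        rel = per_channel_map(w, FS)[:, :7]
        g = global_vector(w, rel)
        for ch in range(3):
            x = w[:, ch]
            mu = x.mean()
            sd = np.sqrt(np.mean((x - mu) ** 2))
            skew = np.mean((x - mu) ** 3) / sd**3
            kurt = np.mean((x - mu) ** 4) / sd**4  # Pearson, non-excess
            np.testing.assert_allclose(g[4 * ch : 4 * ch + 4], [mu, sd, skew, kurt],
                                       atol=1e-10)

    def test_ratio_order(self, rng):
        w = rng.standard_normal((L, 3))
        rel = per_channel_map(w, FS)[:, :7]
        g = global_vector(w, rel)
        avg = rel.mean(axis=0)
        for j, (a, b) in enumerate(RATIO_DEFS):
            assert g[12 + j] == pytest.approx(
                avg[DEFAULT_BANDS.index(a)] / avg[DEFAULT_BANDS.index(b)]
            )


class TestBundles:
    def test_compute_bundles_shapes(self, rng):
        from frontaleeg.io_formats import HC, Recording
        from frontaleeg.preprocessing import prepare_windows

        rec = Recording(subject_id="S1", label=HC, fs=FS,
                        data=rng.standard_normal((22500, 3)))
        ws, _, _ = prepare_windows([rec], L=3840, p=50)
        b = compute_bundles(ws)
        assert b.raw.shape == (10, 3840, 3)
        assert b.maps.shape == (10, 3, 8)
        assert b.glob.shape == (10, 17)

    def test_export_round_trip(self, rng, tmp_path):
        import pandas as pd

        from frontaleeg.io_formats import HC, Recording
        from frontaleeg.preprocessing import prepare_windows

        rec = Recording(subject_id="S1", label=HC, fs=FS,
                        data=rng.standard_normal((8000, 3)))
        ws, _, _ = prepare_windows([rec], L=3840, p=50)
        b = compute_bundles(ws)
        from frontaleeg.features import export_feature_table

        path = tmp_path / "features.csv"
        export_feature_table(b, path)
        df = pd.read_csv(path)
        assert df.shape == (b.n, 2 + 24 + 17)
        np.testing.assert_allclose(
            df.iloc[:, 2:26].to_numpy(), b.maps.reshape(b.n, 24)
        )
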