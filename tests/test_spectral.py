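"""Spectral estimators against brute-force and scipy oracles."""

import numpy as np
import pytest
import scipy.signal
from hypothesis import given
from hypothesis import strategies as st

import statecoh as sc
from statecoh.spectral import SpectralConfig, _windowed_segments


@pytest.mark.parametrize(
    "n_nodes, expected",
    [(2, 1), (10, 45), (80, 3160)],
)
def test_enumerate_pairs_counts(n_nodes, expected):
    pairs = sc.enumerate_pairs(n_nodes)
    brute = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i < j]
    assert len(pairs) == expected
    assert pairs == sorted(set(brute))
    assert all(i < j for i, j in pairs)


def test_enumerate_pairs_rejects_single_node():
    with pytest.raises(ValueError):
        sc.enumerate_pairs(1)


class TestAnalysisBins:
    def test_default_grid_has_51_bins(self):
        bins = sc.analysis_bins(SpectralConfig())
        assert len(bins) == 51
        ks = [k for k, _ in bins]
        assert ks == list(range(4, 55))
        assert bins[0][1] == pytest.approx(4.6875)
        assert bins[-1][1] == pytest.approx(63.28125)

    def test_full_one_sided_spectrum(self):
        bins = sc.analysis_bins(SpectralConfig(f_min=0, f_max=150))
        assert len(bins) == 129

    def test_integer_frequency_grid(self):
        bins = sc.analysis_bins(SpectralConfig(fs=256, f_min=4, f_max=64))
        assert len(bins) == 61
        assert [f for _, f in bins] == list(range(4, 65))

    def test_matches_brute_force_enumeration(self):
        cfg = SpectralConfig()
        brute = [
            (k, k * cfg.fs / cfg.n_fft)
            for k in range(cfg.n_fft // 2 + 1)
            if cfg.f_min <= k * cfg.fs / cfg.n_fft <= cfg.f_max
        ]
        assert sc.analysis_bins(cfg) == brute


class TestSegmentStarts:
    @pytest.mark.parametrize(
        "n, n_fft, hop, expected",
        [(1050, 256, 150, 6), (256, 256, 150, 1), (108000, 256, 150, 719)],
    )
    def test_counts(self, n, n_fft, hop, expected):
        starts = sc.segment_starts(n, n_fft, hop)
        assert len(starts) == expected
        assert starts[0] == 0 and starts[-1] <= n - n_fft

    def test_too_short_record_raises(self):
        with pytest.raises(ValueError):
            sc.segment_starts(200, 256, 150)

    @given(
        n=st.integers(min_value=16, max_value=5000),
        n_fft=st.integers(min_value=2, max_value=512),
        hop=st.integers(min_value=1, max_value=300),
    )
    def test_matches_brute_force(self, n, n_fft, hop):
        if n < n_fft:
            return
        brute = [s for s in range(0, n, hop) if s + n_fft <= n]
        # brute force above walks the hop grid and keeps full segments
        got = sc.segment_starts(n, n_fft, hop).tolist()
        assert got == brute


class TestSegmentSpectra:
    def test_agrees_with_naive_dft(self):
        cfg = SpectralConfig(analysis_duration=256 / 300)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)
        spec = sc.segment_spectra(x, cfg)
        assert spec.shape == (1, 51)
        seg = x - x.mean()
        seg = seg * cfg.taper()
        n = np.arange(256)
        for col, (k, _) in enumerate(sc.analysis_bins(cfg)):
            naive = np.sum(seg * np.exp(-2j * np.pi * k * n / 256))
            assert abs(spec[0, col] - naive) <= 1e-9 * abs(naive)

    def test_sinusoid_peaks_at_its_bin(self):
        cfg = SpectralConfig(analysis_duration=10.0)
        t = np.arange(3000) / cfg.fs
        k = 20  # exact bin: 20 * 300 / 256 Hz
        x = np.sin(2 * np.pi * (k * cfg.fs / cfg.n_fft) * t)
        spec = np.abs(sc.segment_spectra(x, cfg))
        bin_idx = [i for i, (kk, _) in enumerate(sc.analysis_bins(cfg)) if kk == k][0]
        assert (spec.argmax(axis=1) == bin_idx).all()

    def test_linearity(self):
        cfg = SpectralConfig(analysis_duration=2.0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(600)
        np.testing.assert_allclose(
            sc.segment_spectra(3.5 * x, cfg), 3.5 * sc.segment_spectra(x, cfg)
        )

    def test_rejects_non_finite(self):
        cfg = SpectralConfig(analysis_duration=2.0)
        x = np.zeros(600)
        x[10] = np.nan
        with pytest.raises(ValueError):
            sc.segment_spectra(x, cfg)


class TestCoherence:
    cfg = SpectralConfig(analysis_duration=10.0)

    def test_identical_signals_give_unity(self):
        x = np.random.default_rng(2).standard_normal(3000)
        c = sc.coherence(x, x.copy(), self.cfg)
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_scale_and_offset_invariance(self):
        x = np.random.default_rng(3).standard_normal(3000)
        np.testing.assert_allclose(
            sc.coherence(x, 2 * x + 7.0, self.cfg), 1.0, atol=1e-10
        )

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 3000))
        cxy = sc.coherence(x, y, self.cfg)
        assert ((cxy >= 0) & (cxy <= 1)).all()
        np.testing.assert_array_equal(cxy, sc.coherence(y, x, self.cfg))

    def test_zero_power_flagged_missing(self):
        x = np.zeros(3000)
        y = np.random.default_rng(5).standard_normal(3000)
        assert np.isnan(sc.coherence(x, y, self.cfg)).all()

    def test_white_noise_bias_matches_scipy(self):
        """Finite-segment bias of the estimator vs scipy's Welch coherence.

        Independent white noise has true coherence 0; the estimator is
        positively biased at finite segment count.  The same 719-segment
        scheme in scipy.signal.coherence must report the same mean bias.
        """
        cfg = SpectralConfig(analysis_duration=107956 / 300)
        ks = [k for k, _ in sc.analysis_bins(cfg)]
        ours, scipys = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x, y = rng.standard_normal((2, 107956))
            ours.append(sc.coherence(x, y, cfg).mean())
            _, c = scipy.signal.coherence(
                x, y, fs=300, window="hann", nperseg=256, noverlap=106,
                detrend="constant",
            )
            scipys.append(c[ks].mean())
        ours, scipys = np.mean(ours), np.mean(scipys)
        assert ours > 0  # positive bias at finite L
        assert abs(ours - scipys) <= 0.10 * scipys


class TestPowerSpectrum:
    cfg = SpectralConfig(analysis_duration=10.0)

    def test_amplitude_doubling_quadruples_power(self):
        x = np.random.default_rng(6).standard_normal(3000)
        np.testing.assert_allclose(
            sc.power_spectrum(2 * x, self.cfg), 4 * sc.power_spectrum(x, self.cfg)
        )

    def test_white_noise_is_flat_at_719_segments(self):
        cfg = SpectralConfig(analysis_duration=107956 / 300)
        x = np.random.default_rng(7).standard_normal(107956)
        p = sc.power_spectrum(x, cfg)
        assert p.max() / p.min() < 2.0

    def test_component_rescaling_moves_in_band_power_by_18_7_percent(self):
        # amplitude x sqrt(1.187) must scale measured band power by 1.187
        cfg = SpectralConfig(analysis_duration=60.0)
        comp = sc.band_limited_component(18000, 300.0, (32.0, 64.0), rng=8)
        p0 = sc.power_spectrum(comp, cfg)
        p1 = sc.power_spectrum(np.sqrt(1.187) * comp, cfg)
        freqs = np.array([f for _, f in sc.analysis_bins(cfg)])
        gamma = (freqs >= 32) & (freqs <= 64)
        increase = 100 * (p1[gamma].sum() - p0[gamma].sum()) / p0[gamma].sum()
        assert increase == pytest.approx(18.7, abs=0.05)


class TestBuildTensors:
    def test_minimal_shapes(self):
        rng = np.random.default_rng(9)
        ds = sc.VirtualElectrodeDataset(
            rng.standard_normal((1, 2, 2, 600)), ["rest", "test"], ["s1"], [0, 1], 300.0
        )
        coh, power = sc.build_tensors(ds, SpectralConfig(analysis_duration=2.0))
        assert coh.shape == (2, 1, 51, 1)
        assert power.shape == (2, 1, 51, 2)
        assert (power.values >= 0).all()

    def test_full_scale_axis_shapes(self):
        # 80 nodes -> 3160 pairs; one-second blocks keep this light
        rng = np.random.default_rng(10)
        ds = sc.VirtualElectrodeDataset(
            rng.standard_normal((8, 4, 80, 300)),
            ["rest1", "test1", "test2", "rest2"],
            [f"s{i}" for i in range(8)],
            list(range(80)),
            300.0,
        )
        coh, power = sc.build_tensors(ds, SpectralConfig(analysis_duration=1.0))
        assert coh.shape == (4, 8, 51, 3160)
        assert power.shape == (4, 8, 51, 80)

    def test_node_permutation_relabels_pairs_consistently(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal((1, 2, 5, 1200))
        cfg = SpectralConfig(analysis_duration=4.0)
        perm = np.array([3, 0, 4, 1, 2])
        ds1 = sc.VirtualElectrodeDataset(
            base, ["a", "b"], ["s1"], list(range(5)), 300.0
        )
        ds2 = sc.VirtualElectrodeDataset(
            base[:, :, perm], ["a", "b"], ["s1"], list(range(5)), 300.0
        )
        coh1, _ = sc.build_tensors(ds1, cfg)
        coh2, _ = sc.build_tensors(ds2, cfg)
        pairs = sc.enumerate_pairs(5)
        # pair (i,j) in ds2 holds original nodes (perm[i], perm[j])
        inv = {(min(a, b), max(a, b)): idx for idx, (a, b) in enumerate(pairs)}
        for idx2, (i, j) in enumerate(pairs):
            orig = inv[(min(perm[i], perm[j]), max(perm[i], perm[j]))]
            np.testing.assert_allclose(
                coh2.values[:, :, :, idx2], coh1.values[:, :, :, orig]
            )

    def test_short_blocks_need_explicit_truncation(self):
        rng = np.random.default_rng(12)
        ds = sc.VirtualElectrodeDataset(
            rng.standard_normal((1, 2, 2, 600)), ["a", "b"], ["s1"], [0, 1], 300.0
        )
        with pytest.raises(ValueError, match="analysis_duration"):
            sc.build_tensors(ds, SpectralConfig(analysis_duration=10.0))
        coh, _ = sc.build_tensors(
            ds, SpectralConfig(analysis_duration=10.0, truncate_incomplete=True)
        )
        assert coh.shape[0] == 2

    def test_sampling_rate_mismatch_rejected(self):
        rng = np.random.default_rng(13)
        ds = sc.VirtualElectrodeDataset(
            rng.standard_normal((1, 2, 2, 600)), ["a", "b"], ["s1"], [0, 1], 250.0
        )
        with pytest.raises(ValueError, match="Hz"):
            sc.build_tensors(ds, SpectralConfig(analysis_duration=2.0))


def test_windowed_segments_are_demeaned():
    cfg = SpectralConfig(analysis_duration=2.0)
    x = np.random.default_rng(14).standard_normal((1, 600)) + 5.0
    segs = _windowed_segments(x, cfg)
    # de-meaning happens before tapering, so the taper-weighted mean of the
    # raw segment is removed only up to the window shape; verify the raw
    # segments had their means removed by reconstructing one segment
    taper = cfg.taper()
    raw = x[0, :256]
    np.testing.assert_allclose(segs[0, 0], (raw - raw.mean()) * taper)
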