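"""Wavelet transform, smoothing operator, MSWC and coherent-frequency scan."""

import numpy as np
import pytest
from scipy import signal as sps

from vhitwave.coherence import (
    SCALE_DECORRELATION,
    WaveletGrid,
    analytic_morlet_cwt,
    coherent_frequency,
    fourier_factor,
    mswc,
    smooth_spectrum,
    DegenerateInputError,
)

FS = 250.0


@pytest.fixture(scope="module")
def grid():
    return WaveletGrid.default(FS)


@pytest.fixture(scope="module")
def small_grid():
    # coarse, short-signal grid for cheap property checks
    return WaveletGrid.default(FS, f_min=6.0, voices_per_octave=8)


class TestGrid:
    def test_scales_increase_frequencies_decrease(self, grid):
        assert np.all(np.diff(grid.scales) > 0)
        assert np.all(np.diff(grid.frequencies) < 0)

    def test_frequency_coverage(self, grid):
        assert grid.frequencies.max() >= 125.0 - 1e-9
        assert grid.frequencies.min() <= 1.5

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            WaveletGrid(scales=np.array([]))


class TestCwt:
    def test_sinusoid_peaks_at_matching_frequency(self, grid):
        t = np.arange(int(0.7 * FS)) / FS
        x = np.sin(2 * np.pi * 6.0 * t)
        w = analytic_morlet_cwt(x, FS, grid)
        power = np.mean(np.abs(w) ** 2, axis=1)
        f_star = grid.frequencies[np.argmax(power)]
        assert 6.0 * 2 ** (-1 / 12) <= f_star <= 6.0 * 2 ** (1 / 12)

    def test_zero_signal_gives_zero_coefficients(self, grid):
        w = analytic_morlet_cwt(np.zeros(175), FS, grid)
        assert np.all(w == 0)

    def test_linearity(self, grid):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(175)
        wa = analytic_morlet_cwt(3.5 * x, FS, grid)
        wb = 3.5 * analytic_morlet_cwt(x, FS, grid)
        np.testing.assert_allclose(wa, wb, rtol=1e-12, atol=1e-12)

    def test_nan_input_rejected(self, grid):
        x = np.zeros(175)
        x[3] = np.nan
        with pytest.raises(ValueError):
            analytic_morlet_cwt(x, FS, grid)

    def test_short_signal_rejected(self, grid):
        with pytest.raises(ValueError):
            analytic_morlet_cwt(np.ones(16), FS, grid)


def _smooth_oracle(matrix, grid, fs):
    """Direct O(n^2) convolution mirror of the smoothing operator."""
    dt = 1.0 / fs
    n_s, n_t = matrix.shape
    # time: per-scale Gaussian with reflection, truncated at +/- 4 s
    out_t = np.zeros_like(matrix, dtype=complex)
    for i, s in enumerate(grid.scales):
        half = int(np.ceil(4.0 * s / dt))
        m = np.arange(-half, half + 1)
        kern = np.exp(-((m * dt) ** 2) / (2 * s**2))
        pad = min(half, n_t - 1)
        if half > pad:
            kern = kern[half - pad : half + pad + 1]
            half = pad
        kern = kern / kern.sum()
        row = np.pad(matrix[i], pad, mode="reflect")
        for j in range(n_t):
            seg = row[j + pad - half : j + pad + half + 1]
            out_t[i, j] = np.sum(seg * kern)
    # scale: boxcar spanning 0.6 octave with fractional ends, renormalized
    dj = 1.0 / grid.voices_per_octave
    hw = SCALE_DECORRELATION / (2 * dj)
    lo = int(np.floor(hw))
    frac = hw - lo
    offsets = list(range(-lo, lo + 1))
    weights = [1.0] * len(offsets)
    if frac > 0:
        offsets = [-lo - 1] + offsets + [lo + 1]
        weights = [frac] + weights + [frac]
    out = np.zeros_like(out_t)
    for i in range(n_s):
        acc = np.zeros(n_t, dtype=complex)
        norm = 0.0
        for off, wgt in zip(offsets, weights):
            j = i + off
            if 0 <= j < n_s:
                acc += wgt * out_t[j]
                norm += wgt
        out[i] = acc / norm
    return out


class TestSmoothing:
    def test_constant_field_preserved(self, grid):
        m = np.full((grid.n_scales, 175), 3.7)
        out = smooth_spectrum(m, grid, FS)
        np.testing.assert_allclose(out, m, atol=1e-9)

    def test_matches_direct_convolution_oracle(self):
        g = WaveletGrid.default(FS, f_min=20.0)   # 16ish scales
        rng = np.random.default_rng(1)
        m = rng.standard_normal((g.n_scales, 64)) + 1j * rng.standard_normal(
            (g.n_scales, 64)
        )
        ours = smooth_spectrum(m, g, FS)
        oracle = _smooth_oracle(m, g, FS)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_interior_impulse_mass_conserved(self, small_grid):
        m = np.zeros((small_grid.n_scales, 400))
        m[small_grid.n_scales // 2, 200] = 1.0
        out = smooth_spectrum(m, small_grid, FS)
        assert np.sum(out.real) == pytest.approx(1.0, rel=0.02)

    def test_shape_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            smooth_spectrum(np.zeros((3, 10)), grid, FS)


class TestMswc:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(175)
        m = mswc(x, x, FS)
        np.testing.assert_allclose(m.mswc, 1.0, atol=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(175)
        m = mswc(x, 0.8 * x, FS)
        np.testing.assert_allclose(m.mswc, 1.0, atol=1e-6)

    def test_bounded_on_random_pairs(self, small_grid):
        rng = np.random.default_rng(2)
        for _ in range(200):
            x = rng.standard_normal(64)
            y = rng.standard_normal(64)
            m = mswc(x, y, FS, grid=small_grid)
            assert m.mswc.min() >= 0.0
            assert m.mswc.max() <= 1.0 + 1e-9

    def test_degenerate_without_smoothing(self):
        """Eq-level regression: the unsmoothed ratio is identically 1."""
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(175), rng.standard_normal(175)
        m = mswc(x, y, FS, smoothing=False)
        np.testing.assert_allclose(m.mswc, 1.0, atol=1e-9)
        assert mswc(x, y, FS).mswc.min() < 0.9  # smoothing actually applied

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mswc(np.ones(100), np.ones(101), FS)

    def test_all_zero_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            mswc(np.zeros(100), np.zeros(100), FS)

    def test_time_shift_invariance_in_interior(self):
        """Shifting both series by the same sample count leaves interior
        coherence unchanged (away from edges and at scales whose smoothing
        support fits inside the record)."""
        rng = np.random.default_rng(4)
        n, shift = 500, 7
        base_x = np.zeros(n)
        base_y = np.zeros(n)
        core = rng.standard_normal(200)
        resp = 0.8 * core + 0.3 * rng.standard_normal(200)
        base_x[120:320], base_y[120:320] = core, resp
        shifted_x = np.roll(base_x, shift)
        shifted_y = np.roll(base_y, shift)
        grid = WaveletGrid.default(FS, f_min=15.0)
        m0 = mswc(base_x, base_y, FS, grid=grid)
        m1 = mswc(shifted_x, shifted_y, FS, grid=grid)
        # scales with 4 s support << record; central columns
        dt = 1 / FS
        rows = np.flatnonzero(4 * grid.scales / dt < n / 4)
        cols = np.arange(200, 280)
        np.testing.assert_allclose(
            m1.mswc[np.ix_(rows, cols + shift)],
            m0.mswc[np.ix_(rows, cols)],
            atol=1e-6,
        )

    def test_independent_noise_has_low_mean_coherence(self, small_grid):
        """Monte-Carlo null: independent white-noise pairs average well below
        the self-coherence level."""
        rng = np.random.default_rng(5)
        means = [
            mswc(rng.standard_normal(500), rng.standard_normal(500), FS,
                 grid=small_grid).mswc.mean()
            for _ in range(40)
        ]
        assert np.mean(means) < 0.5

    def test_ranking_matches_classical_coherence(self):
        """Frequency-averaged MSWC orders sinusoid+noise pairs like Welch
        magnitude-squared coherence (rank correlation > 0.9)."""
        from vhitwave.features import spearman_rho

        rng = np.random.default_rng(6)
        n = 1000
        t = np.arange(n) / FS
        ours, classical = [], []
        for snr in np.geomspace(0.1, 10.0, 12):
            shared = np.sin(2 * np.pi * 8 * t) + rng.standard_normal(n)
            x = shared + rng.standard_normal(n) / snr
            y = 0.8 * shared + rng.standard_normal(n) / snr
            m = mswc(x, y, FS)
            ours.append(float(m.mswc.mean()))
            f, cxy = sps.coherence(x, y, fs=FS, nperseg=256)
            classical.append(float(np.mean(cxy)))
        assert spearman_rho(ours, classical) > 0.9


class TestCoherentFrequency:
    def test_perfect_coherence_returns_top_of_range(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(175)
        m = mswc(x, 0.98 * x, FS)
        assert m.coherent_frequency == pytest.approx(m.frequencies.max())

    def test_independent_noise_returns_sentinel(self):
        rng = np.random.default_rng(1)
        m = mswc(rng.standard_normal(175), rng.standard_normal(175), FS)
        assert m.coherent_frequency == 0.0

    def test_band_mode_stops_at_first_gap(self, grid):
        from vhitwave.coherence import CoherenceMap, _cone_of_influence

        times = np.arange(175) / FS
        mat = np.zeros((grid.n_scales, 175))
        freqs = grid.frequencies
        mat[freqs <= 5.0] = 0.95            # low band qualifies
        mat[(freqs > 8.0) & (freqs < 12.0)] = 0.95  # detached high band
        cm = CoherenceMap(
            mswc=mat, cross_power=mat, grid=grid, times=times,
            coi=_cone_of_influence(times, grid.omega0),
        )
        band = coherent_frequency(cm, mode="band")
        glob = coherent_frequency(cm, mode="global")
        assert band == pytest.approx(freqs[freqs <= 5.0].max())
        assert glob == pytest.approx(freqs[(freqs > 8.0) & (freqs < 12.0)].max())

    def test_threshold_validation(self):
        rng = np.random.default_rng(2)
        m = mswc(rng.standard_normal(175), rng.standard_normal(175), FS)
        with pytest.raises(ValueError):
            coherent_frequency(m, threshold=0.0)
        with pytest.raises(ValueError):
            coherent_frequency(m, time_window=(10.0, 11.0))

    def test_monotone_degradation_with_noise(self, head_pulse):
        """Mean coherent frequency does not increase as eye noise grows."""
        from vhitwave.synthetic import simulate_eye_response

        noise_levels = [0.0, 5.0, 15.0, 40.0]
        means = []
        for sd in noise_levels:
            vals = []
            for seed in range(25):
                rng = np.random.default_rng(800 + seed)
                head = head_pulse + 1.5 * rng.standard_normal(len(head_pulse))
                eye = simulate_eye_response(
                    head, 0.9, 6.0, noise_sd=sd, sampling_rate=FS, seed=rng
                )
                vals.append(mswc(head, eye, FS).coherent_frequency)
            means.append(np.mean(vals))
        half_voice = 2 ** (1 / 24)
        for lo, hi in zip(means[1:], means[:-1]):
            assert lo <= hi * half_voice
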