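"""Magnitude-squared wavelet coherence (MSWC) and the coherent-frequency statistic.

The analysis follows the standard analytic-Morlet wavelet-coherence
construction: continuous wavelet transforms ``W^X``, ``W^Y`` of the head and
eye velocity series, the cross-wavelet spectrum ``W^XY = W^X (W^Y)*``, and

    R2_n(s) = |S(s^-1 W^XY_n(s))|^2 / ( S(s^-1 |W^X_n(s)|^2) * S(s^-1 |W^Y_n(s)|^2) )

where ``S = S_scale(S_time(.))`` smooths in time (per-scale Gaussian,
``exp(-t^2 / (2 s^2))``) and then across scales (boxcar spanning 0.6 octave,
the Morlet scale-decorrelation length).  Without the smoothing the ratio is
identically 1, so ``S`` is what makes MSWC informative.

The coherent frequency of a record is the highest frequency at which MSWC
stays >= 0.9 at every time of the exam, scanned upward from the lowest
resolvable frequency; 0 is returned as a sentinel when even the lowest
frequency fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.signal import fftconvolve


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal (e.g. all zeros)."""


#: Morlet center frequency (dimensionless); the community default.
OMEGA0 = 6.0
#: scale decorrelation length of the Morlet at omega0 = 6, in octaves
SCALE_DECORRELATION = 0.6


def fourier_factor(omega0: float = OMEGA0) -> float:
    """Wavelength-to-scale conversion: frequency = 1 / (lambda * scale)."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


@dataclass(frozen=True)
class WaveletGrid:
    """Geometric scale grid for the analytic Morlet CWT.

    Scales are strictly increasing; the derived frequencies strictly
    decreasing.  ``voices_per_octave`` controls frequency resolution: one
    "voice" is a factor 2**(1/voices) in frequency.
    """

    scales: np.ndarray
    voices_per_octave: int = 12
    omega0: float = OMEGA0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))
        if self.scales.size == 0:
            raise ValueError("empty scale grid")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")

    @classmethod
    def default(
        cls,
        sampling_rate: float,
        f_min: float = 1.4,
        voices_per_octave: int = 12,
        omega0: float = OMEGA0,
    ) -> "WaveletGrid":
        """Grid from the Nyquist frequency down to ``f_min`` Hz.

        The smallest scale maps to the Nyquist frequency (period of two
        samples), the largest to the full-record period.
        """
        dt = 1.0 / sampling_rate
        lam = fourier_factor(omega0)
        s0 = 2.0 * dt / lam                      # frequency = Nyquist
        s_max = 1.0 / (lam * f_min)
        n_scales = int(np.ceil(voices_per_octave * np.log2(s_max / s0))) + 1
        j = np.arange(n_scales)
        scales = s0 * 2.0 ** (j / voices_per_octave)
        return cls(scales=scales, voices_per_octave=voices_per_octave, omega0=omega0)

    @property
    def frequencies(self) -> np.ndarray:
        """Center frequencies in Hz, one per scale (decreasing)."""
        return 1.0 / (fourier_factor(self.omega0) * self.scales)

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def voice_ratio(self) -> float:
        """Frequency ratio of one voice step."""
        return 2.0 ** (1.0 / self.voices_per_octave)


def analytic_morlet_cwt(
    signal: np.ndarray, sampling_rate: float, grid: WaveletGrid
) -> np.ndarray:
    """Continuous wavelet transform with the analytic Morlet wavelet.

    Computed in the Fourier domain with zero padding (so the record is not
    treated as periodic).  Returns a complex matrix of shape
    ``(grid.n_scales, len(signal))``; row ``i`` corresponds to
    ``grid.scales[i]``.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(x) < 32:
        raise ValueError(f"signal too short ({len(x)} samples; need >= 32)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or Inf")

    n = len(x)
    dt = 1.0 / sampling_rate
    # pad generously so wavelets at the largest scales do not wrap
    n_fft = int(2 ** np.ceil(np.log2(4 * n)))
    xh = np.fft.fft(x, n_fft)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=dt)

    pos = omega > 0
    coeffs = np.empty((grid.n_scales, n), dtype=complex)
    norm_const = np.pi ** (-0.25)
    for i, s in enumerate(grid.scales):
        psi_hat = np.zeros(n_fft)
        psi_hat[pos] = (
            norm_const
            * np.sqrt(2.0 * np.pi * s / dt)
            * np.exp(-0.5 * (s * omega[pos] - grid.omega0) ** 2)
        )
        coeffs[i] = np.fft.ifft(xh * psi_hat)[:n]
    return coeffs


def _time_smooth(matrix: np.ndarray, grid: WaveletGrid, sampling_rate: float) -> np.ndarray:
    """Per-scale Gaussian smoothing along time, reflecting at the edges."""
    dt = 1.0 / sampling_rate
    out = np.empty_like(matrix)
    n = matrix.shape[1]
    for i, s in enumerate(grid.scales):
        half = int(np.ceil(4.0 * s / dt))
        m = np.arange(-half, half + 1) * dt
        kernel = np.exp(-(m**2) / (2.0 * s**2))
        kernel /= kernel.sum()
        pad = min(half, n - 1)
        row = np.pad(matrix[i], pad, mode="reflect")
        if half > pad:
            # kernel wider than the record: clip it to the padded extent
            kernel = kernel[half - pad : half + pad + 1]
            kernel = kernel / kernel.sum()
        out[i] = fftconvolve(row, kernel, mode="same")[pad : pad + n]
    return out


def _scale_smooth(matrix: np.ndarray, grid: WaveletGrid) -> np.ndarray:
    """Boxcar across scales spanning 0.6 octave, with fractional end weights.

    The boxcar is renormalized where it is truncated by the grid edges, so a
    constant field is preserved exactly.
    """
    dj = 1.0 / grid.voices_per_octave
    halfwidth = SCALE_DECORRELATION / (2.0 * dj)   # in voice steps
    lo = int(np.floor(halfwidth))
    frac = halfwidth - lo
    # symmetric kernel over scale indices: full weights plus fractional ends
    weights = np.ones(2 * lo + 1)
    if frac > 0:
        weights = np.concatenate([[frac], weights, [frac]])
    k = len(weights) // 2

    n_s = matrix.shape[0]
    out = np.zeros_like(matrix)
    norm = np.zeros(n_s)
    for off, w in zip(range(-k, k + 1), weights):
        sl_dst = slice(max(0, -off), n_s - max(0, off))
        sl_src = slice(max(0, off), n_s - max(0, -off))
        out[sl_dst] += w * matrix[sl_src]
        norm[np.arange(n_s)[sl_dst]] += w
    return out / norm[:, None]


def smooth_spectrum(
    matrix: np.ndarray, grid: WaveletGrid, sampling_rate: float
) -> np.ndarray:
    """Apply the coherence smoothing operator S = S_scale(S_time(.)).

    Accepts a real or complex (n_scales, n_times) matrix and preserves its
    shape.  Constants are preserved exactly.
    """
    matrix = np.asarray(matrix)
    if matrix.shape[0] != grid.n_scales:
        raise ValueError(
            f"matrix has {matrix.shape[0]} scale rows; grid has {grid.n_scales}"
        )
    if np.iscomplexobj(matrix):
        sm = _time_smooth(matrix.real, grid, sampling_rate) + 1j * _time_smooth(
            matrix.imag, grid, sampling_rate
        )
    else:
        sm = _time_smooth(matrix, grid, sampling_rate)
    return _scale_smooth(sm, grid)


@dataclass
class CoherenceMap:
    """MSWC over time and frequency for one vHIT repeat.

    ``mswc`` has shape (n_scales, n_times); row ``i`` corresponds to
    ``grid.scales[i]`` (so row 0 is the highest frequency).
    """

    mswc: np.ndarray
    cross_power: np.ndarray
    grid: WaveletGrid
    times: np.ndarray
    coi: np.ndarray                      # per-time maximum reliable frequency, Hz
    coherent_frequency: float = 0.0      # Hz; 0 if no band qualifies
    threshold: float = 0.9

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies

    def save(self, directory: str | Path, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = {
            "scales": self.grid.scales.tolist(),
            "voices_per_octave": self.grid.voices_per_octave,
            "omega0": self.grid.omega0,
            "times": self.times.tolist(),
            "coherent_frequency": self.coherent_frequency,
            "threshold": self.threshold,
        }
        with open(directory / f"{stem}.json", "w") as fh:
            json.dump(header, fh)
        np.savetxt(directory / f"{stem}_mswc.csv", self.mswc, delimiter=",")

    @classmethod
    def load(cls, directory: str | Path, stem: str) -> "CoherenceMap":
        directory = Path(directory)
        with open(directory / f"{stem}.json") as fh:
            header = json.load(fh)
        grid = WaveletGrid(
            scales=np.asarray(header["scales"]),
            voices_per_octave=header["voices_per_octave"],
            omega0=header["omega0"],
        )
        m = np.loadtxt(directory / f"{stem}_mswc.csv", delimiter=",", ndmin=2)
        times = np.asarray(header["times"])
        return cls(
            mswc=m,
            cross_power=np.full_like(m, np.nan),
            grid=grid,
            times=times,
            coi=_cone_of_influence(times, grid.omega0),
            coherent_frequency=header["coherent_frequency"],
            threshold=header["threshold"],
        )


def _cone_of_influence(times: np.ndarray, omega0: float) -> np.ndarray:
    """Maximum reliable frequency per time sample (e-folding time sqrt(2) s)."""
    lam = fourier_factor(omega0)
    edge = np.minimum(times - times[0], times[-1] - times)
    with np.errstate(divide="ignore"):
        return np.sqrt(2.0) / (lam * np.maximum(edge, 1e-12))


def mswc(
    head: np.ndarray,
    eye: np.ndarray,
    sampling_rate: float,
    grid: WaveletGrid | None = None,
    threshold: float = 0.9,
    smoothing: bool = True,
) -> CoherenceMap:
    """Magnitude-squared wavelet coherence of paired head/eye series.

    ``smoothing=False`` disables the operator S (for demonstrating that the
    unsmoothed ratio is degenerate); all entries then equal 1.
    """
    head = np.asarray(head, dtype=float)
    eye = np.asarray(eye, dtype=float)
    if head.shape != eye.shape:
        raise ValueError(f"length mismatch: head {head.shape}, eye {eye.shape}")
    if not (np.any(head != 0) and np.any(eye != 0)):
        raise DegenerateInputError("all-zero input series")
    if grid is None:
        grid = WaveletGrid.default(sampling_rate)

    wx = analytic_morlet_cwt(head, sampling_rate, grid)
    wy = analytic_morlet_cwt(eye, sampling_rate, grid)
    inv_s = 1.0 / grid.scales[:, None]

    def smooth(m: np.ndarray) -> np.ndarray:
        return smooth_spectrum(m, grid, sampling_rate) if smoothing else m

    sxy = smooth(inv_s * wx * np.conj(wy))
    sxx = smooth(inv_s * np.abs(wx) ** 2)
    syy = smooth(inv_s * np.abs(wy) ** 2)

    # the smoothed ratio obeys Cauchy-Schwarz (<= 1 mathematically); only
    # exact zero denominators (both spectra underflow) need guarding
    denom = sxx * syy
    num = np.abs(sxy) ** 2
    r2 = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    r2 = np.clip(r2, 0.0, 1.0)

    n = len(head)
    times = np.arange(n) / sampling_rate
    cmap = CoherenceMap(
        mswc=r2,
        cross_power=np.abs(sxy),
        grid=grid,
        times=times,
        coi=_cone_of_influence(times, grid.omega0),
        threshold=threshold,
    )
    cmap.coherent_frequency = coherent_frequency(cmap, threshold=threshold)
    return cmap


def coherent_frequency(
    cmap: CoherenceMap,
    threshold: float = 0.9,
    time_window: tuple[float, float] | None = None,
    mode: str = "band",
    mask_coi: bool = False,
) -> float:
    """Highest frequency whose MSWC stays above ``threshold`` over the exam.

    Frequencies are scanned in ascending order from the lowest resolvable.
    A frequency qualifies when MSWC >= threshold at *every* time sample of
    the window.  ``mode="band"`` (default) returns the top of the contiguous
    qualifying band anchored at the lowest frequency; ``mode="global"``
    returns the highest qualifying frequency regardless of contiguity.
    Returns 0.0 when the lowest frequency already fails.

    ``mask_coi=True`` restricts each frequency's time span to the cone of
    influence; by default the whole exam counts, edges included.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if mode not in ("band", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    times = cmap.times
    if time_window is None:
        tsel = np.ones(len(times), dtype=bool)
    else:
        t0, t1 = time_window
        tsel = (times >= t0) & (times <= t1)
        if not np.any(tsel):
            raise ValueError("empty time window")

    freqs = cmap.frequencies                  # decreasing with row index
    order = np.argsort(freqs)                 # ascending frequency
    qualifies = np.empty(len(freqs), dtype=bool)
    for rank, row in enumerate(order):
        sel = tsel
        if mask_coi:
            sel = tsel & (freqs[row] <= cmap.coi)
            if not np.any(sel):
                qualifies[rank] = False
                continue
        qualifies[rank] = bool(np.min(cmap.mswc[row, sel]) >= threshold)

    if not qualifies[0]:
        return 0.0
    if mode == "global":
        return float(freqs[order][qualifies].max())
    top = np.argmin(qualifies) - 1 if not qualifies.all() else len(freqs) - 1
    return float(freqs[order][top])
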