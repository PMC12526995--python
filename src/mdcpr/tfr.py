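"""Joint time-frequency representations of the slow-time radar signal.

Three representations are provided:

* :func:`stft_spectrogram` -- squared-magnitude short-time Fourier
  transform; linear, cross-term free, resolution set by the window length
  (frequency resolution PRF/L, time resolution L/PRF).
* :func:`wvd` -- discrete Wigner-Ville distribution, the FFT over lag of
  the instantaneous autocorrelation ``x(t + tau/2) x*(t - tau/2)``.  Exactly
  localised for linear FM but bilinear, so multi-component signals produce
  oscillatory cross terms midway between components.
* :func:`spwvd` -- smoothed pseudo WVD: separable Hamming smoothing in time
  and in lag suppresses cross terms while keeping most of the WVD's
  localisation.

The discrete WVD is computed on a two-fold FFT-interpolated copy of the
signal so that the frequency axis covers the full [-PRF/2, PRF/2) band
(the bilinear lag product would otherwise halve the unambiguous band).

Frequency axes are signed and centred on zero; positive Doppler means
motion away from the radar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps

from .synthetic import SlowTimeSignal


@dataclass
class TimeFrequencyMap:
    """Time x signed-frequency power map with axis metadata."""

    power: np.ndarray  # (n_times, n_freqs), linear units
    time_axis_s: np.ndarray
    freq_axis_hz: np.ndarray  # signed, symmetric about 0
    method: str  # "STFT" | "WVD" | "SPWVD"
    prf_hz: float
    window: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.time_axis_s), len(self.freq_axis_hz)):
            raise ValueError("power matrix does not match axis lengths")
        if np.any(np.diff(self.time_axis_s) <= 0):
            raise ValueError("time bins must be strictly increasing")

    @property
    def freq_resolution_hz(self) -> float:
        """Physical frequency resolution PRF / window_length (STFT only)."""
        if self.method != "STFT":
            raise AttributeError("resolution law applies to the STFT")
        return self.prf_hz / self.window["window_length"]

    @property
    def time_resolution_s(self) -> float:
        """Physical time resolution window_length / PRF (STFT only)."""
        if self.method != "STFT":
            raise AttributeError("resolution law applies to the STFT")
        return self.window["window_length"] / self.prf_hz


def _as_complex_array(x: SlowTimeSignal | np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(x, SlowTimeSignal):
        arr = np.asarray(x.samples, dtype=complex)
        return arr, x.prf_hz
    raise TypeError("expected a SlowTimeSignal")


def stft_spectrogram(
    sig: SlowTimeSignal,
    window_length: int = 128,
    overlap: int | None = None,
    fft_length: int | None = None,
) -> TimeFrequencyMap:
    """Squared-magnitude STFT with a Hamming window.

    ``overlap`` defaults to 75% of the window; ``fft_length`` to
    ``max(256, window_length)``.  Only full windows are evaluated (no edge
    padding); each column's time stamp is the window centre.
    """
    x, prf = _as_complex_array(sig)
    n = len(x)
    if n == 0:
        raise ValueError("empty signal")
    if window_length > n:
        raise ValueError("window longer than signal")
    if overlap is None:
        overlap = (3 * window_length) // 4
    if not 0 <= overlap < window_length:
        raise ValueError("overlap must satisfy 0 <= overlap < window_length")
    if fft_length is None:
        fft_length = max(256, window_length)
    hop = window_length - overlap

    win = np.hamming(window_length)
    frames = np.lib.stride_tricks.sliding_window_view(x, window_length)[::hop]
    spec = np.fft.fft(frames * win, n=fft_length, axis=1)
    power = np.abs(np.fft.fftshift(spec, axes=1)) ** 2
    starts = np.arange(frames.shape[0]) * hop
    time_axis = (starts + (window_length - 1) / 2.0) / prf
    freq_axis = np.fft.fftshift(np.fft.fftfreq(fft_length, d=1.0 / prf))
    return TimeFrequencyMap(
        power=power,
        time_axis_s=time_axis,
        freq_axis_hz=freq_axis,
        method="STFT",
        prf_hz=prf,
        window={
            "type": "hamming",
            "window_length": window_length,
            "overlap": overlap,
            "fft_length": fft_length,
        },
    )


def _upsample2(x: np.ndarray) -> np.ndarray:
    """Two-fold FFT interpolation (preserves the original samples)."""
    return sps.resample(x, 2 * len(x))


def _lag_products(x2: np.ndarray, cols: np.ndarray, max_lag: int) -> np.ndarray:
    """Instantaneous autocorrelation r[m, c] = x2[c+m] x2*[c-m].

    Lags outside the signal support contribute zero (zero-padding edge
    rule); the pairing is conjugate-symmetric in m by construction.
    """
    n2 = len(x2)
    m = np.arange(-max_lag, max_lag + 1)[:, None]  # (2M+1, 1)
    ip = cols[None, :] + m
    im = cols[None, :] - m
    valid = (ip >= 0) & (ip < n2) & (im >= 0) & (im < n2)
    r = np.zeros(ip.shape, dtype=complex)
    r[valid] = x2[ip[valid]] * np.conj(x2[im[valid]])
    return r  # rows ordered m = -M..M


def _lag_fft(r: np.ndarray, max_lag: int, fft_length: int, scale: float) -> np.ndarray:
    """FFT over lag of r (rows m=-M..M) -> (n_cols, fft_length) fftshifted."""
    kern = np.zeros((fft_length, r.shape[1]), dtype=complex)
    kern[: max_lag + 1, :] = r[max_lag:, :]  # m = 0..M
    kern[-max_lag:, :] = r[:max_lag, :]  # m = -M..-1
    w = np.fft.fft(kern, axis=0) * scale
    return np.fft.fftshift(np.real(w), axes=0).T


def wvd(
    sig: SlowTimeSignal,
    fft_length: int = 512,
    time_hop: int = 1,
) -> TimeFrequencyMap:
    """Discrete Wigner-Ville distribution.

    Computed as the lag FFT of ``x(t + tau/2) x*(t - tau/2)`` on a two-fold
    interpolated grid; evaluated at every ``time_hop``-th original sample.
    Normalised as a Riemann sum of the continuous transform, so the time
    marginal ``sum_f W(t, f) df`` equals ``|x(t)|^2``.  Values may be
    negative (bilinear distribution).
    """
    x, prf = _as_complex_array(sig)
    if len(x) < 2:
        raise ValueError("signal too short")
    if np.isrealobj(np.asarray(sig.samples)):
        x = sps.hilbert(np.real(x))
    x2 = _upsample2(x)
    cols = np.arange(0, len(x), time_hop) * 2  # even indices = original samples
    max_lag = fft_length // 2 - 1
    r = _lag_products(x2, cols, max_lag)
    power = _lag_fft(r, max_lag, fft_length, scale=1.0 / prf)
    freq_axis = np.fft.fftshift(np.fft.fftfreq(fft_length, d=1.0 / prf))
    time_axis = cols / (2.0 * prf)
    return TimeFrequencyMap(
        power=power,
        time_axis_s=time_axis,
        freq_axis_hz=freq_axis,
        method="WVD",
        prf_hz=prf,
        window={"fft_length": fft_length, "time_hop": time_hop},
    )


def spwvd(
    sig: SlowTimeSignal,
    time_window_length: int = 256,
    freq_window_length: int = 256,
    fft_length: int = 512,
    time_hop: int = 1,
) -> TimeFrequencyMap:
    """Smoothed pseudo Wigner-Ville distribution.

    Separable smoothing of the WVD: a Hamming window over lag (frequency
    smoothing) and a Hamming window over time, both 256 points on the
    original slow-time grid by default.  Window lengths are adjusted to the
    nearest odd count so the kernels are symmetric.  The time window is
    normalised to unit sum and the lag window to unit centre value, so a
    stationary ridge keeps the WVD's scale.
    """
    x, prf = _as_complex_array(sig)
    if len(x) < 2:
        raise ValueError("signal too short")
    if np.isrealobj(np.asarray(sig.samples)):
        x = sps.hilbert(np.real(x))
    if time_window_length > len(x) or freq_window_length > len(x):
        raise ValueError("smoothing windows longer than signal")
    x2 = _upsample2(x)
    n2 = len(x2)

    # lag window: freq_window_length points on the original grid = lags in
    # original-sample units; odd-adjusted, unit centre value
    m_half = freq_window_length // 2
    max_lag = min(m_half, fft_length // 2 - 1)
    h = np.hamming(2 * max_lag + 1)
    h = h / h[max_lag]

    # time window: spans time_window_length original samples on the
    # (two-fold) upsampled grid, odd-adjusted, unit sum
    g = np.hamming(2 * time_window_length + 1)
    g = g / g.sum()

    # time-smoothed autocorrelation, one convolution per lag
    m = np.arange(-max_lag, max_lag + 1)
    r_sm = np.zeros((len(m), n2), dtype=complex)
    for i, mi in enumerate(m):
        lo, hi = abs(mi), n2 - abs(mi)
        y = np.zeros(n2, dtype=complex)
        y[lo:hi] = x2[lo + mi : hi + mi] * np.conj(x2[lo - mi : hi - mi])
        r_sm[i] = sps.fftconvolve(y, g, mode="same")

    cols = np.arange(0, len(x), time_hop) * 2
    power = _lag_fft(r_sm[:, cols] * h[:, None], max_lag, fft_length, scale=1.0 / prf)
    freq_axis = np.fft.fftshift(np.fft.fftfreq(fft_length, d=1.0 / prf))
    time_axis = cols / (2.0 * prf)
    return TimeFrequencyMap(
        power=power,
        time_axis_s=time_axis,
        freq_axis_hz=freq_axis,
        method="SPWVD",
        prf_hz=prf,
        window={
            "type": "hamming",
            "time_window_length": time_window_length,
            "freq_window_length": freq_window_length,
            "fft_length": fft_length,
            "time_hop": time_hop,
        },
    )


def to_image(
    tfmap: TimeFrequencyMap,
    dynamic_range_db: float = 60.0,
    out_size: tuple[int, int] = (64, 64),
) -> np.ndarray:
    """Convert a map to a normalised grayscale image (rows = frequency).

    dB-scales relative to the map's peak, clips ``dynamic_range_db`` below
    it, resamples to ``out_size`` (bilinear) and min-max normalises to
    [0, 1].  Negative WVD values are clipped to the dB floor.
    """
    p = np.maximum(tfmap.power, 0.0)
    peak = p.max()
    if peak <= 0.0:
        raise ValueError("degenerate all-zero map")
    db = 10.0 * np.log10(np.maximum(p / peak, 10.0 ** (-dynamic_range_db / 10.0 - 1)))
    db = np.clip(db, -dynamic_range_db, 0.0)
    img = (db + dynamic_range_db) / dynamic_range_db  # [0, 1]
    img = img.T  # rows = frequency, columns = time
    zoom = (out_size[0] / img.shape[0], out_size[1] / img.shape[1])
    # anti-alias before shrinking so narrow features survive resampling
    sigma = [max(0.0, (1.0 / z - 1.0) / 2.0) for z in zoom]
    if any(s > 0 for s in sigma):
        img = ndimage.gaussian_filter(img, sigma, mode="nearest")
    img = ndimage.zoom(img, zoom, order=1, mode="nearest", grid_mode=True)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return img
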