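"""Per-segment amplitude and spectral features.

Amplitude side: rectified signal, integrated EMG (IEMG, the time integral of
the rectified signal, mV*s), mean amplitude (mV), RMS and a centred moving
RMS envelope.

Spectral side: a single-window (boxcar) periodogram of the 1-s segment via
the DFT, one-sided, density-scaled so the integral of the PSD over
[0, fs/2] recovers the time-domain mean square (Parseval); band power is
the trapezoidal integral of the PSD over the 5-15 Hz tremor band, and the
band fraction is that integral as a percentage of the total.

``featurize`` ties both sides to the preprocessing branches: amplitude
features are computed on the fully filtered signal, spectral features on the
mains-notched signal only, because the 20 Hz high-pass would remove the very
band being analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .filtering import preprocess
from .segmentation import Segment

__all__ = [
    "BandSpec",
    "Spectrum",
    "FeatureVector",
    "rectify",
    "iemg",
    "mean_amplitude",
    "rms",
    "rms_envelope",
    "compute_spectrum",
    "band_power",
    "band_fraction",
    "featurize",
]


@dataclass(frozen=True)
class BandSpec:
    """Tremor analysis band, default 5-15 Hz."""

    lo_hz: float = 5.0
    hi_hz: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo_hz < self.hi_hz:
            raise ValueError(f"require 0 <= lo < hi, got ({self.lo_hz}, {self.hi_hz})")


@dataclass(frozen=True)
class Spectrum:
    """One-sided PSD (mV^2/Hz) and amplitude spectrum (mV) on a 0..fs/2 grid."""

    freqs: np.ndarray
    psd: np.ndarray
    amplitude: np.ndarray
    resolution_hz: float


@dataclass(frozen=True)
class FeatureVector:
    """All per-segment features; ``zero_power`` flags an all-zero segment."""

    iemg: float
    mean_amp: float
    rms: float
    band_power: float
    total_power: float
    band_fraction: float
    zero_power: bool = False


def rectify(values: np.ndarray) -> np.ndarray:
    return np.abs(np.asarray(values, dtype=float))


def _check_nonempty(values: np.ndarray, minimum: int = 1) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < minimum:
        raise ValueError(f"need at least {minimum} samples, got {values.size}")
    return values


def iemg(values: np.ndarray, fs: float) -> float:
    """Time integral of the rectified signal: sum(|x|)/fs, in mV*s."""
    values = _check_nonempty(values, 2)
    return float(np.sum(np.abs(values)) / fs)


def mean_amplitude(values: np.ndarray) -> float:
    values = _check_nonempty(values)
    return float(np.mean(np.abs(values)))


def rms(values: np.ndarray) -> float:
    values = _check_nonempty(values)
    return float(np.sqrt(np.mean(values**2)))


def rms_envelope(values: np.ndarray, fs: float, window_s: float = 0.05) -> np.ndarray:
    """Centred moving RMS with edge windows truncated; same length as input."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    values = _check_nonempty(values)
    m = values.size
    w = max(1, int(round(window_s * fs)))
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(values**2)])
    idx = np.arange(m)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(m, idx - half + w)
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def compute_spectrum(values: np.ndarray, fs: float) -> Spectrum:
    """Boxcar periodogram of the segment (one-sided, density scaling).

    At the protocol's 1-s window the frequency resolution is 1 Hz.  The
    amplitude spectrum holds per-component peak amplitudes in mV.
    """
    values = _check_nonempty(values)
    freqs, psd = sps.periodogram(values, fs=fs, window="boxcar", detrend=False)
    n = values.size
    amp = np.abs(np.fft.rfft(values)) / n
    if n > 1:
        amp[1:] *= 2.0
        if n % 2 == 0:
            amp[-1] /= 2.0
    return Spectrum(freqs, psd, amp, resolution_hz=float(freqs[1] - freqs[0]) if len(freqs) > 1 else fs)


from functools import lru_cache


@lru_cache(maxsize=32)
def _band_weights(n_bins: int, df: float, lo: float, hi: float) -> np.ndarray:
    """Weights w such that w @ psd equals the trapezoidal band integral.

    The trapezoidal rule on the linear interpolant of the PSD is linear in
    the PSD values, so the integral over [lo, hi] is an exact dot product.
    """
    w = np.zeros(n_bins)
    lo = max(lo, 0.0)
    hi = min(hi, (n_bins - 1) * df)
    for i in range(n_bins - 1):
        f0, f1 = i * df, (i + 1) * df
        a, b = max(f0, lo), min(f1, hi)
        if b <= a:
            continue
        # integral of the linear interpolant over [a, b]
        ta = (a - f0) / df
        tb = (b - f0) / df
        length = b - a
        mean_t = (ta + tb) / 2.0
        w[i] += length * (1.0 - mean_t)
        w[i + 1] += length * mean_t
    return w


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] with edge interpolation."""
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, freqs, psd)
    return float(np.trapezoid(vals, grid))


def band_power(spectrum: Spectrum, band: BandSpec = BandSpec()) -> float:
    if band.hi_hz > spectrum.freqs[-1] + 1e-9:
        raise ValueError(f"band upper edge {band.hi_hz} Hz exceeds Nyquist")
    return _band_integral(spectrum.freqs, spectrum.psd, band.lo_hz, band.hi_hz)


def band_fraction(spectrum: Spectrum, band: BandSpec = BandSpec()
                  ) -> tuple[float, float, float]:
    """(percent in band, band power, total power); 0% flagged if total is 0."""
    bp = band_power(spectrum, band)
    total = float(np.trapezoid(spectrum.psd, spectrum.freqs))
    if total <= 0.0:
        return 0.0, bp, total
    return 100.0 * bp / total, bp, total


def featurize(
    segment: Segment,
    band: BandSpec = BandSpec(),
    *,
    mode_amplitude: str = "full",
    mode_band: str = "notch_only",
    preprocessed: dict[str, np.ndarray] | None = None,
) -> FeatureVector:
    """Assemble the per-segment feature vector.

    ``preprocessed`` may map a preprocessing mode to the already filtered
    full-recording array, avoiding repeated filtering when many segments
    come from one recording; missing modes are computed on demand.
    """
    fs = segment.recording.fs

    def branch(mode: str) -> np.ndarray:
        if preprocessed is not None and mode in preprocessed:
            full = preprocessed[mode]
        else:
            full = preprocess(segment.recording, mode).values
            if preprocessed is not None:
                preprocessed[mode] = full
        return segment.slice(full)

    x_amp = branch(mode_amplitude)
    x_band = branch(mode_band)
    spectrum = compute_spectrum(x_band, fs)
    frac, bp, total = band_fraction(spectrum, band)
    return FeatureVector(
        iemg=iemg(x_amp, fs),
        mean_amp=mean_amplitude(x_amp),
        rms=rms(x_amp),
        band_power=bp,
        total_power=total,
        band_fraction=frac,
        zero_power=total <= 0.0,
    )


def featurize_batch(
    segments: list[Segment],
    x_amplitude: np.ndarray,
    x_band: np.ndarray,
    band: BandSpec = BandSpec(),
) -> list[FeatureVector]:
    """Vectorized :func:`featurize` over many segments of one recording.

    ``x_amplitude`` and ``x_band`` are the two preprocessed full-recording
    arrays.  Numerically equivalent to calling ``featurize`` per segment.
    """
    if not segments:
        return []
    fs = segments[0].recording.fs
    n = segments[0].n_samples

    def matrix(values: np.ndarray) -> np.ndarray:
        starts = np.array(
            [min(max(s.start_index, 0), len(values) - n) for s in segments])
        return values[starts[:, None] + np.arange(n)]

    a = matrix(x_amplitude)
    absa = np.abs(a)
    iemg_v = absa.sum(axis=1) / fs
    mean_v = absa.mean(axis=1)
    rms_v = np.sqrt((a * a).mean(axis=1))

    b = matrix(x_band)
    spec = np.fft.rfft(b, axis=1)
    psd = (np.abs(spec) ** 2) / (fs * n)
    psd[:, 1:] *= 2.0
    if n % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    df = float(freqs[1] - freqs[0]) if len(freqs) > 1 else fs
    w_band = _band_weights(len(freqs), df, band.lo_hz, band.hi_hz)
    w_total = _band_weights(len(freqs), df, 0.0, float(freqs[-1]))
    bp_v = psd @ w_band
    total_v = psd @ w_total
    out: list[FeatureVector] = []
    for i in range(len(segments)):
        bp, total = float(bp_v[i]), float(total_v[i])
        frac = 100.0 * bp / total if total > 0 else 0.0
        out.append(FeatureVector(
            iemg=float(iemg_v[i]), mean_amp=float(mean_v[i]), rms=float(rms_v[i]),
            band_power=bp, total_power=total, band_fraction=frac,
            zero_power=total <= 0.0,
        ))
    return out
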