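"""Adaptive low-pass murmur elimination (ALPF).

Murmurs are band-limited noise lying above the frequency band where S1-S4
concentrate their energy.  Instead of a fixed 200 Hz low-pass, the cutoff
is read from the smoothed FFT-magnitude envelope of the signal: the primary
peak of the envelope holds the component energy, and the first valley after
it whose (normalized) value drops below a small coefficient marks where the
component band ends and murmur energy begins.  If no such valley exists in
the 20-200 Hz search range, the conventional 200 Hz cutoff is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioSignal
from .preprocessing import normalize_unit_peak, normalize_unit_peak_array

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutoffParams:
    """Cutoff-search configuration (defaults are the method's constants)."""

    smoothing_radius: int = 5       # L_F, moving-average neighborhood radius (bins)
    coeff_threshold: float = 0.2    # a valley qualifies only below this envelope value
    search_lo_hz: float = 20.0
    search_hi_hz: float = 200.0
    filter_order: int = 6           # Butterworth order (applied forward-backward)


@dataclass(frozen=True)
class SpectralEnvelope:
    """One-sided FFT modulus and its smoothed, unit-peak envelope."""

    fft_modulus: np.ndarray
    env: np.ndarray
    freq_hz: np.ndarray

    def __post_init__(self):
        if not (len(self.fft_modulus) == len(self.env) == len(self.freq_hz)):
            raise ValueError("fft_modulus, env and freq_hz must have equal length")


@dataclass(frozen=True)
class CutoffResult:
    cutoff_hz: float
    primary_peak_hz: float
    found_valley: bool


def fft_modulus(signal: AudioSignal) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT magnitude and its frequency axis.

    Returns bins 0..floor(N/2); the magnitude spectrum of a real signal is
    symmetric, so nothing is lost for a cutoff search below Nyquist.
    """
    n = signal.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    mod = np.abs(np.fft.rfft(signal.samples))
    freq = np.fft.rfftfreq(n, d=1.0 / signal.fs)
    return mod, freq


def moving_average_envelope(x: np.ndarray, radius: int = 5) -> np.ndarray:
    """Edge-aware moving average with neighborhood radius ``radius``.

    Interior points average the full 2*radius+1 window; the leading edge
    averages bins 0..n+radius, and the trailing edge averages bins
    n-radius..N-1 (the window is clipped to valid bins, and the divisor is
    the clipped window length).  Output is NOT normalized; see
    :func:`spectral_envelope` for the normalized version.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= n:
        raise ValueError(f"radius {radius} must be smaller than sequence length {n}")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - radius, 0)
    hi = np.minimum(idx + radius, n - 1)
    sums = csum[hi + 1] - csum[lo]
    return sums / (hi - lo + 1)


def spectral_envelope(signal: AudioSignal, params: CutoffParams | None = None) -> SpectralEnvelope:
    """FFT modulus -> moving-average smoothing -> unit-peak normalization."""
    params = params or CutoffParams()
    mod, freq = fft_modulus(signal)
    env = moving_average_envelope(mod, params.smoothing_radius)
    env = normalize_unit_peak_array(env)
    return SpectralEnvelope(fft_modulus=mod, env=env, freq_hz=freq)


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local minima; a plateau collapses to its first bin."""
    n = len(values)
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if j < n - 1 and values[i] < values[i - 1] and values[j + 1] > values[i]:
            out.append(i)
        i = j + 1
    return np.asarray(out, dtype=int)


def find_cutoff_frequency(env: SpectralEnvelope,
                          params: CutoffParams | None = None) -> CutoffResult:
    """Locate the ALPF cutoff from the normalized spectral envelope.

    The primary peak is the global maximum of the envelope (restricted to
    the search band if the raw global maximum falls above it, which would
    contradict the low-frequency concentration of heart-sound energy).  The
    cutoff is the first local minimum after that peak lying inside the
    search range with envelope value below ``coeff_threshold``; without one
    the cutoff falls back to the upper end of the range.
    """
    params = params or CutoffParams()
    values, freq = env.env, env.freq_hz
    if len(values) < 3:
        raise ValueError("envelope must have at least 3 bins")
    peak_idx = int(np.argmax(values))
    if freq[peak_idx] > params.search_hi_hz:
        in_band = freq <= params.search_hi_hz
        if not np.any(in_band):
            raise ValueError("no envelope bins below the search range upper bound")
        peak_idx = int(np.argmax(np.where(in_band, values, -np.inf)))
        logger.warning(
            "global spectral-envelope maximum above %.0f Hz; primary peak "
            "restricted to the search band (%.1f Hz)",
            params.search_hi_hz, freq[peak_idx],
        )
    minima = _local_minima(values)
    for idx in minima:
        if idx <= peak_idx:
            continue
        if not (params.search_lo_hz <= freq[idx] <= params.search_hi_hz):
            continue
        if values[idx] < params.coeff_threshold:
            return CutoffResult(cutoff_hz=float(freq[idx]),
                                primary_peak_hz=float(freq[peak_idx]),
                                found_valley=True)
    return CutoffResult(cutoff_hz=float(params.search_hi_hz),
                        primary_peak_hz=float(freq[peak_idx]),
                        found_valley=False)


def apply_alpf(signal: AudioSignal, cutoff: CutoffResult,
               params: CutoffParams | None = None) -> AudioSignal:
    """Zero-phase Butterworth low-pass at the found cutoff, then unit-peak.

    Forward-backward filtering keeps component onsets time-aligned, which
    boundary detection depends on.
    """
    params = params or CutoffParams()
    nyq = signal.fs / 2.0
    if not 0 < cutoff.cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff.cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    sos = butter(params.filter_order, cutoff.cutoff_hz, btype="low",
                 fs=signal.fs, output="sos")
    filtered = sosfiltfilt(sos, signal.samples)
    return normalize_unit_peak(AudioSignal(samples=filtered, fs=signal.fs))


def eliminate_murmurs(signal: AudioSignal,
                      params: CutoffParams | None = None
                      ) -> tuple[AudioSignal, CutoffResult]:
    """Full ALPF stage on a preprocessed (2 kHz, unit-peak) signal."""
    params = params or CutoffParams()
    env = spectral_envelope(signal, params)
    cutoff = find_cutoff_frequency(env, params)
    logger.info("ALPF cutoff %.1f Hz (primary peak %.1f Hz, valley %s)",
                cutoff.cutoff_hz, cutoff.primary_peak_hz, cutoff.found_valley)
    return apply_alpf(signal, cutoff, params), cutoff
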