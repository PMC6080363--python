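"""Recording standardization: down-sampling, wavelet denoising, normalization.

Heart-sound energy lies below 1 kHz, so every recording is brought to a
common 2 kHz rate (polyphase FIR resampling, which anti-alias filters before
rate reduction).  Broadband noise is then reduced by soft wavelet
thresholding with a db4 mother wavelet at decomposition level 7, and the
result is scaled to unit peak so that all later amplitude thresholds are
relative to the loudest component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pywt
from scipy.signal import resample_poly

from .audio_io import AudioSignal


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the standardization stage.

    target_fs : common sampling rate, Hz (2000 covers the <1 kHz band of
        heart sounds with Nyquist margin)
    wavelet_name : mother wavelet for denoising (db4: 4 vanishing moments,
        shape similar to a heart-sound transient)
    decomposition_level : DWT depth for denoising
    threshold_mode : shrinkage rule applied to detail coefficients
    """

    target_fs: float = 2000.0
    wavelet_name: str = "db4"
    decomposition_level: int = 7
    threshold_mode: str = "soft"

    def __post_init__(self):
        if self.target_fs < 2000.0:
            raise ValueError("target_fs must be at least 2 kHz (Nyquist for 1 kHz content)")
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")


def downsample(signal: AudioSignal, target_fs: float) -> AudioSignal:
    """Resample to ``target_fs`` (<= signal.fs) with anti-alias filtering.

    Uses polyphase FIR resampling by the rational factor target_fs/fs.
    A signal already at the target rate is returned unchanged.
    """
    if signal.fs < target_fs:
        raise ValueError(
            f"cannot downsample from {signal.fs} Hz to {target_fs} Hz (would upsample)"
        )
    if signal.fs == target_fs:
        return signal
    ratio = Fraction(target_fs / signal.fs).limit_denominator(10**6)
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return AudioSignal(samples=out, fs=float(target_fs))


def _universal_threshold(coeffs: list[np.ndarray], n: int) -> float:
    """sigma_hat * sqrt(2 ln N) with sigma_hat from the MAD of the finest details."""
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6744897501960817
    return sigma * math.sqrt(2.0 * math.log(max(n, 2)))


def denoise(signal: AudioSignal, params: PreprocessParams | None = None) -> AudioSignal:
    """Soft wavelet-threshold denoising (details only, symmetric extension).

    The threshold is the universal threshold estimated from the
    finest-detail coefficients; the approximation band is left untouched.
    Raises ValueError when the signal is too short for the requested level.
    """
    params = params or PreprocessParams()
    x = signal.samples
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(params.wavelet_name).dec_len)
    if params.decomposition_level > max_level:
        raise ValueError(
            f"signal of {len(x)} samples supports at most level {max_level} "
            f"for {params.wavelet_name}, requested {params.decomposition_level}"
        )
    coeffs = pywt.wavedec(x, params.wavelet_name,
                          level=params.decomposition_level, mode="symmetric")
    thr = _universal_threshold(coeffs, len(x))
    if params.threshold_mode != "soft":
        raise ValueError("only soft thresholding is supported")
    # soft shrinkage, safe for exactly-zero coefficients
    denoised = [coeffs[0]] + [
        np.sign(c) * np.maximum(np.abs(c) - thr, 0.0) for c in coeffs[1:]
    ]
    out = pywt.waverec(denoised, params.wavelet_name, mode="symmetric")
    return AudioSignal(samples=out[: len(x)], fs=signal.fs)


def normalize_unit_peak(signal: AudioSignal) -> AudioSignal:
    """Scale so that max(|x|) == 1.  Errors on an all-zero signal."""
    peak = np.max(np.abs(signal.samples))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero signal")
    return AudioSignal(samples=signal.samples / peak, fs=signal.fs)


def normalize_unit_peak_array(x: np.ndarray) -> np.ndarray:
    """Unit-peak normalization of a bare array (used for envelopes/spectra)."""
    x = np.asarray(x, dtype=float)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero sequence")
    return x / peak


def preprocess(signal: AudioSignal, params: PreprocessParams | None = None,
               clamp_level: bool = False) -> AudioSignal:
    """Full standardization: downsample -> denoise -> unit-peak normalize.

    With ``clamp_level=True`` the decomposition level is reduced to the
    maximum the signal length allows instead of raising (used by the
    pipeline on very short inputs).
    """
    params = params or PreprocessParams()
    out = downsample(signal, params.target_fs) if signal.fs > params.target_fs else signal
    level = params.decomposition_level
    if clamp_level:
        max_level = pywt.dwt_max_level(out.n_samples,
                                       pywt.Wavelet(params.wavelet_name).dec_len)
        level = max(1, min(level, max_level))
    eff = PreprocessParams(target_fs=params.target_fs,
                           wavelet_name=params.wavelet_name,
                           decomposition_level=level,
                           threshold_mode=params.threshold_mode)
    out = denoise(out, eff)
    return normalize_unit_peak(out)
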