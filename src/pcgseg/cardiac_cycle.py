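"""Average cardiac-cycle estimation from the final boundary envelope.

Heart sounds are quasi-periodic, so the lag of the autocorrelation primary
peaks gives the cycle length.  The biased sample autocorrelation (divisor
N) attenuates with lag, letting side peaks — alignments of S1 with S2 —
compete with the true period; the unbiased form (divisor N-m) keeps the
primary peaks at full height.  Squaring and thresholding the unbiased
autocorrelation removes most side peaks; the last surviving peak is then
dropped outright (at large lags a side peak can survive on its own), the
unbiased autocorrelation is taken once more, and the lags of its dominant
peaks are averaged into the cycle estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import correlate

from .boundary_detection import EnvelopeSignal, _nonzero_runs

logger = logging.getLogger(__name__)

SIDE_PEAK_FRAC = 0.4    # energy threshold, fraction of the lag-0 maximum
FINAL_PEAK_FRAC = 0.5   # peak threshold on the final autocorrelation


class CycleEstimationError(RuntimeError):
    """No non-origin peak survived; the recording has no usable periodicity."""


class AutocorrKind(str, Enum):
    BIASED = "pacf"          # divisor N
    UNBIASED = "uacf"        # divisor N - m
    ENERGY = "energy"
    THRESHOLDED = "thresholded"
    FINAL = "final"


@dataclass(frozen=True)
class AutocorrSeq:
    values: np.ndarray
    kind: AutocorrKind


@dataclass(frozen=True)
class CycleEstimate:
    avg_cycle_samples: float
    fs: float
    peak_lags: np.ndarray
    n_intervals: int

    @property
    def avg_cycle_s(self) -> float:
        return self.avg_cycle_samples / self.fs


def _raw_autocorr(x: np.ndarray) -> np.ndarray:
    """sum_n x[n] x[n+m] for m = 0..N-1 (FFT-based)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    full = correlate(x, x, mode="full", method="auto")
    return full[len(x) - 1:]


def pacf(x: np.ndarray) -> AutocorrSeq:
    """Biased sample autocorrelation: divisor N at every lag."""
    raw = _raw_autocorr(x)
    return AutocorrSeq(values=raw / len(np.asarray(x)), kind=AutocorrKind.BIASED)


def uacf(x: np.ndarray) -> AutocorrSeq:
    """Unbiased sample autocorrelation: divisor N - m at lag m.

    At the largest lag a single product remains (divisor 1).
    """
    x = np.asarray(x, dtype=float)
    raw = _raw_autocorr(x)
    divisors = len(x) - np.arange(len(x))
    return AutocorrSeq(values=raw / divisors, kind=AutocorrKind.UNBIASED)


def suppress_side_peaks(r: AutocorrSeq, side_frac: float = SIDE_PEAK_FRAC) -> AutocorrSeq:
    """Square the autocorrelation and zero values below side_frac * max."""
    if r.kind is not AutocorrKind.UNBIASED:
        raise ValueError("side-peak suppression expects the unbiased autocorrelation")
    energy = r.values ** 2
    sigma = side_frac * np.max(energy)
    out = np.where(energy >= sigma, energy, 0.0)
    return AutocorrSeq(values=out, kind=AutocorrKind.THRESHOLDED)


def remove_last_peak(e: AutocorrSeq) -> AutocorrSeq:
    """Zero the last contiguous non-zero run (by lag).

    A single surviving run is kept (with a warning): removing it would
    destroy the sequence altogether.
    """
    runs = _nonzero_runs(e.values)
    if not runs:
        raise ValueError("all-zero sequence: nothing to remove")
    if len(runs) == 1:
        warnings.warn("only one peak region present; last-peak removal skipped",
                      stacklevel=2)
        return e
    out = e.values.copy()
    start, stop = runs[-1]
    out[start:stop] = 0.0
    return AutocorrSeq(values=out, kind=e.kind)


def estimate_cycle(env: EnvelopeSignal, fs: float | None = None,
                   side_frac: float = SIDE_PEAK_FRAC,
                   final_frac: float = FINAL_PEAK_FRAC) -> CycleEstimate:
    """Average cardiac cycle from the energy-filtered envelope.

    Pipeline: unbiased autocorrelation -> squared-energy side-peak
    suppression -> forced last-peak removal -> unbiased autocorrelation of
    the result -> threshold at final_frac * max -> peaks = argmax of each
    non-zero run excluding the origin run -> cycle = mean gap between
    consecutive peak lags (a single surviving peak contributes its own lag).

    Raises CycleEstimationError when no non-origin peak survives.
    """
    fs = fs if fs is not None else env.fs
    values = env.values
    if np.count_nonzero(values) == 0:
        raise CycleEstimationError("envelope is all zero")
    r = uacf(values)
    thresholded = suppress_side_peaks(r, side_frac)
    trimmed = remove_last_peak(thresholded)
    r_final = uacf(trimmed.values)
    peak_threshold = final_frac * np.max(r_final.values)
    surviving = np.where(r_final.values >= peak_threshold, r_final.values, 0.0)
    peak_lags = []
    for start, stop in _nonzero_runs(surviving):
        if start == 0:  # origin run: lag 0 is trivially maximal
            continue
        peak_lags.append(start + int(np.argmax(surviving[start:stop])))
    if not peak_lags:
        raise CycleEstimationError(
            "no non-origin autocorrelation peak survived thresholding"
        )
    peak_lags = np.asarray(peak_lags, dtype=int)
    if len(peak_lags) == 1:
        avg = float(peak_lags[0])
        n_intervals = 1
    else:
        gaps = np.diff(peak_lags)
        avg = float(np.mean(gaps))
        n_intervals = len(gaps)
    logger.info("cycle estimate %.1f samples (%.3f s) from %d peak lag(s)",
                avg, avg / fs, len(peak_lags))
    return CycleEstimate(avg_cycle_samples=avg, fs=fs,
                         peak_lags=peak_lags, n_intervals=n_intervals)
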