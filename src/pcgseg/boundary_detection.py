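"""Component boundary detection on the murmur-reduced signal.

The amplitude envelope is taken as the morphological closing of the
rectified signal with a short flat structuring element: dilation (windowed
maximum) bridges the oscillations inside a component, erosion restores the
support.  Low-amplitude murmur/noise residue is then removed in three
passes — a small adaptive amplitude threshold, a morphological opening that
deletes humps shorter than the briefest component, and an energy threshold
on each surviving zero-delimited run.  The zero/non-zero transitions of the
final envelope are the component onsets and offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .audio_io import AudioSignal
from .preprocessing import normalize_unit_peak_array


@dataclass(frozen=True)
class MorphologyParams:
    """Flat structuring-element lengths, in samples at 2 kHz.

    close_len (Q) must stay below the shortest inter-component gap
    (>= 100 ms = 200 samples) or closing would merge adjacent components;
    open_len (Q') must stay below the shortest component (~50 ms = 100
    samples) or opening would delete real components.
    """

    close_len: int = 30
    open_len: int = 50

    def __post_init__(self):
        if not 0 < self.close_len < 200:
            raise ValueError("close_len must be in (0, 200) samples")
        if not 0 < self.open_len < 100:
            raise ValueError("open_len must be in (0, 100) samples")


@dataclass(frozen=True)
class ThresholdParams:
    """Amplitude/energy thresholding constants.

    lambda_std scales the envelope standard deviation into the adaptive
    threshold; ceiling_threshold (theta_C) caps it so boundary detail is
    preserved; energy_threshold (eta) rejects low-energy candidate runs.
    """

    lambda_std: float = 0.8
    ceiling_threshold: float = 0.025
    energy_threshold: float = 0.25

    def __post_init__(self):
        if min(self.lambda_std, self.ceiling_threshold, self.energy_threshold) <= 0:
            raise ValueError("threshold parameters must be strictly positive")


class EnvelopeStage(str, Enum):
    CLOSED = "closed"
    THRESHOLDED = "thresholded"
    OPENED = "opened"
    ENERGY_FILTERED = "energy_filtered"


@dataclass(frozen=True)
class EnvelopeSignal:
    """Nonnegative envelope in [0, 1] with its pipeline stage tag."""

    values: np.ndarray
    fs: float
    stage: EnvelopeStage

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if np.any(values < 0) or np.any(values > 1 + 1e-12):
            raise ValueError("envelope values must lie in [0, 1]")


@dataclass(frozen=True)
class BoundarySet:
    """Paired candidate onsets/offsets with per-pair energies.

    onsets[k] is the last zero sample before the k-th non-zero run of the
    envelope; offsets[k] the first zero sample after it (runs touching the
    sequence edge use the edge index).  Pairs interleave strictly:
    onsets[k] < offsets[k] < onsets[k+1].
    """

    onsets: np.ndarray
    offsets: np.ndarray
    energies: np.ndarray

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=int)
        offsets = np.asarray(self.offsets, dtype=int)
        energies = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "energies", energies)
        if not (len(onsets) == len(offsets) == len(energies)):
            raise ValueError("onsets, offsets and energies must have equal length")
        merged = np.empty(2 * len(onsets), dtype=int)
        merged[0::2] = onsets
        merged[1::2] = offsets
        if np.any(np.diff(merged) <= 0):
            raise ValueError("boundary pairs must interleave strictly")

    @property
    def n_pairs(self) -> int:
        return len(self.onsets)


def morphological_dilation(x: np.ndarray, length: int,
                           reflected: bool = False) -> np.ndarray:
    """Windowed maximum with a flat zero structuring element of ``length``.

    Windows are centred (left radius length//2) and shrink at the edges.
    ``reflected`` mirrors the element — required as the second stage of an
    opening so that even-length elements keep the operator anti-extensive.
    """
    if length < 1:
        raise ValueError("structuring element length must be >= 1")
    x = np.asarray(x, dtype=float)
    if reflected:  # mirror the element by filtering the reversed sequence
        return maximum_filter1d(x[::-1], size=length, mode="nearest")[::-1]
    return maximum_filter1d(x, size=length, mode="nearest")


def morphological_erosion(x: np.ndarray, length: int,
                          reflected: bool = False) -> np.ndarray:
    """Windowed minimum with a flat zero structuring element of ``length``."""
    if length < 1:
        raise ValueError("structuring element length must be >= 1")
    x = np.asarray(x, dtype=float)
    if reflected:
        return minimum_filter1d(x[::-1], size=length, mode="nearest")[::-1]
    return minimum_filter1d(x, size=length, mode="nearest")


def morphological_closing(x: np.ndarray, length: int) -> np.ndarray:
    """Dilation then erosion (with the reflected element): fills valleys
    narrower than the element.  Extensive (output >= input) and idempotent.
    """
    return morphological_erosion(morphological_dilation(x, length), length,
                                 reflected=True)


def morphological_opening(x: np.ndarray, length: int) -> np.ndarray:
    """Erosion then dilation (with the reflected element): removes spikes
    narrower than the element.  Anti-extensive (output <= input) and
    idempotent.
    """
    return morphological_dilation(morphological_erosion(x, length), length,
                                  reflected=True)


def adaptive_threshold(env: EnvelopeSignal, params: ThresholdParams | None = None
                       ) -> tuple[EnvelopeSignal, float, float, float]:
    """Zero envelope values below theta = min(lambda*std, ceiling).

    Returns (thresholded envelope, theta, theta_adaptive, mean).  The
    statistics use the population convention (divisor N).
    """
    params = params or ThresholdParams()
    values = env.values
    if len(values) == 0:
        raise ValueError("empty envelope")
    mu = float(np.mean(values))
    theta_a = params.lambda_std * float(np.sqrt(np.mean((values - mu) ** 2)))
    theta = min(theta_a, params.ceiling_threshold)
    out = np.where(values >= theta, values, 0.0)
    return (EnvelopeSignal(values=out, fs=env.fs, stage=EnvelopeStage.THRESHOLDED),
            theta, theta_a, mu)


def _nonzero_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal non-zero runs, stop exclusive."""
    nz = np.flatnonzero(values != 0)
    if len(nz) == 0:
        return []
    breaks = np.flatnonzero(np.diff(nz) > 1)
    starts = np.concatenate([[nz[0]], nz[breaks + 1]])
    stops = np.concatenate([nz[breaks] + 1, [nz[-1] + 1]])
    return list(zip(starts.tolist(), stops.tolist()))


def extract_candidate_boundaries(env: EnvelopeSignal) -> BoundarySet:
    """Zero/non-zero transitions of an opened envelope as onset/offset pairs.

    The onset index is the zero sample *before* the first non-zero sample of
    a run, the offset the zero sample *after* its last; a run touching the
    sequence edge takes the edge index itself.  Runs separated by a single
    zero sample are merged: that sample would otherwise serve as both an
    offset and the next onset, and a one-sample notch is not a component gap.
    """
    values = env.values
    runs = _nonzero_runs(values)
    merged_runs: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged_runs and start - merged_runs[-1][1] <= 1:
            merged_runs[-1] = (merged_runs[-1][0], stop)
        else:
            merged_runs.append((start, stop))
    onsets, offsets = [], []
    for start, stop in merged_runs:
        onsets.append(start - 1 if start > 0 else 0)
        offsets.append(stop if stop < len(values) else len(values) - 1)
    energies = [float(np.sum(values[a:b + 1] ** 2))
                for a, b in zip(onsets, offsets)]
    return BoundarySet(onsets=np.asarray(onsets, dtype=int),
                       offsets=np.asarray(offsets, dtype=int),
                       energies=np.asarray(energies, dtype=float))


def energy_filter(env: EnvelopeSignal, bs: BoundarySet,
                  energy_threshold: float = 0.25
                  ) -> tuple[EnvelopeSignal, BoundarySet]:
    """Remove candidate pairs with run energy below ``energy_threshold``.

    The energy of pair k is the sum of squared envelope values over the
    inclusive span [onset_k, offset_k]; removed spans are zeroed in the
    envelope.  Ties (energy exactly at the threshold) are kept.
    """
    values = env.values.copy()
    keep = bs.energies >= energy_threshold
    for a, b in zip(bs.onsets[~keep], bs.offsets[~keep]):
        values[a:b + 1] = 0.0
    out_env = EnvelopeSignal(values=values, fs=env.fs,
                             stage=EnvelopeStage.ENERGY_FILTERED)
    out_bs = BoundarySet(onsets=bs.onsets[keep], offsets=bs.offsets[keep],
                         energies=bs.energies[keep])
    return out_env, out_bs


def detect_boundaries(signal: AudioSignal,
                      morph: MorphologyParams | None = None,
                      thresh: ThresholdParams | None = None
                      ) -> tuple[BoundarySet, EnvelopeSignal, dict]:
    """Full boundary-detection stage on the murmur-eliminated signal.

    closing of |x| -> normalize -> adaptive threshold -> opening ->
    normalize -> candidate extraction -> energy filter.  Closing operates
    on the rectified signal so the envelope bounds both polarities.

    Returns (final boundaries, final envelope, diagnostics dict).
    """
    morph = morph or MorphologyParams()
    thresh = thresh or ThresholdParams()
    rectified = np.abs(signal.samples)
    closed = morphological_closing(rectified, morph.close_len)
    if np.max(closed) == 0:
        empty = BoundarySet(onsets=np.array([], dtype=int),
                            offsets=np.array([], dtype=int),
                            energies=np.array([], dtype=float))
        env0 = EnvelopeSignal(values=closed, fs=signal.fs,
                              stage=EnvelopeStage.ENERGY_FILTERED)
        return empty, env0, {"theta": 0.0, "theta_adaptive": 0.0, "mu": 0.0,
                             "n_candidates": 0, "n_final": 0}
    closed_env = EnvelopeSignal(values=normalize_unit_peak_array(closed),
                                fs=signal.fs, stage=EnvelopeStage.CLOSED)
    thresholded, theta, theta_a, mu = adaptive_threshold(closed_env, thresh)
    opened = morphological_opening(thresholded.values, morph.open_len)
    if np.max(opened) == 0:
        empty = BoundarySet(onsets=np.array([], dtype=int),
                            offsets=np.array([], dtype=int),
                            energies=np.array([], dtype=float))
        env0 = EnvelopeSignal(values=opened, fs=signal.fs,
                              stage=EnvelopeStage.ENERGY_FILTERED)
        return empty, env0, {"theta": theta, "theta_adaptive": theta_a, "mu": mu,
                             "n_candidates": 0, "n_final": 0}
    opened_env = EnvelopeSignal(values=normalize_unit_peak_array(opened),
                                fs=signal.fs, stage=EnvelopeStage.OPENED)
    candidates = extract_candidate_boundaries(opened_env)
    final_env, final_bs = energy_filter(opened_env, candidates,
                                        thresh.energy_threshold)
    diag = {"theta": theta, "theta_adaptive": theta_a, "mu": mu,
            "n_candidates": candidates.n_pairs, "n_final": final_bs.n_pairs}
    return final_bs, final_env, diag
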