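"""Component identification: which burst is S1, S2, S3 or S4?

Physiological priors drive the labelling.  In time, the systolic S1->S2
interval is shorter than the diastolic S2->S1 interval; S3 follows S2
closely (S2S3 < S3S1) while S4 hugs the next S1 (S2S4 > S4S1).  In
frequency, S3 and S4 are gallop sounds well below S1/S2.  The frequency
evidence comes from the Stockwell (S-) transform: a time-frequency map
with frequency-dependent Gaussian windows, collapsed per time sample into
an amplitude-weighted mean frequency ("instantaneous frequency") and
averaged over each detected component span.

Beats are formed by anchoring a window of one estimated cycle at each
first unassigned component; beats with 2, 3 or 4 components are labelled
by the rules above, anything else is flagged unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal, Annotation
from .boundary_detection import BoundarySet
from .cardiac_cycle import CycleEstimate

logger = logging.getLogger(__name__)

#: fraction of the estimated cycle covered by one beat window; leaves margin
#: so the next beat's first component never falls into the current window
BEAT_WINDOW_FRAC = 0.92

#: S3/S4 disambiguation rules for three-component beats
S3S4_PRIORS = "priors"      # S2S3 < S3S1 and S2S4 > S4S1 (default)
S3S4_VERBATIM = "verbatim"  # the opposite reading: short gap to S2 => S4


@dataclass(frozen=True)
class TimeFrequencyMatrix:
    """S-transform rows (frequency) x columns (time samples).

    ``freq_hz[m]`` is the nominal frequency of row m on the halved axis
    m * fs / (2N); only the ordering of rows matters for classification, so
    the uniform halving is harmless.
    """

    S: np.ndarray
    freq_hz: np.ndarray
    fs: float

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.S)


@dataclass(frozen=True)
class InstantaneousFrequency:
    values_hz: np.ndarray
    fs: float


@dataclass(frozen=True)
class LabeledComponent:
    label: str
    beat_index: int
    position_in_beat: int
    onset_sample: int
    offset_sample: int
    avg_freq_hz: float


@dataclass(frozen=True)
class Segmentation:
    """Final labelled segmentation with named inter-component intervals."""

    components: list[LabeledComponent]
    intervals: list[dict]
    cycle: CycleEstimate | None
    fs: float

    def to_annotations(self) -> list[Annotation]:
        return [
            Annotation(label=c.label, onset_sample=c.onset_sample,
                       offset_sample=c.offset_sample, fs=self.fs)
            for c in self.components
        ]


def _st_gaussian(n_row: int, n: int) -> np.ndarray:
    """Frequency-domain Gaussian voice window exp(-2 pi^2 m^2 / n_row^2)."""
    m = np.arange(n, dtype=float)
    with np.errstate(over="ignore"):
        return np.exp(-2.0 * np.pi**2 * m**2 / float(n_row) ** 2)


def stockwell_transform(signal: AudioSignal, max_freq_hz: float | None = None
                        ) -> TimeFrequencyMatrix:
    """Discrete S-transform, rows restricted to frequencies <= max_freq_hz.

    Row n (n >= 1) is the inverse DFT of the spectrum shifted by n bins and
    weighted by the Gaussian voice window — identical to the corresponding
    rows of the full transform.  The zero-frequency row is the signal mean.
    Frequencies are reported on the halved axis m * fs / (2N).
    """
    x = signal.samples
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples for the S-transform")
    if max_freq_hz is None:
        max_freq_hz = signal.fs / 4.0  # full halved axis
    if max_freq_hz > signal.fs / 2.0:
        raise ValueError("max_freq_hz above Nyquist")
    # halved axis: row m sits at m*fs/(2N)
    n_rows = min(n, int(np.floor(max_freq_hz * 2 * n / signal.fs)) + 1)
    H = np.fft.fft(x)
    S = np.empty((n_rows, n), dtype=complex)
    S[0, :] = np.mean(x)
    for row in range(1, n_rows):
        shifted = H[(np.arange(n) + row) % n]
        S[row, :] = n * np.fft.ifft(shifted * _st_gaussian(row, n))
    freq = np.arange(n_rows) * signal.fs / (2.0 * n)
    return TimeFrequencyMatrix(S=S, freq_hz=freq, fs=signal.fs)


def instantaneous_frequency(tf: TimeFrequencyMatrix) -> InstantaneousFrequency:
    """Per-column amplitude-weighted mean frequency of the S-modulus.

    All-zero columns have no defined frequency; they are set to 0 Hz.
    """
    mod = tf.modulus
    denom = mod.sum(axis=0)
    numer = (tf.freq_hz[:, None] * mod).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_h = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    if np.any(denom == 0):
        logger.warning("%d all-zero S-transform column(s); instantaneous "
                       "frequency set to 0 there", int(np.sum(denom == 0)))
    return InstantaneousFrequency(values_hz=f_h, fs=tf.fs)


def instantaneous_frequency_from_signal(signal: AudioSignal,
                                        max_freq_hz: float = 300.0
                                        ) -> InstantaneousFrequency:
    """Instantaneous frequency without materializing the S-matrix.

    Accumulates the weighted-mean numerator/denominator row by row, so
    memory stays O(N) however long the recording is.  Values are identical
    to instantaneous_frequency(stockwell_transform(...)).
    """
    x = signal.samples
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples for the S-transform")
    n_rows = min(n, int(np.floor(max_freq_hz * 2 * n / signal.fs)) + 1)
    H = np.fft.fft(x)
    numer = np.zeros(n)
    denom = np.full(n, abs(np.mean(x)))  # row 0 at frequency 0 adds nothing to numer
    idx = np.arange(n)
    for row in range(1, n_rows):
        mod_row = np.abs(n * np.fft.ifft(H[(idx + row) % n] * _st_gaussian(row, n)))
        freq = row * signal.fs / (2.0 * n)
        numer += freq * mod_row
        denom += mod_row
    f_h = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return InstantaneousFrequency(values_hz=f_h, fs=signal.fs)


def component_avg_frequencies(inst: InstantaneousFrequency, bs: BoundarySet
                              ) -> np.ndarray:
    """Mean instantaneous frequency over each inclusive [onset, offset] span."""
    out = []
    for a, b in zip(bs.onsets, bs.offsets):
        if b < a:
            raise ValueError("empty component span")
        out.append(float(np.mean(inst.values_hz[a:b + 1])))
    return np.asarray(out)


def group_into_beats(bs: BoundarySet, cycle: CycleEstimate,
                     window_frac: float = BEAT_WINDOW_FRAC
                     ) -> list[list[int]]:
    """Partition component indices into beats of one estimated cycle each.

    Each beat window is anchored at the onset of the first component not
    yet assigned and spans window_frac of the average cycle.  Anchoring at
    every beat (rather than on a fixed grid from the first onset) stops
    cycle-estimate error from accumulating across the recording.
    """
    n = bs.n_pairs
    beats: list[list[int]] = []
    i = 0
    window = window_frac * cycle.avg_cycle_samples
    while i < n:
        anchor = bs.onsets[i]
        beat = [i]
        i += 1
        while i < n and bs.onsets[i] < anchor + window:
            beat.append(i)
            i += 1
        beats.append(beat)
    return beats


def _gap_s(bs: BoundarySet, fs: float, a: int, b: int) -> float:
    """Offset-to-onset gap between components a and b (a before b), seconds."""
    return (bs.onsets[b] - bs.offsets[a]) / fs


def recognize_components(beats: list[list[int]], avg_freqs: np.ndarray,
                         bs: BoundarySet, fs: float,
                         s3s4_rule: str = S3S4_PRIORS) -> list[LabeledComponent]:
    """Label every component using the per-beat timing/frequency rules.

    Two components: the shorter of the intra-beat gap and the gap to the
    next beat's first component is the systolic S1->S2 interval.  Three
    components: the lowest-frequency component is the gallop sound; its
    cyclic predecessor is S2 and successor S1, and the gallop resolves to
    S3 (close to S2) or S4 (close to S1) by the timing priors.  Four
    components: the two lowest-frequency components are S3 then S4 in
    cyclic order, flanked by S2 before and S1 after.  Beats with any other
    component count are labelled unknown.
    """
    if s3s4_rule not in (S3S4_PRIORS, S3S4_VERBATIM):
        raise ValueError(f"unknown s3s4_rule {s3s4_rule!r}")
    labels: dict[int, str] = {}
    # orientation of 2-component beats decided so far, for the tail beat
    orientations: list[bool] = []  # True = S1-first
    # gallop (S3-vs-S4) decisions: (component index, decision, informed?);
    # a decision made without a cross-beat neighbor (recording edge) is
    # uninformed and gets overridden by the majority of informed ones
    gallops: list[tuple[int, str, bool]] = []

    for b, beat in enumerate(beats):
        if len(beat) == 2:
            c1, c2 = beat
            next_first = beats[b + 1][0] if b + 1 < len(beats) else None
            if next_first is not None:
                t_intra = _gap_s(bs, fs, c1, c2)
                t_inter = _gap_s(bs, fs, c2, next_first)
                s1_first = t_intra < t_inter
            elif orientations:
                # recording tail: propagate the majority decision so far
                s1_first = sum(orientations) * 2 >= len(orientations)
            else:
                labels[c1] = labels[c2] = "unknown"
                continue
            orientations.append(s1_first)
            labels[c1], labels[c2] = ("S1", "S2") if s1_first else ("S2", "S1")
        elif len(beat) == 3:
            rel = int(np.argmin(avg_freqs[list(beat)]))
            extra = beat[rel]
            before = beat[(rel - 1) % 3]
            after = beat[(rel + 1) % 3]
            labels[before] = "S2"
            labels[after] = "S1"
            # gap from the nearest S2 (cyclically before) and to the nearest
            # S1 (cyclically after); cross-beat neighbors when the gallop
            # sits at the beat edge
            prev_s2 = extra - 1 if extra > 0 else None
            next_s1 = extra + 1 if extra < bs.n_pairs - 1 else None
            gap_before = _gap_s(bs, fs, prev_s2, extra) if prev_s2 is not None else np.inf
            gap_after = _gap_s(bs, fs, extra, next_s1) if next_s1 is not None else np.inf
            informed = np.isfinite(gap_before) and np.isfinite(gap_after)
            if s3s4_rule == S3S4_PRIORS:
                decision = "S3" if gap_before < gap_after else "S4"
            else:
                decision = "S4" if gap_before < gap_after else "S3"
            labels[extra] = decision
            gallops.append((extra, decision, informed))
        elif len(beat) == 4:
            order = np.argsort(avg_freqs[list(beat)])
            low_rel = sorted([int(order[0]), int(order[1])])
            if low_rel == [0, 3]:
                # cyclic wrap: the beat window starts at S4
                rel_s3, rel_s4 = 3, 0
            elif low_rel[1] - low_rel[0] == 1:
                rel_s3, rel_s4 = low_rel
            else:
                # the two low-frequency components are not neighbors: S3 and
                # S4 are always adjacent in a beat, so the frequency evidence
                # is inconsistent — flag the whole beat
                for c in beat:
                    labels[c] = "unknown"
                logger.info("beat %d: non-adjacent low-frequency pair; "
                            "labelled unknown", b)
                continue
            labels[beat[rel_s3]] = "S3"
            labels[beat[rel_s4]] = "S4"
            labels[beat[(rel_s3 - 1) % 4]] = "S2"
            labels[beat[(rel_s4 + 1) % 4]] = "S1"
        else:
            for c in beat:
                labels[c] = "unknown"
            logger.info("beat %d has %d component(s); labelled unknown",
                        b, len(beat))

    # recording-edge gallops (no cross-beat neighbor to compare against)
    # follow the majority of the fully-informed decisions
    informed_votes = [dec for _, dec, inf in gallops if inf]
    if informed_votes:
        majority = max(set(informed_votes), key=informed_votes.count)
        for idx, _, informed in gallops:
            if not informed:
                labels[idx] = majority

    out = []
    for b, beat in enumerate(beats):
        for j, c in enumerate(beat):
            out.append(LabeledComponent(
                label=labels[c], beat_index=b, position_in_beat=j,
                onset_sample=int(bs.onsets[c]), offset_sample=int(bs.offsets[c]),
                avg_freq_hz=float(avg_freqs[c]),
            ))
    return out


def build_segmentation(labeled: list[LabeledComponent], fs: float,
                       cycle: CycleEstimate | None = None) -> Segmentation:
    """Name the gaps between consecutive labelled components (S1S2, S2S1, ...).

    Unknown components contribute no named interval.
    """
    labeled = sorted(labeled, key=lambda c: c.onset_sample)
    intervals = []
    for cur, nxt in zip(labeled, labeled[1:]):
        if cur.label == "unknown" or nxt.label == "unknown":
            continue
        duration = (nxt.onset_sample - cur.offset_sample) / fs
        intervals.append({
            "name": f"{cur.label}{nxt.label}",
            "start_sample": cur.offset_sample,
            "stop_sample": nxt.onset_sample,
            "duration_s": duration,
        })
    return Segmentation(components=labeled, intervals=intervals,
                        cycle=cycle, fs=fs)
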