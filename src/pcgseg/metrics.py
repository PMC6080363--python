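"""Evaluation machinery: SMR, event-detection metrics, paired t-test.

The signal-murmur ratio (SMR) scores murmur elimination: the dB ratio of
signal energy inside component regions (U) to energy inside murmur
regions (V), both fixed on the unfiltered recording so filters are
compared on equal footing.  Boundary detection and identification are
scored as event detection — detections matched one-to-one to ground
truth within a tolerance — with sensitivity, positive predictive value
and accuracy derived from the TP/FN/FP/TN counts.  There is no negative
class in event detection, so TN is structurally zero and accuracy reduces
to TP / (TP + FN + FP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .audio_io import AudioSignal, Annotation


@dataclass(frozen=True)
class RegionMask:
    """Component regions U and murmur regions V as half-open sample ranges."""

    component_ranges: tuple[tuple[int, int], ...]
    murmur_ranges: tuple[tuple[int, int], ...]

    def __post_init__(self):
        comp = tuple((int(a), int(b)) for a, b in self.component_ranges)
        mur = tuple((int(a), int(b)) for a, b in self.murmur_ranges)
        object.__setattr__(self, "component_ranges", comp)
        object.__setattr__(self, "murmur_ranges", mur)
        for a, b in comp + mur:
            if b <= a:
                raise ValueError(f"empty/inverted range ({a}, {b})")
        spans = sorted(comp + mur)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("U and V ranges must be disjoint")

    def to_dict(self) -> dict:
        return {"U": [list(r) for r in self.component_ranges],
                "V": [list(r) for r in self.murmur_ranges]}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionMask":
        return cls(component_ranges=tuple(tuple(r) for r in d["U"]),
                   murmur_ranges=tuple(tuple(r) for r in d["V"]))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")


def _region_energy(x: np.ndarray, ranges) -> float:
    return float(sum(np.sum(x[a:b] ** 2) for a, b in ranges))


def smr(signal: AudioSignal, mask: RegionMask) -> float:
    """Signal-murmur ratio in dB: 10 log10(energy in U / energy in V)."""
    if not mask.component_ranges or not mask.murmur_ranges:
        raise ValueError("both component (U) and murmur (V) regions are required")
    u = _region_energy(signal.samples, mask.component_ranges)
    v = _region_energy(signal.samples, mask.murmur_ranges)
    if v == 0:
        raise ValueError("murmur-region energy is zero; SMR undefined")
    return 10.0 * np.log10(u / v)


def smr_gain(filtered_smr: float, original_smr: float) -> float:
    """SMR improvement of a filter over the unfiltered recording, dB."""
    return filtered_smr - original_smr


def percent_gain(a_db: float, b_db: float) -> float:
    """Relative improvement of a over b in percent: (a - b) / b * 100."""
    if b_db == 0:
        raise ValueError("reference gain is zero; percent gain undefined")
    return (a_db - b_db) / b_db * 100.0


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(Se, PPV, Acc) in percent.  Errors on a zero denominator."""
    if c.tp + c.fn == 0:
        raise ValueError("Se undefined: TP + FN == 0")
    if c.tp + c.fp == 0:
        raise ValueError("PPV undefined: TP + FP == 0")
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise ValueError("Acc undefined: no counts")
    se = c.tp / (c.tp + c.fn) * 100.0
    ppv = c.tp / (c.tp + c.fp) * 100.0
    acc = (c.tp + c.tn) / total * 100.0
    return se, ppv, acc


def match_detections(predicted: list[Annotation], truth: list[Annotation],
                     tol_s: float = 0.05, require_label: bool = False
                     ) -> ConfusionCounts:
    """Greedy one-to-one onset matching of detections to ground truth.

    Predictions are taken in time order; each claims the nearest unmatched
    truth whose onset lies within ``tol_s``.  Matched pairs count as TP
    (with label equality additionally required when ``require_label``);
    unmatched predictions are FP, unmatched truths FN.  TN stays zero —
    event detection has no negative class.
    """
    if tol_s < 0:
        raise ValueError("tolerance must be nonnegative")
    truth = sorted(truth, key=lambda a: a.onset_s)
    predicted = sorted(predicted, key=lambda a: a.onset_s)
    matched = [False] * len(truth)
    tp = fp = mislabeled = 0
    for pred in predicted:
        best, best_d = None, tol_s
        for i, t in enumerate(truth):
            if matched[i]:
                continue
            d = abs(t.onset_s - pred.onset_s)
            if d <= best_d:
                best, best_d = i, d
        if best is None:
            fp += 1
        elif require_label and truth[best].label != pred.label:
            # position matched but label wrong: the truth is still missed
            matched[best] = True
            fp += 1
            mislabeled += 1
        else:
            matched[best] = True
            tp += 1
    fn = matched.count(False) + mislabeled
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=0)


def paired_t(x, y) -> float:
    """Paired two-sample t statistic: mean(d) / (sd(d) / sqrt(n)), d = x - y.

    Uses the sample standard deviation (divisor n - 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D sequences of length >= 2")
    d = x - y
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    return float(np.mean(d) / (sd / np.sqrt(len(d))))


def t_critical(alpha: float, df: int) -> float:
    """Two-sided critical value: upper alpha/2 quantile of Student's t."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))
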