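"""Heart-rate and QRS-duration correction of QT, and long-QT classification.

QTc uses Bazett's formula, QTc = QT / sqrt(RR in seconds).  In wide-QRS
records (QRS >= 120 ms, e.g. bundle branch block) the manual protocol
additionally subtracts the conduction-delay excess: QTc_adj = QTc - (QRS -
100 ms).  Long QT is a sex-specific, inclusive threshold: QTc >= 470 ms in
males, >= 480 ms in females.  Paired automated/manual calls are labeled with
the manual measurement as the gold standard, so a false positive is an
automated long-QT call that the manual measurement does not confirm.

All values are carried at full floating precision; rounding to integer
milliseconds is a reporting concern and is applied before classification
only if explicitly requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MALE_LQT_THRESHOLD_MS = 470.0
FEMALE_LQT_THRESHOLD_MS = 480.0
QRS_ADJUST_CUTOFF_MS = 120.0
QRS_ADJUST_REFERENCE_MS = 100.0


def bazett(qt_ms: float, rr_ms: float) -> float:
    """Bazett heart-rate correction: QT / sqrt(RR in seconds)."""
    if not (qt_ms > 0 and rr_ms > 0):
        raise ValueError("qt_ms and rr_ms must be positive")
    return qt_ms / math.sqrt(rr_ms / 1000.0)


def qrs_adjust(
    qtc_ms: float,
    qrs_ms: float,
    cutoff_ms: float = QRS_ADJUST_CUTOFF_MS,
    reference_ms: float = QRS_ADJUST_REFERENCE_MS,
) -> float:
    """Subtract conduction delay in wide-QRS records.

    For QRS >= cutoff (120 ms): QTc_adj = QTc - (QRS - 100).  Narrower QRS
    leaves QTc unchanged.
    """
    if not (qtc_ms > 0 and qrs_ms > 0):
        raise ValueError("qtc_ms and qrs_ms must be positive")
    if qrs_ms < cutoff_ms:
        return qtc_ms
    adjusted = qtc_ms - (qrs_ms - reference_ms)
    if adjusted <= 0:
        raise ValueError("QRS adjustment produced a non-positive QTc")
    return adjusted


def classify_lqt(
    qtc_ms: float,
    sex: str,
    male_threshold_ms: float = MALE_LQT_THRESHOLD_MS,
    female_threshold_ms: float = FEMALE_LQT_THRESHOLD_MS,
    round_to_ms: bool = False,
) -> bool:
    """Sex-specific long-QT call (thresholds inclusive)."""
    if sex == "M":
        thr = male_threshold_ms
    elif sex == "F":
        thr = female_threshold_ms
    else:
        raise ValueError(f"unknown sex {sex!r}; expected 'M' or 'F'")
    value = round(qtc_ms) if round_to_ms else qtc_ms
    return value >= thr


def label_pair(auto_lqt: bool, manual_lqt: bool) -> str:
    """2x2 category with the manual call as gold standard."""
    if auto_lqt and manual_lqt:
        return "TP"
    if auto_lqt and not manual_lqt:
        return "FP"
    if not auto_lqt and manual_lqt:
        return "FN"
    return "TN"


@dataclass(frozen=True)
class QtcResult:
    """Full corrected-QT determination for one measurement."""

    qt_ms: float
    rr_ms: float
    qtc_bazett_ms: float
    qrs_ms: float
    qtc_adjusted_ms: float
    sex: str
    lqt: bool


@dataclass(frozen=True)
class PairedCall:
    """One record's paired automated/manual long-QT calls."""

    record_id: str
    auto_lqt: bool
    manual_lqt: bool

    @property
    def category(self) -> str:
        return label_pair(self.auto_lqt, self.manual_lqt)


def correct_manual(qt_ms: float, rr_ms: float, qrs_ms: float,
                   sex: str) -> QtcResult:
    """Manual pipeline: Bazett then QRS adjustment; classify on the adjusted value."""
    qtc_b = bazett(qt_ms, rr_ms)
    qtc_a = qrs_adjust(qtc_b, qrs_ms)
    return QtcResult(qt_ms, rr_ms, qtc_b, qrs_ms, qtc_a, sex,
                     classify_lqt(qtc_a, sex))
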