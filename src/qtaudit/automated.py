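"""Stylized emulator of an ECG machine's automated QT/QTc.

This is an explicit mechanistic caricature of how bedside electrocardiographs
over-read QTc relative to a human using the tangent method, built from the
mechanisms clinically attributed to them:

* **lead superimposition** — the machine overlays all leads, so its QT runs
  from the *earliest* QRS onset in any lead to the *latest* T-end in any
  lead, which can only be at least as long as any single lead's QT;
* **no QRS-duration adjustment** — the machine applies Bazett's heart-rate
  correction but does not subtract conduction delay in wide-QRS records;
* **global-average RR** — the machine corrects with the record-mean RR, not
  the RR of the measured beat.

It also renders the machine's interpretation banner: a numerically long QTc
may or may not be accompanied by a "prolonged QT" statement; the machine's
real decision logic is unknown and is modeled as a Bernoulli suppression
flag with a configurable probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import qtc as qtc_mod
from .delineate import Beat, beat_fiducials, detect_beats, select_beats
from .errors import ExcludedRecordError, UnmeasurableTError
from .synth import ECGRecord, GroundTruth, STANDARD_LEADS

DEFAULT_SUPPRESSION_PROB = 0.75


@dataclass(frozen=True)
class AutoMeasurement:
    """One automated QT/QTc determination."""

    qt_ms: float
    rr_ms: float
    qtc_ms: float
    interpretation_text: str = ""
    suppressed: bool = False

    def __post_init__(self) -> None:
        if self.qt_ms < 0:
            raise ValueError("qt_ms must be non-negative")


def superimposed_qt(
    onsets_ms: Mapping[str, float], t_ends_ms: Mapping[str, float]
) -> float:
    """Earliest-onset-to-latest-end rule over the measurable leads."""
    if not onsets_ms or not t_ends_ms:
        raise ExcludedRecordError("no measurable lead for automated QT")
    return max(t_ends_ms.values()) - min(onsets_ms.values())


def automated_qt(
    record: ECGRecord,
    beats: list[Beat] | None = None,
    truth: GroundTruth | None = None,
    rhythm_kind: str | None = None,
) -> AutoMeasurement:
    """Automated QT/QTc on one record.

    Uses the same beat selection as the manual protocol, but on each measured
    beat pools fiducials across every measurable lead (min onset, max T-end),
    corrects with Bazett only, and uses the record-mean RR.
    """
    if beats is None:
        beats = detect_beats(record, truth=truth)
    rhythm = rhythm_kind or str(record.meta.get("rhythm", "sinus"))
    classes = [b.beat_class for b in beats]
    rrs = [b.rr_preceding_ms for b in beats]
    beats_used, _ = select_beats(classes, rhythm, rrs)

    fs = record.sample_rate_hz
    beat_qts: list[float] = []
    for bi in beats_used:
        nxt = beats[bi + 1].qrs_onset_ms if bi + 1 < len(beats) else None
        onsets: dict[str, float] = {}
        ends: dict[str, float] = {}
        for lead in record.lead_names:
            if lead not in STANDARD_LEADS:
                continue
            try:
                fid = beat_fiducials(record.lead(lead), fs, beats[bi], nxt,
                                     lead=lead)
            except (UnmeasurableTError, ValueError):
                continue
            onsets[lead] = fid.qrs_onset_ms
            ends[lead] = fid.t_end_ms
        if onsets:
            beat_qts.append(superimposed_qt(onsets, ends))
    if not beat_qts:
        raise ExcludedRecordError("no measurable lead for automated QT")

    qt = float(np.mean(beat_qts))
    finite_rr = [r for r in rrs if np.isfinite(r)]
    rr = float(np.mean(finite_rr)) if finite_rr else float("nan")
    qtc = qtc_mod.bazett(qt, rr)
    return AutoMeasurement(qt_ms=qt, rr_ms=rr, qtc_ms=qtc)


def render_interpretation(
    qtc_ms: float,
    sex: str,
    suppression_prob: float = DEFAULT_SUPPRESSION_PROB,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, bool]:
    """Machine interpretation banner for a QTc value.

    When the QTc meets the sex-specific long-QT threshold, the "prolonged QT"
    statement is omitted (suppressed) with probability ``suppression_prob``.
    Records below threshold never mention it.
    """
    if not 0.0 <= suppression_prob <= 1.0:
        raise ValueError("suppression_prob must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lqt = qtc_mod.classify_lqt(qtc_ms, sex)
    if not lqt:
        return f"QTc {qtc_ms:.0f} ms. No acute abnormality.", False
    suppressed = bool(rng.random() < suppression_prob)
    if suppressed:
        return f"QTc {qtc_ms:.0f} ms. Borderline ECG.", True
    return f"QTc {qtc_ms:.0f} ms. Prolonged QT.", False
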