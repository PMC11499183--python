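"""Algorithmic realization of the manual tangent-method QT protocol.

The measurement chain mirrors what a trained reader does with calipers:

1. estimate the isoelectric baseline from the quiet PR segment;
2. find the beats (derivative-and-threshold QRS detection) and classify them
   from RR pattern and QRS width (normal / PVC / PAC / post-ectopic);
3. pick the beats to measure — ectopic beats and the beat immediately after
   an ectopic are avoided, atrial fibrillation is averaged over five beats,
   bigeminal records are excluded as unmeasurable;
4. on each lead, drop a tangent on the steepest terminal limb of the T wave
   and take its intersection with the baseline as T-end (U waves, whose limbs
   are shallower and later, never carry the steepest slope and are ignored);
5. QT = QRS onset to tangent T-end; the reported lead is II or V5 unless
   another standard lead reads longer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import ExcludedRecordError, UnmeasurableTError, UnusableRecordError
from .synth import ECGRecord, GroundTruth, STANDARD_LEADS

PRIMARY_LEADS: tuple[str, ...] = ("II", "V5")

# tunables of the delineator, in the units a reader would use
BASELINE_WINDOW_MS = (60.0, 20.0)   # window before QRS onset (PR segment proxy)
SLOPE_SMOOTH_MS = 20.0              # derivative smoothing window
MIN_TANGENT_SLOPE = 2.5e-4          # mV/ms; flatter limbs are unmeasurable
MIN_R_AMPLITUDE_MV = 0.25           # reject "beats" smaller than this
WIDE_QRS_MS = 120.0                 # wide-complex threshold
PREMATURITY_FRACTION = 0.85         # RR below this fraction of median = early
LEAD_TIE_TOLERANCE_MS = 8.0         # QT differences a reader cannot resolve
T_LOC_SMOOTH_MS = 40.0              # heavy smoothing for limb localization
MIN_SLOPE_TSTAT = 4.0               # tangent slope must beat noise by this
MAX_T_END_SE_MS = 8.0               # leads less precise than this are unreadable


@dataclass(frozen=True)
class BeatFiducials:
    """Detected landmarks for one beat on one lead (absolute ms)."""

    lead: str
    qrs_onset_ms: float
    r_peak_ms: float
    t_peak_ms: float
    t_end_ms: float
    baseline_mv: float
    rr_preceding_ms: float  # nan for the first beat

    def __post_init__(self) -> None:
        if not self.qrs_onset_ms < self.r_peak_ms < self.t_peak_ms < self.t_end_ms:
            raise ValueError("fiducials must be ordered onset < R < Tpeak < Tend")


@dataclass(frozen=True)
class Measurement:
    """One QT/RR determination for a record."""

    qt_ms: float
    rr_ms: float
    lead_used: str
    n_beats_averaged: int
    beats_used: tuple[int, ...]
    method: str  # manual_tangent | automated_global
    flagged: bool = False  # e.g. AF averaged over fewer than five beats

    def __post_init__(self) -> None:
        if self.qt_ms <= 0:
            raise ValueError("qt_ms must be positive")
        if self.n_beats_averaged < 1:
            raise ValueError("n_beats_averaged must be >= 1")


@dataclass(frozen=True)
class Beat:
    """Record-level beat bookkeeping from the reference lead."""

    index: int
    r_peak_ms: float
    qrs_onset_ms: float
    qrs_offset_ms: float
    rr_preceding_ms: float
    beat_class: str


def estimate_baseline(signal: np.ndarray, window: slice) -> float:
    """Median amplitude over a pre-QRS window (robust isoelectric estimate)."""
    seg = np.asarray(signal)[window]
    if seg.size < 10:
        raise ValueError("baseline window must contain at least 10 samples")
    return float(np.median(seg))


def _smoothed_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """Savitzky-Golay first derivative in mV/ms."""
    w = int(round(SLOPE_SMOOTH_MS * fs / 1000.0))
    w = max(5, w | 1)  # odd, >= 5
    return savgol_filter(x, window_length=w, polyorder=2, deriv=1,
                         delta=1000.0 / fs)


def _smooth(x: np.ndarray, fs: float, window_ms: float = 15.0) -> np.ndarray:
    w = int(round(window_ms * fs / 1000.0))
    w = max(5, w | 1)
    return savgol_filter(x, window_length=w, polyorder=2)


def _qrs_bounds(x: np.ndarray, fs: float, r_idx: int,
                xs: np.ndarray | None = None) -> tuple[float, float]:
    """QRS onset/offset (ms) around one R peak by return-to-baseline.

    Works on a lightly smoothed trace so measurement noise does not drag the
    walk past the true edge.  Walking out from the R peak, the QRS ends where
    the trace sits within a small band around a provisional local baseline
    for three consecutive samples (a single zero-crossing inside the complex
    cannot satisfy that).
    """
    ms = 1000.0 / fs
    n = x.size
    if xs is None:
        xs = _smooth(x, fs)
    lo = max(0, r_idx - int(90 / ms))
    hi = max(lo + 1, r_idx - int(60 / ms))
    base = float(np.median(xs[lo:hi])) if hi - lo >= 3 else float(np.median(xs))
    ramp = abs(xs[r_idx] - base)
    thr = max(0.02 * ramp, 0.025)
    below = np.abs(xs - base) < thr

    onset_idx = max(0, r_idx - int(130 / ms))
    for i in range(r_idx, max(1, r_idx - int(130 / ms)), -1):
        if i >= 2 and below[i] and below[i - 1] and below[i - 2]:
            onset_idx = i
            break
    offset_idx = min(n - 1, r_idx + int(170 / ms))
    for i in range(r_idx, min(n - 2, r_idx + int(170 / ms))):
        if below[i] and below[i + 1] and below[i + 2]:
            offset_idx = i
            break
    return onset_idx * ms, offset_idx * ms


def detect_beats(
    record: ECGRecord,
    truth: GroundTruth | None = None,
    reference_lead: str = "II",
) -> list[Beat]:
    """Find beats on the reference lead and classify them from RR and width.

    With ``truth`` given, detection is bypassed and beats are taken from the
    generator's ground truth (oracle pass-through mode).
    """
    if truth is not None:
        return [
            Beat(i, b.qrs_onset_ms + 35.0, b.qrs_onset_ms, b.qrs_offset_ms,
                 b.rr_preceding_ms, b.beat_class)
            for i, b in enumerate(truth.beats)
        ]
    if len(record.lead_names) < 1:
        raise UnusableRecordError("record has no leads")
    try:
        x = record.lead(reference_lead)
    except KeyError:
        x = record.signals[0]
    fs = record.sample_rate_hz
    ms = 1000.0 / fs

    d = np.abs(np.gradient(x) / ms)  # mV per ms
    k = max(3, int(round(0.02 * fs)))
    ds = np.convolve(d, np.ones(k) / k, mode="same")
    if ds.max() <= 0:
        raise UnusableRecordError("flat record, no beats found")
    peaks, _ = find_peaks(ds, distance=max(1, int(0.25 * fs)),
                          height=0.25 * ds.max())
    med = float(np.median(x))
    half = int(60 / ms)
    r_peaks: list[int] = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half)
        r = lo + int(np.argmax(np.abs(x[lo:hi] - med)))
        if abs(x[r] - med) < MIN_R_AMPLITUDE_MV:
            continue
        if not r_peaks or r - r_peaks[-1] > int(0.2 * fs):
            r_peaks.append(r)
    if len(r_peaks) < 2:
        raise UnusableRecordError("no beats found")

    bounds = [_qrs_bounds(x, fs, r) for r in r_peaks]
    rrs = [float("nan")] + [
        (r_peaks[i] - r_peaks[i - 1]) * ms for i in range(1, len(r_peaks))
    ]
    med_rr = float(np.nanmedian(rrs)) if len(rrs) > 1 else float("nan")

    beats: list[Beat] = []
    prev_ectopic = False
    for i, (r, (on, off)) in enumerate(zip(r_peaks, bounds)):
        width = off - on
        premature = (not math.isnan(rrs[i])
                     and rrs[i] < PREMATURITY_FRACTION * med_rr)
        if premature and width >= WIDE_QRS_MS:
            cls = "pvc"
        elif premature:
            cls = "pac"
        elif prev_ectopic:
            cls = "post_ectopic"
        else:
            cls = "normal"
        prev_ectopic = cls in ("pvc", "pac")
        beats.append(Beat(i, r * ms, on, off, rrs[i], cls))
    return beats


def tangent_t_end(
    signal: np.ndarray,
    fs: float,
    t_peak_ms: float,
    baseline_mv: float,
    search_end_ms: float,
) -> float:
    """T-wave end by the tangent method.

    Finds the steepest point of the terminal limb (maximum slope *toward*
    the baseline after the T apex — descending for an upright T, ascending
    for an inverted one), fits a line to the raw samples around it, and
    returns the line's intersection with the baseline level, with sub-sample
    resolution.  Later, shallower deflections (U waves) beyond the crossing
    play no role.
    """
    x = np.asarray(signal, dtype=float)
    ms = 1000.0 / fs
    i0 = int(round(t_peak_ms / ms))
    i1 = min(x.size - 1, int(round(search_end_ms / ms)))
    if not 0 <= i0 < i1 - 3:
        raise UnmeasurableTError("T search window too small")
    xl = _smooth(x, fs, T_LOC_SMOOTH_MS)  # heavy: localization only
    amp = xl[i0] - baseline_mv
    if amp == 0:
        raise UnmeasurableTError("T apex is on the baseline")
    toward = -np.sign(amp)  # slope sign that heads back to baseline

    # the terminal limb: where the deflection has decayed from 85% to 20% of
    # the apex amplitude -- the stretch a reader aligns the ruler to,
    # bracketing the inflection point where the limb is steepest
    rel = (xl[i0:i1 + 1] - baseline_mv) / amp
    past_hi = np.nonzero(rel < 0.85)[0]
    if past_hi.size == 0:
        raise UnmeasurableTError("T wave never leaves its apex in the window")
    j_hi = int(past_hi[0])
    past_lo = np.nonzero(rel[j_hi:] < 0.20)[0]
    if past_lo.size:
        j_lo = j_hi + int(past_lo[0])
    else:
        j_lo = j_hi + int(np.argmin(rel[j_hi:]))
        if rel[j_lo] > 0.6:
            raise UnmeasurableTError("terminal limb too flat for a tangent")
    lo, hi = i0 + j_hi, i0 + j_lo
    if hi - lo < 4:
        hi = min(x.size - 1, lo + 4)
    region_ms = (hi - lo) * ms

    # tangent at the steepest point: cubic fit of the lightly smoothed limb,
    # tangent taken at the cubic's inflection (straight fit for short limbs)
    fit_ms = float(np.clip(region_ms / 3.0, 10.0, 25.0))
    xf = _smooth(x, fs, fit_ms)
    t_local = np.arange(lo, hi + 1) * ms
    t_mid = t_local.mean()
    deg = 3 if hi - lo >= 6 else 1
    coeffs = np.polyfit(t_local - t_mid, xf[lo:hi + 1], deg)
    if deg == 3:
        c3, c2 = coeffs[0], coeffs[1]
        t_star = -c2 / (3 * c3) if c3 != 0 else 0.0
        if not t_local[0] - t_mid <= t_star <= t_local[-1] - t_mid:
            t_star = 0.0  # inflection outside the limb: tangent at its middle
    else:
        t_star = 0.0
    dcoeffs = np.polyder(coeffs)
    slope = float(np.polyval(dcoeffs, t_star))
    value = float(np.polyval(coeffs, t_star))
    t0 = t_star + t_mid
    fitted = np.polyval(coeffs, t_local - t_mid)
    if abs(slope) < MIN_TANGENT_SLOPE or np.sign(slope) != toward:
        raise UnmeasurableTError("tangent parallel to baseline")

    # the tangent must beat the record's noise: slope t-statistic against the
    # raw-sample residual scatter (flat or noise-dominated T -> unmeasurable)
    resid_sd = float(np.std(x[lo:hi + 1] - fitted))
    npts = hi - lo + 1
    span = max(t_local[-1] - t_local[0], ms)
    slope_se = resid_sd * math.sqrt(12.0 / npts) / span
    if slope_se > 0 and abs(slope) / slope_se < MIN_SLOPE_TSTAT:
        raise UnmeasurableTError("tangent slope indistinguishable from noise")

    t_end = t0 + (baseline_mv - value) / slope

    # precision gate: delta-method standard error of the crossing point.  A
    # reader does not report a longer QT from a lead whose T-end cannot be
    # read to caliper precision; such leads are unmeasurable, not evidence.
    if resid_sd > 0:
        X = np.vander(t_local - t_mid, deg + 1)
        try:
            C = np.linalg.inv(X.T @ X) * resid_sd**2
        except np.linalg.LinAlgError:
            raise UnmeasurableTError("degenerate tangent fit")
        phi = np.array([t_star ** k for k in range(deg, -1, -1)])
        psi = np.array([k * t_star ** (k - 1) if k > 0 else 0.0
                        for k in range(deg, -1, -1)])
        excess = (baseline_mv - value) / slope
        grad = -phi / slope - excess * psi / slope
        t_end_se = float(math.sqrt(max(grad @ C @ grad, 0.0)))
        if t_end_se > MAX_T_END_SE_MS:
            raise UnmeasurableTError("T-end less precise than caliper resolution")

    if not t_peak_ms < t_end <= min(search_end_ms + 100.0,
                                    t_local[-1] + 1.5 * region_ms):
        raise UnmeasurableTError("tangent crossing outside the T window")
    return float(t_end)


def measure_lead_qt(fiducials: BeatFiducials) -> float:
    """QT in ms: QRS onset to tangent T-end."""
    qt = fiducials.t_end_ms - fiducials.qrs_onset_ms
    if qt <= 0:
        raise ValueError("non-positive QT")
    return qt


def beat_fiducials(
    x: np.ndarray,
    fs: float,
    beat: Beat,
    next_onset_ms: float | None,
    lead: str = "",
) -> BeatFiducials:
    """Per-lead landmarks for one beat.

    The QRS is re-localized on this lead (leads see activation at slightly
    different times), the baseline is the median of the 60-20 ms pre-onset
    segment, and T-end comes from the tangent rule.
    """
    ms = 1000.0 / fs
    n = x.size
    # local R peak near the reference-lead R peak
    c = int(round(beat.r_peak_ms / ms))
    lo, hi = max(0, c - int(40 / ms)), min(n, c + int(40 / ms))
    if hi - lo < 3:
        raise UnmeasurableTError("beat too close to the record edge")
    med = float(np.median(x))
    r_idx = lo + int(np.argmax(np.abs(x[lo:hi] - med)))
    onset_ms, offset_ms = _qrs_bounds(x, fs, r_idx)

    b0 = int(round((onset_ms - BASELINE_WINDOW_MS[0]) / ms))
    b1 = int(round((onset_ms - BASELINE_WINDOW_MS[1]) / ms))
    if b0 < 0 or b1 - b0 < 10:
        raise UnmeasurableTError("no room for a baseline window before QRS")
    baseline = estimate_baseline(x, slice(b0, b1))

    t_lo = offset_ms + 30.0
    t_hi = onset_ms + 600.0
    if next_onset_ms is not None:
        t_hi = min(t_hi, next_onset_ms - 30.0)
    t_hi = min(t_hi, (n - 2) * ms)
    j0, j1 = int(round(t_lo / ms)), int(round(t_hi / ms))
    if j1 - j0 < 5:
        raise UnmeasurableTError("no T search window")
    t_peak_idx = j0 + int(np.argmax(np.abs(x[j0:j1] - baseline)))
    t_peak_ms = t_peak_idx * ms
    t_end = tangent_t_end(x, fs, t_peak_ms, baseline, t_hi)
    return BeatFiducials(
        lead=lead,
        qrs_onset_ms=onset_ms,
        r_peak_ms=r_idx * ms,
        t_peak_ms=t_peak_ms,
        t_end_ms=t_end,
        baseline_mv=baseline,
        rr_preceding_ms=beat.rr_preceding_ms,
    )


def select_beats(
    beat_classes: Sequence[str],
    rhythm_kind: str,
    rr_ms: Sequence[float],
) -> tuple[list[int], bool]:
    """Choose which beats the protocol measures.

    Ectopic and post-ectopic beats are avoided; bigeminal rhythm makes the
    record unmeasurable.  AF is averaged over the first five usable beats
    (fewer usable beats -> average over all, flagged).  For regular rhythms
    one representative beat is read: the usable beat whose preceding RR is
    closest to the record's median RR.
    """
    if len(beat_classes) < 1:
        raise UnusableRecordError("no beats to select from")
    ectopic = [i for i, c in enumerate(beat_classes) if c in ("pvc", "pac")]
    if len(ectopic) >= 3 and all(b - a == 2 for a, b in
                                 zip(ectopic, ectopic[1:])):
        raise ExcludedRecordError("bigeminal rhythm: QT not measurable")
    usable = [
        i for i, c in enumerate(beat_classes)
        if c == "normal" and i < len(rr_ms) and math.isfinite(rr_ms[i])
    ]
    if not usable:
        raise ExcludedRecordError("no usable beat in record")
    if rhythm_kind == "af":
        if len(usable) >= 5:
            return usable[:5], False
        return usable, True
    finite = [r for r in rr_ms if isinstance(r, (int, float)) and math.isfinite(r)]
    med = float(np.median(finite)) if finite else float("nan")
    best = min(usable, key=lambda i: (abs(rr_ms[i] - med), i))
    return [best], False


def choose_lead(
    lead_qt_ms: Mapping[str, float],
    primary_leads: Sequence[str] = PRIMARY_LEADS,
) -> tuple[str, float]:
    """Lead-selection rule: II or V5 unless another lead reads longer.

    The longest measurable QT wins; differences below the reader's caliper
    resolution (~8 ms) count as ties, broken in favour of II, then V5, then
    the remaining leads in record order.
    """
    if not lead_qt_ms:
        raise ExcludedRecordError("no measurable lead")
    ranks = {lead: i for i, lead in enumerate(primary_leads)}
    order = list(lead_qt_ms)
    qt_max = max(lead_qt_ms.values())
    tied = [l for l, q in lead_qt_ms.items() if q >= qt_max - LEAD_TIE_TOLERANCE_MS]
    lead = min(tied, key=lambda l: (ranks.get(l, len(ranks) + order.index(l))))
    return lead, lead_qt_ms[lead]


def manual_qt(
    record: ECGRecord,
    beats: list[Beat] | None = None,
    truth: GroundTruth | None = None,
    rhythm_kind: str | None = None,
    primary_leads: Sequence[str] = PRIMARY_LEADS,
) -> Measurement:
    """Full manual protocol on one record -> a single QT/RR Measurement.

    Only standard 12-lead names participate in the lead rule; unknown leads
    are carried in the record but never selected.
    """
    if beats is None:
        beats = detect_beats(record, truth=truth)
    rhythm = rhythm_kind or str(record.meta.get("rhythm", "sinus"))
    classes = [b.beat_class for b in beats]
    rrs = [b.rr_preceding_ms for b in beats]
    beats_used, flagged = select_beats(classes, rhythm, rrs)

    fs = record.sample_rate_hz
    lead_qt: dict[str, float] = {}
    lead_nbeats: dict[str, int] = {}
    for lead in record.lead_names:
        if lead not in STANDARD_LEADS:
            continue
        x = record.lead(lead)
        qts = []
        for bi in beats_used:
            nxt = beats[bi + 1].qrs_onset_ms if bi + 1 < len(beats) else None
            try:
                fid = beat_fiducials(x, fs, beats[bi], nxt, lead=lead)
                qts.append(measure_lead_qt(fid))
            except (UnmeasurableTError, ValueError):
                continue
        if qts:
            lead_qt[lead] = float(np.mean(qts))
            lead_nbeats[lead] = len(qts)
    if not lead_qt:
        raise ExcludedRecordError("QT not measurable on any lead")
    lead, qt = choose_lead(lead_qt, primary_leads)

    if rhythm == "af":
        rr = float(np.mean([beats[i].rr_preceding_ms for i in beats_used]))
    else:
        rr = float(beats[beats_used[0]].rr_preceding_ms)
    return Measurement(
        qt_ms=qt,
        rr_ms=rr,
        lead_used=lead,
        n_beats_averaged=lead_nbeats[lead],
        beats_used=tuple(beats_used),
        method="manual_tangent",
        flagged=flagged or lead_nbeats[lead] < len(beats_used),
    )


def measure_qrs_ms(
    record: ECGRecord,
    beats: list[Beat],
    beats_used: Sequence[int],
) -> float:
    """QRS duration (ms): median width over the measured beats (reference lead)."""
    widths = [beats[i].qrs_offset_ms - beats[i].qrs_onset_ms for i in beats_used]
    if not widths:
        raise UnusableRecordError("no beats to measure QRS on")
    return float(np.median(widths))
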