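"""Synthetic 12-lead ECG generator with analytically known fiducials.

Each beat is a sum of gaussian deflections (P, Q, R, S, T, optional U), in the
style of classic dynamical ECG simulators.  The gaussian T wave gives the
generator an exact, closed-form "tangent" T-end: the tangent at the descending
limb's inflection point (center + sigma) crosses the baseline at
center + 2*sigma.  Ground-truth QT is therefore defined tangent-consistently,
from QRS onset to t_center + 2*t_sigma, matching the manual measurement
protocol the delineator implements — the gold standard here *is* the tangent
method, so the truth is defined on its terms.

Leads are scaled copies of one beat template with small fixed per-lead time
shifts (ventricular activation reaches different leads at slightly different
times).  Per-lead QT is shift-invariant, so the shifts do not move the manual
measurement; they are what makes the "superimpose all leads" automated rule
read longer than any single lead.

A cohort generator draws covariates (sex, rhythm, BBB, artifact, ectopy,
U waves, heart rate, target QTc) matching an unselected hospital ECG
population and synthesizes one record per row.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UnusableRecordError

STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

# Relative deflection size per lead (dimensionless; lead II is the reference).
# aVR is negative: its axis points away from the mean QRS/T vector.
DEFAULT_LEAD_SCALE: dict[str, float] = {
    "I": 0.7, "II": 1.0, "III": 0.5, "aVR": -0.6, "aVL": 0.4, "aVF": 0.6,
    "V1": 0.5, "V2": 0.8, "V3": 0.9, "V4": 1.0, "V5": 1.0, "V6": 0.8,
}

# Fixed per-lead activation delays in ms (multiples of the 2 ms sample period
# at the default 500 Hz).  Spread −10..+8 ms; II and V5 are the zero reference,
# so per-lead QT equals the template QT everywhere while the across-lead
# earliest-onset/latest-end span exceeds any single lead's QT by ~18 ms.
DEFAULT_LEAD_SHIFT_MS: dict[str, float] = {
    "I": 0.0, "II": 0.0, "III": -4.0, "aVR": 2.0, "aVL": -2.0, "aVF": 0.0,
    "V1": -10.0, "V2": -6.0, "V3": -4.0, "V4": -2.0, "V5": 0.0, "V6": 8.0,
}

_FIRST_BEAT_MS = 400.0   # onset of the first beat after record start
_TAIL_PAD_MS = 250.0     # room required after T-end for a beat to count


@dataclass(frozen=True)
class WaveComponent:
    """One gaussian deflection of a beat template."""

    center_ms: float
    sigma_ms: float
    amplitude_mv: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma_ms <= 0:
            raise ValueError("sigma_ms must be positive")
        if not math.isfinite(self.amplitude_mv):
            raise ValueError("amplitude_mv must be finite")
        if self.shape != "gaussian":
            raise ValueError(f"unsupported shape {self.shape!r}")


@dataclass(frozen=True)
class BeatTemplate:
    """Gaussian-sum beat morphology with tangent-consistent QT truth.

    Times are in ms relative to QRS onset (so ``qrs_onset_ms`` is normally 0).
    """

    components: tuple[WaveComponent, ...]
    qrs_onset_ms: float
    qrs_offset_ms: float
    t_center_ms: float
    t_sigma_ms: float

    def __post_init__(self) -> None:
        if not self.qrs_onset_ms < self.qrs_offset_ms < self.t_center_ms:
            raise ValueError("need qrs_onset < qrs_offset < t_center")
        if self.t_sigma_ms <= 0:
            raise ValueError("t_sigma_ms must be positive")

    @property
    def true_qt_ms(self) -> float:
        """QRS onset to the tangent T-end (t_center + 2 t_sigma)."""
        return self.t_center_ms + 2.0 * self.t_sigma_ms - self.qrs_onset_ms

    @property
    def true_qrs_ms(self) -> float:
        return self.qrs_offset_ms - self.qrs_onset_ms

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Sample the template (mV) on an absolute-relative time axis."""
        out = np.zeros_like(t_ms, dtype=float)
        for c in self.components:
            # restrict to ±6 sigma: exp() there is < 2e-8, below any signal
            lo, hi = c.center_ms - 6 * c.sigma_ms, c.center_ms + 6 * c.sigma_ms
            m = (t_ms >= lo) & (t_ms <= hi)
            if m.any():
                z = (t_ms[m] - c.center_ms) / c.sigma_ms
                out[m] += c.amplitude_mv * np.exp(-0.5 * z * z)
        return out


def make_beat_template(
    *,
    qt_ms: float = 400.0,
    sex: str = "M",
    bbb: bool = False,
    include_p: bool = True,
    u_wave: bool = False,
) -> BeatTemplate:
    """Build the default sinus beat template for a given true QT.

    Sex shapes the T wave (smaller, narrower/earlier T for females); BBB
    widens the QRS to 130 ms and inverts the T (discordant repolarization).
    """
    t_sigma = 45.0 if sex == "F" else 50.0
    t_amp = 0.30 if sex == "F" else 0.35
    comps: list[WaveComponent] = []
    if include_p:
        comps.append(WaveComponent(-140.0, 22.0, 0.12))
    if bbb:
        # broad notched complex; R and S overlap so the trace never returns
        # to baseline inside the QRS
        comps += [
            WaveComponent(10.0, 5.0, -0.08),
            WaveComponent(45.0, 14.0, 1.10),
            WaveComponent(100.0, 12.0, -0.30),
        ]
        qrs_offset = 124.0
        t_amp = -t_amp
    else:
        comps += [
            WaveComponent(10.0, 5.0, -0.10),
            WaveComponent(35.0, 10.0, 1.10),
            WaveComponent(76.0, 7.0, -0.25),
        ]
        qrs_offset = 90.0
    t_center = qt_ms - 2.0 * t_sigma  # qrs onset is the time origin
    if t_center < qrs_offset + 45.0:
        raise ValueError(f"qt_ms={qt_ms} too short for this QRS morphology")
    comps.append(WaveComponent(t_center, t_sigma, t_amp))
    if u_wave:
        comps.append(WaveComponent(qt_ms + 60.0, 18.0, 0.05))
    return BeatTemplate(tuple(comps), 0.0, qrs_offset, t_center, t_sigma)


def make_pvc_template() -> BeatTemplate:
    """Wide, bizarre ventricular ectopic beat: no P, broad QRS, discordant T."""
    comps = (
        WaveComponent(12.0, 6.0, -0.12),
        WaveComponent(50.0, 18.0, 1.30),
        WaveComponent(118.0, 11.0, -0.35),
        WaveComponent(340.0, 55.0, -0.45),
    )
    return BeatTemplate(comps, 0.0, 140.0, 340.0, 55.0)


@dataclass(frozen=True)
class RhythmSpec:
    """Rhythm model for one record.

    ``force_pvc_beats`` / ``force_pac_beats`` place ectopic beats at explicit
    beat indices (0-based), on top of the per-beat Bernoulli probabilities.
    """

    kind: str = "sinus"  # sinus | af | paced | other
    mean_rr_ms: float = 60000.0 / 83.0
    rr_cv: float = 0.03
    pvc_prob: float = 0.0
    pac_prob: float = 0.0
    bigeminy: bool = False
    force_pvc_beats: tuple[int, ...] = ()
    force_pac_beats: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("sinus", "af", "paced", "other"):
            raise ValueError(f"unknown rhythm kind {self.kind!r}")
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be positive")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be >= 0")
        for p in (self.pvc_prob, self.pac_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("ectopy probabilities must lie in [0, 1]")
        if self.kind == "af" and self.rr_cv == 0:
            raise ValueError("atrial fibrillation requires rr_cv > 0")
        if self.kind == "af" and self.bigeminy:
            raise ValueError("bigeminy is incompatible with atrial fibrillation")


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of one synthetic record."""

    sample_rate_hz: float = 500.0
    duration_s: float = 10.0
    lead_names: tuple[str, ...] = STANDARD_LEADS
    lead_scale: Mapping[str, float] | None = None
    lead_shift_ms: Mapping[str, float] | None = None
    noise_sd_mv: float = 0.0
    baseline_wander_amp_mv: float = 0.0
    artifact: bool = False
    u_wave: bool = False
    sex: str = "M"
    rhythm: RhythmSpec = field(default_factory=RhythmSpec)
    bbb: bool = False
    qt_ms: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz < 250:
            raise ValueError("sample_rate_hz must be >= 250")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if len(self.lead_names) < 1:
            raise ValueError("need at least one lead")

    def scale_for(self, lead: str) -> float:
        table = self.lead_scale or DEFAULT_LEAD_SCALE
        return float(table.get(lead, 1.0))

    def shift_for(self, lead: str) -> float:
        table = self.lead_shift_ms or DEFAULT_LEAD_SHIFT_MS
        return float(table.get(lead, 0.0))


@dataclass(frozen=True, eq=False)
class TruthBeat:
    """Generator-side truth for one beat (absolute ms, lead II time frame)."""

    qrs_onset_ms: float
    qrs_offset_ms: float
    t_tangent_end_ms: float
    rr_preceding_ms: float  # nan for the first beat
    beat_class: str  # normal | pvc | pac | post_ectopic

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def __eq__(self, other) -> bool:  # nan-aware (first-beat RR is nan)
        if not isinstance(other, TruthBeat):
            return NotImplemented

        def feq(a: float, b: float) -> bool:
            return a == b or (math.isnan(a) and math.isnan(b))

        return (self.beat_class == other.beat_class
                and feq(self.qrs_onset_ms, other.qrs_onset_ms)
                and feq(self.qrs_offset_ms, other.qrs_offset_ms)
                and feq(self.t_tangent_end_ms, other.t_tangent_end_ms)
                and feq(self.rr_preceding_ms, other.rr_preceding_ms))


@dataclass(frozen=True)
class GroundTruth:
    beats: tuple[TruthBeat, ...]
    true_qt_ms: float
    true_qrs_ms: float

    def to_dict(self) -> dict:
        return {
            "true_qt_ms": self.true_qt_ms,
            "true_qrs_ms": self.true_qrs_ms,
            "beats": [b.to_dict() for b in self.beats],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        beats = tuple(TruthBeat(**b) for b in d["beats"])
        return cls(beats, float(d["true_qt_ms"]), float(d["true_qrs_ms"]))


@dataclass
class ECGRecord:
    """Multi-lead sampled waveform plus per-record metadata."""

    record_id: str
    sample_rate_hz: float
    lead_names: tuple[str, ...]
    signals: np.ndarray  # shape (n_leads, n_samples), mV
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * (1000.0 / self.sample_rate_hz)

    def lead(self, name: str) -> np.ndarray:
        try:
            i = self.lead_names.index(name)
        except ValueError as exc:
            raise KeyError(f"lead {name!r} not present") from exc
        return self.signals[i]


def _draw_rr(rhythm: RhythmSpec, rng: np.random.Generator) -> float:
    mean, cv = rhythm.mean_rr_ms, rhythm.rr_cv
    if cv == 0:
        return mean
    if rhythm.kind == "af":
        shape = 1.0 / (cv * cv)
        rr = rng.gamma(shape, mean / shape)
    else:
        rr = rng.normal(mean, cv * mean)
    return float(np.clip(rr, 250.0, 2600.0))


def _schedule_beats(
    rhythm: RhythmSpec, duration_ms: float, qt_ms: float, rng: np.random.Generator
) -> list[tuple[float, float, str]]:
    """Lay beats on the RR grid.

    Returns (onset_time_ms, rr_preceding_ms, beat_class) per beat; the first
    beat's rr_preceding is nan.  A PVC/PAC arrives early (short coupling
    interval) and is followed by a compensatory pause; the beat after any
    ectopic is flagged post_ectopic.
    """
    beats: list[tuple[float, float, str]] = []
    t = _FIRST_BEAT_MS
    i = 0
    prev_ectopic = False
    pending_pause = 1.0
    while t + qt_ms + _TAIL_PAD_MS <= duration_ms:
        if rhythm.bigeminy:
            if i % 2 == 1:
                cls = "pvc"
            else:
                cls = "post_ectopic" if i > 0 else "normal"
        elif i in rhythm.force_pvc_beats:
            cls = "pvc"
        elif i in rhythm.force_pac_beats:
            cls = "pac"
        elif prev_ectopic:
            # the beat after an ectopic is the post-ectopic beat; random
            # ectopy is not drawn for it (no spontaneous back-to-back runs)
            cls = "post_ectopic"
        elif rng.random() < rhythm.pvc_prob:
            cls = "pvc"
        elif rng.random() < rhythm.pac_prob:
            cls = "pac"
        else:
            cls = "normal"
        rr = float("nan") if i == 0 else beats_rr
        beats.append((t, rr, cls))
        prev_ectopic = cls in ("pvc", "pac")
        # provisional interval to the next beat; intervals around ectopic
        # beats are reshaped in the second pass below
        base = _draw_rr(rhythm, rng) * pending_pause
        pending_pause = 1.0
        beats_rr = base
        t = t + base
        i += 1
    # second pass: reshape intervals around ectopic beats so they are early
    # (coupling 0.65/0.75 of mean RR) with a compensatory pause after.
    if any(c in ("pvc", "pac") for _, _, c in beats):
        mean = rhythm.mean_rr_ms
        times = [b[0] for b in beats]
        classes = [b[2] for b in beats]
        for j in range(1, len(beats)):
            if classes[j] == "pvc":
                times[j] = times[j - 1] + 0.65 * mean
            elif classes[j] == "pac":
                times[j] = times[j - 1] + 0.75 * mean
            elif classes[j - 1] == "pvc":
                times[j] = times[j - 1] + 1.35 * mean
            elif classes[j - 1] == "pac":
                times[j] = times[j - 1] + 1.15 * mean
        # drop beats pushed past the record end, recompute RRs
        beats = []
        for j, (tt, cls) in enumerate(zip(times, classes)):
            if tt + qt_ms + _TAIL_PAD_MS > duration_ms:
                break
            rr = float("nan") if j == 0 else tt - times[j - 1]
            beats.append((tt, rr, cls))
        # a trailing ectopic with no successor simply has no post_ectopic beat
    return beats


def synthesize_record(
    config: SynthConfig, record_id: str = "rec"
) -> tuple[ECGRecord, GroundTruth]:
    """Generate one seeded multi-lead record with its ground truth.

    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    duration_ms = config.duration_s * 1000.0
    include_p = config.rhythm.kind != "af"
    normal_tmpl = make_beat_template(
        qt_ms=config.qt_ms, sex=config.sex, bbb=config.bbb,
        include_p=include_p, u_wave=config.u_wave,
    )
    pvc_tmpl = make_pvc_template()

    beats = _schedule_beats(config.rhythm, duration_ms, config.qt_ms, rng)
    if not beats:
        raise UnusableRecordError(
            f"duration {config.duration_s} s too short to contain one full beat"
        )

    truth_beats = []
    for t0, rr, cls in beats:
        tmpl = pvc_tmpl if cls == "pvc" else normal_tmpl
        truth_beats.append(TruthBeat(
            qrs_onset_ms=t0,
            qrs_offset_ms=t0 + tmpl.qrs_offset_ms,
            t_tangent_end_ms=t0 + tmpl.t_center_ms + 2.0 * tmpl.t_sigma_ms,
            rr_preceding_ms=rr,
            beat_class=cls,
        ))
    truth = GroundTruth(
        beats=tuple(truth_beats),
        true_qt_ms=normal_tmpl.true_qt_ms,
        true_qrs_ms=normal_tmpl.true_qrs_ms,
    )

    n = int(round(config.duration_s * config.sample_rate_hz))
    t_axis = np.arange(n) * (1000.0 / config.sample_rate_hz)
    signals = np.zeros((len(config.lead_names), n))

    # deterministic draw order: wander phase, then per-lead noise, then artifact
    wander_phase = rng.uniform(0, 2 * np.pi)
    for li, lead in enumerate(config.lead_names):
        scale = config.scale_for(lead)
        shift = config.shift_for(lead)
        x = np.zeros(n)
        for (t0, _rr, cls) in beats:
            tmpl = pvc_tmpl if cls == "pvc" else normal_tmpl
            x += tmpl.evaluate(t_axis - (t0 + shift))
        signals[li] = scale * x
    if config.baseline_wander_amp_mv > 0:
        wander = config.baseline_wander_amp_mv * np.sin(
            2 * np.pi * 0.3 * (t_axis / 1000.0) + wander_phase
        )
        signals += wander  # common-mode across leads
    if config.noise_sd_mv > 0:
        signals += rng.normal(0.0, config.noise_sd_mv, size=signals.shape)
    if config.artifact:
        # high-frequency noise bursts on 1-3 random leads; no truth change
        n_bursts = int(rng.integers(1, 4))
        for _ in range(n_bursts):
            li = int(rng.integers(0, len(config.lead_names)))
            width = int(rng.uniform(0.2, 0.8) * config.sample_rate_hz)
            start = int(rng.integers(0, max(1, n - width)))
            signals[li, start:start + width] += rng.normal(0.0, 0.15, size=width)

    meta = {
        "sex": config.sex,
        "rhythm": config.rhythm.kind,
        "bbb": config.bbb,
        "artifact": config.artifact,
        "u_wave": config.u_wave,
        "seed": config.seed,
    }
    rec = ECGRecord(record_id, config.sample_rate_hz, tuple(config.lead_names),
                    signals, meta)
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

DEFAULT_PREVALENCE: dict[str, float] = {
    "af": 0.03,
    "paced": 0.002,
    "other": 0.014,
    "bbb": 0.044,
    "artifact": 0.16,
    "pvc": 0.04,
    "pac": 0.0176,
    "u_wave": 0.007,
    "female": 0.52,
}


@dataclass(frozen=True)
class CohortConfig:
    """Unselected hospital ECG cohort: covariate mix and waveform settings.

    Defaults reproduce the covariate distribution of an unselected inpatient/
    outpatient ECG stream: 95% sinus, 3% AF, 4.4% BBB, 16% artifact, 4% PVC,
    1.76% PAC, 0.7% U waves, 52% female, heart rate 83±19 bpm, age 52±18 y,
    manual QTc centred at 417±35 ms.
    """

    n_records: int = 200
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    hr_mean: float = 83.0
    hr_sd: float = 19.0
    qtc_mean: float = 417.0
    qtc_sd: float = 35.0
    age_mean: float = 52.0
    age_sd: float = 18.0
    pediatric_fraction: float | None = None
    sample_rate_hz: float = 500.0
    duration_s: float = 10.0
    noise_sd_mv: float = 0.02
    baseline_wander_amp_mv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        for k, v in self.prevalence.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence[{k!r}]={v} outside [0, 1]")


def sample_cohort_covariates(config: CohortConfig) -> pd.DataFrame:
    """Draw the cohort's covariate table (no waveforms).

    Rhythm categories (sinus/af/paced/other) are mutually exclusive; the
    binary flags are independent Bernoulli draws at the configured
    prevalences, so empirical frequencies converge to them as n grows.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_records + 1)
    rng = np.random.default_rng(children[0])
    n = config.n_records
    p = {**DEFAULT_PREVALENCE, **dict(config.prevalence)}

    u = rng.random(n)
    p_af, p_paced, p_other = p["af"], p["paced"], p["other"]
    rhythm = np.where(
        u < p_af, "af",
        np.where(u < p_af + p_paced, "paced",
                 np.where(u < p_af + p_paced + p_other, "other", "sinus")),
    )
    female = rng.random(n) < p["female"]
    bbb = rng.random(n) < p["bbb"]
    artifact = rng.random(n) < p["artifact"]
    pvc = rng.random(n) < p["pvc"]
    pac = rng.random(n) < p["pac"]
    u_wave = rng.random(n) < p["u_wave"]
    hr = np.clip(rng.normal(config.hr_mean, config.hr_sd, n), 40.0, 160.0)
    qtc_target = np.clip(rng.normal(config.qtc_mean, config.qtc_sd, n),
                         330.0, 560.0)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.5, 100.0)
    if config.pediatric_fraction is not None:
        k = int(round(config.pediatric_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        age[idx] = rng.uniform(1.0, 17.9, size=k)

    df = pd.DataFrame({
        "record_id": [f"rec_{i:05d}" for i in range(n)],
        "sex": np.where(female, "F", "M"),
        "age": age,
        "hr_bpm": hr,
        "rhythm": rhythm,
        "bbb": bbb,
        "artifact": artifact,
        "pvc": pvc,
        "pac": pac,
        "u_wave": u_wave,
        "qtc_target_ms": qtc_target,
        "wave_seed": [int(c.generate_state(1)[0] & 0x7FFFFFFF)
                      for c in children[1:]],
    })
    df["af"] = df["rhythm"] == "af"
    df["abnormal_rhythm"] = df["rhythm"] != "sinus"
    df["irregular_rhythm"] = df["af"] | df["pvc"] | df["pac"]
    return df


def _config_from_row(row: Mapping, config: CohortConfig,
                     rng: np.random.Generator) -> SynthConfig:
    mean_rr = 60000.0 / float(row["hr_bpm"])
    kind = str(row["rhythm"])
    force_pvc: tuple[int, ...] = ()
    force_pac: tuple[int, ...] = ()
    n_beats_expected = max(3, int((config.duration_s * 1000 - 800) // mean_rr))
    if row["pvc"]:
        force_pvc = (int(rng.integers(1, max(2, n_beats_expected - 1))),)
    if row["pac"]:
        lo = 1
        choices = [i for i in range(lo, max(2, n_beats_expected - 1))
                   if i not in force_pvc]
        force_pac = (int(rng.choice(choices)),) if choices else (1,)
    rhythm = RhythmSpec(
        kind=kind if kind in ("sinus", "af", "paced", "other") else "sinus",
        mean_rr_ms=mean_rr,
        rr_cv=0.24 if kind == "af" else 0.03,
        force_pvc_beats=force_pvc,
        force_pac_beats=force_pac,
    )
    # target the *corrected* QTc: draw QTc, convert to QT at this heart rate
    qt = float(row["qtc_target_ms"]) * math.sqrt(mean_rr / 1000.0)
    qt = float(np.clip(qt, 300.0, 580.0))
    return SynthConfig(
        sample_rate_hz=config.sample_rate_hz,
        duration_s=config.duration_s,
        noise_sd_mv=config.noise_sd_mv,
        baseline_wander_amp_mv=config.baseline_wander_amp_mv,
        artifact=bool(row["artifact"]),
        u_wave=bool(row["u_wave"]),
        sex=str(row["sex"]),
        rhythm=rhythm,
        bbb=bool(row["bbb"]),
        qt_ms=qt,
        seed=int(row["wave_seed"]),
    )


@dataclass
class CohortRecord:
    record: ECGRecord
    truth: GroundTruth
    covariates: dict


def make_cohort(config: CohortConfig) -> list[CohortRecord]:
    """Synthesize a full cohort: one (record, truth, covariate row) per draw."""
    df = sample_cohort_covariates(config)
    out: list[CohortRecord] = []
    for _, row in df.iterrows():
        rng = np.random.default_rng(int(row["wave_seed"]) ^ 0x5A5A5A)
        cfg = _config_from_row(row, config, rng)
        rec, truth = synthesize_record(cfg, record_id=str(row["record_id"]))
        cov = row.to_dict()
        cov["true_qt_ms"] = truth.true_qt_ms
        cov["true_qrs_ms"] = truth.true_qrs_ms
        rec.meta.update({"age": float(row["age"]),
                         "pvc": bool(row["pvc"]), "pac": bool(row["pac"])})
        out.append(CohortRecord(rec, truth, cov))
    return out
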