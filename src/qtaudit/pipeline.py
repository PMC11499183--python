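"""End-to-end orchestration: simulate -> measure -> correct -> classify -> analyze.

``run_pipeline`` generates (or accepts) a cohort, runs the manual tangent
protocol and the automated emulator on every record, applies the correction
and classification rules, tabulates the paired calls, and fits the
predictor regression.  Unmeasurable records (bigeminy, no measurable lead,
pure noise) are excluded and counted, so generated = analyzed + excluded at
every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import automated, delineate, qtc, stats
from .errors import QTAuditError
from .io import RunConfig, config_hash, write_record_csv, write_table
from .synth import CohortRecord, make_cohort

log = logging.getLogger("qtaudit")

REGRESSION_COVARIATES = [
    "male", "abnormal_rhythm", "pvc", "bbb", "hr_bpm", "irregular_rhythm",
]


@dataclass
class PipelineResult:
    measurements: pd.DataFrame
    paired: pd.DataFrame
    report: dict
    excluded: dict = field(default_factory=dict)
    out_dir: Path | None = None


def _measure_record(cr: CohortRecord, config: RunConfig,
                    interp_rng: np.random.Generator) -> dict:
    record, truth = cr.record, cr.truth
    rhythm = str(cr.covariates.get("rhythm", "sinus"))
    beats = delineate.detect_beats(
        record, truth=truth if config.use_truth_fiducials else None)

    manual = delineate.manual_qt(record, beats=beats, rhythm_kind=rhythm)
    qrs_ms = delineate.measure_qrs_ms(record, beats, manual.beats_used)
    man = qtc.correct_manual(manual.qt_ms, manual.rr_ms, qrs_ms,
                             str(cr.covariates["sex"]))

    auto = automated.automated_qt(record, beats=beats, rhythm_kind=rhythm)
    auto_lqt = qtc.classify_lqt(auto.qtc_ms, str(cr.covariates["sex"]),
                                config.male_threshold_ms,
                                config.female_threshold_ms)
    text, suppressed = automated.render_interpretation(
        auto.qtc_ms, str(cr.covariates["sex"]),
        suppression_prob=config.suppression_prob, rng=interp_rng)

    return {
        "record_id": record.record_id,
        "manual_qt_ms": manual.qt_ms,
        "manual_rr_ms": manual.rr_ms,
        "manual_lead": manual.lead_used,
        "manual_n_beats": manual.n_beats_averaged,
        "qrs_ms": qrs_ms,
        "manual_qtc_bazett_ms": man.qtc_bazett_ms,
        "manual_qtc_adjusted_ms": man.qtc_adjusted_ms,
        "manual_lqt": man.lqt,
        "auto_qt_ms": auto.qt_ms,
        "auto_rr_ms": auto.rr_ms,
        "auto_qtc_ms": auto.qtc_ms,
        "auto_lqt": auto_lqt,
        "interpretation_text": text,
        "suppressed": suppressed,
        "true_qt_ms": truth.true_qt_ms,
    }


def run_pipeline(
    config: RunConfig,
    cohort: list[CohortRecord] | None = None,
) -> PipelineResult:
    """Run the full audit on a synthetic cohort; write artifacts if out_dir set.

    Deterministic for a given config (seed included); re-runs are
    byte-identical.
    """
    if config.n_records < 1 and cohort is None:
        raise ValueError("n_records must be >= 1")
    cfg_hash = config_hash(config)
    if cohort is None:
        cohort = make_cohort(config.cohort_config())
    log.info("generated %d records", len(cohort))

    # separate fixed stream for interpretation banners, decoupled from synthesis
    interp_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x17E9]))
    rows: list[dict] = []
    excluded: dict[str, str] = {}
    for cr in cohort:
        try:
            rows.append({**_measure_record(cr, config, interp_rng),
                         **{k: cr.covariates[k] for k in
                            ("sex", "age", "hr_bpm", "rhythm", "bbb",
                             "artifact", "pvc", "pac", "u_wave", "af",
                             "abnormal_rhythm", "irregular_rhythm")}})
        except QTAuditError as exc:
            excluded[cr.record.record_id] = str(exc)
    log.info("analyzed %d records, excluded %d", len(rows), len(excluded))
    assert len(rows) + len(excluded) == len(cohort)

    df = pd.DataFrame(rows)
    report: dict = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "n_generated": len(cohort),
        "n_analyzed": len(rows),
        "n_excluded": len(excluded),
        "exclusions": excluded,
    }
    if df.empty:
        report["message"] = "no analyzable records: all excluded"
        return PipelineResult(df, pd.DataFrame(), report, excluded,
                              _write_artifacts(config, cfg_hash, df,
                                               pd.DataFrame(), report, cohort))

    df["male"] = df["sex"] == "M"
    paired = df[["record_id", "auto_lqt", "manual_lqt"]].copy()
    paired["category"] = [
        qtc.label_pair(a, m) for a, m in zip(df["auto_lqt"], df["manual_lqt"])
    ]
    counts = stats.confusion(paired["category"])
    metrics = stats.diagnostic_metrics(counts)
    agree = stats.agreement(
        (df["auto_qtc_ms"], df["manual_qtc_adjusted_ms"]),
        (df["auto_lqt"], df["manual_lqt"]),
    ) if len(df) >= 3 else None

    report.update({
        "counts": {"tp": counts.tp, "fp": counts.fp,
                   "tn": counts.tn, "fn": counts.fn},
        "metrics": {
            name: {"estimate": m.estimate, "ci": [m.ci_low, m.ci_high]}
            for name, m in [("sensitivity", metrics.sensitivity),
                            ("specificity", metrics.specificity),
                            ("ppv", metrics.ppv), ("npv", metrics.npv)]
        },
        "cell_percent": metrics.cell_percent,
        "mean_qtc_diff_ms": float(
            (df["auto_qtc_ms"] - df["manual_qtc_adjusted_ms"]).mean()),
        "mean_qt_diff_ms": float(
            (df["auto_qt_ms"] - df["manual_qt_ms"]).mean()),
    })
    if agree is not None:
        report["agreement"] = {"pearson_r": agree.pearson_r,
                               "cohen_kappa": agree.cohen_kappa}
    n_auto_lqt = int(df["auto_lqt"].sum())
    if n_auto_lqt:
        report["suppression_rate"] = float(
            df.loc[df["auto_lqt"], "suppressed"].mean())

    outcome = paired["category"] == "FP"
    if 0 < outcome.sum() < len(outcome) and len(df) > len(REGRESSION_COVARIATES) + 2:
        reg = stats.fit_logistic(df[REGRESSION_COVARIATES], outcome)
        report["regression"] = {
            "converged": reg.converged,
            "separation": reg.separation,
            "table": reg.table.round(6).to_dict(orient="index"),
        }
    else:
        report["regression"] = {"skipped": "false-positive outcome degenerate"}

    out_dir = _write_artifacts(config, cfg_hash, df, paired, report, cohort)
    return PipelineResult(df, paired, report, excluded, out_dir)


def _write_artifacts(config, cfg_hash, df, paired, report, cohort):
    if not config.out_dir:
        return None
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(df, out / "measurements.csv", config.seed, cfg_hash)
    write_table(paired, out / "paired_calls.csv", config.seed, cfg_hash)
    cov = pd.DataFrame([cr.covariates for cr in cohort])
    write_table(cov, out / "covariates.csv", config.seed, cfg_hash)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    if config.write_waveforms:
        for cr in cohort:
            write_record_csv(cr.record, out / "waveforms", cr.truth,
                             seed=config.seed, cfg_hash=cfg_hash)
    return out
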