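# qtaudit

Tangent-method QT/QTc measurement and an audit of automated long-QT calls,
with a synthetic 12-lead ECG cohort generator that has analytically known
ground truth.

## The problem

Bedside electrocardiographs print an automated corrected QT interval (QTc)
and often a "prolonged QT" banner. Clinicians are advised to verify those
numbers manually, because automated QTc systematically reads higher than a
careful manual measurement: the machine superimposes all leads to locate the
end of the T wave (so its QT runs from the earliest QRS onset in any lead to
the latest T-end in any lead), it corrects with the record-average RR, and it
does not subtract conduction delay in wide-QRS records. Against the manual
tangent method as gold standard, an automated long-QT (LQT) call therefore
has a low positive predictive value and a high negative predictive value —
good for ruling LQT out, poor for ruling it in.

`qtaudit` packages that whole audit as reusable, testable code for
biostatisticians and ECG-methods researchers:

* **`qtaudit.synth`** — a seeded gaussian-template ECG generator
  (ECGSYN-style). The T wave is a gaussian, so the tangent at its steepest
  descending point crosses the baseline at exactly `center + 2·sigma`: every
  record carries a closed-form ground-truth QT. A cohort generator draws the
  covariate mix of an unselected hospital ECG stream (95% sinus, 3% AF,
  4.4% bundle branch block, 16% artifact, 4% PVC, 1.76% PAC, 0.7% U waves,
  52% female, heart rate 83±19 bpm, manual QTc 417±35 ms).
* **`qtaudit.delineate`** — the manual protocol: PR-segment baseline, QRS
  detection and beat classification, the tangent-method T-end
  (`QT = QRS onset → tangent ∩ baseline`), lead rule (II or V5 unless
  another lead is clearly longer), five-beat averaging in AF, avoidance of
  post-ectopic beats, exclusion of bigeminal records.
* **`qtaudit.automated`** — a stylized machine emulator built from the
  mechanisms above (lead superimposition, Bazett-only correction, global
  mean RR) plus a Bernoulli model of "prolonged QT" banner suppression.
* **`qtaudit.qtc`** — Bazett correction `QTc = QT/√(RR s)`, the wide-QRS
  adjustment `QTc_adj = QTc − (QRS − 100)` for QRS ≥ 120 ms, sex-specific
  LQT thresholds (≥470 ms male, ≥480 ms female), and paired-call labels
  with manual as gold standard (false positive = automated LQT not
  confirmed manually).
* **`qtaudit.stats`** — 2×2 diagnostic metrics with Wilson 95% CIs, Pearson
  r and Cohen's kappa agreement, multivariable logistic regression for
  predictors of false-positive calls, and t/chi-square/Fisher group
  comparisons.
* **`qtaudit.pipeline` / CLI** — end-to-end orchestration
  (`simulate → measure → correct → classify → analyze`) with seeded,
  byte-reproducible artifacts.

## Worked example

```python
from qtaudit import RunConfig, run_pipeline

result = run_pipeline(RunConfig(n_records=200, seed=7, out_dir="audit_run"))
r = result.report
print(f"analyzed {r['n_analyzed']}/{r['n_generated']} records "
      f"({r['n_excluded']} excluded)")
print("2x2 counts:", r["counts"])
print(f"PPV  {100*r['metrics']['ppv']['estimate']:.0f}%   "
      f"NPV  {100*r['metrics']['npv']['estimate']:.0f}%")
print(f"mean automated - manual QTc: {r['mean_qtc_diff_ms']:+.1f} ms")
```

prints

```
analyzed 195/200 records (5 excluded)
2x2 counts: {'tp': 7, 'fp': 22, 'tn': 166, 'fn': 0}
PPV  24%   NPV  100%
mean automated - manual QTc: +21.5 ms
```

Five records were excluded by protocol (unmeasurable QT). The automated
emulator over-reads QTc by ~21 ms on average, which converts into many
unconfirmed LQT calls: only 7 of 29 automated positives are confirmed by the
manual gold standard (PPV 24%), while no automated negative hides a manual
LQT (NPV 100%) — the low-PPV / high-NPV screening pattern the audit is
about. `audit_run/` contains the measurement and paired-call CSVs, the
covariates, and `report.json` (all stamped with the seed and a config hash).

The same flow is available from a shell:

```bash
qtaudit simulate --n 20 --seed 3 --out waves/
qtaudit measure --in waves/ --method manual  --out manual.csv
qtaudit run --n 200 --seed 7 --out audit_run/
```

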