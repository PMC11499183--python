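# Methods

## Scope and model

`qtaudit` implements, as code, a measurement-audit design from clinical
electrocardiography: compare an ECG machine's automated corrected QT (QTc)
and its long-QT (LQT) diagnosis against a manual gold standard that uses the
tangent method, on an unselected stream of 12-lead ECGs, and characterize
the false-positive automated LQT calls (their rate, and their predictors by
logistic regression). Because raw clinical waveforms cannot ship with a
package, every stage runs against a synthetic cohort whose ground truth is
known in closed form; the synthetic generator is first-class, tested code,
not a fixture.

## Synthetic ECG generator

**Beat morphology.** Each beat is a sum of gaussian deflections
(P, Q, R, S, T, optional U) in the tradition of dynamical ECG simulators.
The default sinus template (times in ms from QRS onset, amplitudes in mV) is
P(−140, σ22, 0.12), Q(10, σ5, −0.10), R(35, σ10, 1.10), S(76, σ7, −0.25),
and a T gaussian whose center is placed so that the record's target QT is
met. QRS onset/offset are defined as the ±2σ edges of the outer QRS
gaussians (duration 90 ms for the narrow template).

**Tangent-consistent truth.** For a gaussian T with center c and width σ,
the tangent at the steepest point of the terminal limb (the inflection at
c + σ) crosses the baseline at exactly c + 2σ. Ground-truth QT is therefore
defined as `qrs_onset → c + 2σ`, not as the decay to baseline: the gold
standard being emulated *is* the tangent method, and this gives the
delineator an analytic oracle. All recovery statements in the tests are
relative to this tangent-consistent truth.

**Leads.** The 12 leads are scaled copies of one template (lead II scale 1;
aVR negative) with small fixed per-lead activation delays spanning −10 to
+8 ms (II and V5 at zero). Per-lead QT is invariant to a time shift, so the
delays do not move any single-lead measurement; they are exactly what makes
the machine's earliest-onset-to-latest-end superimposition read ~18 ms
longer than any one lead. The delays are even multiples of the 2 ms sample
period at the default 500 Hz so that all leads sample the same waveform
phase.

**Sex, BBB, ectopy, artifact.** Females get a smaller, narrower T
(0.30 mV, σ45 vs 0.35 mV, σ50) — a mechanistic hook for the sex covariate;
the magnitudes are package choices, not literature estimates. Bundle branch
block widens the QRS to 124 ms (overlapping R and S so the complex never
touches baseline internally) and inverts the T. PVCs are wide (140 ms),
early (coupling 0.65·RR), with discordant T and a compensatory pause; PACs
are narrow and early (0.75·RR). The beat after any ectopic is flagged
`post_ectopic`, and spontaneous back-to-back ectopics are not generated, so
post-ectopic flagging is exhaustive (bigeminy is an explicit flag that
alternates normal/PVC). "Artifact" adds 1–3 high-frequency noise bursts on
random leads and changes no ground truth. Baseline wander is a common-mode
0.3 Hz sine.

**RR model.** Sinus RR is normal with CV 0.03; atrial fibrillation draws RR
from a gamma distribution with CV 0.24 and omits the P wave. RR draws are
clipped to [250, 2600] ms.

**Cohort.** `CohortConfig` defaults encode an unselected hospital cohort:
AF 3%, paced 0.2%, other rhythm 1.4% (mutually exclusive with sinus),
BBB 4.4%, artifact 16%, PVC 4%, PAC 1.76%, U wave 0.7%, female 52%, heart
rate 83±19 bpm, age 52±18 y, and a target *corrected* QTc of 417±35 ms which
is converted to a per-record QT at that record's heart rate. A record
flagged for PVC/PAC is guaranteed at least one such beat (one forced at a
random position), so empirical covariate frequencies converge to the
configured prevalences; the binomial-recovery test runs on the covariate
sampler at n = 10⁴. A `pediatric_fraction` parameter exists for cohorts
with a known under-18 share; by default ages are simply normal draws.
Record synthesis is driven by `numpy` `SeedSequence` spawning, so identical
config and seed give bit-identical waveforms and truth.

What the generator does **not** emulate: real vectorcardiographic lead
projection, P-wave pathology, biphasic or notched T waves, QT dispersion
between leads, muscle artifact with QRS-like spectra, or electrode
misplacement. Passing recovery tests therefore demonstrate correctness of
the measurement chain against its own gold-standard geometry, not clinical
performance on hospital ECGs.

## Manual delineation (tangent method)

* **Baseline**: median amplitude of the 60–20 ms window before QRS onset
  (PR-segment proxy — the protocol's "isoelectric line" is never formally
  defined in clinical practice).
* **Beat detection**: moving-average-smoothed absolute derivative on lead II
  with peak picking (≥250 ms separation), R peaks validated by a 0.25 mV
  amplitude floor. QRS onset/offset are found by walking out from R on a
  15 ms Savitzky–Golay-smoothed trace until the signal sits within
  max(2% of R, 0.025 mV) of a provisional baseline for three consecutive
  samples. Beat classes come from RR pattern plus QRS width: premature
  (< 0.85 · median RR) and wide (≥120 ms) → PVC; premature and narrow →
  PAC; the successor of any ectopic → post-ectopic. A ground-truth
  pass-through mode bypasses detection for oracle experiments.
* **T-end**: on each lead the T apex is the largest deflection from
  baseline after the QRS; the terminal limb is localized on a heavily
  (40 ms) smoothed copy as the stretch where the deflection decays from 85%
  to 20% of apex amplitude; a cubic is fitted to a lightly smoothed copy of
  that limb and the tangent is taken at the cubic's inflection — the
  steepest point — then intersected with the baseline, with sub-sample
  resolution. An inverted T works by sign symmetry. U waves are later and
  shallower than the terminal limb, so they never carry the steepest slope
  and are ignored.
* **Measurability**: a T limb is unmeasurable when its slope is below
  2.5×10⁻⁴ mV/ms, when the slope fails a t-test against the raw residual
  scatter (t < 4), or when the delta-method standard error of the crossing
  point exceeds 8 ms — a reader does not report a longer QT from a lead
  they cannot read to caliper precision. These gates are what keep the
  pick-the-longest-lead rule from converting per-lead noise into a
  systematic positive bias.
* **Beat selection**: ectopic and post-ectopic beats are avoided; AF
  averages the first five usable beats (fewer → all usable, flagged);
  alternating normal/ectopic patterns (bigeminy) make the record
  unmeasurable. For regular rhythms one representative beat is read — the
  usable beat whose preceding RR is closest to the record's median RR. The
  clinical protocol does not state how many beats a reader measures in
  sinus rhythm; one representative beat is this package's explicit
  stand-in, and multi-beat averaging remains available per lead.
* **Lead rule**: II or V5 unless another standard lead reads longer; QT
  differences under 8 ms (a caliper-resolution tie) go to II, then V5, then
  record order. Non-standard lead names are carried but never selected.
* **RR for correction**: the preceding RR of the measured beat; in AF, the
  mean preceding RR of the five averaged beats. The protocol is silent
  here; this is the package's choice.

## Automated emulator

An explicit mechanistic caricature — the vendor algorithm is proprietary —
built from exactly three documented behaviours: (1) per measured beat, QT =
latest tangent T-end across measurable leads minus earliest QRS onset
across leads (necessarily ≥ any single lead's QT); (2) heart-rate
correction by Bazett only, with no QRS-duration adjustment; (3) RR taken as
the record-wide mean rather than the measured beat's RR. Beat selection is
shared with the manual protocol so the comparison isolates the mechanisms.
The "prolonged QT" banner is suppressed, for records meeting the LQT
threshold, with configurable probability (default 0.75, the reported
suppression proportion); the machine's true suppression logic is unknown
and is deliberately modeled as a coin flip.

## Correction and classification

Bazett: `QTc = QT/√(RR in s)`. Wide QRS (≥120 ms): `QTc_adj = QTc −
(QRS − 100)`; the printed form of this rule is self-referential
("QTc = QTc − …") and is read as adjusted = Bazett value minus the excess.
LQT thresholds are inclusive: ≥470 ms (male), ≥480 ms (female); there is no
unisex fallback and no pediatric threshold (the source protocol
distinguishes none). QTc is carried at full precision; rounding to integer
ms before classification is available but off by default, since the
protocol does not state a rounding order. Pairs are labeled TP/FP/TN/FN
with the manual call as gold standard.

## Statistics

Sensitivity, specificity, PPV and NPV are simple proportions with Wilson
score 95% intervals (the source reports none, so an interval method had to
be chosen; Wilson behaves at the boundaries). Zero-denominator metrics are
reported as NaN, never as 0 or 1. Agreement uses Pearson's r and Cohen's
kappa with marginal-product expected agreement. The predictor model is a
maximum-likelihood logistic regression (statsmodels Logit, Newton/IRLS)
of the false-positive indicator on six pre-specified covariates — male sex,
abnormal rhythm (≠ sinus), PVC, BBB, heart rate in bpm (continuous,
unstandardized), and irregular rhythm (AF/PVC/PAC) — with Wald 95% CIs and
ORs by exponentiation. Complete separation or non-convergence is flagged on
the result (huge |coef| or standard errors, or a solver failure), never
silently reported. Group comparisons use Student's pooled-variance t for
continuous data and chi-square for categorical, switching to Fisher's exact
for 2×2 tables with any expected cell ≤ 5.

The pipeline's agreement numbers compare the automated emulator with the
manual pipeline; they are not a model of two human readers reading the same
tracing.

## Numerical choices and problem sizes

All times are ms from record start, samples 0-based, crossings by linear/
polynomial interpolation; QT is rounded only at the reporting layer.
Default sampling is 500 Hz × 10 s. The recovery suites use 200-record
noise-free and 0.02 mV-noise sinus cohorts; the regression-recovery suite
uses 100 replicates of n = 5000 with a true OR of 2.0; the suppression
check uses 1000 Bernoulli draws — sizes chosen to make sampling error small
relative to the tolerances being asserted while keeping the default test
run fast on a laptop. On the printed 2×2 audit table (TN 485, FN 4, FP 53,
TP 25) the metrics evaluate to PPV 32.05% and NPV 99.18%, which the tests
assert only through the computation itself.

## Known limitations

* The tangent estimator is tuned for single-peaked T waves; genuinely
  biphasic T morphology is delineated on the final deflection's terminal
  limb but is not generated, hence not stress-tested.
* The automated emulator's overestimate magnitude is configuration-
  dependent (it scales with the per-lead delay spread); only its sign is a
  stable claim, and the package treats it that way.
* Bazett's formula itself over-corrects at high heart rates; alternative
  corrections (Fridericia, Framingham, Hodges) are deliberately out of
  scope because the audited comparison uses the same correction on both
  arms.
* The cohort generator reproduces marginal covariate frequencies, not the
  joint dependence structure of real hospital populations (e.g. AF and age
  are independent here).
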