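"""Delineator: baseline, beat detection, tangent T-end, protocol rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qtaudit.delineate import (
    beat_fiducials,
    choose_lead,
    detect_beats,
    estimate_baseline,
    manual_qt,
    measure_lead_qt,
    select_beats,
    tangent_t_end,
    BeatFiducials,
)
from qtaudit.errors import (
    ExcludedRecordError,
    UnmeasurableTError,
    UnusableRecordError,
)
from qtaudit.synth import ECGRecord, RhythmSpec, SynthConfig, synthesize_record


class TestBaseline:
    def test_flat_zero(self):
        assert estimate_baseline(np.zeros(100), slice(0, 50)) == 0.0

    def test_shift_equivariance(self):
        x = np.zeros(100) + 0.3
        assert estimate_baseline(x, slice(0, 50)) == pytest.approx(0.3)

    def test_median_concentrates_under_noise(self):
        x = np.random.default_rng(0).normal(0, 0.05, 100)
        assert abs(estimate_baseline(x, slice(0, 100))) < 0.02

    def test_window_too_small(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.zeros(100), slice(0, 5))


class TestTangentTEnd:
    def test_straight_limb_is_its_own_tangent(self):
        # linear descent from (600 ms, 0.4 mV) to (700 ms, 0 mV)
        fs = 500.0
        t = np.arange(500) * 2.0
        x = np.where(t < 600, 0.4, np.where(t <= 700, 0.4 * (700 - t) / 100, 0.0))
        t_end = tangent_t_end(x, fs, 600.0, 0.0, 760.0)
        assert t_end == pytest.approx(700.0, abs=2.0)

    @pytest.mark.parametrize("sigma", [20, 30, 40, 50, 60])
    @pytest.mark.parametrize("amp", [0.35, -0.35])
    def test_gaussian_closed_form(self, gaussian_t, sigma, amp):
        # tangent at the inflection (center + sigma) crosses zero at
        # center + 2*sigma
        x = gaussian_t(center_ms=600.0, sigma_ms=sigma, amplitude_mv=amp)
        t_end = tangent_t_end(x, 500.0, 600.0, 0.0, 600.0 + 6 * sigma)
        assert t_end == pytest.approx(600.0 + 2 * sigma, abs=2.0)

    def test_converges_with_sampling_rate(self, gaussian_t):
        errs = {}
        for fs in (500.0, 1000.0):
            x = gaussian_t(sigma_ms=40.0, fs=fs)
            t_end = tangent_t_end(x, fs, 600.0, 0.0, 840.0)
            errs[fs] = abs(t_end - 680.0)
        assert errs[1000.0] <= 1.0

    def test_flat_t_unmeasurable(self):
        x = np.zeros(1000) + 0.2
        with pytest.raises(UnmeasurableTError):
            tangent_t_end(x, 500.0, 600.0, 0.2, 900.0)

    def test_noise_dominated_t_unmeasurable(self):
        x = np.random.default_rng(3).normal(0, 0.05, 1000)
        x += 0.04 * np.exp(-0.5 * ((np.arange(1000) * 2.0 - 600) / 40) ** 2)
        with pytest.raises(UnmeasurableTError):
            tangent_t_end(x, 500.0, 600.0, 0.0, 840.0)

    def test_u_wave_ignored(self, gaussian_t):
        # U wave: smaller, later deflection past the tangent crossing
        x = gaussian_t(center_ms=600.0, sigma_ms=40.0)
        t = np.arange(x.size) * 2.0
        x = x + 0.05 * np.exp(-0.5 * ((t - 740.0) / 18.0) ** 2)
        t_end = tangent_t_end(x, 500.0, 600.0, 0.0, 880.0)
        assert t_end == pytest.approx(680.0, abs=3.0)

    @given(scale=st.floats(0.3, 4.0))
    def test_amplitude_equivariance(self, scale):
        t = np.arange(1000) * 2.0
        x = 0.35 * np.exp(-0.5 * ((t - 600.0) / 40.0) ** 2)
        ref = tangent_t_end(x, 500.0, 600.0, 0.0, 840.0)
        scaled = tangent_t_end(scale * x, 500.0, 600.0, 0.0, 840.0)
        assert scaled == pytest.approx(ref, abs=1e-6)

    def test_monotone_in_sigma(self, gaussian_t):
        ends = [
            tangent_t_end(gaussian_t(sigma_ms=s), 500.0, 600.0, 0.0,
                          600.0 + 6 * s)
            for s in (25.0, 35.0, 45.0, 55.0)
        ]
        assert all(b > a for a, b in zip(ends, ends[1:]))


class TestDetectBeats:
    def test_recovers_clean_sinus_beats(self, clean_sinus):
        rec, truth = clean_sinus
        beats = detect_beats(rec)
        assert len(beats) == len(truth.beats)
        for b, tb in zip(beats, truth.beats):
            assert b.qrs_onset_ms == pytest.approx(tb.qrs_onset_ms, abs=4.0)

    def test_pure_noise_is_unusable(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(0, 0.05, (12, 5000))
        rec = ECGRecord("noise", 500.0,
                        tuple("I II III aVR aVL aVF V1 V2 V3 V4 V5 V6".split()),
                        sig)
        with pytest.raises(UnusableRecordError):
            detect_beats(rec)

    def test_pvc_classified_and_next_beat_flagged(self):
        cfg = SynthConfig(seed=2, rhythm=RhythmSpec(force_pvc_beats=(3,)))
        rec, truth = synthesize_record(cfg)
        beats = detect_beats(rec)
        assert [b.beat_class for b in beats] == \
            [b.beat_class for b in truth.beats]
        assert beats[3].beat_class == "pvc"
        assert beats[4].beat_class == "post_ectopic"

    def test_truth_passthrough_mode(self, clean_sinus):
        rec, truth = clean_sinus
        beats = detect_beats(rec, truth=truth)
        assert [b.qrs_onset_ms for b in beats] == \
            [b.qrs_onset_ms for b in truth.beats]


class TestSelectBeats:
    def test_sinus_picks_median_rr_beat(self):
        classes = ["normal"] * 6
        rrs = [float("nan"), 900.0, 1000.0, 980.0, 1100.0, 1000.0]
        used, flagged = select_beats(classes, "sinus", rrs)
        assert len(used) == 1 and not flagged
        assert rrs[used[0]] == 1000.0

    def test_af_averages_first_five_usable(self):
        classes = ["normal"] * 8
        rrs = [float("nan")] + [800.0 + 10 * i for i in range(7)]
        used, flagged = select_beats(classes, "af", rrs)
        assert used == [1, 2, 3, 4, 5] and not flagged

    def test_af_with_fewer_beats_flagged(self):
        classes = ["normal"] * 4
        rrs = [float("nan"), 700.0, 820.0, 650.0]
        used, flagged = select_beats(classes, "af", rrs)
        assert used == [1, 2, 3] and flagged

    def test_ectopic_and_post_ectopic_avoided(self):
        classes = ["normal", "normal", "pvc", "post_ectopic", "normal"]
        rrs = [float("nan"), 1000.0, 650.0, 1350.0, 1000.0]
        used, _ = select_beats(classes, "sinus", rrs)
        assert set(used) <= {1, 4}

    def test_bigeminy_excluded(self):
        classes = ["normal", "pvc", "post_ectopic", "pvc", "post_ectopic",
                   "pvc", "post_ectopic"]
        rrs = [float("nan")] + [700.0] * 6
        with pytest.raises(ExcludedRecordError):
            select_beats(classes, "sinus", rrs)

    def test_no_usable_beats_is_error(self):
        with pytest.raises(ExcludedRecordError):
            select_beats(["pvc", "post_ectopic"], "sinus",
                         [float("nan"), 700.0])


class TestLeadRule:
    def test_longer_lead_wins(self):
        qts = {"II": 400.0, "V5": 410.0, "V1": 395.0}
        assert choose_lead(qts) == ("V5", 410.0)

    def test_other_lead_beats_primaries(self):
        qts = {"II": 400.0, "V5": 400.0, "V3": 430.0}
        assert choose_lead(qts) == ("V3", 430.0)

    def test_all_equal_ties_to_lead_ii(self):
        qts = {lead: 400.0 for lead in ("I", "II", "V3", "V5")}
        assert choose_lead(qts) == ("II", 400.0)

    def test_sub_resolution_difference_is_a_tie(self):
        qts = {"II": 400.0, "V6": 404.0}
        assert choose_lead(qts)[0] == "II"

    def test_no_leads_is_excluded(self):
        with pytest.raises(ExcludedRecordError):
            choose_lead({})


class TestMeasureLeadQt:
    def test_qt_is_tend_minus_onset(self):
        fid = BeatFiducials("II", 100.0, 140.0, 400.0, 500.0, 0.0, 1000.0)
        assert measure_lead_qt(fid) == pytest.approx(400.0)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            BeatFiducials("II", 500.0, 140.0, 400.0, 450.0, 0.0, 1000.0)


class TestManualQt:
    def test_clean_recovery(self, clean_sinus):
        rec, truth = clean_sinus
        m = manual_qt(rec)
        assert m.method == "manual_tangent"
        assert m.qt_ms == pytest.approx(truth.true_qt_ms, abs=3.0)
        assert m.rr_ms == pytest.approx(1000.0, abs=10.0)
        assert m.n_beats_averaged == 1

    def test_noisy_recovery_single_record(self, make_record):
        rec, truth = make_record(seed=17, noise_sd_mv=0.02)
        m = manual_qt(rec)
        assert m.qt_ms == pytest.approx(truth.true_qt_ms, abs=25.0)

    def test_offset_invariance_of_qt(self, clean_sinus):
        rec, truth = clean_sinus
        shifted = ECGRecord(rec.record_id, rec.sample_rate_hz,
                            rec.lead_names, rec.signals + 0.3, dict(rec.meta))
        m0 = manual_qt(rec)
        m1 = manual_qt(shifted)
        assert m1.qt_ms == pytest.approx(m0.qt_ms, abs=1.0)

    def test_af_uses_five_beats(self):
        cfg = SynthConfig(seed=5, rhythm=RhythmSpec(kind="af", rr_cv=0.24))
        rec, _ = synthesize_record(cfg)
        m = manual_qt(rec)
        assert m.n_beats_averaged == 5
        assert len(m.beats_used) == 5

    def test_bigeminy_record_excluded(self):
        cfg = SynthConfig(seed=2, rhythm=RhythmSpec(bigeminy=True))
        rec, _ = synthesize_record(cfg)
        with pytest.raises(ExcludedRecordError):
            manual_qt(rec)

    def test_nonstandard_lead_not_selected(self, clean_sinus):
        rec, _ = clean_sinus
        # append a copy of lead II with an exaggerated (longer-QT) name X9
        sig = np.vstack([rec.signals, rec.lead("II")[None, :] * 1.2])
        rec2 = ECGRecord("x9", rec.sample_rate_hz,
                         rec.lead_names + ("X9",), sig, dict(rec.meta))
        m = manual_qt(rec2)
        assert m.lead_used != "X9"
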