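"""The STV statistic, Poincaré pairs, QT dispersion, ST deviation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stvqt as sq
from stvqt.metrics import QTSeries

from conftest import clean_config


def brute_force_stv(qt, valid, denominator="beats"):
    """Independent loop oracle for the STV statistic."""
    total = 0.0
    n_diff = 0
    for i in range(len(qt) - 1):
        if valid[i] and valid[i + 1]:
            total += abs(qt[i + 1] - qt[i])
            n_diff += 1
    n = int(np.sum(valid)) if denominator == "beats" else n_diff
    return total / (n * math.sqrt(2.0))


def make_series(qt, valid=None):
    qt = np.asarray(qt, dtype=float)
    valid = np.ones(len(qt), bool) if valid is None else np.asarray(valid, bool)
    return QTSeries(beat_times=np.arange(len(qt)) * 800.0, qt=qt, valid=valid,
                    lead="II")


class TestStv:
    def test_constant_series_is_zero(self):
        assert sq.stv(make_series([400.0] * 4)) == 0.0

    def test_alternating_series_hand_value(self):
        # sum |diff| = 30 over 4 beats -> 30 / (4 sqrt 2)
        assert sq.stv(make_series([400.0, 410.0, 400.0, 410.0])) == pytest.approx(
            30.0 / (4.0 * math.sqrt(2.0)))

    def test_denominator_differences_option(self):
        s = make_series([400.0, 410.0, 400.0, 410.0])
        assert sq.stv(s, denominator="differences") == pytest.approx(
            30.0 / (3.0 * math.sqrt(2.0)))

    def test_matches_brute_force_on_random_masked_series(self, rng):
        for _ in range(200):
            n = rng.integers(4, 80)
            qt = 400.0 + rng.normal(0, 5, n)
            valid = rng.random(n) > 0.25
            if valid.sum() < 2:
                continue
            s = make_series(qt, valid)
            try:
                ours = sq.stv(s)
            except sq.InsufficientDataError:
                continue
            theirs = brute_force_stv(qt, valid)
            assert ours == pytest.approx(theirs, rel=1e-12)

    def test_gap_differences_are_dropped_not_bridged(self):
        qt = np.array([400.0, 500.0, 400.0])
        valid = np.array([True, False, True])
        # only pair (0,1) and (1,2) are consecutive; both touch the invalid
        # beat, so no admissible difference remains
        with pytest.raises(sq.InsufficientDataError):
            sq.stv(make_series(qt, valid))

    def test_too_few_valid_beats(self):
        with pytest.raises(sq.InsufficientDataError):
            sq.stv(make_series([400.0, 410.0], [True, False]))

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 5.0),
           seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_translation_invariance_and_homogeneity(self, shift, scale, seed):
        r = np.random.default_rng(seed)
        qt = 400.0 + r.normal(0, 4, 20)
        valid = r.random(20) > 0.2
        if valid.sum() < 2:
            return
        try:
            base = sq.stv(make_series(qt, valid))
        except sq.InsufficientDataError:
            return
        assert sq.stv(make_series(qt + shift, valid)) == pytest.approx(base)
        assert sq.stv(make_series(qt * scale, valid)) == pytest.approx(
            scale * base, rel=1e-9)

    def test_excluded_pvc_leaves_constant_series_at_zero(self):
        qt = np.full(20, 400.0)
        qt[9] = 250.0                      # the PVC's own (bogus) interval
        labels = np.array(["sinus"] * 20, dtype=object)
        labels[9] = "pvc"
        r = np.arange(20) * 800.0
        excl = sq.exclusion_mask(labels, r, r + 380.0)
        valid = np.ones(20, bool)
        valid[excl] = False
        assert sq.stv(make_series(qt, valid)) == 0.0


class TestPoincare:
    def test_enumeration(self):
        pts = sq.poincare(make_series([400.0, 410.0, 400.0]))
        assert pts.tolist() == [[400.0, 410.0], [410.0, 400.0]]

    def test_constant_series_on_identity_line(self):
        pts = sq.poincare(make_series([400.0] * 5))
        assert np.all(pts[:, 0] == pts[:, 1])

    def test_pair_count_equals_stv_differences(self, rng):
        for _ in range(50):
            qt = 400.0 + rng.normal(0, 5, 30)
            valid = rng.random(30) > 0.3
            if valid.sum() < 2:
                continue
            s = make_series(qt, valid)
            n_pairs = int(np.sum(valid[:-1] & valid[1:]))
            if n_pairs == 0:
                continue
            assert len(sq.poincare(s)) == n_pairs


class TestQtDispersion:
    def test_identical_leads_zero(self):
        assert sq.qt_dispersion({ld: 400.0 for ld in sq.CLINICAL_LEADS}) == 0.0

    def test_range_arithmetic(self):
        vals = dict(zip(sq.CLINICAL_LEADS, np.linspace(380.0, 420.0, 12)))
        assert sq.qt_dispersion(vals) == pytest.approx(40.0)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            vals = rng.normal(400, 20, 12)
            assert sq.qt_dispersion(vals) == pytest.approx(
                max(vals) - min(vals))

    def test_needs_two_leads(self):
        with pytest.raises(sq.InsufficientDataError):
            sq.qt_dispersion({"II": 400.0})


@pytest.fixture(scope="module")
def ischemic_pair():
    cfg = clean_config(duration=40.0, leads=("II", "V4"), seed=8,
                       qt_white_sd=0.5)
    base_rec, truth = sq.synthesize_record(cfg)
    isch_rec, _ = sq.apply_ischemia(base_rec, truth, {"V4": 0.2},
                                    onset_s=0.0)
    out = {}
    for name, rec in (("base", base_rec), ("isch", isch_rec)):
        beats = {}
        for lead in rec.lead_names:
            idx = sq.detect_r_peaks(rec.lead(lead), rec.fs)
            tmpl = sq.annotate_template(sq.build_template(rec, idx, lead))
            beats[lead] = sq.measure_beats(rec, lead, idx, tmpl)
        out[name] = (rec, beats)
    return out


class TestStDeviation:
    def test_identity_segments_give_zero(self, ischemic_pair):
        rec, beats = ischemic_pair["base"]
        dev = sq.st_deviation(rec, rec, beats, beats)
        for lead in rec.lead_names:
            assert dev[lead] == pytest.approx(0.0, abs=1e-9)

    def test_injected_offset_recovered(self, ischemic_pair):
        rec_b, beats_b = ischemic_pair["base"]
        rec_i, beats_i = ischemic_pair["isch"]
        dev = sq.st_deviation(rec_i, rec_b, beats_i, beats_b)
        assert dev["V4"] == pytest.approx(0.2, abs=0.02)
        assert dev["II"] == pytest.approx(0.0, abs=0.02)

    def test_sign_flip(self, ischemic_pair):
        rec_b, beats_b = ischemic_pair["base"]
        rec_i, beats_i = ischemic_pair["isch"]
        # swapping segment and baseline flips the sign
        fwd = sq.st_deviation(rec_i, rec_b, beats_i, beats_b)
        rev = sq.st_deviation(rec_b, rec_i, beats_b, beats_i)
        assert rev["V4"] == pytest.approx(-fwd["V4"], abs=1e-9)


class TestSegmentMetrics:
    def test_identical_leads_aggregate(self):
        qt = [400.0, 405.0, 400.0, 405.0, 400.0]
        series = {ld: make_series(qt) for ld in sq.CLINICAL_LEADS}
        r = np.arange(5) * 1000.0
        m = sq.segment_metrics(series, r)
        per_lead = sq.stv(make_series(qt))
        assert m.cumulative_bvr == pytest.approx(12 * per_lead)
        assert m.max_bvr == pytest.approx(per_lead)
        assert m.qt_dispersion == 0.0

    def test_hr_from_constant_rr(self):
        series = {"II": make_series([400.0] * 5)}
        m = sq.segment_metrics(series, np.arange(5) * 1000.0)
        assert m.hr == pytest.approx(60.0)

    def test_hr_uses_sinus_beats_only(self):
        r = np.array([0.0, 1000.0, 1600.0, 3000.0, 4000.0])
        labels = np.array(["sinus", "sinus", "pvc", "sinus", "sinus"],
                          dtype=object)
        hr = sq.heart_rate(r, labels)
        assert hr == pytest.approx(60.0)  # only the 1000-ms sinus RRs count

    def test_failed_lead_recorded_not_raised(self):
        series = {"II": make_series([400.0] * 5),
                  "V1": make_series([400.0, 410.0], [True, False])}
        m = sq.segment_metrics(series, np.arange(5) * 1000.0)
        assert "V1" in m.failed_leads
        assert "II" in m.bvr

    def test_cumulative_st_is_sum_of_absolutes(self):
        series = {"II": make_series([400.0] * 5)}
        m = sq.segment_metrics(series, np.arange(5) * 1000.0,
                               st_dev_by_lead={"II": -0.1, "V4": 0.25})
        assert m.cumulative_st == pytest.approx(0.35)
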