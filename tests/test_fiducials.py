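"""Detection, template averaging, tangent T-end and per-beat QT."""

import numpy as np
import pytest

import stvqt as sq
from stvqt.fiducials import FiducialsConfig

from conftest import clean_config


def _match_fraction(detected_ms, truth_ms, tol_ms=10.0):
    return np.mean([np.min(np.abs(detected_ms - t)) <= tol_ms for t in truth_ms])


class TestDetectRPeaks:
    def test_clean_record_all_beats_recovered(self, clean_record):
        rec, truth = clean_record
        idx = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        assert len(idx) == len(truth.r_times)
        assert np.all(np.abs(idx * 1000.0 / rec.fs - truth.r_times) <= 10.0)
        assert np.all(np.diff(idx) > 0)

    def test_all_zero_signal_raises(self):
        with pytest.raises(sq.NoBeatsError):
            sq.detect_r_peaks(np.zeros(5000), 1000.0)

    def test_recall_under_broadband_noise(self):
        cfg = clean_config(noise_broadband=0.05, seed=11)
        rec, truth = sq.synthesize_record(cfg)
        idx = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        det_ms = idx * 1000.0 / rec.fs
        assert _match_fraction(det_ms, truth.r_times, 20.0) >= 0.98

    def test_refractory_enforced(self, clean_record):
        rec, _ = clean_record
        idx = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        assert np.all(np.diff(idx) >= 0.2 * rec.fs)


class TestBuildTemplate:
    def test_identical_beats_average_to_single_beat(self):
        cfg = clean_config(qt_white_sd=0.0, rr_sd=0.0)
        rec, truth = sq.synthesize_record(cfg)
        idx = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        tmpl = sq.build_template(rec, idx, "II")
        fcfg = FiducialsConfig()
        from stvqt.fiducials import preprocess
        y = preprocess(rec.lead("II"), rec.fs, fcfg)  # same conditioning
        pre = int(fcfg.pre_ms * rec.fs / 1000.0)
        r = idx[len(idx) // 2]
        beat = y[r - pre: r + int(fcfg.post_ms * rec.fs / 1000.0)]
        assert np.max(np.abs(tmpl.waveform - beat)) < 2e-3
        assert tmpl.n_beats_averaged >= 8

    def test_noise_reduction_by_averaging(self):
        cfg = clean_config(qt_white_sd=0.0, rr_sd=0.0, noise_broadband=0.02,
                           seed=5)
        rec, truth = sq.synthesize_record(cfg)
        clean_rec, _ = sq.synthesize_record(clean_config(qt_white_sd=0.0,
                                                         rr_sd=0.0, seed=5))
        idx = np.round(truth.r_times * rec.fs / 1000.0).astype(int)
        fcfg = FiducialsConfig(lowpass_hz=None)   # keep the raw noise
        tmpl = sq.build_template(rec, idx, "II", fcfg)
        pre = int(fcfg.pre_ms * rec.fs / 1000.0)
        r = idx[len(idx) // 2]
        ref = clean_rec.lead("II")[r - pre: r + int(fcfg.post_ms * rec.fs / 1000.0)]
        resid = np.std(tmpl.waveform - ref)
        n = tmpl.n_beats_averaged
        # averaging n beats cuts noise roughly sqrt(n)-fold
        assert resid < 3.0 * 0.02 / np.sqrt(n)

    def test_pvc_rejected_from_average(self):
        cfg = clean_config(qt_white_sd=0.0, seed=9,
                           pvc_schedule=((30, 400.0, 1.2),))
        rec, truth = sq.synthesize_record(cfg)
        idx = np.round(truth.r_times * rec.fs / 1000.0).astype(int)
        tmpl = sq.build_template(rec, idx, "II")
        rec0, truth0 = sq.synthesize_record(clean_config(qt_white_sd=0.0, seed=9))
        idx0 = np.round(truth0.r_times * rec0.fs / 1000.0).astype(int)
        tmpl0 = sq.build_template(rec0, idx0, "II")
        assert np.max(np.abs(tmpl.waveform - tmpl0.waveform)) < 5e-3

    def test_too_few_beats_raises(self, clean_record):
        rec, truth = clean_record
        idx = np.round(truth.r_times[:5] * rec.fs / 1000.0).astype(int)
        with pytest.raises(sq.InsufficientBeatsError):
            sq.build_template(rec, idx, "II")


class TestTangentTEnd:
    @pytest.mark.parametrize("sigma", [20.0, 40.0, 60.0])
    def test_gaussian_closed_form(self, sigma):
        t = np.arange(800.0)
        w = 0.3 * np.exp(-0.5 * ((t - 300.0) / sigma) ** 2)
        te = sq.tangent_t_end(w, 1000.0, 300.0, 0.0)
        assert te == pytest.approx(300.0 + 2.0 * sigma, abs=1.0)

    def test_linear_ramp_exact(self):
        # descending ramp from its peak hits baseline at 420 ms
        t = np.arange(600.0)
        w = np.clip((420.0 - t) / 120.0, 0.0, 1.0) * np.where(t >= 300.0, 1, 0)
        w[t < 300.0] = np.clip(t[t < 300.0] - 180.0, 0, 120)[...] / 120.0
        te = sq.tangent_t_end(w, 1000.0, 300.0, 0.0)
        assert te == pytest.approx(420.0, abs=1.0)

    def test_baseline_shift_invariance(self):
        t = np.arange(800.0)
        w = 0.3 * np.exp(-0.5 * ((t - 300.0) / 40.0) ** 2)
        te0 = sq.tangent_t_end(w, 1000.0, 300.0, 0.0)
        te1 = sq.tangent_t_end(w + 0.1, 1000.0, 300.0, 0.1)
        assert te1 == pytest.approx(te0, abs=1e-6)

    def test_negative_t_wave_supported(self):
        t = np.arange(800.0)
        w = -0.3 * np.exp(-0.5 * ((t - 300.0) / 40.0) ** 2)
        te = sq.tangent_t_end(w, 1000.0, 300.0, 0.0)
        assert te == pytest.approx(380.0, abs=1.0)

    def test_absent_t_wave_raises(self):
        w = np.zeros(800)
        w[200] = 1.0  # lone spike far from the hint
        with pytest.raises(sq.TEndNotFoundError):
            sq.tangent_t_end(w, 1000.0, 500.0, 0.0)


class TestAnnotateTemplate:
    def _template(self, fs=1000.0):
        cfg = clean_config(fs=fs, qt_white_sd=0.0)
        rec, truth = sq.synthesize_record(cfg)
        idx = np.round(truth.r_times * fs / 1000.0).astype(int)
        return sq.annotate_template(sq.build_template(rec, idx, "II")), truth

    def test_fiducials_match_generator_truth(self):
        tmpl, truth = self._template()
        f = tmpl.fiducials
        fcfg = FiducialsConfig()
        onset_true = fcfg.pre_ms + truth.meta["qrs_onset_rel_ms"]
        tend_true = onset_true + truth.meta["qt_base_ms"]
        assert f["qrs_on_ms"] == pytest.approx(onset_true, abs=4.0)
        assert f["t_end_ms"] == pytest.approx(tend_true, abs=4.0)
        assert f["qrs_on_ms"] < f["r_ms"] < f["t_peak_ms"] < f["t_end_ms"]

    def test_rate_consistency_1k_vs_4k(self):
        t1, _ = self._template(1000.0)
        t4, _ = self._template(4000.0)
        for key in ("qrs_on_ms", "t_end_ms"):
            assert t1.fiducials[key] == pytest.approx(t4.fiducials[key], abs=1.5)

    def test_absent_t_wave_raises(self):
        morpho = sq.default_morphology(400.0, leads=("II",))
        amps = {"II": dict(morpho.amplitudes["II"], T=0.0)}
        m = sq.BeatMorphology(waves=morpho.waves, amplitudes=amps)
        wf, _ = sq.make_beat_template(m, fs=1000.0)
        tmpl = sq.BeatTemplate(waveform=wf["II"], fs=1000.0, r_offset_ms=250.0,
                               n_beats_averaged=8, lead="II")
        with pytest.raises((sq.TEndNotFoundError, sq.AnnotationError)):
            sq.annotate_template(tmpl)


class TestMeasureQT:
    def test_constant_qt_recovered_within_2ms(self, clean_record):
        rec, truth = clean_record
        idx = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        tmpl = sq.annotate_template(sq.build_template(rec, idx, "II"))
        qts = sq.measure_qt_per_beat(rec, "II", idx, tmpl)
        assert len(qts.qt) == len(idx)
        measured = qts.qt[qts.valid]
        assert np.all(np.abs(measured - truth.qt_true[qts.valid]) <= 2.0)

    def test_prescribed_series_correlation_under_noise(self):
        cfg = clean_config(stv_target=3.0, qt_ar_coef=0.4, seed=21,
                           noise_broadband=0.02)
        rec, truth = sq.synthesize_record(cfg)
        idx = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        tmpl = sq.annotate_template(sq.build_template(rec, idx, "II"))
        qts = sq.measure_qt_per_beat(rec, "II", idx, tmpl)
        ok = qts.valid & np.isfinite(truth.qt_true[: len(qts.qt)])
        r = np.corrcoef(qts.qt[ok], truth.qt_true[: len(qts.qt)][ok])[0, 1]
        assert r >= 0.9

    def test_downsampled_measurement_is_quantization_limited(self):
        cfg = clean_config(stv_target=0.3, seed=3)
        rec, truth = sq.synthesize_record(cfg)
        rec200 = sq.resample(rec, 200.0)

        def _bvr(r):
            idx = sq.detect_r_peaks(r.lead("II"), r.fs)
            tmpl = sq.annotate_template(sq.build_template(r, idx, "II"))
            return sq.stv(sq.measure_qt_per_beat(r, "II", idx, tmpl))

        assert _bvr(rec200) > _bvr(rec)

    def test_fs_mismatch_raises(self, clean_record):
        rec, truth = clean_record
        idx = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        tmpl = sq.annotate_template(sq.build_template(rec, idx, "II"))
        rec200 = sq.resample(rec, 200.0)
        with pytest.raises(sq.ConfigurationError):
            sq.measure_qt_per_beat(rec200, "II", idx, tmpl)

    def test_amplitude_invariance(self, clean_record):
        rec, _ = clean_record
        idx = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        tmpl = sq.annotate_template(sq.build_template(rec, idx, "II"))
        beats = sq.measure_beats(rec, "II", idx, tmpl)
        rec2 = sq.ECGRecord(rec.fs, rec.lead_names, 2.5 * rec.signal)
        idx2 = sq.detect_r_peaks(rec2.lead("II"), rec2.fs)
        assert np.array_equal(idx, idx2)
        tmpl2 = sq.annotate_template(sq.build_template(rec2, idx2, "II"))
        beats2 = sq.measure_beats(rec2, "II", idx2, tmpl2)
        assert np.allclose(beats.t_end, beats2.t_end, atol=1e-6, equal_nan=True)
        assert np.allclose(beats.qrs_on, beats2.qrs_on, atol=1e-6, equal_nan=True)

    def test_time_shift_equivariance(self, clean_record):
        rec, _ = clean_record
        shift_s = 1.6
        rec2 = rec.slice(shift_s, rec.duration_s)
        rec2 = sq.ECGRecord(rec2.fs, rec2.lead_names, rec2.signal)  # t0 reset
        idx1 = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        idx2 = sq.detect_r_peaks(rec2.lead("II"), rec2.fs)
        t1 = sq.annotate_template(sq.build_template(rec, idx1, "II"))
        t2 = sq.annotate_template(sq.build_template(rec2, idx2, "II"))
        b1 = sq.measure_beats(rec, "II", idx1, t1)
        b2 = sq.measure_beats(rec2, "II", idx2, t2)
        common = min(np.sum(b1.r_times >= shift_s * 1000.0 + 300.0), len(b2.r_times))
        a = b1.t_end[-common:] - b1.r_times[-common:]
        b = b2.t_end[-common:] - b2.r_times[-common:]
        ok = np.isfinite(a) & np.isfinite(b)
        assert np.allclose(a[ok], b[ok], atol=0.25)

    def test_bookkeeping_preserves_beat_count_and_order(self, clean_record):
        rec, _ = clean_record
        idx = sq.detect_r_peaks(rec.lead("II"), rec.fs)
        tmpl = sq.annotate_template(sq.build_template(rec, idx, "II"))
        qts = sq.measure_qt_per_beat(rec, "II", idx, tmpl)
        assert len(qts.qt) == len(idx)
        assert np.all(np.diff(qts.beat_times) > 0)
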