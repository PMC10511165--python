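# stvqt — beat-to-beat variability of repolarization on the 12-lead ECG

Ventricular fibrillation (VF) during acute myocardial ischemia is preceded by
growing instability of cardiac repolarization. A noninvasive window on that
instability is the **short-term variability of the QT interval** (STVQT, also
called beat-to-beat variability of repolarization, BVR),

```
STV = Σ |QT(n+1) − QT(n)| / (N · √2)        [ms]
```

the mean absolute difference between successive per-beat QT intervals, scaled
by √2, over a 1-minute ECG segment of N analyzed beats. Tracking STV through
an ischemic episode — at baseline, early after coronary occlusion, and in the
minutes before VF — turns it into an early-warning statistic; measuring it
per lead maps the spatial footprint of the ischemic region; and relating it
to programmed-stimulation inducibility connects it to arrhythmia
vulnerability in the chronic phase.

`stvqt` is a tested, reusable implementation of that analysis for
electrophysiologists and biomedical-signal engineers:

* **`stvqt.synth`** — a 12-lead synthetic-ECG generator with fully known
  ground truth: sum-of-Gaussians beats, a prescribed AR(1) per-beat QT series
  whose expected STV is analytic (so any target STV can be calibrated
  exactly), scheduled premature ventricular complexes (PVCs), lead-specific
  ST-segment shifts and T-wave scaling from a chosen ischemia onset, and
  polyphase resampling for sampling-rate experiments.
* **`stvqt.fiducials`** — R-peak detection, fiducial-segment-averaging (FSA)
  QT measurement: an averaged sinus template is annotated once (QRS onset by
  a derivative-threshold rule, T end by the tangent method) and re-aligned to
  every beat, with a shift+stretch registration of the T wave so that
  beat-to-beat QT changes are tracked with unit gain.
* **`stvqt.rhythm`** — PVC classification (prematurity × morphology), the
  exclusion rule (each PVC plus its succeeding sinus beat, plus the preceding
  beat when the PVC interrupts its T wave), PVC counts and coupling
  intervals.
* **`stvqt.metrics`** — the STV statistic on validated QT series, Poincaré
  pairs, QT dispersion, ST-segment deviation, per-segment metric bundles.
* **`stvqt.pipeline`** — study orchestration: named 1-minute analysis
  windows around occlusion and VF onset, the pre-VF ΔBVR surge detector, the
  200 Hz / 1 kHz / 4 kHz sampling-rate study, the programmed-electrical-
  stimulation (PES) inducibility index, and tidy reporting.

## Worked example

```python
import numpy as np
import stvqt as sq
from stvqt.pipeline import analyze_window, sampling_study

# one minute of 1-lead ECG at 1 kHz with STV calibrated to 1.5 ms
cfg = sq.SynthConfig(duration=50.0, leads=("II",), stv_target=1.5, seed=42)
record, truth = sq.synthesize_record(cfg)
print("prescribed STV :", round(truth.stv_true, 3), "ms")

idx   = sq.detect_r_peaks(record.lead("II"), record.fs)
tmpl  = sq.annotate_template(sq.build_template(record, idx, "II"))
beats = sq.measure_beats(record, "II", idx, tmpl)
qts   = beats.qt_series()
print("beats detected :", len(idx))
print("mean QT        :", round(np.mean(qts.qt[qts.valid]), 1), "ms")
print("measured BVR   :", round(sq.stv(qts), 3), "ms")

print(sampling_study(record)[["fs_hz", "bvr_ms", "n_valid"]].to_string(index=False))
```

prints

```
prescribed STV : 1.5 ms
beats detected : 62
mean QT        : 399.8 ms
measured BVR   : 1.08 ms
 fs_hz   bvr_ms  n_valid
 200.0 1.168268       62
1000.0 1.079702       62
```

All 62 beats are found and measured; the mean QT matches the programmed
400 ms. The measured BVR of 1.08 ms is not a measurement error against the
1.5 ms calibration target: the *realized* sample STV of this particular
62-beat draw of the QT process is 1.085 ms, and the pipeline recovers it to
0.005 ms. (Averaged over many seeds the measured BVR converges on the
calibration target; the acceptance suite checks this to three standard
errors.) The sampling-rate table shows the quantization effect: downsampling
the very same signal to 200 Hz inflates the apparent BVR, which is why
QT-variability comparisons require a uniform sampling rate above 500 Hz.

The PES inducibility scale maps the stimulation step at which sustained
VT/VF is first induced onto 0–100 %:

```python
sq.inducibility_index(sq.PESOutcome(induced_at_step=1))   # 100.0
sq.inducibility_index(sq.PESOutcome(induced_at_step=5))   # 55.6
sq.inducibility_index(sq.PESOutcome())                    # 0.0 (noninducible)
```

A thin CLI mirrors the library: `stvqt simulate`, `stvqt analyze`,
`stvqt sampling-study`, `stvqt induce`, `stvqt report`.

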