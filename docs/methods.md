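# Methods

This note documents the models, conventions and numerical choices behind
`stvqt`, in the order the pipeline runs.

## Synthetic ECG generator

**Beat model.** Each sinus beat is a sum of Gaussian waves (P, Q, R, S, T)
with shared timing across leads and lead-specific amplitudes approximating
clinical 12-lead proportions. A dipole/torso model would be more realistic
but would not provide what the generator exists for: closed-form fiducial
truth. With a single-Gaussian T wave, `A·exp(−(t−t_p)²/2σ²)`, the steepest
downslope sits at `t_p + σ` and its tangent crosses the baseline at
`t_p + 2σ`, so the tangent-method T end — the same convention the
measurement uses — is analytic.

**Truth conventions.** The true QRS onset (and QRS end / J point) is defined
by the same rule the measurement applies: walking outward from the steepest
QRS slope, the complex ends where |dV/dt| drops below 2 % of the maximal
in-QRS |dV/dt|, evaluated analytically on a 8 kHz grid of the reference lead
(largest R). True per-beat QT is prescribed by stretching the T wave about
its (fixed) peak: σ is chosen per beat so that `t_p + 2σ − onset` equals the
target QT. Ground truth and measurement therefore share one definition of
"QT", which is what makes ±2 ms recovery claims meaningful.

**QT variability model.** Per-beat QT = `qt_base + x_n`, with `x_n` a
stationary AR(1) process, `x_n = φ x_{n−1} + ε_n`, `ε_n ~ N(0, σ_w²)`. The
successive difference has `sd(Δ) = σ_w √(2/(1+φ))`, and since Δ is Gaussian,
`E|Δ| = sd(Δ)·√(2/π)`, giving the analytic expectation

```
E[STV] = σ_w · √(2 / (π (1+φ)))
```

`stv_target` inverts this formula to calibrate `σ_w`; `GroundTruth.stv_true`
records the analytic value. Note the finite-window statistic divides by the
number of beats N while only N−1 differences exist, so a 60-beat window has
a deterministic (N−1)/N ≈ −1.7 % expectation offset relative to `stv_true`;
the calibration Monte-Carlo test uses 200-beat windows where the offset is
within its 2 % tolerance, and the recovery tests compare against three
standard errors across 100 seeds, which absorbs it.

**Defaults as study conditions.** RR 800 ± 25 ms (75 beats/min, an
anesthetized large animal at rest), QT 400 ms, white QT noise 0.5 ms
(expected STV ≈ 0.40 ms, a quiescent baseline), AR coefficient 0. Noise:
baseline wander 0.05 mV at 0.3 Hz (respiration), broadband 5 µV, powerline
5 µV at 50 Hz — a good-quality laboratory recording. PVCs are wide, early,
inverted complexes with discordant T waves; the beat after a PVC falls a
full compensatory pause (2·RR − coupling) after the last sinus beat. RR
draws are truncated at RR/2 to prevent beat overlap.

**Ischemia overlay.** `apply_ischemia` adds, for every sinus beat at or
after the onset, a raised-cosine-edged ST plateau between the QRS end and
the T onset, and rescales the T amplitude by adding `(scale−1)` times the
analytically reconstructed T Gaussian. Pre-onset samples are bit-identical
to the input; PVC complexes are left untouched (they are excluded from
repolarization analysis anyway).

**Resampling** uses `scipy.signal.resample_poly` (polyphase FIR with the
default Kaiser β = 5.0 design): anti-aliasing on downsampling, interpolation
on upsampling. Identity conversions return a verbatim copy.

**Serialization** is CSV + JSON sidecar: a signal CSV (one column per lead,
mV, 6 decimals), a sidecar with `fs`/`leads`/`t0` and the scalar truth
fields, and a truth CSV (`beat_time_ms,label,qt_true_ms`). This build does
not link the WFDB libraries; requesting WFDB output raises a clear error.

## QT measurement

**Preprocessing.** A zero-phase 4th-order 50 Hz low-pass mirrors the
recording systems' filter (configurable off). Baseline wander is *not*
removed by a high-pass — its step response sags around every QRS and the
sag varies with RR, injecting artificial beat-to-beat QT noise. Instead a
cubic spline through one isoelectric anchor per beat (median over
R−90…R−50 ms) is subtracted once R positions are known.

**R detection** is a Pan–Tompkins-style energy detector: 5–25 Hz band-pass,
differentiate, square, 120 ms integration, adaptive threshold, 200 ms
refractory, and refinement to the band-passed extremum.

**Template.** Beats are windowed R−250…R+560 ms, aligned to the running
mean by cross-correlation (±20 ms), gated at correlation ≥ 0.9 (this is
what rejects ectopic and artifact beats from the average), and averaged;
at least 8 beats are required. Annotation finds the QRS onset/end by the
2 %-of-max derivative rule (10 ms quadratic Savitzky–Golay derivative), the
T peak as the baseline-corrected extremum 120–460 ms after R, and the T end
by the tangent method.

**Tangent method.** The steepest post-peak downslope is located on a short
(10 ms) quadratic SG derivative — a positively weighted average of local
difference quotients, so it cannot overshoot at corners, and near-minimal
plateaus (a linear ramp) resolve to the plateau midpoint; the tangent line
at that point is intersected with the baseline with sub-sample linear
resolution. Both T polarities are handled. On clean Gaussian T waves the
implementation is within 0.3 ms of the `t_p + 2σ` closed form for
σ = 20–60 ms at 1 kHz.

**Per-beat fiducial-segment averaging.** For each beat, the template's
QRS-onset neighborhood (40 ms) is re-aligned by shift-only normalized
cross-correlation with parabolic sub-sample refinement — depolarization
shape is stable across sinus beats, so a pure shift suffices. The T wave is
different: repolarization lability *is* a change of T-wave duration, and a
shift-only re-alignment of a stretching wave recovers only ~70 % of the
true QT change (the correlation is dominated by the steep region near the
peak, not the T end). The T segment — the whole T wave, from
`t_p − 1.2·(t_end − t_p)` to `t_end + 40 ms` — is therefore registered with
the model

```
beat(x) ≈ a · T(t_p + (x − u − t_p)/s) + b
```

(T = template, u = shift, s = stretch about the template T peak, a/b =
nuisance amplitude/offset), solved by a coarse grid over (u, s) followed by
a four-parameter Gauss–Newton refinement (the joint update is required: the
shift/stretch/amplitude valley is ill-conditioned and alternating updates
converge only linearly). The beat's T end is the template's tangent T end
mapped through the fitted warp, `t_p + s·(t_end − t_p) + u`. Because the
whole wave constrains the fit, band-limited noise is averaged rather than
differentiated: per-beat QT error is ≈ 0.006 ms on clean 1 kHz records,
≈ 0.4 ms at 5 µV broadband noise, and the measured-vs-true per-beat
correlation stays above 0.9 at 20 µV. Beats whose QRS or T correlation
falls below 0.8, or whose mapped T end is inconsistent, are flagged invalid
— never silently dropped. Per-beat QT = mapped T end − re-aligned QRS
onset.

This registration view also explains the sampling-rate experiment: at
1 kHz and 4 kHz the sub-sample refinement leaves essentially no
discretization error (their BVRs agree to < 0.001 ms on average), while at
200 Hz the 5 ms grid leaves genuine per-beat measurement error that
inflates the apparent BVR whenever the true STV is below the sample period
— the package reproduces the inflation qualitatively on the same underlying
signal, and `sampling_study` refuses inputs below 500 Hz without `--force`.

## Rhythm rules

A beat is a PVC iff it is premature (RR < 0.80 × trailing 8-beat
sinus-to-sinus RR mean) *and* morphologically aberrant (template correlation
< 0.8); the second gate prevents RR-only false alarms during sinus
arrhythmia. Both thresholds are config defaults, not literature constants.
Exclusion: every PVC, its succeeding beat unconditionally (chaining through
runs), and its preceding beat iff the PVC's R falls before that beat's T end
(unknown T ends are treated conservatively as interrupted). Runs of ≥ 3
PVCs are flagged nonsustained VT. PVC counts are reported per consecutive
5-min window over 30 min from occlusion; the maximal PVC rate is the
largest count in any sliding 60 s window; coupling intervals are RR from
the prior sinus beat.

## Metrics conventions

* **STV denominator**: the number of QT intervals analyzed (N), reading the
  formula's "n beats" literally; `denominator="differences"` (N−1 style) is
  available for sensitivity analysis. Differences across an exclusion gap
  are dropped, never bridged — a bridged pair is not beat-to-beat.
* **ST level**: median amplitude over J+60…J+80 ms referenced to the PR
  segment (onset−55…−15 ms) of the same beat, averaged over valid beats;
  deviation = segment − baseline, signed; unmeasurable leads are reported
  absent, not zero. The measurement point is a documented choice, not a
  protocol constant.
* **QT dispersion**: inter-lead range (max − min) of segment-mean QT.
* **Heart rate**: from consecutive sinus-to-sinus RR only.
* Cumulative scores: sum of per-lead BVR; sum of per-lead |ST deviation|.

## Study pipeline

Windows are 60 s: baseline ends 15 min before occlusion; "5 min AMI" starts
occlusion + 5 min; "1 min pre-VF" ends exactly at VF onset; "5 min pre-VF"
is the minute centered on the 5-minute mark (ending at VF − 4 min), with a
config alternative ending at VF − 5 min. Matched time points for
non-fibrillating animals reuse the same arithmetic on a supplied matched
time. Windows are clipped to the record and flagged; less than 30 s of
analyzable signal marks a window unavailable, and unavailable or failed
windows keep their (NA) rows in every output table.

The analysis lead ("lead II or V4, as appropriate") is chosen as whichever
of II/V4 shows the larger absolute baseline→ischemia ST deviation, falling
back to the first analyzable lead; a fixed lead can be configured.

**Surge detector**: ΔBVR = BVR(1 min pre-VF) − BVR(5 min pre-VF), flagged
when above a threshold defaulting to 1.4 ms — the midpoint of the reported
group-mean deltas of fibrillating (2.23 ms) and non-fibrillating (0.66 ms)
animals. It is a screening default with no claim of clinical validity. The
synthetic evaluation cohort programs each group's mean trajectory
(1.67→3.78 ms vs 1.47→2.04 ms) into every animal and lets beat-level
stochasticity (QT draws, noise, measurement) differentiate individuals;
between-animal spread is deliberately not resampled, so the cohort tests
the detector and the measurement chain, not population heterogeneity.

**PES inducibility**: the protocol ladder is anchored at its published
endpoints — step 1: drive 600 ms + one extrastimulus at 400 ms; final step:
drive 350 ms + three extrastimuli at 200/180/150 ms — with intermediate
rungs interpolating drive cycles {600, 400, 350} ms × 1–3 extrastimuli in
strictly increasing aggressiveness. Induction at step k of S maps linearly
to `100·(S−k+1)/S` %; noninducibility is 0 %. Both the intermediate rungs
and the linearity are package decisions (only the endpoints are protocol
facts); the index is defined over whatever ladder the user supplies.
**ERP** is the shortest non-capturing S2 at the 400 ms drive train;
all-capturing, none-capturing and non-monotone ladders return flagged
boundary results.

## What the generator does and does not emulate

It emulates: per-beat QT lability with controllable short-term variability
and autocorrelation; PVC timing, morphology and compensatory pauses;
lead-specific ST shifts and T-amplitude changes with a sharp onset;
realistic noise classes; sampling rates of 200/1000/4000 Hz. It does not
emulate: species-specific lead morphology, QT–RR adaptation
(rate-correction is out of scope since heart rate is held stable),
respiratory or autonomic QT modulation, T-wave alternans, morphology drift
during ischemia beyond ST/T-amplitude changes, conduction slowing, or VF
waveforms (VF onset is an event time, not a signal). Passing tests
therefore demonstrate correctness of the *measurement and study logic*
under controlled conditions, not field performance on animal or patient
recordings — in particular, real T-wave shape change during ischemia will
degrade template correlation in ways the generator does not produce.

## Problem sizes and numerical tolerances

Test and acceptance runs use 60-beat (≈50 s) single-lead windows at 1 kHz;
recovery and quantization studies use 100 seeds per condition; the
calibration Monte-Carlo uses 200 seeds (and 200 beats for the 2 %
invariant); the surge cohort is 20+20 animals × 2 windows; the sampling
study synthesizes true 4 kHz records rather than upsampling. The STV oracle
comparison is at 1e-12 relative; fiducial truth comparisons allow ±4 ms on
templates, ±2 ms per clean beat, ±1.5 ms for 1 kHz-vs-4 kHz consistency.
Gauss–Newton registration runs at most 40 iterations, stopping when the
mapped T end moves < 1e-3 samples, with the stretch clamped to 1 ± 0.25.

## Known limitations

* The 2 %-derivative QRS-onset rule lands a few ms after the earliest
  Gaussian-tail activity; since truth and measurement share the rule, QT is
  consistent, but absolute onsets differ from a visual tangent-style onset.
* Warp registration assumes the T wave changes by shift+stretch about its
  peak; asymmetric T-shape change (e.g. biphasic T development) is only
  approximated and lowers the validity correlation rather than being
  modeled.
* The PVC detector is a two-threshold stand-in for expert adjudication; its
  defaults were not tuned against human labels.
* `pvc_profile`'s sliding-window maximum is evaluated at PVC onsets, which
  is exact for counts but reports 0 for a PVC-free record rather than an
  undefined rate.
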