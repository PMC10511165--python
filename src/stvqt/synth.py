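"""Synthetic multi-lead ECG with fully known ground truth.

The generator emulates the recording conditions of a closed-chest large-animal
acute-ischemia experiment: 12-lead sinus-rhythm ECG at a configurable sampling
rate, a prescribed per-beat QT series with controllable short-term variability,
scheduled premature ventricular complexes (PVCs), lead-specific ST-segment
shifts and T-wave amplitude changes from a chosen onset time, and additive
baseline wander / broadband / powerline noise.

Beat model
----------
Each beat is a sum of Gaussians, one per wave (P, Q, R, S, T), in the spirit of
the classical dynamical ECG beat models.  The T wave is a *single* Gaussian so
that its tangent-method end point has a closed form: the steepest downslope of
``A·exp(-(t-t_p)^2 / 2σ^2)`` is at ``t_p + σ`` and the tangent there crosses
the baseline at ``t_p + 2σ``.  Per-beat QT is prescribed by stretching the T
wave about its (fixed) peak, i.e. choosing σ so that the tangent T-end minus
the QRS onset equals the target QT.  Ground truth therefore follows the exact
same convention the measurement pipeline uses.

QT noise model
--------------
Per-beat QT = ``qt_base + x_n`` with ``x_n`` a stationary AR(1) process,
``x_n = φ·x_{n-1} + ε_n``, ``ε_n ~ N(0, σ_w²)``.  The successive difference
``Δ_n = x_{n+1} - x_n`` is Gaussian with ``sd(Δ) = σ_w·sqrt(2/(1+φ))``, so the
expected short-term variability statistic (mean |Δ| / √2) is analytic::

    E[STV] = σ_w · sqrt(2 / (π (1+φ)))

``stv_target`` inverts this to calibrate ``σ_w``; the analytic value is stored
in ``GroundTruth.stv_true``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.signal import resample_poly

from .errors import (
    CalibrationError,
    ConfigurationError,
    InvalidParameterError,
    RangeError,
    UnsupportedFormatError,
)

CLINICAL_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

_FINE_FS = 8000.0  # Hz, grid used for analytic fiducial truth


# ---------------------------------------------------------------------------
# Beat morphology
# ---------------------------------------------------------------------------

#: per-lead wave amplitudes in mV; crude adult-limb/precordial proportions.
_DEFAULT_AMPLITUDES: dict[str, dict[str, float]] = {
    "I":   {"P": 0.05, "Q": -0.05, "R": 0.60, "S": -0.10, "T": 0.20},
    "II":  {"P": 0.10, "Q": -0.08, "R": 1.00, "S": -0.15, "T": 0.30},
    "III": {"P": 0.06, "Q": -0.05, "R": 0.50, "S": -0.10, "T": 0.15},
    "aVR": {"P": -0.08, "Q": 0.05, "R": -0.70, "S": 0.10, "T": -0.25},
    "aVL": {"P": 0.03, "Q": -0.03, "R": 0.30, "S": -0.08, "T": 0.10},
    "aVF": {"P": 0.08, "Q": -0.06, "R": 0.70, "S": -0.12, "T": 0.22},
    "V1":  {"P": 0.04, "Q": 0.00, "R": 0.25, "S": -0.80, "T": -0.10},
    "V2":  {"P": 0.05, "Q": 0.00, "R": 0.45, "S": -0.70, "T": 0.20},
    "V3":  {"P": 0.05, "Q": -0.03, "R": 0.60, "S": -0.50, "T": 0.30},
    "V4":  {"P": 0.06, "Q": -0.05, "R": 1.10, "S": -0.30, "T": 0.40},
    "V5":  {"P": 0.06, "Q": -0.06, "R": 1.00, "S": -0.20, "T": 0.35},
    "V6":  {"P": 0.06, "Q": -0.06, "R": 0.80, "S": -0.15, "T": 0.30},
}


@dataclass(frozen=True)
class BeatMorphology:
    """Sum-of-Gaussians beat description.

    ``waves`` maps a wave name to ``(center_ms, sigma_ms)`` with centers
    relative to the R peak; ``amplitudes`` maps lead -> wave -> mV.
    """

    waves: Mapping[str, tuple[float, float]]
    amplitudes: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for name, (c, s) in self.waves.items():
            if not (np.isfinite(c) and np.isfinite(s)):
                raise InvalidParameterError(f"wave {name}: non-finite center/width")
            if s <= 0:
                raise InvalidParameterError(f"wave {name}: width must be > 0, got {s}")
        for lead, amps in self.amplitudes.items():
            for w, a in amps.items():
                if not np.isfinite(a):
                    raise InvalidParameterError(f"{lead}/{w}: non-finite amplitude")

    @property
    def leads(self) -> tuple[str, ...]:
        return tuple(self.amplitudes.keys())


def default_morphology(qt_ms: float = 400.0,
                       leads: Sequence[str] = CLINICAL_LEADS,
                       t_peak_frac: float = 0.8) -> BeatMorphology:
    """Default 12-lead morphology whose tangent QT equals ``qt_ms``.

    The T peak is placed at ``qrs_onset + t_peak_frac*qt_ms`` and the T width
    at ``(1 - t_peak_frac)*qt_ms / 2`` so that ``t_peak + 2σ`` lands exactly at
    ``qrs_onset + qt_ms``.
    """
    qrs = {"P": (-170.0, 22.0), "Q": (-22.0, 4.5), "R": (0.0, 7.0), "S": (25.0, 5.5)}
    amps = {ld: dict(_DEFAULT_AMPLITUDES[ld]) for ld in leads}
    base = BeatMorphology(waves=qrs, amplitudes=amps)
    onset_rel, _ = _analytic_qrs_bounds(base)
    t_center = onset_rel + t_peak_frac * qt_ms
    t_sigma = (1.0 - t_peak_frac) * qt_ms / 2.0
    waves = dict(qrs)
    waves["T"] = (t_center, t_sigma)
    return BeatMorphology(waves=waves, amplitudes=amps)


def _gauss_add(out: np.ndarray, t_ms: np.ndarray, center: float, sigma: float,
               amp: float) -> None:
    """Add ``amp * exp(-(t-center)^2/2σ^2)`` to ``out`` within ±6σ (in place)."""
    if amp == 0.0:
        return
    lo = np.searchsorted(t_ms, center - 6.0 * sigma)
    hi = np.searchsorted(t_ms, center + 6.0 * sigma)
    if hi <= lo:
        return
    u = (t_ms[lo:hi] - center) / sigma
    out[lo:hi] += amp * np.exp(-0.5 * u * u)


def _gauss_deriv(t_ms: np.ndarray, center: float, sigma: float,
                 amp: float) -> np.ndarray:
    u = (t_ms - center) / sigma
    return -amp * u / sigma * np.exp(-0.5 * u * u)


def _reference_lead(morpho: BeatMorphology) -> str:
    return max(morpho.leads, key=lambda ld: abs(morpho.amplitudes[ld].get("R", 0.0)))


def _analytic_qrs_bounds(morpho: BeatMorphology) -> tuple[float, float]:
    """(QRS onset, QRS end) in ms relative to the R peak, by the derivative rule.

    Convention shared with the measurement side: walking outward from the
    steepest QRS slope, the complex ends at the first sample where |dV/dt|
    drops below 2 % of the maximal |dV/dt| inside the complex.  Evaluated on
    the analytic derivative at a fine grid, on the lead with the tallest R.
    """
    lead = _reference_lead(morpho)
    amps = morpho.amplitudes[lead]
    t = np.arange(-120.0, 160.0, 1000.0 / _FINE_FS)
    deriv = np.zeros_like(t)
    for name, (c, s) in morpho.waves.items():
        if name == "T":
            continue
        deriv += _gauss_deriv(t, c, s, amps.get(name, 0.0))
    absd = np.abs(deriv)
    core = (t >= -60.0) & (t <= 60.0)
    dmax = absd[core].max()
    if dmax <= 0:
        raise InvalidParameterError("flat QRS: cannot locate onset/end")
    thr = 0.02 * dmax
    i_r = np.searchsorted(t, 0.0)
    up = slice(np.searchsorted(t, -45.0), i_r)
    i_up = up.start + int(np.argmax(absd[up]))
    i = i_up
    while i > 0 and absd[i] >= thr:
        i -= 1
    onset = float(t[i])
    down = slice(i_r, np.searchsorted(t, 60.0))
    i_dn = down.start + int(np.argmax(absd[down]))
    i = i_dn
    while i < len(t) - 1 and absd[i] >= thr:
        i += 1
    end = float(t[i])
    return onset, end


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ECGRecord:
    """Multi-lead waveform; ``signal`` is (n_leads, n_samples) in mV."""

    fs: float
    lead_names: tuple[str, ...]
    signal: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.lead_names = tuple(self.lead_names)
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.lead_names):
            raise InvalidParameterError("signal must be (n_leads, n_samples)")
        if not np.all(np.isfinite(self.signal)):
            raise InvalidParameterError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.signal[self.lead_names.index(name)]
        except ValueError:
            raise KeyError(f"lead {name!r} not in record {self.lead_names}") from None

    def slice(self, start_s: float, end_s: float) -> "ECGRecord":
        """Sub-record covering [start_s, end_s) on this record's clock."""
        i0 = max(0, int(round((start_s - self.t0) * self.fs)))
        i1 = min(self.n_samples, int(round((end_s - self.t0) * self.fs)))
        if i1 <= i0:
            raise RangeError(f"empty slice [{start_s}, {end_s}) s")
        return ECGRecord(self.fs, self.lead_names, self.signal[:, i0:i1].copy(),
                         t0=self.t0 + i0 / self.fs)


@dataclass
class GroundTruth:
    """Generation truth: beat times, per-beat QT, labels, prescribed STV."""

    r_times: np.ndarray            # ms from record start, strictly increasing
    qt_true: np.ndarray            # ms; NaN for PVC beats
    labels: np.ndarray             # 'sinus' | 'pvc'
    st_offset_per_lead: dict[str, float]
    stv_true: float
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.qt_true = np.asarray(self.qt_true, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.r_times) == len(self.qt_true) == len(self.labels)):
            raise InvalidParameterError("truth arrays must have equal length")
        if len(self.r_times) > 1 and not np.all(np.diff(self.r_times) > 0):
            raise InvalidParameterError("r_times must be strictly increasing")
        if self.stv_true < 0:
            raise InvalidParameterError("stv_true must be >= 0")


@dataclass
class SynthConfig:
    """Generation parameters; defaults are the package's study conditions.

    Heart rate 75/min (RR 800 ms) with a small respiratory RR sd, QT 400 ms
    and white QT noise 0.5 ms (expected STV ~0.40 ms) match the quiescent
    baseline of an anesthetized large animal; noise amplitudes are those of a
    good-quality lab recording.
    """

    fs: float = 1000.0
    duration: float = 60.0                       # s
    leads: tuple[str, ...] = CLINICAL_LEADS
    rr_mean: float = 800.0                       # ms
    rr_sd: float = 25.0                          # ms
    qt_base: float = 400.0                       # ms
    qt_white_sd: float = 0.5                     # ms
    qt_ar_coef: float = 0.0                      # lag-1 autocorrelation in [0,1)
    stv_target: float | None = None              # ms; overrides qt_white_sd
    pvc_schedule: tuple[tuple[int, float, float], ...] = ()
    # (beat index, coupling interval ms, morphology scale)
    st_offset_per_lead: Mapping[str, float] = field(default_factory=dict)
    t_amp_scale_per_lead: Mapping[str, float] = field(default_factory=dict)
    noise_wander: tuple[float, float] = (0.05, 0.3)   # (mV, Hz)
    noise_broadband: float = 0.005               # mV sd
    noise_powerline: float = 0.005               # mV at 50 Hz
    t_peak_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise InvalidParameterError("fs and duration must be > 0")
        if not (self.rr_mean > self.qt_base > 0):
            raise InvalidParameterError("need rr_mean > qt_base > 0")
        if self.qt_white_sd < 0:
            raise InvalidParameterError("qt_white_sd must be >= 0")
        if not (0.0 <= self.qt_ar_coef < 1.0):
            raise InvalidParameterError("qt_ar_coef must be in [0, 1)")
        for idx, coupling, _scale in self.pvc_schedule:
            if not (0 < coupling < self.rr_mean):
                raise InvalidParameterError(
                    f"PVC coupling {coupling} ms must be < rr_mean")
            if idx < 1:
                raise InvalidParameterError("PVC beat index must be >= 1")
        self.leads = tuple(self.leads)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "pvc_schedule" in data:
            data["pvc_schedule"] = tuple(tuple(row) for row in data["pvc_schedule"])
        if "noise_wander" in data:
            data["noise_wander"] = tuple(data["noise_wander"])
        if "leads" in data:
            data["leads"] = tuple(data["leads"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def expected_stv(qt_white_sd: float, qt_ar_coef: float) -> float:
    """Analytic E[STV] of the AR(1) QT noise (mean |successive diff| / √2)."""
    return qt_white_sd * math.sqrt(2.0 / (math.pi * (1.0 + qt_ar_coef)))


def calibrate_white_sd(stv_target: float, qt_ar_coef: float) -> float:
    """White-noise sd achieving a prescribed expected STV (inverse of above)."""
    if stv_target < 0 or not np.isfinite(stv_target):
        raise CalibrationError(f"stv_target must be finite and >= 0, got {stv_target}")
    if not (0.0 <= qt_ar_coef < 1.0):
        raise CalibrationError("qt_ar_coef must be in [0, 1)")
    return stv_target * math.sqrt(math.pi * (1.0 + qt_ar_coef) / 2.0)


# ---------------------------------------------------------------------------
# Template rendering
# ---------------------------------------------------------------------------

def make_beat_template(morphology: BeatMorphology, fs: float = 1000.0,
                       rr_mean: float = 800.0, r_offset_ms: float = 250.0,
                       ) -> tuple[dict[str, np.ndarray], dict]:
    """Render one beat per lead plus the fiducials implied by the parameters.

    Returns ``(waveforms, info)`` where each waveform spans ``rr_mean`` ms at
    ``fs`` with the R peak at ``r_offset_ms``.  ``info`` carries the analytic
    ``qrs_onset_ms``, ``t_peak_ms``, ``t_end_ms`` (tangent convention,
    ``t_peak + 2σ``) and ``qt_ms`` in template time, or None when the relevant
    waves are absent (all-zero amplitudes).
    """
    if fs <= 0:
        raise InvalidParameterError(f"fs must be > 0, got {fs}")
    n = int(round(rr_mean * fs / 1000.0))
    t = np.arange(n) * (1000.0 / fs)
    waveforms: dict[str, np.ndarray] = {}
    for lead in morpho_leads(morphology):
        w = np.zeros(n)
        amps = morphology.amplitudes[lead]
        for name, (c, s) in morphology.waves.items():
            _gauss_add(w, t, r_offset_ms + c, s, amps.get(name, 0.0))
        waveforms[lead] = w

    ref = _reference_lead(morphology)
    has_qrs = any(morphology.amplitudes[ref].get(wv, 0.0) != 0.0
                  for wv in ("Q", "R", "S"))
    has_t = "T" in morphology.waves and any(
        a.get("T", 0.0) != 0.0 for a in morphology.amplitudes.values())
    info: dict = {"fs": fs, "r_ms": r_offset_ms, "qrs_onset_ms": None,
                  "qrs_end_ms": None, "t_peak_ms": None, "t_end_ms": None,
                  "qt_ms": None}
    if has_qrs:
        onset_rel, end_rel = _analytic_qrs_bounds(morphology)
        info["qrs_onset_ms"] = r_offset_ms + onset_rel
        info["qrs_end_ms"] = r_offset_ms + end_rel
    if has_t:
        c, s = morphology.waves["T"]
        info["t_peak_ms"] = r_offset_ms + c
        info["t_end_ms"] = r_offset_ms + c + 2.0 * s
    if info["qrs_onset_ms"] is not None and info["t_end_ms"] is not None:
        info["qt_ms"] = info["t_end_ms"] - info["qrs_onset_ms"]
    return waveforms, info


def morpho_leads(morphology: BeatMorphology) -> tuple[str, ...]:
    return morphology.leads


# ---------------------------------------------------------------------------
# Record synthesis
# ---------------------------------------------------------------------------

def _beat_train(cfg: SynthConfig, rng: np.random.Generator,
                ) -> tuple[np.ndarray, np.ndarray]:
    """R times (ms) and labels; PVCs at scheduled indices with compensatory pause."""
    schedule = {idx: (coupling, scale) for idx, coupling, scale in cfg.pvc_schedule}
    first = max(300.0, 0.5 * cfg.rr_mean)
    tail = 700.0  # leave room for the last T wave and its tangent
    r_times: list[float] = []
    labels: list[str] = []
    t = first
    i = 0
    while t < cfg.duration * 1000.0 - tail:
        r_times.append(t)
        labels.append("pvc" if i in schedule else "sinus")
        nxt = i + 1
        if nxt in schedule:
            rr = schedule[nxt][0]
        elif i in schedule:
            rr = 2.0 * cfg.rr_mean - schedule[i][0]  # compensatory pause
        else:
            rr = float(np.clip(rng.normal(cfg.rr_mean, cfg.rr_sd),
                               cfg.rr_mean / 2.0, None))
        t += rr
        i += 1
    if not r_times:
        raise InvalidParameterError("duration too short for a single beat")
    return np.asarray(r_times), np.asarray(labels, dtype=object)


def _qt_series(cfg: SynthConfig, labels: np.ndarray, rng: np.random.Generator,
               ) -> tuple[np.ndarray, float]:
    if cfg.stv_target is not None:
        white_sd = calibrate_white_sd(cfg.stv_target, cfg.qt_ar_coef)
    else:
        white_sd = cfg.qt_white_sd
    stv_true = expected_stv(white_sd, cfg.qt_ar_coef)
    phi = cfg.qt_ar_coef
    n = len(labels)
    x = np.zeros(n)
    if white_sd > 0:
        sd_stat = white_sd / math.sqrt(1.0 - phi * phi)
        x[0] = rng.normal(0.0, sd_stat)
        eps = rng.normal(0.0, white_sd, n - 1)
        for k in range(1, n):
            x[k] = phi * x[k - 1] + eps[k - 1]
    qt = cfg.qt_base + x
    qt[labels == "pvc"] = np.nan
    return qt, stv_true


def synthesize_record(cfg: SynthConfig) -> tuple[ECGRecord, GroundTruth]:
    """Generate an (ECGRecord, GroundTruth) pair; bit-reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    morpho = default_morphology(cfg.qt_base, cfg.leads, cfg.t_peak_frac)
    onset_rel, j_rel = _analytic_qrs_bounds(morpho)
    t_peak_rel = morpho.waves["T"][0]

    r_times, labels = _beat_train(cfg, rng)
    qt, stv_true = _qt_series(cfg, labels, rng)

    # per-beat T width from the prescribed QT (tangent convention)
    t_sigma = np.full(len(r_times), morpho.waves["T"][1])
    sinus = labels == "sinus"
    t_sigma[sinus] = (qt[sinus] - (t_peak_rel - onset_rel)) / 2.0
    if np.any(t_sigma[sinus] < 4.0):
        raise InvalidParameterError(
            "prescribed QT too short for the T-peak position; "
            "decrease t_peak_frac or raise qt_base")

    n = int(round(cfg.duration * cfg.fs))
    t_ms = np.arange(n) * (1000.0 / cfg.fs)
    signal = np.zeros((len(cfg.leads), n))
    st_cfg = {ld: float(cfg.st_offset_per_lead.get(ld, 0.0)) for ld in cfg.leads}
    t_scale_cfg = {ld: float(cfg.t_amp_scale_per_lead.get(ld, 1.0))
                   for ld in cfg.leads}

    for li, lead in enumerate(cfg.leads):
        amps = morpho.amplitudes[lead]
        w = signal[li]
        for bi, (rt, lab) in enumerate(zip(r_times, labels)):
            if lab == "sinus":
                for name, (c, s) in morpho.waves.items():
                    if name == "T":
                        continue
                    _gauss_add(w, t_ms, rt + c, s, amps.get(name, 0.0))
                _gauss_add(w, t_ms, rt + t_peak_rel, t_sigma[bi],
                           amps.get("T", 0.0) * t_scale_cfg[lead])
            else:  # wide, early, inverted ectopic complex with discordant T
                scale = next(sc for idx, _c, sc in cfg.pvc_schedule if idx == bi)
                qrs_amp = -math.copysign(max(abs(amps.get("R", 0.0)), 0.3),
                                         amps.get("R", 1.0)) * scale
                _gauss_add(w, t_ms, rt, 24.0, qrs_amp)
                _gauss_add(w, t_ms, rt + 300.0, 60.0, -0.5 * qrs_amp)
            if st_cfg[lead] != 0.0 and lab == "sinus":
                _add_st_plateau(w, t_ms, rt, j_rel, t_peak_rel - 2.0 * t_sigma[bi],
                                st_cfg[lead])

    _add_noise(signal, t_ms, cfg, rng)

    record = ECGRecord(cfg.fs, cfg.leads, signal)
    truth = GroundTruth(
        r_times=r_times, qt_true=qt, labels=labels,
        st_offset_per_lead=dict(st_cfg), stv_true=stv_true, seed=cfg.seed,
        meta={
            "qrs_onset_rel_ms": onset_rel,
            "qrs_end_rel_ms": j_rel,
            "t_peak_rel_ms": t_peak_rel,
            "t_sigma_ms": t_sigma.tolist(),
            "t_amp_per_lead": {ld: morpho.amplitudes[ld].get("T", 0.0)
                               * t_scale_cfg[ld] for ld in cfg.leads},
            "rr_mean_ms": cfg.rr_mean,
            "qt_base_ms": cfg.qt_base,
        })
    return record, truth


def _add_st_plateau(w: np.ndarray, t_ms: np.ndarray, r_time: float, j_rel: float,
                    t_on_rel: float, offset_mv: float, ramp_ms: float = 14.0) -> None:
    """Raised-cosine-edged ST plateau between QRS end and T onset of one beat."""
    a = r_time + j_rel
    b = r_time + max(t_on_rel, j_rel + 2.0 * ramp_ms)
    lo = np.searchsorted(t_ms, a - ramp_ms)
    hi = np.searchsorted(t_ms, b + ramp_ms)
    if hi <= lo:
        return
    tt = t_ms[lo:hi]
    env = np.ones_like(tt)
    up = tt < a
    env[up] = 0.5 * (1.0 + np.cos(np.pi * (a - tt[up]) / ramp_ms))
    dn = tt > b
    env[dn] = 0.5 * (1.0 + np.cos(np.pi * (tt[dn] - b) / ramp_ms))
    w[lo:hi] += offset_mv * env


def _add_noise(signal: np.ndarray, t_ms: np.ndarray, cfg: SynthConfig,
               rng: np.random.Generator) -> None:
    t_s = t_ms / 1000.0
    amp_w, f_w = cfg.noise_wander
    for li in range(signal.shape[0]):
        if amp_w > 0:
            phase = rng.uniform(0, 2 * np.pi)
            signal[li] += amp_w * np.sin(2 * np.pi * f_w * t_s + phase)
        if cfg.noise_powerline > 0:
            phase = rng.uniform(0, 2 * np.pi)
            signal[li] += cfg.noise_powerline * np.sin(2 * np.pi * 50.0 * t_s + phase)
        if cfg.noise_broadband > 0:
            signal[li] += rng.normal(0.0, cfg.noise_broadband, signal.shape[1])


# ---------------------------------------------------------------------------
# Ischemia overlay
# ---------------------------------------------------------------------------

def apply_ischemia(record: ECGRecord, truth: GroundTruth,
                   st_offsets: Mapping[str, float],
                   t_scale: float | Mapping[str, float] = 1.0,
                   onset_s: float = 0.0) -> tuple[ECGRecord, GroundTruth]:
    """Shift ST plateaus and scale T amplitudes from ``onset_s`` onward.

    Only beats whose R time falls at or after the onset are touched, so every
    pre-onset sample is bit-identical to the input.  PVC beats are left
    unchanged (they are excluded from repolarization analysis anyway).
    """
    if not (0.0 <= onset_s <= record.duration_s):
        raise RangeError(f"onset {onset_s}s outside record "
                         f"[0, {record.duration_s:.3f}] s")
    for ld, v in st_offsets.items():
        if not np.isfinite(v):
            raise InvalidParameterError(f"non-finite ST offset for lead {ld}")
    meta = truth.meta
    j_rel = meta["qrs_end_rel_ms"]
    t_peak_rel = meta["t_peak_rel_ms"]
    t_sigma = np.asarray(meta["t_sigma_ms"])
    t_amp = meta["t_amp_per_lead"]

    signal = record.signal.copy()
    t_ms = np.arange(record.n_samples) * (1000.0 / record.fs)
    scales = (t_scale if isinstance(t_scale, Mapping)
              else {ld: float(t_scale) for ld in record.lead_names})
    for li, lead in enumerate(record.lead_names):
        off = float(st_offsets.get(lead, 0.0))
        sc = float(scales.get(lead, 1.0))
        if off == 0.0 and sc == 1.0:
            continue
        w = signal[li]
        for bi, (rt, lab) in enumerate(zip(truth.r_times, truth.labels)):
            if rt < onset_s * 1000.0 or lab != "sinus":
                continue
            if off != 0.0:
                _add_st_plateau(w, t_ms, rt, j_rel,
                                t_peak_rel - 2.0 * t_sigma[bi], off)
            if sc != 1.0:
                _gauss_add(w, t_ms, rt + t_peak_rel, t_sigma[bi],
                           (sc - 1.0) * t_amp.get(lead, 0.0))

    new_offsets = dict(truth.st_offset_per_lead)
    for ld, v in st_offsets.items():
        new_offsets[ld] = new_offsets.get(ld, 0.0) + float(v)
    new_truth = dataclasses.replace(truth, st_offset_per_lead=new_offsets)
    return ECGRecord(record.fs, record.lead_names, signal, record.t0), new_truth


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(record: ECGRecord, fs_new: float) -> ECGRecord:
    """Polyphase anti-aliased rate conversion (scipy ``resample_poly``).

    The conversion uses scipy's default Kaiser-windowed (β=5.0) low-pass FIR
    at the polyphase rate, which anti-aliases on downsampling and acts as the
    interpolation filter on upsampling.  ``fs_new == fs`` returns a verbatim
    copy.
    """
    if fs_new <= 0:
        raise InvalidParameterError(f"fs_new must be > 0, got {fs_new}")
    if fs_new == record.fs:
        return ECGRecord(record.fs, record.lead_names, record.signal.copy(),
                         record.t0)
    frac = Fraction(fs_new / record.fs).limit_denominator(10000)
    out = resample_poly(record.signal, frac.numerator, frac.denominator, axis=1)
    return ECGRecord(fs_new, record.lead_names, out, record.t0)


# ---------------------------------------------------------------------------
# Serialization: CSV signal + JSON sidecar + truth CSV
# ---------------------------------------------------------------------------

_SIGNAL_CSV = "signal.csv"
_SIDECAR_JSON = "record.json"
_TRUTH_CSV = "truth.csv"


def write_record(record: ECGRecord, truth: GroundTruth | None,
                 path: str | Path, format: str = "csv") -> Path:
    """Write a record (and optional truth) to ``path`` (a directory).

    Format ``csv``: one signal CSV (column per lead, mV, 6 decimals), a JSON
    sidecar with ``fs``/``leads``/``t0`` plus the scalar truth fields, and a
    truth CSV table ``beat_time_ms,label,qt_true_ms``.  The WFDB format
    requires the ``wfdb`` package and is not supported by this build.
    """
    if format.lower() == "wfdb":
        raise UnsupportedFormatError(
            "WFDB output requires the 'wfdb' package, which this build does "
            "not ship; use format='csv'")
    if format.lower() != "csv":
        raise UnsupportedFormatError(f"unknown format {format!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = ",".join(record.lead_names)
    np.savetxt(path / _SIGNAL_CSV, record.signal.T, delimiter=",",
               header=header, comments="", fmt="%.6f")
    sidecar: dict = {"fs": record.fs, "leads": list(record.lead_names),
                     "t0": record.t0}
    if truth is not None:
        sidecar["truth"] = {
            "stv_true": truth.stv_true,
            "seed": truth.seed,
            "st_offset_per_lead": truth.st_offset_per_lead,
            "meta": truth.meta,
        }
        with open(path / _TRUTH_CSV, "w") as fh:
            fh.write("beat_time_ms,label,qt_true_ms\n")
            for rt, lab, q in zip(truth.r_times, truth.labels, truth.qt_true):
                qs = "" if np.isnan(q) else f"{q:.6f}"
                fh.write(f"{rt:.6f},{lab},{qs}\n")
    (path / _SIDECAR_JSON).write_text(json.dumps(sidecar, indent=1))
    return path


def read_record(path: str | Path) -> tuple[ECGRecord, GroundTruth | None]:
    """Inverse of :func:`write_record` (CSV format)."""
    path = Path(path)
    sidecar_path = path / _SIDECAR_JSON
    if not sidecar_path.exists():
        raise ConfigurationError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for fld in ("fs", "leads"):
        if fld not in sidecar:
            raise ConfigurationError(
                f"sidecar {sidecar_path} is missing required field {fld!r}")
    with open(path / _SIGNAL_CSV) as fh:
        header = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if header != list(sidecar["leads"]):
        raise ConfigurationError("signal CSV header does not match sidecar leads")
    record = ECGRecord(float(sidecar["fs"]), tuple(sidecar["leads"]), data.T,
                       float(sidecar.get("t0", 0.0)))
    truth = None
    truth_path = path / _TRUTH_CSV
    if truth_path.exists() and "truth" in sidecar:
        rows = truth_path.read_text().strip().splitlines()[1:]
        r_times, labels, qts = [], [], []
        for row in rows:
            rt, lab, q = row.split(",")
            r_times.append(float(rt))
            labels.append(lab)
            qts.append(float(q) if q else np.nan)
        ts = sidecar["truth"]
        truth = GroundTruth(np.asarray(r_times), np.asarray(qts),
                            np.asarray(labels, dtype=object),
                            dict(ts.get("st_offset_per_lead", {})),
                            float(ts["stv_true"]), int(ts["seed"]),
                            meta=dict(ts.get("meta", {})))
    return record, truth
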