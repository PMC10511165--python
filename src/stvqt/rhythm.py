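"""Beat classification and the PVC exclusion rule.

A beat is labeled a premature ventricular complex (PVC) when it is both
premature (RR to the previous beat shorter than 80 % of the trailing 8-beat
sinus RR mean) and morphologically aberrant (correlation with the sinus
template below 0.8).  For QT-variability analysis every PVC is excluded
together with the succeeding sinus beat, and with the *preceding* sinus beat
when the PVC fell before that beat's T-wave end (its QT cannot be measured
reliably).  Runs of three or more consecutive PVCs are additionally flagged as
nonsustained VT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError


@dataclass
class RhythmConfig:
    prematurity: float = 0.80        # RR fraction of trailing sinus mean
    morph_corr_max: float = 0.8      # below this = aberrant morphology
    trailing_beats: int = 8
    nsvt_run_length: int = 3


@dataclass
class RhythmReport:
    pvc_count_per_window: list[int]
    max_pvc_rate: float                      # PVCs/min over 1-min sliding windows
    coupling_intervals: list[float]          # ms, RR from prior sinus beat
    excluded_beat_indices: list[int]
    nsvt_runs: list[tuple[int, int]] = field(default_factory=list)
    truncated: bool = False


def classify_beats(r_times_ms: np.ndarray, morph_corr: np.ndarray,
                   cfg: RhythmConfig | None = None) -> np.ndarray:
    """Label each beat ``'sinus'`` or ``'pvc'``.

    The prematurity gate compares each RR with the running mean of the last
    ``trailing_beats`` sinus-to-sinus RR intervals (seeded with the overall
    median RR); the morphology gate prevents RR-only false alarms during
    sinus arrhythmia.
    """
    cfg = cfg or RhythmConfig()
    r = np.asarray(r_times_ms, dtype=float)
    corr = np.asarray(morph_corr, dtype=float)
    if len(r) < 3:
        raise InsufficientDataError(f"need >= 3 beats, have {len(r)}")
    if len(corr) != len(r):
        raise InsufficientDataError("morph_corr must align with r_times")
    rr = np.diff(r)
    trailing: list[float] = [float(np.median(rr))]
    labels = np.empty(len(r), dtype=object)
    labels[0] = "sinus"
    for i in range(1, len(r)):
        mean_rr = float(np.mean(trailing[-cfg.trailing_beats:]))
        premature = rr[i - 1] < cfg.prematurity * mean_rr
        aberrant = corr[i] < cfg.morph_corr_max
        labels[i] = "pvc" if (premature and aberrant) else "sinus"
        if labels[i] == "sinus" and labels[i - 1] == "sinus":
            trailing.append(float(rr[i - 1]))
    return labels


def nsvt_runs(labels: np.ndarray, run_length: int = 3) -> list[tuple[int, int]]:
    """(start, end) index pairs (inclusive) of PVC runs of >= run_length."""
    runs = []
    i = 0
    lab = np.asarray(labels, dtype=object)
    while i < len(lab):
        if lab[i] == "pvc":
            j = i
            while j + 1 < len(lab) and lab[j + 1] == "pvc":
                j += 1
            if j - i + 1 >= run_length:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def exclusion_mask(labels: np.ndarray, r_times_ms: np.ndarray,
                   t_end_ms: np.ndarray | None = None) -> np.ndarray:
    """Beat indices excluded from QT analysis (sorted, unique).

    Every PVC is excluded; its succeeding beat is excluded unconditionally
    (chaining through PVC runs); its preceding beat is excluded iff the PVC's
    R wave falls before that beat's T-wave end (R-on-T interruption).  When a
    preceding beat's T end is unknown (``t_end_ms`` None or NaN) the beat is
    excluded conservatively.  Idempotent and order-independent by
    construction (set semantics).
    """
    lab = np.asarray(labels, dtype=object)
    r = np.asarray(r_times_ms, dtype=float)
    n = len(lab)
    excluded: set[int] = set()
    for i in np.flatnonzero(lab == "pvc"):
        i = int(i)
        excluded.add(i)
        if i + 1 < n:
            excluded.add(i + 1)
        if i - 1 >= 0 and lab[i - 1] != "pvc":
            if t_end_ms is None or not np.isfinite(t_end_ms[i - 1]):
                excluded.add(i - 1)
            elif r[i] < t_end_ms[i - 1]:
                excluded.add(i - 1)
    return np.asarray(sorted(excluded), dtype=int)


def pvc_profile(labels: np.ndarray, r_times_ms: np.ndarray,
                occlusion_time_s: float, window_s: float = 300.0,
                span_s: float = 1800.0,
                t_end_ms: np.ndarray | None = None) -> RhythmReport:
    """PVC counts per consecutive window across ``span_s`` after occlusion.

    ``max_pvc_rate`` is the maximum count in any sliding 60-s window
    (evaluated at every PVC time), expressed per minute; each PVC's coupling
    interval is its RR from the prior sinus beat.
    """
    lab = np.asarray(labels, dtype=object)
    r = np.asarray(r_times_ms, dtype=float)
    t_occ = occlusion_time_s * 1000.0
    truncated = False
    if len(r) and r[-1] < t_occ + span_s * 1000.0:
        truncated = True
        warnings.warn("record ends before the requested PVC-counting span; "
                      "window counts are truncated", stacklevel=2)
    n_win = int(np.ceil(span_s / window_s))
    counts = [0] * n_win
    pvc_times = r[lab == "pvc"]
    for t in pvc_times:
        k = int((t - t_occ) // (window_s * 1000.0))
        if 0 <= k < n_win:
            counts[k] += 1
    max_rate = 0.0
    for t in pvc_times:
        c = int(np.sum((pvc_times >= t) & (pvc_times < t + 60000.0)))
        max_rate = max(max_rate, float(c))
    couplings = []
    for i in np.flatnonzero(lab == "pvc"):
        if i >= 1 and lab[i - 1] == "sinus":
            couplings.append(float(r[i] - r[i - 1]))
    return RhythmReport(
        pvc_count_per_window=counts,
        max_pvc_rate=max_rate,
        coupling_intervals=couplings,
        excluded_beat_indices=exclusion_mask(lab, r, t_end_ms).tolist(),
        nsvt_runs=nsvt_runs(lab),
        truncated=truncated,
    )
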