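"""Beat-to-beat repolarization metrics.

The core statistic is the short-term variability of the QT interval
(STVQT, also called beat-to-beat variability of repolarization, BVR)::

    STV = Σ |QT_{n+1} - QT_n| / (N · √2)

summed over *admissible* consecutive beat pairs — both beats valid and
adjacent in the original beat ordering, so a pair bridging an excluded beat is
dropped (it is no longer beat-to-beat).  ``N`` is by default the number of QT
intervals analyzed (the beat count), the literal reading of the formula's
"n beats" denominator; ``denominator="differences"`` switches to the number of
successive differences for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError


@dataclass
class QTSeries:
    """Ordered per-beat QT intervals with validity mask, one lead."""

    beat_times: np.ndarray       # ms, strictly increasing
    qt: np.ndarray               # ms; NaN where measurement failed
    valid: np.ndarray            # bool, post-exclusion validity
    lead: str = ""

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.qt = np.asarray(self.qt, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.beat_times) == len(self.qt) == len(self.valid)):
            raise InvalidParameterError("QTSeries arrays must be equal length")
        if len(self.beat_times) > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise InvalidParameterError("beat_times must be strictly increasing")
        bad = self.valid & ~(self.qt > 0)
        if np.any(bad):
            raise InvalidParameterError("valid beats must have qt > 0")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class SegmentMetrics:
    """Per-window metric bundle; per-lead values keyed by lead name."""

    bvr: dict[str, float] = field(default_factory=dict)          # ms
    mean_qt: dict[str, float] = field(default_factory=dict)      # ms
    st_dev: dict[str, float] = field(default_factory=dict)       # mV, signed
    hr: float = math.nan                                         # beats/min
    qt_dispersion: float = math.nan                              # ms
    cumulative_bvr: float = math.nan                             # ms
    cumulative_st: float = math.nan                              # mV
    max_bvr: float = math.nan                                    # ms
    pvc_count: int = 0
    failed_leads: dict[str, str] = field(default_factory=dict)
    window: tuple[float, float] | None = None                    # s


def _admissible_pairs(qts: QTSeries) -> np.ndarray:
    """Indices i where beats (i, i+1) are both valid and adjacent."""
    v = qts.valid
    if v.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 valid beats, have {int(v.sum())}")
    return np.flatnonzero(v[:-1] & v[1:])


def stv(qts: QTSeries, denominator: str = "beats") -> float:
    """Short-term QT variability (BVR) in ms.

    ``denominator="beats"`` divides by the number of valid QT intervals
    (default); ``"differences"`` divides by the number of admissible
    successive differences.
    """
    pairs = _admissible_pairs(qts)
    if len(pairs) == 0:
        raise InsufficientDataError("no admissible consecutive beat pairs")
    diffs = np.abs(qts.qt[pairs + 1] - qts.qt[pairs])
    if denominator == "beats":
        n = qts.n_valid
    elif denominator == "differences":
        n = len(pairs)
    else:
        raise InvalidParameterError(
            f"denominator must be 'beats' or 'differences', got {denominator!r}")
    return float(diffs.sum() / (n * math.sqrt(2.0)))


def poincare(qts: QTSeries) -> np.ndarray:
    """(QT_n, QT_{n+1}) pairs over admissible consecutive beats, shape (m, 2)."""
    pairs = _admissible_pairs(qts)
    return np.column_stack([qts.qt[pairs], qts.qt[pairs + 1]])


def qt_dispersion(per_lead_mean_qt: Mapping[str, float] | Sequence[float]) -> float:
    """Inter-lead range (max − min) of segment-mean QT, ms."""
    vals = (list(per_lead_mean_qt.values())
            if isinstance(per_lead_mean_qt, Mapping) else list(per_lead_mean_qt))
    vals = [v for v in vals if np.isfinite(v)]
    if len(vals) < 2:
        raise InsufficientDataError("QT dispersion needs >= 2 leads")
    return float(max(vals) - min(vals))


# ---------------------------------------------------------------------------
# ST-segment level
# ---------------------------------------------------------------------------

def st_level(record, lead: str, beats, window_ms: tuple[float, float] = (60.0, 80.0),
             pr_ms: tuple[float, float] = (55.0, 15.0)) -> float:
    """Mean ST level of one lead over valid beats, mV.

    Per beat: median amplitude over [J+60, J+80] ms (J = QRS end) referenced
    to the PR-segment median of the same beat; averaged over valid beats.
    ``beats`` is a BeatSet-like object with ``j_point``/``qrs_on``/``valid``
    arrays in record-clock ms.
    """
    y = record.lead(lead)
    fs = record.fs
    t0_ms = record.t0 * 1000.0
    levels = []
    for ok, j_ms, on_ms in zip(beats.valid, beats.j_point, beats.qrs_on):
        if not ok or not (np.isfinite(j_ms) and np.isfinite(on_ms)):
            continue
        a = int(round((j_ms + window_ms[0] - t0_ms) * fs / 1000.0))
        b = int(round((j_ms + window_ms[1] - t0_ms) * fs / 1000.0))
        p = int(round((on_ms - pr_ms[0] - t0_ms) * fs / 1000.0))
        q = int(round((on_ms - pr_ms[1] - t0_ms) * fs / 1000.0))
        if a < 0 or b > len(y) or p < 0 or q <= p or b <= a:
            continue
        levels.append(float(np.median(y[a:b]) - np.median(y[p:q])))
    if not levels:
        raise InsufficientDataError(f"no measurable ST level on lead {lead}")
    return float(np.mean(levels))


def st_deviation(record, baseline_record, beats_by_lead: Mapping[str, object],
                 baseline_beats_by_lead: Mapping[str, object],
                 ) -> dict[str, float]:
    """Signed per-lead ST deviation (segment minus baseline), mV.

    Leads where either segment has no measurable J point are omitted from the
    result (flagged absent by the caller), never reported as zero.
    """
    out: dict[str, float] = {}
    for lead, beats in beats_by_lead.items():
        if lead not in baseline_beats_by_lead:
            continue
        try:
            seg = st_level(record, lead, beats)
            ref = st_level(baseline_record, lead, baseline_beats_by_lead[lead])
        except InsufficientDataError:
            continue
        out[lead] = seg - ref
    return out


# ---------------------------------------------------------------------------
# Segment assembly
# ---------------------------------------------------------------------------

def heart_rate(r_times_ms: np.ndarray, labels: np.ndarray | None = None) -> float:
    """Mean heart rate (beats/min) from consecutive sinus-to-sinus RR intervals."""
    r = np.asarray(r_times_ms, dtype=float)
    if labels is None:
        sinus = np.ones(len(r), dtype=bool)
    else:
        sinus = np.asarray(labels, dtype=object) == "sinus"
    pair = sinus[:-1] & sinus[1:]
    rr = np.diff(r)[pair]
    if len(rr) == 0:
        raise InsufficientDataError("no consecutive sinus RR intervals")
    return float(60000.0 / rr.mean())


def segment_metrics(qtseries_by_lead: Mapping[str, QTSeries],
                    r_times_ms: np.ndarray,
                    labels: np.ndarray | None = None,
                    st_dev_by_lead: Mapping[str, float] | None = None,
                    denominator: str = "beats",
                    window: tuple[float, float] | None = None) -> SegmentMetrics:
    """Assemble per-lead BVR/mean-QT plus cumulative and cross-lead scores.

    A lead whose QT series cannot support the statistic is recorded in
    ``failed_leads`` with the reason; aggregates run over the remaining leads.
    """
    m = SegmentMetrics(window=window)
    for lead, qts in qtseries_by_lead.items():
        try:
            m.bvr[lead] = stv(qts, denominator=denominator)
            m.mean_qt[lead] = float(np.mean(qts.qt[qts.valid]))
        except InsufficientDataError as exc:
            m.failed_leads[lead] = str(exc)
    if st_dev_by_lead:
        m.st_dev = dict(st_dev_by_lead)
        m.cumulative_st = float(sum(abs(v) for v in m.st_dev.values()))
    if m.bvr:
        m.cumulative_bvr = float(sum(m.bvr.values()))
        m.max_bvr = float(max(m.bvr.values()))
    if len(m.mean_qt) >= 2:
        m.qt_dispersion = qt_dispersion(m.mean_qt)
    try:
        m.hr = heart_rate(r_times_ms, labels)
    except InsufficientDataError:
        m.hr = math.nan
    if labels is not None:
        m.pvc_count = int(np.sum(np.asarray(labels, dtype=object) == "pvc"))
    return m
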