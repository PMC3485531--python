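"""Dyssynchrony metrics: SDI, L-E, Pre-/Post-/total STV, and global function.

Traditional 3D-echo dyssynchrony indices use only segmental *timing*:

* **SDI** — the standard deviation of the 16 times from QRS onset to minimal
  segmental volume, in %RR (sample SD, divisor N-1, by default; the
  population divisor is available via ``sdi_divisor="n"``).
* **L-E** — the interval between the earliest and the latest segment to
  reach its minimal volume, in %RR.

The segmental time-volume loss (STV) family additionally weights each
segment's timing offset by its volume excursion.  For a segment whose
minimal volume occurs at time ``t_seg`` while the global minimum occurs at
``t_glob``, the segment's contribution is the area under its time-volume
curve, measured above its minimal volume, between the two end-systolic
times:

    area = ∫ max(V(t) - V_min, 0) dt   over [min(t_seg, t_glob), max(...)]

in ml × %RR ("ml%").  Segments with ``t_seg < t_glob`` contribute to
**Pre-STV**, segments with ``t_seg > t_glob`` to **Post-STV**, and segments
whose minimum coincides with global end-systole are *synchronous* and
contribute zero to either sum.  Total STV = Pre-STV + Post-STV.

A delayed but severely hypokinetic segment (small excursion) therefore
contributes almost nothing to STV even though it moves SDI and L-E by the
same amount as a normokinetic segment with the same delay — the dissociation
that motivates the metric.  Conversely, high-volume (basal) segments weigh
more than apical ones.

Integration is trapezoidal on the shared uniform grid; both end-systolic
times are grid points after resampling, so no partial intervals arise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .curves import (
    N_SEGMENTS,
    SEGMENT_NAMES,
    EndSystoleTable,
    SegmentalCurveSet,
    TimeVolumeCurve,
    end_systole_table,
    global_curve,
    resample_uniform,
)
from .errors import DegenerateDataError, ValidationError

PRE = "pre"
POST = "post"
SYNCHRONOUS = "synchronous"

#: Default analysis grid density: 201 points, i.e. 0.5 %RR resolution.
DEFAULT_N_SAMPLES = 201


@dataclass(frozen=True)
class SegmentStvEntry:
    """Per-segment STV breakdown: classification and area in ml × %RR."""

    segment: str
    classification: str  # "pre" | "post" | "synchronous"
    area: float
    es_time: float
    es_volume: float


@dataclass(frozen=True)
class DyssynchronyReport:
    """All per-study outputs: global function, timing indices, STV."""

    study_id: str
    edv: float
    esv: float
    ef: float
    sdi: float
    le: float
    pre_stv: float
    post_stv: float
    total_stv: float
    entries: tuple[SegmentStvEntry, ...]
    es_table: EndSystoleTable

    def to_dict(self) -> dict:
        """JSON-ready dict; percentages on the 0-100 scale, STV in ml%."""
        return {
            "study_id": self.study_id,
            "edv_ml": self.edv,
            "esv_ml": self.esv,
            "ef_pct": self.ef,
            "sdi_pct_rr": self.sdi,
            "le_pct_rr": self.le,
            "pre_stv_ml_pct_rr": self.pre_stv,
            "post_stv_ml_pct_rr": self.post_stv,
            "total_stv_ml_pct_rr": self.total_stv,
            "global_es_time_pct_rr": self.es_table.global_es_time,
            "global_es_volume_ml": self.es_table.global_es_volume,
            "segments": [
                {
                    "segment": e.segment,
                    "classification": e.classification,
                    "area_ml_pct_rr": e.area,
                    "es_time_pct_rr": e.es_time,
                    "es_volume_ml": e.es_volume,
                }
                for e in self.entries
            ],
        }


def _check_es_times(es_times: Sequence[float], allow_partial: bool) -> np.ndarray:
    t = np.asarray(es_times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("end-systolic times must be finite")
    if np.any(t < 0) or np.any(t > 100):
        raise ValidationError("end-systolic times must lie in [0, 100] %RR")
    if t.size != N_SEGMENTS and not allow_partial:
        raise ValidationError(
            f"expected {N_SEGMENTS} segmental end-systolic times, got {t.size} "
            "(pass allow_partial=True to compute over the available segments)"
        )
    if t.size < 2:
        raise ValidationError("need at least 2 segmental times")
    return t


def compute_sdi(
    es_times: Sequence[float],
    *,
    divisor: str = "n_minus_1",
    allow_partial: bool = False,
) -> float:
    """Systolic dyssynchrony index: SD of segmental end-systolic times, %RR.

    ``divisor`` selects the sample ("n_minus_1", default) or population
    ("n") standard deviation; the convention of the original analysis
    software is unpublished, so both are exposed.
    """
    t = _check_es_times(es_times, allow_partial)
    if divisor == "n_minus_1":
        ddof = 1
    elif divisor == "n":
        ddof = 0
    else:
        raise ValidationError(f"unknown SDI divisor {divisor!r}")
    return float(np.std(t, ddof=ddof))


def compute_le(es_times: Sequence[float], *, allow_partial: bool = False) -> float:
    """Latest-minus-earliest segmental end-systolic time, %RR."""
    t = _check_es_times(es_times, allow_partial)
    return float(t.max() - t.min())


def segment_stv(
    curve: TimeVolumeCurve,
    t_seg_es: float,
    v_seg_min: float,
    t_glob_es: float,
) -> SegmentStvEntry:
    """One segment's time-volume loss between segmental and global end-systole.

    Both end-systolic times must be grid points of the curve (guaranteed
    after shared resampling).  The integrand ``V(t) - v_seg_min`` is clamped
    at zero to guard against numerical noise below the stored minimum.
    """
    if t_seg_es == t_glob_es:
        return SegmentStvEntry(curve.label, SYNCHRONOUS, 0.0, float(t_seg_es), float(v_seg_min))
    lo, hi = (t_seg_es, t_glob_es) if t_seg_es < t_glob_es else (t_glob_es, t_seg_es)
    t = curve.times
    i0 = int(np.searchsorted(t, lo))
    i1 = int(np.searchsorted(t, hi))
    if i0 >= t.size or t[i0] != lo or i1 >= t.size or t[i1] != hi:
        raise ValidationError(
            f"{curve.label!r}: end-systolic times ({lo}, {hi}) must lie on the curve grid"
        )
    integrand = np.clip(curve.volumes[i0 : i1 + 1] - v_seg_min, 0.0, None)
    area = float(np.trapezoid(integrand, t[i0 : i1 + 1]))
    cls = PRE if t_seg_es < t_glob_es else POST
    return SegmentStvEntry(curve.label, cls, area, float(t_seg_es), float(v_seg_min))


def compute_stv(
    curve_set: SegmentalCurveSet,
    es_table: EndSystoleTable | None = None,
) -> tuple[float, float, float, tuple[SegmentStvEntry, ...]]:
    """Pre-, Post-, and total STV with the per-segment breakdown.

    Every segment is classified exactly once (pre / post / synchronous);
    total STV is the sum of the Pre- and Post-STV sums.
    """
    if es_table is None:
        es_table = end_systole_table(curve_set)
    entries = []
    for name in SEGMENT_NAMES:
        entries.append(
            segment_stv(
                curve_set.segments[name],
                es_table.es_times[name],
                es_table.es_volumes[name],
                es_table.global_es_time,
            )
        )
    pre = float(sum(e.area for e in entries if e.classification == PRE))
    post = float(sum(e.area for e in entries if e.classification == POST))
    return pre, post, pre + post, tuple(entries)


def compute_global_function(curve_set: SegmentalCurveSet) -> tuple[float, float, float]:
    """EDV, ESV (ml) and EF (%) from the global time-volume curve.

    EDV is the maximum and ESV the minimum of the summed curve;
    EF = 100 × (EDV − ESV) / EDV.
    """
    g = global_curve(curve_set)
    edv = float(g.volumes.max())
    esv = float(g.volumes.min())
    if edv <= 0:
        raise DegenerateDataError(
            f"study {curve_set.study_id!r}: zero end-diastolic volume"
        )
    ef = 100.0 * (edv - esv) / edv
    return edv, esv, ef


def analyze_study(
    curve_set: SegmentalCurveSet,
    *,
    n_samples: int = DEFAULT_N_SAMPLES,
    sdi_divisor: str = "n_minus_1",
) -> DyssynchronyReport:
    """Full per-study analysis on one shared resampled grid.

    Resamples to ``n_samples`` uniform points, detects global and segmental
    end-systole, and computes EDV/ESV/EF, SDI, L-E and the STV family.
    """
    cs = resample_uniform(curve_set, n_samples)
    es = end_systole_table(cs)
    times16 = [es.es_times[n] for n in SEGMENT_NAMES]
    sdi = compute_sdi(times16, divisor=sdi_divisor)
    le = compute_le(times16)
    pre, post, total, entries = compute_stv(cs, es)
    edv, esv, ef = compute_global_function(cs)
    return DyssynchronyReport(
        study_id=cs.study_id,
        edv=edv,
        esv=esv,
        ef=ef,
        sdi=sdi,
        le=le,
        pre_stv=pre,
        post_stv=post,
        total_stv=total,
        entries=entries,
        es_table=es,
    )
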