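"""16-segment time-volume curve model for 3D-echo dyssynchrony analysis.

The left ventricle is divided into the standard 16 segments (6 basal, 6
mid-ventricular, 4 apical).  Each segment carries a cavity-volume trace over
one cardiac cycle: time is expressed as a percentage of the RR-interval
(0 %RR = QRS onset, 100 %RR = the next QRS) and volume in ml.  The global
time-volume curve is the pointwise sum of the 16 segmental curves, and global
end-systole is the moment of minimal total volume — which, under
dyssynchrony, need not coincide with any individual segment's minimum.

End-systole detection is a discrete argmin on the (optionally resampled)
grid, with ties broken toward the earliest time.  No sub-sample refinement is
applied; the analysis resolution is set by the resampling density (201
uniform points, i.e. 0.5 %RR, by default elsewhere in the package).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Canonical ASE 16-segment nomenclature, fixed order: 6 basal, 6 mid,
#: 4 apical.  This order defines the study CSV column layout.
SEGMENT_NAMES: tuple[str, ...] = (
    "basal_anterior",
    "basal_anteroseptal",
    "basal_inferoseptal",
    "basal_inferior",
    "basal_inferolateral",
    "basal_anterolateral",
    "mid_anterior",
    "mid_anteroseptal",
    "mid_inferoseptal",
    "mid_inferior",
    "mid_inferolateral",
    "mid_anterolateral",
    "apical_anterior",
    "apical_septal",
    "apical_lateral",
    "apical_inferior",
)

N_SEGMENTS = len(SEGMENT_NAMES)
GLOBAL_LABEL = "global"

#: Minimum number of samples accepted for any analysis grid.
MIN_SAMPLES = 8


@dataclass(frozen=True)
class TimeVolumeCurve:
    """One segment's (or the global) volume trace over one cardiac cycle.

    Parameters
    ----------
    times
        Sample times in %RR, strictly increasing, within [0, 100], length >= 3.
    volumes
        Cavity volumes in ml, same length as ``times``, non-negative.
    label
        Segment name, or ``"global"`` for the summed curve.
    """

    times: np.ndarray
    volumes: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValidationError(f"{self.label!r}: times and volumes must be 1-D")
        if t.size != v.size:
            raise ValidationError(
                f"{self.label!r}: times ({t.size}) and volumes ({v.size}) differ in length"
            )
        if t.size < 3:
            raise ValidationError(f"{self.label!r}: need at least 3 samples, got {t.size}")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValidationError(f"{self.label!r}: non-finite values in curve")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{self.label!r}: times must be strictly increasing")
        if t[0] < 0 or t[-1] > 100:
            raise ValidationError(
                f"{self.label!r}: times must lie within [0, 100] %RR, got [{t[0]}, {t[-1]}]"
            )
        if np.any(v < 0):
            raise ValidationError(f"{self.label!r}: volumes must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)

    def __len__(self) -> int:
        return self.times.size

    def resample(self, new_times: np.ndarray) -> "TimeVolumeCurve":
        """Linearly interpolate onto ``new_times``, clamping outside the
        original span (with a logged warning)."""
        new_times = np.asarray(new_times, dtype=float)
        if new_times[0] < self.times[0] or new_times[-1] > self.times[-1]:
            logger.warning(
                "curve %r spans [%g, %g] %%RR; values outside are held constant "
                "at the boundary during resampling",
                self.label, self.times[0], self.times[-1],
            )
        v = np.interp(new_times, self.times, self.volumes)
        return TimeVolumeCurve(new_times, v, self.label)


@dataclass(frozen=True)
class SegmentalCurveSet:
    """The 16 labelled segmental curves of one echo study on a shared grid.

    ``metadata`` is an opaque key-value store (may carry NYHA class, BNP,
    etc.); it is never used in any computation.
    """

    segments: Mapping[str, TimeVolumeCurve]
    study_id: str = ""
    rr_interval_ms: float | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = list(self.segments.keys())
        missing = [n for n in SEGMENT_NAMES if n not in keys]
        extra = [k for k in keys if k not in SEGMENT_NAMES]
        if missing or extra:
            msg = []
            if missing:
                msg.append(f"missing segments: {', '.join(missing)}")
            if extra:
                msg.append(f"unknown segments: {', '.join(extra)}")
            raise ValidationError(f"study {self.study_id!r}: " + "; ".join(msg))
        # canonical order, shared grid
        ordered = {n: self.segments[n] for n in SEGMENT_NAMES}
        ref = ordered[SEGMENT_NAMES[0]].times
        for name, curve in ordered.items():
            if not np.array_equal(curve.times, ref):
                raise ValidationError(
                    f"study {self.study_id!r}: segment {name!r} is not on the shared time grid"
                )
        if self.rr_interval_ms is not None and self.rr_interval_ms <= 0:
            raise ValidationError(
                f"study {self.study_id!r}: rr_interval_ms must be positive"
            )
        object.__setattr__(self, "segments", ordered)

    @property
    def times(self) -> np.ndarray:
        """The shared time grid, %RR."""
        return self.segments[SEGMENT_NAMES[0]].times

    def volume_matrix(self) -> np.ndarray:
        """(16, T) array of segmental volumes in canonical order."""
        return np.stack([self.segments[n].volumes for n in SEGMENT_NAMES])


@dataclass(frozen=True)
class EndSystoleTable:
    """Global and per-segment end-systolic times (%RR) and volumes (ml)."""

    global_es_time: float
    global_es_volume: float
    es_times: Mapping[str, float]
    es_volumes: Mapping[str, float]


def uniform_grid(n_samples: int) -> np.ndarray:
    """The uniform analysis grid 0, 100/(n-1), ..., 100 %RR."""
    if n_samples < MIN_SAMPLES:
        raise ValidationError(f"n_samples must be >= {MIN_SAMPLES}, got {n_samples}")
    return np.linspace(0.0, 100.0, int(n_samples))


def resample_uniform(curve_set: SegmentalCurveSet, n_samples: int) -> SegmentalCurveSet:
    """Resample every segmental curve onto a uniform grid spanning [0, 100] %RR.

    Linear interpolation; curves not spanning the full cycle are clamped at
    their boundary values (a warning is logged).  Resampling a set onto its
    own grid is the identity.
    """
    grid = uniform_grid(n_samples)
    if np.array_equal(curve_set.times, grid):
        return curve_set
    segments = {n: c.resample(grid) for n, c in curve_set.segments.items()}
    return SegmentalCurveSet(
        segments=segments,
        study_id=curve_set.study_id,
        rr_interval_ms=curve_set.rr_interval_ms,
        metadata=curve_set.metadata,
    )


def global_curve(curve_set: SegmentalCurveSet) -> TimeVolumeCurve:
    """Global LV time-volume curve: the pointwise sum of all 16 segments."""
    total = curve_set.volume_matrix().sum(axis=0)
    return TimeVolumeCurve(curve_set.times, total, GLOBAL_LABEL)


def find_end_systole(curve: TimeVolumeCurve) -> tuple[float, float]:
    """End-systole of one curve: the grid point of minimal volume.

    Ties are broken toward the earliest time.  Returns ``(time, volume)``.
    """
    i = int(np.argmin(curve.volumes))  # argmin returns the first minimum
    return float(curve.times[i]), float(curve.volumes[i])


def end_systole_table(curve_set: SegmentalCurveSet) -> EndSystoleTable:
    """Global and segmental end-systole for one study.

    The global end-systole is computed on the summed curve; each segment
    reaches its own minimal volume at its own time.
    """
    g_time, g_vol = find_end_systole(global_curve(curve_set))
    es_times: dict[str, float] = {}
    es_volumes: dict[str, float] = {}
    for name in SEGMENT_NAMES:
        t, v = find_end_systole(curve_set.segments[name])
        es_times[name] = t
        es_volumes[name] = v
    return EndSystoleTable(g_time, g_vol, es_times, es_volumes)
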