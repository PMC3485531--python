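"""Synthetic 16-segment time-volume curves and CRT cohorts.

Emulates the output of semi-automated 3D-echo endocardial border detection:
16 smooth per-segment volume traces over one cardiac cycle, each

    V(t) = v_min + amplitude * w((t - delay) mod 100) + noise,   clipped at 0,

where ``w`` is a smooth unimodal waveform with minimum 0 at the study's
reference end-systolic time and value 1 at t = 0 (and t = 100, so the
circular delay shift stays continuous across the cycle boundary).  The
``amplitude`` (= V_max − V_min) is the segment's volume excursion and serves
as the contractility surrogate; ``delay`` shifts the segmental end-systole.
Two waveforms are provided: a piecewise raised cosine (default) and an
asymmetric-systole variant with a faster volume descent than rise.

The two phenotypes that motivate STV are both expressible:

* delayed segment with preserved inward motion — large delay, normal
  amplitude (contributes strongly to Pre-/Post-STV *and* to SDI / L-E);
* delayed hypokinetic segment — large delay, small amplitude (contributes
  to SDI / L-E but almost nothing to STV).

The cohort generator builds paired baseline / follow-up studies for a CRT
population of responders and non-responders, with group-level baseline
distributions (EDV, EF, Pre-STV target) and a follow-up effect model
(responder ESV-reduction distribution, non-responder ESV drift, and a delay
homogenization factor for the resynchronized responders).  Per-patient
amplitudes of the delayed segments are calibrated — by analysing a noiseless
prototype of the study — so that the achieved baseline Pre-STV matches the
drawn group target.  Ground-truth labels, delays and amplitudes are stored
with every patient.

Additive Gaussian noise is independent per sample and per segment (no
temporal autocorrelation — a documented simplification).  All randomness
derives from a single root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .curves import (
    N_SEGMENTS,
    SEGMENT_NAMES,
    SegmentalCurveSet,
    TimeVolumeCurve,
    uniform_grid,
)
from .errors import ValidationError
from .metrics import DEFAULT_N_SAMPLES, analyze_study

RAISED_COSINE = "raised_cosine"
ASYMMETRIC = "asymmetric_systole"

#: Relative weight of basal / mid / apical segments when distributing
#: ventricular volume; basal segments are the largest, so they dominate STV.
_LEVEL_WEIGHT = {"basal": 1.4, "mid": 1.0, "apical": 0.65}


def _segment_weights() -> np.ndarray:
    w = np.array([_LEVEL_WEIGHT[n.split("_", 1)[0]] for n in SEGMENT_NAMES])
    return w / w.sum()


def waveform(t, t_es: float, kind: str = RAISED_COSINE) -> np.ndarray:
    """Unimodal cycle waveform: w(0) = w(100) = 1, w(t_es) = 0.

    ``raised_cosine``: half-cosine descent on [0, t_es], half-cosine rise on
    [t_es, 100].  ``asymmetric_systole``: the descent is squared (cos^4
    shape), giving a faster early volume loss for the same end-systolic time.
    """
    t = np.asarray(t, dtype=float)
    if not 0.0 < t_es < 100.0:
        raise ValidationError(f"reference end-systolic time must be in (0, 100), got {t_es}")
    down = 0.5 * (1.0 + np.cos(np.pi * np.clip(t, 0.0, t_es) / t_es))
    up = 0.5 * (1.0 - np.cos(np.pi * (np.clip(t, t_es, 100.0) - t_es) / (100.0 - t_es)))
    if kind == RAISED_COSINE:
        pass
    elif kind == ASYMMETRIC:
        down = down * down
    else:
        raise ValidationError(f"unknown waveform {kind!r}")
    return np.where(t <= t_es, down, up)


@dataclass(frozen=True)
class SegmentParams:
    """Generative parameters of one segmental curve."""

    v_min: float
    amplitude: float
    delay: float = 0.0
    waveform: str = RAISED_COSINE
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.v_min <= 0:
            raise ValidationError(f"v_min must be positive, got {self.v_min}")
        if self.amplitude < 0:
            raise ValidationError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class StudyParams:
    """Parameters of one synthetic echo study (16 segments, shared grid)."""

    segments: tuple[SegmentParams, ...]
    reference_es_time: float = 40.0
    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = 0
    study_id: str = ""

    def __post_init__(self) -> None:
        if len(self.segments) != N_SEGMENTS:
            raise ValidationError(
                f"need {N_SEGMENTS} SegmentParams, got {len(self.segments)}"
            )


def make_segment_curve(
    params: SegmentParams,
    grid: np.ndarray,
    reference_es_time: float,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> TimeVolumeCurve:
    """One segmental curve on ``grid``; the minimum falls at
    ``reference_es_time + delay`` (mod 100) up to grid resolution."""
    grid = np.asarray(grid, dtype=float)
    if grid.size < 8:
        raise ValidationError(f"grid must have >= 8 points, got {grid.size}")
    phase = np.mod(grid - params.delay, 100.0)
    v = params.v_min + params.amplitude * waveform(phase, reference_es_time, params.waveform)
    if params.noise_sd > 0:
        if rng is None:
            raise ValidationError("noise requested but no random generator supplied")
        v = v + rng.normal(0.0, params.noise_sd, size=grid.size)
    v = np.clip(v, 0.0, None)
    return TimeVolumeCurve(grid, v, label)


def make_study(params: StudyParams) -> SegmentalCurveSet:
    """Deterministic (given seed) 16-segment study from explicit parameters."""
    grid = uniform_grid(params.n_samples)
    rng = np.random.default_rng(params.seed)
    segments = {
        name: make_segment_curve(sp, grid, params.reference_es_time, rng, label=name)
        for name, sp in zip(SEGMENT_NAMES, params.segments)
    }
    return SegmentalCurveSet(
        segments=segments,
        study_id=params.study_id or f"synthetic-{params.seed}",
        metadata={"seed": params.seed, "reference_es_time": params.reference_es_time},
    )


def synchronous_study(
    *,
    v_min: float = 8.0,
    amplitude: float = 2.5,
    reference_es_time: float = 40.0,
    n_samples: int = DEFAULT_N_SAMPLES,
    waveform_kind: str = RAISED_COSINE,
    seed: int = 0,
) -> StudyParams:
    """Convenience: a fully synchronous noiseless ventricle (equal segments)."""
    seg = SegmentParams(v_min=v_min, amplitude=amplitude, waveform=waveform_kind)
    return StudyParams(
        segments=(seg,) * N_SEGMENTS,
        reference_es_time=reference_es_time,
        n_samples=n_samples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class Dist:
    """A (possibly truncated) scalar distribution for cohort parameters.

    ``family="truncated_normal"`` (default) truncates a normal at
    [lower, upper]; ``family="log_normal"`` moment-matches a log-normal to
    (mean, sd) — provided because strongly right-skewed group distributions
    (SD comparable to or exceeding the mean) are poorly captured by a
    truncated normal.
    """

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf
    family: str = "truncated_normal"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")
        if self.lower >= self.upper:
            raise ValidationError(
                f"empty support: lower {self.lower} >= upper {self.upper}"
            )
        if self.family not in ("truncated_normal", "log_normal"):
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.family == "log_normal" and self.mean <= 0:
            raise ValidationError("log_normal requires a positive mean")

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.sd == 0:
            x = np.full(size or 1, self.mean)
        elif self.family == "truncated_normal":
            # rejection sampling; the cohort defaults keep the accepted mass large
            n = size or 1
            out = np.empty(n)
            filled = 0
            while filled < n:
                draw = rng.normal(self.mean, self.sd, size=2 * (n - filled) + 8)
                ok = draw[(draw >= self.lower) & (draw <= self.upper)]
                take = min(ok.size, n - filled)
                out[filled : filled + take] = ok[:take]
                filled += take
            x = out
        else:
            s2 = math.log1p((self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - s2 / 2.0
            x = rng.lognormal(mu, math.sqrt(s2), size=size or 1)
            x = np.clip(x, self.lower, self.upper)
        return x if size is not None else float(x[0])


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroupProfile:
    """Baseline and follow-up distributions for one response group."""

    n: int
    edv: Dist
    ef_pct: Dist
    pre_stv_target: Dist
    n_delayed: tuple[int, int]  # inclusive range of delayed-segment count
    delay_magnitude: tuple[float, float]  # %RR range of |delay|
    early_fraction: float  # probability a delayed segment contracts early
    hypokinetic_fraction: float  # fraction of delayed segments that are hypokinetic
    esv_change_pct: Dist  # follow-up ESV change, % (negative = reduction)
    timing_jitter_sd: float = 1.5  # %RR small random delay on every segment


def default_responder_profile(n: int = 20) -> GroupProfile:
    """Responders: dyssynchrony carried by normokinetic segments, large
    baseline Pre-STV, substantial reverse remodelling at follow-up."""
    return GroupProfile(
        n=n,
        edv=Dist(195.0, 45.0, lower=90.0),
        ef_pct=Dist(19.0, 8.0, lower=5.0, upper=38.0),
        pre_stv_target=Dist(51.4, 51.2, lower=2.0),
        n_delayed=(4, 7),
        delay_magnitude=(12.0, 28.0),
        early_fraction=0.5,
        hypokinetic_fraction=0.1,
        esv_change_pct=Dist(-22.0, 7.0, upper=-13.0),
    )


def default_non_responder_profile(n: int = 8) -> GroupProfile:
    """Non-responders: comparable timing dispersion but concentrated in
    hypokinetic segments, hence little Pre-STV; no remodelling at follow-up."""
    return GroupProfile(
        n=n,
        edv=Dist(176.0, 60.0, lower=90.0),
        ef_pct=Dist(20.0, 11.0, lower=5.0, upper=38.0),
        pre_stv_target=Dist(5.2, 6.8, lower=0.3),
        n_delayed=(2, 4),
        delay_magnitude=(8.0, 18.0),
        early_fraction=0.75,
        hypokinetic_fraction=0.9,
        esv_change_pct=Dist(3.0, 5.0, lower=-5.0),
    )


@dataclass(frozen=True)
class CohortParams:
    """Parameters of a synthetic CRT cohort (baseline + follow-up)."""

    responders: GroupProfile = field(default_factory=default_responder_profile)
    non_responders: GroupProfile = field(default_factory=default_non_responder_profile)
    crt_homogenization: float = 0.85  # fraction by which responder delays shrink
    hypokinetic_amp_factor: float = 0.15
    reference_es_time: float = 40.0
    n_samples: int = DEFAULT_N_SAMPLES
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crt_homogenization <= 1.0:
            raise ValidationError("crt_homogenization must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticPatient:
    """One generated patient: curve sets plus generator ground truth."""

    patient_id: str
    true_responder: bool
    baseline: SegmentalCurveSet
    followup: SegmentalCurveSet
    truth: dict


def _patient_params(
    profile: GroupProfile, cohort: CohortParams, rng: np.random.Generator
) -> tuple[list[SegmentParams], np.ndarray]:
    """Draw baseline segment parameters for one patient (before calibration)."""
    weights = _segment_weights()
    edv = profile.edv.sample(rng)
    ef = profile.ef_pct.sample(rng)
    esv = edv * (1.0 - ef / 100.0)
    jitter = rng.lognormal(0.0, 0.15, size=N_SEGMENTS)
    v_min = esv * weights * jitter / (weights * jitter).sum()
    jitter_a = rng.lognormal(0.0, 0.2, size=N_SEGMENTS)
    amp = (edv - esv) * weights * jitter_a / (weights * jitter_a).sum()

    n_delayed = int(rng.integers(profile.n_delayed[0], profile.n_delayed[1] + 1))
    # dyssynchrony preferentially involves the high-volume basal/mid walls
    delayed_idx = rng.choice(N_SEGMENTS, size=n_delayed, replace=False, p=weights)
    # every segment carries a small timing jitter; delayed segments add a
    # large shift on top
    delays = rng.normal(0.0, profile.timing_jitter_sd, size=N_SEGMENTS)
    delays = np.clip(delays, -3.0 * profile.timing_jitter_sd, 3.0 * profile.timing_jitter_sd)
    # per-patient severity: real cohorts spread widely around the group mean
    severity = rng.lognormal(0.0, 0.3)
    lo, hi = (severity * d for d in profile.delay_magnitude)
    # a fixed fraction of the delayed segments contracts early, the rest
    # late — the late, strong group holds the global minimum late, which is
    # what lets the early group accumulate pre-systolic volume loss
    n_early = int(round(profile.early_fraction * n_delayed))
    signs = np.r_[-np.ones(n_early), np.ones(n_delayed - n_early)]
    rng.shuffle(signs)
    for i, sign in zip(delayed_idx, signs):
        mag = rng.uniform(lo, hi)
        # keep segmental minima inside the cycle (no wrap across end-diastole)
        d = sign * mag
        d = float(np.clip(d, 4.0 - cohort.reference_es_time, 96.0 - cohort.reference_es_time))
        delays[i] = d
        if rng.random() < profile.hypokinetic_fraction:
            amp[i] *= cohort.hypokinetic_amp_factor
    params = [
        SegmentParams(
            v_min=float(v_min[k]),
            amplitude=float(amp[k]),
            delay=float(delays[k]),
            noise_sd=cohort.noise_sd,
        )
        for k in range(N_SEGMENTS)
    ]
    return params, delayed_idx


def _noiseless(params: Sequence[SegmentParams]) -> tuple[SegmentParams, ...]:
    return tuple(replace(p, noise_sd=0.0) for p in params)


def _study(params, cohort: CohortParams, seed: int, study_id: str) -> SegmentalCurveSet:
    return make_study(
        StudyParams(
            segments=tuple(params),
            reference_es_time=cohort.reference_es_time,
            n_samples=cohort.n_samples,
            seed=seed,
            study_id=study_id,
        )
    )


def _calibrate_pre_stv(
    params: list[SegmentParams],
    delayed_idx: np.ndarray,
    target: float,
    cohort: CohortParams,
) -> list[SegmentParams]:
    """Scale all delayed segments' amplitudes so that the noiseless study's
    Pre-STV approaches ``target``.

    Scaling only the early segments would be self-defeating: the global
    minimum follows the volume, so boosting the early group drags global
    end-systole toward it and the pre-systolic areas collapse.  Scaling the
    whole delayed group instead keeps the late, strong segments holding the
    global minimum late while the early group supplies the area, so Pre-STV
    grows roughly linearly in the factor.  Three measured passes with
    progressively tighter clamps absorb the residual nonlinearity from the
    drifting global end-systole."""
    for clamp in ((0.25, 6.0), (0.5, 2.0), (0.7, 1.4)):
        rep = analyze_study(
            _study(_noiseless(params), cohort, seed=0, study_id="calib"),
            n_samples=cohort.n_samples,
        )
        f = float(np.clip(target / max(rep.pre_stv, 1e-3), *clamp))
        params = [
            replace(p, amplitude=p.amplitude * f) if k in delayed_idx else p
            for k, p in enumerate(params)
        ]
    return params


def make_cohort(params: CohortParams) -> list[SyntheticPatient]:
    """Generate a full baseline + follow-up CRT cohort.

    Responders' follow-up studies have their delays shrunk by the CRT
    homogenization factor and their ESV scaled to the drawn reduction;
    non-responders keep their baseline activation pattern and drift in ESV
    per their effect distribution.  Measured ESVs (and hence the responder
    labels recovered by :func:`dyssync.cohort.classify_response`) track the
    drawn changes up to the small measurement noise.
    """
    patients: list[SyntheticPatient] = []
    groups = (
        ("R", True, params.responders),
        ("N", False, params.non_responders),
    )
    idx = 0
    for tag, is_resp, profile in groups:
        for j in range(profile.n):
            rng = np.random.default_rng(np.random.SeedSequence([params.seed, idx]))
            seg_params, delayed_idx = _patient_params(profile, params, rng)
            target = profile.pre_stv_target.sample(rng)
            seg_params = _calibrate_pre_stv(seg_params, delayed_idx, target, params)

            pid = f"{tag}{j + 1:03d}"
            base_seed = int(rng.integers(0, 2**31 - 1))
            baseline = _study(seg_params, params, base_seed, f"{pid}-baseline")
            base_nl = analyze_study(
                _study(_noiseless(seg_params), params, 0, "nl"),
                n_samples=params.n_samples,
            )

            # follow-up: homogenize responder delays, then scale volumes to
            # the drawn ESV change
            delta = profile.esv_change_pct.sample(rng)
            fu_params = list(seg_params)
            if is_resp:
                shrink = 1.0 - params.crt_homogenization
                fu_params = [replace(p, delay=p.delay * shrink) for p in fu_params]
            fu_nl = analyze_study(
                _study(_noiseless(fu_params), params, 0, "nl"),
                n_samples=params.n_samples,
            )
            esv_target = base_nl.esv * (1.0 + delta / 100.0)
            scale = esv_target / fu_nl.esv
            fu_params = [
                replace(p, v_min=p.v_min * scale, amplitude=p.amplitude * scale)
                for p in fu_params
            ]
            fu_seed = int(rng.integers(0, 2**31 - 1))
            followup = _study(fu_params, params, fu_seed, f"{pid}-followup")

            patients.append(
                SyntheticPatient(
                    patient_id=pid,
                    true_responder=is_resp,
                    baseline=baseline,
                    followup=followup,
                    truth={
                        "delays": [p.delay for p in seg_params],
                        "amplitudes": [p.amplitude for p in seg_params],
                        "delayed_segments": [SEGMENT_NAMES[k] for k in delayed_idx],
                        "pre_stv_target": target,
                        "esv_change_pct": delta,
                        "baseline_seed": base_seed,
                        "followup_seed": fu_seed,
                    },
                )
            )
            idx += 1
    return patients
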