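"""Cohort-level evaluation: response classification, ROC, group statistics.

A patient *responds* to cardiac resynchronisation therapy when the
end-systolic volume at follow-up is reduced by at least 10% relative to
baseline.  Baseline dyssynchrony metrics are then evaluated as predictors of
response:

* empirical ROC curve and trapezoidal AUC (equal to the Mann-Whitney
  statistic with ties counted 1/2), 95% CI by the Hanley-McNeil formula;
* an optimal cutoff by the Youden index (J = sensitivity + specificity − 1),
  with sensitivity / specificity / NPV / PPV from the resulting 2×2 table;
* paired comparison of two correlated AUCs by the DeLong test;
* Pearson correlation of each metric with reverse remodelling (Δ-ESV);
* responder vs non-responder group comparison by Student's t-test (pooled
  variance; Welch available), paired t-tests baseline vs follow-up;
* inter-/intra-observer reproducibility by Bland-Altman analysis.

Percentages are reported on the 0-100 scale.  The positive-test direction
is configurable per metric and is never silently auto-flipped: a metric
whose high values predict non-response simply yields AUC < 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .metrics import DyssynchronyReport

logger = logging.getLogger(__name__)

HIGHER = "higher_is_positive"
LOWER = "lower_is_positive"

#: Baseline metrics evaluated as predictors of response, with the default
#: positive-test direction (higher values predict response for all four).
DEFAULT_METRICS: tuple[str, ...] = ("pre_stv", "post_stv", "sdi", "le")
DEFAULT_DIRECTIONS: Mapping[str, str] = {m: HIGHER for m in DEFAULT_METRICS}

#: Relative ESV reduction (in %) defining response.
RESPONSE_THRESHOLD_PCT = 10.0


# ---------------------------------------------------------------------------
# patient records


@dataclass
class PatientRecord:
    """Baseline (and optionally follow-up) analysis of one patient."""

    patient_id: str
    baseline: DyssynchronyReport
    followup: DyssynchronyReport | None = None
    delta_esv_pct: float | None = None
    responder: bool | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def from_reports(
        cls,
        patient_id: str,
        baseline: DyssynchronyReport,
        followup: DyssynchronyReport | None = None,
        metadata: Mapping[str, object] | None = None,
    ) -> "PatientRecord":
        delta = responder = None
        if followup is not None:
            responder, delta = classify_response(baseline.esv, followup.esv)
        return cls(patient_id, baseline, followup, delta, responder, metadata or {})


def classify_response(esv_base: float, esv_fu: float) -> tuple[bool, float]:
    """Responder flag and Δ-ESV (%) from baseline and follow-up ESV.

    Δ-ESV = 100 × (ESV_fu − ESV_base) / ESV_base (negative = reduction);
    a reduction of exactly 10% counts as response (inclusive threshold).
    """
    if esv_base <= 0:
        raise ValidationError(f"baseline ESV must be positive, got {esv_base}")
    delta = 100.0 * (esv_fu - esv_base) / esv_base
    return delta <= -RESPONSE_THRESHOLD_PCT, float(delta)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flat cohort table: one row per patient, baseline/follow-up metrics."""
    cols = ("edv", "esv", "ef", "sdi", "le", "pre_stv", "post_stv", "total_stv")
    rows = []
    for r in records:
        row: dict[str, object] = {"patient_id": r.patient_id}
        for c in cols:
            row[f"baseline_{c}"] = getattr(r.baseline, c)
        for c in cols:
            row[f"followup_{c}"] = getattr(r.followup, c) if r.followup else np.nan
        row["delta_esv_pct"] = np.nan if r.delta_esv_pct is None else r.delta_esv_pct
        row["responder"] = r.responder
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with trapezoidal AUC and Hanley-McNeil 95% CI."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # score cutoffs in original units, one per ROC step
    auc: float
    auc_ci_95: tuple[float, float]
    direction: str
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffStats:
    """2×2-table statistics at a chosen cutoff; percentages 0-100."""

    cutoff: float
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    tp: int
    fp: int
    tn: int
    fn: int


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and equal length")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    if y.all() or not y.any():
        raise DegenerateDataError(
            "ROC analysis needs at least one responder and one non-responder; "
            "the supplied cohort contains a single class"
        )
    return s, y


def roc_curve(scores, labels, direction: str = HIGHER) -> RocResult:
    """Empirical ROC over all distinct score thresholds.

    AUC is the trapezoidal area, identical to the Mann-Whitney concordance
    probability with tied pairs counted 1/2.
    """
    s, y = _split_scores(scores, labels)
    if direction not in (HIGHER, LOWER):
        raise ValidationError(f"unknown direction {direction!r}")
    x = s if direction == HIGHER else -s
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    order = np.argsort(-x, kind="stable")
    xs, ys = x[order], y[order]
    # last index of each tie group of distinct threshold values
    last = np.r_[np.diff(xs) != 0, True]
    tp = np.cumsum(ys)[last]
    fp = np.cumsum(~ys)[last]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = xs[last] if direction == HIGHER else -xs[last]
    auc = float(np.trapezoid(tpr, fpr))
    ci = hanley_mcneil_ci(auc, n_pos, n_neg)
    return RocResult(fpr, tpr, thresholds, auc, ci, direction, n_pos, n_neg)


def hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """95% CI for an AUC by the Hanley-McNeil standard-error formula."""
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se))


def optimal_cutoff(roc: RocResult, scores, labels) -> CutoffStats:
    """Youden-index cutoff and its 2×2-table statistics.

    The positive test is score >= cutoff (direction ``higher_is_positive``)
    or score <= cutoff (``lower_is_positive``).  Ties in the Youden index are
    broken toward higher sensitivity.  NPV/PPV are NaN when their denominator
    is empty (degenerate all-positive / all-negative cutoffs).
    """
    s, y = _split_scores(scores, labels)
    n_pos, n_neg = roc.n_pos, roc.n_neg
    best = None  # (J, sens, idx)
    for k, thr in enumerate(roc.thresholds):
        sens = roc.tpr[k + 1]
        spec = 1.0 - roc.fpr[k + 1]
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and sens > best[1]):
            best = (j, sens, k)
    _, _, k = best
    cutoff = float(roc.thresholds[k])
    tp = int(round(roc.tpr[k + 1] * n_pos))
    fp = int(round(roc.fpr[k + 1] * n_neg))
    fn = n_pos - tp
    tn = n_neg - fp
    sens = 100.0 * tp / n_pos
    spec = 100.0 * tn / n_neg
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) else float("nan")
    npv = 100.0 * tn / (tn + fn) if (tn + fn) else float("nan")
    return CutoffStats(cutoff, sens, spec, npv, ppv, tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison


def _placements(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-observation placement values (midrank construction)."""
    pos, neg = x[y], x[~y]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.r_[pos, neg], method="average")
    pos_ranks = stats.rankdata(pos, method="average")
    neg_ranks = stats.rankdata(neg, method="average")
    v10 = (all_ranks[:m] - pos_ranks) / n  # P(neg < pos_i), ties 1/2
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def compare_auc_paired(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong p-value for the difference of two correlated AUCs.

    Both score vectors must be measured on the same patients (paired design).
    Identical score vectors give p = 1.0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired AUC comparison requires equal-length score vectors")
    _, y = _split_scores(a, labels)
    auc_a, v10_a, v01_a = _placements(a, y)
    auc_b, v10_b, v01_b = _placements(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 1e-15:
        return 1.0 if abs(diff) <= 1e-15 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Bland-Altman reproducibility


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two observers: bias ± 1.96·SD limits of agreement."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int
    means: np.ndarray  # per-pair average of the two observations
    diffs: np.ndarray  # per-pair difference obs1 - obs2


def bland_altman(obs1, obs2) -> BlandAltmanResult:
    """Bland-Altman analysis of paired observations (obs1 − obs2).

    Bias is the mean difference; limits of agreement are bias ± 1.96 times
    the sample SD of the differences.
    """
    a = np.asarray(obs1, dtype=float)
    b = np.asarray(obs2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("observer vectors must be 1-D and equal length")
    if a.size < 2:
        raise ValidationError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=a.size,
        means=(a + b) / 2.0,
        diffs=d,
    )


# ---------------------------------------------------------------------------
# group comparison & correlation


@dataclass(frozen=True)
class GroupComparison:
    """Responder vs non-responder group statistics for one metric.

    Means ± sample SD at baseline and follow-up per group; unpaired
    between-group p-values and paired baseline-vs-follow-up p-values
    (two-sided).  Statistics whose group is too small are NaN.
    """

    metric: str
    n_responders: int
    n_non_responders: int
    responders_baseline: tuple[float, float]  # (mean, sd)
    non_responders_baseline: tuple[float, float]
    responders_followup: tuple[float, float]
    non_responders_followup: tuple[float, float]
    p_between_baseline: float
    p_between_followup: float
    p_paired_responders: float
    p_paired_non_responders: float
    p_paired_all: float


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return float("nan"), float("nan")
    return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else float("nan")


def _unpaired_p(x: np.ndarray, y: np.ndarray, t_test: str) -> float:
    if x.size < 2 or y.size < 2:
        logger.warning("group size < 2; unpaired t-test suppressed")
        return float("nan")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=(t_test == "student"))
    return float(res.pvalue)


def _paired_p(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        logger.warning("group size < 2; paired t-test suppressed")
        return float("nan")
    d = x - y
    if d.std(ddof=1) == 0:
        return 1.0 if d.mean() == 0 else 0.0
    return float(stats.ttest_rel(x, y).pvalue)


def group_compare(
    records: Sequence[PatientRecord],
    metric: str,
    *,
    t_test: str = "student",
) -> GroupComparison:
    """Responder vs non-responder comparison of one metric.

    Unpaired two-sample t-test between groups (Student's pooled-variance by
    default, Welch via ``t_test="welch"``); paired t-test baseline vs
    follow-up within each group and over all patients.
    """
    if t_test not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {t_test!r}")
    labelled = [r for r in records if r.responder is not None]
    if not labelled:
        raise DegenerateDataError("no patients with follow-up / responder status")
    resp = [r for r in labelled if r.responder]
    non = [r for r in labelled if not r.responder]

    def vals(group, phase):
        return np.array(
            [getattr(getattr(r, phase), metric) for r in group if getattr(r, phase) is not None],
            dtype=float,
        )

    rb, nb = vals(resp, "baseline"), vals(non, "baseline")
    rf, nf = vals(resp, "followup"), vals(non, "followup")
    ab, af = vals(labelled, "baseline"), vals(labelled, "followup")
    return GroupComparison(
        metric=metric,
        n_responders=len(resp),
        n_non_responders=len(non),
        responders_baseline=_mean_sd(rb),
        non_responders_baseline=_mean_sd(nb),
        responders_followup=_mean_sd(rf),
        non_responders_followup=_mean_sd(nf),
        p_between_baseline=_unpaired_p(rb, nb, t_test),
        p_between_followup=_unpaired_p(rf, nf, t_test),
        p_paired_responders=_paired_p(vals(resp, "baseline"), rf) if rf.size == len(resp) else float("nan"),
        p_paired_non_responders=_paired_p(vals(non, "baseline"), nf) if nf.size == len(non) else float("nan"),
        p_paired_all=_paired_p(ab, af) if af.size == len(labelled) else float("nan"),
    )


def correlate_remodelling(scores, delta_esv_pct) -> tuple[float, float]:
    """Pearson correlation between a baseline metric and Δ-ESV.

    Returns (r, two-sided p) via the t-transform with n−2 degrees of
    freedom.  Rejects n < 3 and zero-variance inputs.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(delta_esv_pct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("scores and delta_esv_pct must be 1-D and equal length")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# whole-cohort evaluation


def evaluate_cohort(
    records: Sequence[PatientRecord],
    *,
    metrics: Sequence[str] = DEFAULT_METRICS,
    directions: Mapping[str, str] | None = None,
    t_test: str = "student",
) -> dict:
    """Full predictive-value evaluation of baseline metrics against response.

    For each metric: ROC (AUC + 95% CI), Youden cutoff with sensitivity /
    specificity / NPV / PPV, correlation with Δ-ESV, and responder vs
    non-responder group comparison.  Returns a nested dict of result
    objects keyed by metric name.
    """
    frame = records_to_frame(records)
    return evaluate_cohort_frame(
        frame, records=records, metrics=metrics, directions=directions, t_test=t_test
    )


def evaluate_cohort_frame(
    frame: pd.DataFrame,
    *,
    records: Sequence[PatientRecord] | None = None,
    metrics: Sequence[str] = DEFAULT_METRICS,
    directions: Mapping[str, str] | None = None,
    t_test: str = "student",
) -> dict:
    """Cohort evaluation from the flat per-patient table (see
    :func:`records_to_frame` for the column layout)."""
    directions = dict(DEFAULT_DIRECTIONS) | dict(directions or {})
    labelled = frame.dropna(subset=["responder"])
    labels = labelled["responder"].astype(bool).to_numpy()
    delta = labelled["delta_esv_pct"].to_numpy(dtype=float)
    out: dict[str, dict] = {}
    for m in metrics:
        scores = labelled[f"baseline_{m}"].to_numpy(dtype=float)
        direction = directions.get(m, HIGHER)
        roc = roc_curve(scores, labels, direction)
        cut = optimal_cutoff(roc, scores, labels)
        r, p = correlate_remodelling(scores, delta)
        entry: dict[str, object] = {
            "roc": roc,
            "cutoff": cut,
            "correlation_r": r,
            "correlation_p": p,
        }
        if records is not None:
            entry["groups"] = group_compare(records, m, t_test=t_test)
        out[m] = entry
    return out


def evaluation_to_dict(evaluation: Mapping[str, Mapping[str, object]]) -> dict:
    """JSON-ready rendering of :func:`evaluate_cohort` output.

    Percentages are rounded to one decimal; 2×2 counts are retained for
    auditability.
    """
    out = {}
    for m, e in evaluation.items():
        roc: RocResult = e["roc"]  # type: ignore[assignment]
        cut: CutoffStats = e["cutoff"]  # type: ignore[assignment]
        d = {
            "auc": roc.auc,
            "auc_ci_95": list(roc.auc_ci_95),
            "direction": roc.direction,
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
            "cutoff": cut.cutoff,
            "sensitivity_pct": round(cut.sensitivity, 1),
            "specificity_pct": round(cut.specificity, 1),
            "npv_pct": round(cut.npv, 1) if np.isfinite(cut.npv) else None,
            "ppv_pct": round(cut.ppv, 1) if np.isfinite(cut.ppv) else None,
            "table_2x2": {"tp": cut.tp, "fp": cut.fp, "tn": cut.tn, "fn": cut.fn},
            "correlation_r": e["correlation_r"],
            "correlation_p": e["correlation_p"],
        }
        g = e.get("groups")
        if g is not None:
            d["groups"] = {
                "n_responders": g.n_responders,
                "n_non_responders": g.n_non_responders,
                "responders_baseline_mean_sd": list(g.responders_baseline),
                "non_responders_baseline_mean_sd": list(g.non_responders_baseline),
                "responders_followup_mean_sd": list(g.responders_followup),
                "non_responders_followup_mean_sd": list(g.non_responders_followup),
                "p_between_baseline": g.p_between_baseline,
                "p_between_followup": g.p_between_followup,
                "p_paired_responders": g.p_paired_responders,
                "p_paired_non_responders": g.p_paired_non_responders,
                "p_paired_all": g.p_paired_all,
            }
        out[m] = d
    return out
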