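"""Prospective-validation analytics for the CoAo score.

Everything needed to evaluate a probabilistic predictor of postnatal
coarctation on a labelled cohort: the empirical ROC curve with a
Mann–Whitney AUC and a DeLong 95% CI, operating-point selection (Youden
best balance, maximum sensitivity, maximum specificity), 2×2 diagnostic
metrics with Wilson score intervals, early/late-onset subgrouping,
probability-band summaries, and the standard two-group comparisons
(Welch t / Mann–Whitney for continuous variables, chi-square / Fisher for
categorical ones, chosen by a Shapiro–Wilk normality screen and the
expected-cell-count rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import expected_freq
from statsmodels.stats.proportion import proportion_confint

from .score import (
    FetalEchoExam,
    ScoringModel,
    cardiac_ratios,
    default_model,
    score_exam,
)
from .zscores import CardiacStructure, ZScoreReference, attach_zscores

__all__ = [
    "CohortRecord",
    "RocAnalysis",
    "MetricEstimate",
    "DiagnosticMetrics",
    "CutoffCriterion",
    "CutoffReport",
    "GroupComparison",
    "GroupStats",
    "Band",
    "BandAnalysis",
    "SingleClassError",
    "InsufficientDataError",
    "empirical_roc",
    "roc_from_scores",
    "select_cutoff",
    "diagnostic_metrics",
    "wilson_ci",
    "split_by_onset",
    "probability_bands",
    "compare_groups",
    "summarize_probabilities",
    "proportion_percent",
    "score_records",
]


class SingleClassError(ValueError):
    """Both outcome classes are required for a ROC analysis."""


class InsufficientDataError(ValueError):
    """Too few usable observations for the requested comparison."""


@dataclass(frozen=True)
class CohortRecord:
    """One fetus: exam, predicted CoAo probability, and postnatal outcome."""

    record_id: str
    exam: FetalEchoExam
    predicted_probability: float
    outcome_coao: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.predicted_probability < 1.0:
            raise ValueError("predicted_probability must lie in (0, 1)")

    @property
    def onset_group(self) -> str:
        """'early' for asymmetry diagnosed at <=28 weeks, else 'late'."""
        return "early" if self.exam.ga_weeks <= 28.0 else "late"


def proportion_percent(k: int, n: int, decimals: int = 1) -> float:
    """Display percentage for a count fraction, rounded half-to-even."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("count must lie in [0, n]")
    return round(100.0 * k / n, decimals)


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score 95% (by default) interval for a binomial proportion."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return (float(max(0.0, lo)), float(min(1.0, hi)))


# --------------------------------------------------------------------------
# ROC / AUC / DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), ties sharing the average rank."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _auc_delong(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney AUC (ties count 1/2) and its DeLong standard error."""
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m  # over negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s01 / m + s10 / n)
    return float(auc), float(se)


@dataclass(frozen=True)
class RocAnalysis:
    """Empirical ROC over the attained score values ('>= threshold' positive)."""

    thresholds: tuple[float, ...]  # ascending, distinct attained scores
    points: tuple[tuple[float, float], ...]  # (sensitivity, specificity)
    auc: float
    auc_ci: tuple[float, float]
    n_positive: int
    n_negative: int

    @property
    def auc_trapezoid(self) -> float:
        """AUC by trapezoidal integration of the empirical curve."""
        # sweep thresholds descending; start at (fpr, tpr) = (0, 0)
        fpr = [0.0] + [1.0 - sp for sn, sp in reversed(self.points)]
        tpr = [0.0] + [sn for sn, sp in reversed(self.points)]
        return float(np.trapezoid(tpr, fpr))


def _scores_labels(records: Sequence[CohortRecord]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([r.predicted_probability for r in records], dtype=float)
    labels = np.array([bool(r.outcome_coao) for r in records], dtype=bool)
    for r in records:
        if r.outcome_coao is None:
            raise ValueError(f"record {r.record_id!r} lacks an outcome label")
    return scores, labels


def roc_from_scores(scores, labels) -> RocAnalysis:
    """ROC analysis from raw score and boolean-outcome arrays."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise SingleClassError("both outcome classes are required for a ROC curve")
    pos = scores[labels]
    neg = scores[~labels]
    thresholds = np.unique(scores)
    points = []
    for t in thresholds:
        sn = float((pos >= t).mean())
        sp = float((neg < t).mean())
        points.append((sn, sp))
    auc, se = _auc_delong(pos, neg)
    zcrit = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - zcrit * se), min(1.0, auc + zcrit * se))
    return RocAnalysis(
        thresholds=tuple(float(t) for t in thresholds),
        points=tuple(points),
        auc=auc,
        auc_ci=ci,
        n_positive=int(labels.sum()),
        n_negative=int((~labels).sum()),
    )


def empirical_roc(records: Sequence[CohortRecord]) -> RocAnalysis:
    """ROC/AUC of the predicted probabilities against postnatal outcome."""
    scores, labels = _scores_labels(records)
    return roc_from_scores(scores, labels)


# --------------------------------------------------------------------------
# diagnostic metrics


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its Wilson CI; ``defined`` is False on a 0 denominator."""

    value: float | None
    ci: tuple[float, float] | None
    defined: bool = True


@dataclass(frozen=True)
class DiagnosticMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    npv: MetricEstimate
    ppv: MetricEstimate

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _metric(k: int, n: int) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(value=None, ci=None, defined=False)
    return MetricEstimate(value=k / n, ci=wilson_ci(k, n))


def diagnostic_metrics(predicted_positive, outcome) -> DiagnosticMetrics:
    """2×2 sensitivity/specificity/NPV/PPV, each with a Wilson 95% CI."""
    pred = np.asarray(predicted_positive, dtype=bool)
    out = np.asarray(outcome, dtype=bool)
    if pred.shape != out.shape or pred.ndim != 1:
        raise ValueError("predicted and outcome vectors must be equal-length 1-D")
    if len(pred) == 0:
        raise InsufficientDataError("empty input")
    tp = int((pred & out).sum())
    fp = int((pred & ~out).sum())
    tn = int((~pred & ~out).sum())
    fn = int((~pred & out).sum())
    return DiagnosticMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_metric(tp, tp + fn),
        specificity=_metric(tn, tn + fp),
        npv=_metric(tn, tn + fn),
        ppv=_metric(tp, tp + fp),
    )


# --------------------------------------------------------------------------
# operating-point selection


class CutoffCriterion(str, Enum):
    BEST_BALANCE = "best_balance"
    MAX_SENSITIVITY = "max_sensitivity"
    MAX_SPECIFICITY = "max_specificity"


@dataclass(frozen=True)
class CutoffReport:
    criterion: CutoffCriterion
    threshold: float  # '>= threshold' predicts CoAo; an attained score value
    threshold_percent: int  # display percent, rounded half-to-even
    metrics: DiagnosticMetrics


def select_cutoff(
    roc: RocAnalysis,
    records: Sequence[CohortRecord],
    criterion: CutoffCriterion | str,
) -> CutoffReport:
    """Pick an operating point from the attained thresholds.

    best_balance maximises the Youden index J = Sn + Sp − 1, breaking ties
    toward higher specificity (fewer false referrals); max_sensitivity
    takes, among thresholds attaining the maximal sensitivity, the one with
    the highest specificity; max_specificity takes, among thresholds
    attaining the maximal specificity with non-zero sensitivity, the one
    with the highest sensitivity.
    """
    criterion = CutoffCriterion(criterion)
    scores, labels = _scores_labels(records)
    candidates = []
    for t, (sn, sp) in zip(roc.thresholds, roc.points):
        candidates.append((t, sn, sp))
    if criterion is CutoffCriterion.BEST_BALANCE:
        best = max(candidates, key=lambda c: (c[1] + c[2] - 1.0, c[2], c[0]))
    elif criterion is CutoffCriterion.MAX_SENSITIVITY:
        max_sn = max(c[1] for c in candidates)
        best = max(
            (c for c in candidates if c[1] == max_sn), key=lambda c: (c[2], c[0])
        )
    else:
        usable = [c for c in candidates if c[1] > 0.0]
        max_sp = max(c[2] for c in usable)
        best = max(
            (c for c in usable if c[2] == max_sp), key=lambda c: (c[1], -c[0])
        )
    t = best[0]
    metrics = diagnostic_metrics(scores >= t, labels)
    return CutoffReport(
        criterion=criterion,
        threshold=float(t),
        threshold_percent=round(100.0 * t),
        metrics=metrics,
    )


# --------------------------------------------------------------------------
# subgroups and probability bands


def split_by_onset(
    records: Iterable[CohortRecord],
) -> tuple[list[CohortRecord], list[CohortRecord]]:
    """Partition into early-onset (GA <= 28 weeks, inclusive) and late-onset."""
    early = [r for r in records if r.onset_group == "early"]
    late = [r for r in records if r.onset_group == "late"]
    return early, late


@dataclass(frozen=True)
class Band:
    label: str
    count: int
    coao_count: int

    @property
    def coao_rate(self) -> float | None:
        return self.coao_count / self.count if self.count else None


@dataclass(frozen=True)
class BandAnalysis:
    low: float
    high: float
    bands: tuple[Band, Band, Band]

    @property
    def total(self) -> int:
        return sum(b.count for b in self.bands)


def probability_bands(
    records: Sequence[CohortRecord], low: float = 0.35, high: float = 0.96
) -> BandAnalysis:
    """Counts and CoAo confirmation rates in [0, low), [low, high), [high, 1]."""
    if not 0.0 < low < high < 1.0:
        raise ValueError("bands must satisfy 0 < low < high < 1")
    edges = [
        (f"<{low:g}", lambda p: p < low),
        (f"[{low:g},{high:g})", lambda p: low <= p < high),
        (f">={high:g}", lambda p: p >= high),
    ]
    bands = []
    for label, member in edges:
        in_band = [r for r in records if member(r.predicted_probability)]
        bands.append(
            Band(
                label=label,
                count=len(in_band),
                coao_count=sum(1 for r in in_band if r.outcome_coao),
            )
        )
    return BandAnalysis(low=low, high=high, bands=tuple(bands))


# --------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float | None = None
    sd: float | None = None
    count: int | None = None  # categorical: positives
    percent: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_summaries: Mapping[str, GroupStats]
    test: str  # welch_t | mann_whitney | chi_square | fisher | degenerate
    statistic: float | None
    p_value: float | None
    degenerate: bool = False


_CONTINUOUS_RATIOS = ("tv_mv", "pv_av", "mpa_aao", "isthmus_da")


def _extract_variable(record: CohortRecord, variable: str):
    if variable == "predicted_probability":
        return record.predicted_probability
    if variable in _CONTINUOUS_RATIOS:
        return cardiac_ratios(record.exam).get(variable)
    return getattr(record.exam, variable)


def _is_normal(values: np.ndarray) -> bool:
    if len(values) < 3 or np.ptp(values) == 0.0:
        return False
    return stats.shapiro(values).pvalue > 0.05


def compare_groups(records: Sequence[CohortRecord], variable: str) -> GroupComparison:
    """Compare one variable between confirmed-CoAo and non-CoAo fetuses.

    Continuous variables use Welch's t-test when both groups pass a
    Shapiro–Wilk screen (alpha 0.05), otherwise Mann–Whitney; categorical
    (boolean) variables use the chi-square test unless any expected cell
    count falls below 5, in which case Fisher's exact test.  All p-values
    are two-sided.
    """
    groups: dict[str, list] = {"coao": [], "no_coao": []}
    for r in records:
        if r.outcome_coao is None:
            continue
        v = _extract_variable(r, variable)
        if v is None:
            continue
        groups["coao" if r.outcome_coao else "no_coao"].append(v)
    g1, g0 = groups["coao"], groups["no_coao"]
    categorical = all(isinstance(v, (bool, np.bool_)) for v in g1 + g0) and g1 + g0

    if categorical:
        if not g1 or not g0:
            raise InsufficientDataError(
                f"variable {variable!r} needs observations in both outcome groups"
            )
        k1, n1 = sum(g1), len(g1)
        k0, n0 = sum(g0), len(g0)
        table = np.array([[k1, n1 - k1], [k0, n0 - k0]], dtype=float)
        summaries = {
            "coao": GroupStats(n=n1, count=int(k1), percent=proportion_percent(k1, n1)),
            "no_coao": GroupStats(n=n0, count=int(k0), percent=proportion_percent(k0, n0)),
        }
        if np.any(table.sum(axis=0) == 0) or np.any(expected_freq(table) < 5):
            odds, p = stats.fisher_exact(table)
            return GroupComparison(variable, summaries, "fisher", float(odds), float(p))
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison(variable, summaries, "chi_square", float(chi2), float(p))

    a1 = np.asarray(g1, dtype=float)
    a0 = np.asarray(g0, dtype=float)
    if len(a1) < 2 or len(a0) < 2:
        raise InsufficientDataError(
            f"variable {variable!r} needs >= 2 observations per outcome group"
        )
    summaries = {
        "coao": GroupStats(n=len(a1), mean=float(a1.mean()), sd=float(a1.std(ddof=1))),
        "no_coao": GroupStats(n=len(a0), mean=float(a0.mean()), sd=float(a0.std(ddof=1))),
    }
    pooled = np.concatenate([a1, a0])
    if np.ptp(pooled) == 0.0:
        return GroupComparison(variable, summaries, "degenerate", None, None, degenerate=True)
    if _is_normal(a1) and _is_normal(a0):
        res = stats.ttest_ind(a1, a0, equal_var=False)
        return GroupComparison(variable, summaries, "welch_t", float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(a1, a0, alternative="two-sided")
    return GroupComparison(variable, summaries, "mann_whitney", float(res.statistic), float(res.pvalue))


def summarize_probabilities(
    records: Sequence[CohortRecord],
) -> dict[str, GroupStats]:
    """Mean ± sample SD of the predicted probability per outcome group, in percent."""
    groups: dict[str, list[float]] = {"coao": [], "no_coao": []}
    for r in records:
        if r.outcome_coao is None:
            continue
        groups["coao" if r.outcome_coao else "no_coao"].append(
            100.0 * r.predicted_probability
        )
    out: dict[str, GroupStats] = {}
    for name, values in groups.items():
        if not values:
            raise InsufficientDataError(f"outcome group {name!r} is empty")
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
        out[name] = GroupStats(n=len(arr), mean=float(arr.mean()), sd=sd)
    return out


# --------------------------------------------------------------------------
# scoring cohort rows into records


def score_records(
    rows,
    model: ScoringModel | None = None,
    zrefs: Mapping[CardiacStructure, ZScoreReference] | None = None,
    *,
    missing: str = "raise",
) -> list[CohortRecord]:
    """Score cohort rows (id, exam, optional outcome) into CohortRecords.

    When ``zrefs`` is given, z-scores absent from an exam are first derived
    from its raw diameters.
    """
    if model is None:
        model = default_model()
    out = []
    for row in rows:
        exam = row.exam
        if zrefs is not None:
            exam = attach_zscores(exam, zrefs)
        result = score_exam(exam, model, missing=missing)
        out.append(
            CohortRecord(
                record_id=row.record_id,
                exam=exam,
                predicted_probability=result.post_test_probability,
                outcome_coao=getattr(row, "outcome_coao", None),
            )
        )
    return out
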