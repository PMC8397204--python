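"""Validation-report document: pydantic models, builder, and schema.

The report is the machine-readable product of a validation run: ROC and
AUC with CI, the three operating points, early/late-onset subgroup
analyses, probability bands, group comparisons, and the per-class
probability summary.  ``validate_report`` checks any JSON document
against the schema; the published JSON Schema ships with the package
data and is generated from these models.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict

from . import __version__
from .score import ScoringModel, default_model
from .validation import (
    Band,
    BandAnalysis,
    CohortRecord,
    CutoffCriterion,
    CutoffReport,
    DiagnosticMetrics,
    GroupComparison,
    GroupStats,
    InsufficientDataError,
    MetricEstimate,
    RocAnalysis,
    SingleClassError,
    compare_groups,
    empirical_roc,
    probability_bands,
    select_cutoff,
    split_by_onset,
    summarize_probabilities,
)

__all__ = [
    "ValidationReport",
    "build_validation_report",
    "validate_report",
    "report_json_schema",
    "model_digest",
    "DEFAULT_COMPARISON_VARIABLES",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MetricModel(_Strict):
    value: Optional[float]
    ci: Optional[tuple[float, float]]
    defined: bool


class DiagnosticsModel(_Strict):
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: MetricModel
    specificity: MetricModel
    npv: MetricModel
    ppv: MetricModel


class CutoffModel(_Strict):
    criterion: str
    threshold: float
    threshold_percent: int
    metrics: DiagnosticsModel


class RocModel(_Strict):
    thresholds: list[float]
    sensitivity: list[float]
    specificity: list[float]
    auc: float
    auc_ci: tuple[float, float]
    n_positive: int
    n_negative: int


class GroupStatsModel(_Strict):
    n: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    count: Optional[int] = None
    percent: Optional[float] = None


class GroupComparisonModel(_Strict):
    variable: str
    group_summaries: dict[str, GroupStatsModel]
    test: str
    statistic: Optional[float]
    p_value: Optional[float]
    degenerate: bool


class BandModel(_Strict):
    label: str
    count: int
    coao_count: int
    coao_rate: Optional[float]
    percent_of_cohort: float


class BandsModel(_Strict):
    low: float
    high: float
    bands: list[BandModel]


class ProbabilitySummaryModel(_Strict):
    groups: dict[str, GroupStatsModel]
    p_value: Optional[float]


class SubgroupModel(_Strict):
    name: str
    n: int
    n_coao: int
    roc: Optional[RocModel]
    cutoffs: Optional[list[CutoffModel]]
    probability_summary: Optional[ProbabilitySummaryModel]
    note: Optional[str] = None


class ValidationReport(_Strict):
    schema_version: str
    package_version: str
    model_digest: str
    n: int
    n_coao: int
    prevalence_percent: float
    roc: RocModel
    cutoffs: list[CutoffModel]
    subgroups: dict[str, SubgroupModel]
    bands: BandsModel
    group_comparisons: list[GroupComparisonModel]
    probability_summary: ProbabilitySummaryModel
    comparator_benchmark: Optional[dict[str, DiagnosticsModel]] = None
    comparator_skipped: Optional[dict[str, str]] = None


def model_digest(model: ScoringModel) -> str:
    payload = json.dumps(model.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _metric(m: MetricEstimate) -> MetricModel:
    return MetricModel(value=m.value, ci=m.ci, defined=m.defined)


def diagnostics_model(d: DiagnosticMetrics) -> DiagnosticsModel:
    return DiagnosticsModel(
        tp=d.tp,
        fp=d.fp,
        tn=d.tn,
        fn=d.fn,
        sensitivity=_metric(d.sensitivity),
        specificity=_metric(d.specificity),
        npv=_metric(d.npv),
        ppv=_metric(d.ppv),
    )


def _cutoff(c: CutoffReport) -> CutoffModel:
    return CutoffModel(
        criterion=c.criterion.value,
        threshold=c.threshold,
        threshold_percent=c.threshold_percent,
        metrics=diagnostics_model(c.metrics),
    )


def _roc(r: RocAnalysis) -> RocModel:
    return RocModel(
        thresholds=list(r.thresholds),
        sensitivity=[sn for sn, _ in r.points],
        specificity=[sp for _, sp in r.points],
        auc=r.auc,
        auc_ci=r.auc_ci,
        n_positive=r.n_positive,
        n_negative=r.n_negative,
    )


def _group_stats(g: GroupStats) -> GroupStatsModel:
    return GroupStatsModel(n=g.n, mean=g.mean, sd=g.sd, count=g.count, percent=g.percent)


def _probability_summary(
    records: Sequence[CohortRecord],
) -> ProbabilitySummaryModel:
    groups = summarize_probabilities(records)
    try:
        p = compare_groups(records, "predicted_probability").p_value
    except InsufficientDataError:
        p = None
    return ProbabilitySummaryModel(
        groups={k: _group_stats(v) for k, v in groups.items()}, p_value=p
    )


def _bands(b: BandAnalysis) -> BandsModel:
    total = b.total
    return BandsModel(
        low=b.low,
        high=b.high,
        bands=[
            BandModel(
                label=band.label,
                count=band.count,
                coao_count=band.coao_count,
                coao_rate=band.coao_rate,
                percent_of_cohort=round(100.0 * band.count / total, 1) if total else 0.0,
            )
            for band in b.bands
        ],
    )


def _subgroup(name: str, records: Sequence[CohortRecord]) -> SubgroupModel:
    n = len(records)
    n_coao = sum(1 for r in records if r.outcome_coao)
    roc = cutoffs = prob = None
    note = None
    if 0 < n_coao < n:
        roc_analysis = empirical_roc(records)
        roc = _roc(roc_analysis)
        cutoffs = [
            _cutoff(select_cutoff(roc_analysis, records, crit))
            for crit in CutoffCriterion
        ]
        prob = _probability_summary(records)
    else:
        note = "single outcome class; ROC and operating points undefined"
    return SubgroupModel(
        name=name, n=n, n_coao=n_coao, roc=roc, cutoffs=cutoffs,
        probability_summary=prob, note=note,
    )


DEFAULT_COMPARISON_VARIABLES = (
    "ga_weeks",
    "aao_z",
    "isthmus_3vt_z",
    "pv_av",
    "tv_mv",
    "mpa_aao",
    "isthmus_da",
    "predicted_probability",
    "plsvc",
    "rfop",
)


def build_validation_report(
    records: Sequence[CohortRecord],
    model: ScoringModel | None = None,
    *,
    band_low: float = 0.35,
    band_high: float = 0.96,
    comparison_variables: Sequence[str] = DEFAULT_COMPARISON_VARIABLES,
    comparator_benchmark: Mapping[str, DiagnosticMetrics] | None = None,
    comparator_skipped: Mapping[str, str] | None = None,
) -> ValidationReport:
    """Run the full validation analysis and assemble the report document."""
    if model is None:
        model = default_model()
    if any(r.outcome_coao is None for r in records):
        raise ValueError("validation requires a postnatal outcome on every record")
    n = len(records)
    n_coao = sum(1 for r in records if r.outcome_coao)
    roc_analysis = empirical_roc(records)  # raises SingleClassError if degenerate
    cutoffs = [
        _cutoff(select_cutoff(roc_analysis, records, crit)) for crit in CutoffCriterion
    ]
    early, late = split_by_onset(records)
    comparisons = []
    for variable in comparison_variables:
        try:
            comparisons.append(compare_groups(records, variable))
        except InsufficientDataError:
            continue
    return ValidationReport(
        schema_version="1",
        package_version=__version__,
        model_digest=model_digest(model),
        n=n,
        n_coao=n_coao,
        prevalence_percent=round(100.0 * n_coao / n, 1),
        roc=_roc(roc_analysis),
        cutoffs=cutoffs,
        subgroups={
            "early": _subgroup("early", early),
            "late": _subgroup("late", late),
        },
        bands=_bands(probability_bands(records, band_low, band_high)),
        group_comparisons=[
            GroupComparisonModel(
                variable=c.variable,
                group_summaries={k: _group_stats(v) for k, v in c.group_summaries.items()},
                test=c.test,
                statistic=c.statistic,
                p_value=c.p_value,
                degenerate=c.degenerate,
            )
            for c in comparisons
        ],
        probability_summary=_probability_summary(records),
        comparator_benchmark=(
            {k: diagnostics_model(v) for k, v in comparator_benchmark.items()}
            if comparator_benchmark is not None
            else None
        ),
        comparator_skipped=dict(comparator_skipped) if comparator_skipped else None,
    )


def validate_report(doc: Mapping) -> ValidationReport:
    """Validate a report JSON document; raises pydantic.ValidationError."""
    return ValidationReport.model_validate(doc)


def report_json_schema() -> dict:
    """The JSON Schema of the report document (also shipped in package data)."""
    return ValidationReport.model_json_schema()
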