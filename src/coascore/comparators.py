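"""Alternative published rule-based predictors of fetal coarctation.

Several groups have proposed echocardiographic decision rules for
predicting postnatal confirmation of CoAo in fetuses with cardiac
asymmetry.  The rules whose decision procedure is fully stated are
implemented here so they can be benchmarked head-to-head on the same
cohort records; rules published only as parameter lists (no aggregation
logic or coefficients) are registered as descriptive-only and refuse to
evaluate rather than guess.

Note on Beattie 2017: the published criterion is printed as
MPA/AAo <= 0.65, which is directionally inconsistent with right dominance
(CoAo fetuses have a *larger* pulmonary artery relative to the ascending
aorta).  It is implemented exactly as printed; ``evaluate_rule`` attaches
a warning in the prediction detail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .score import FetalEchoExam, ScoringModel, cardiac_ratios, default_model, score_exam
from .validation import CohortRecord, DiagnosticMetrics, diagnostic_metrics

__all__ = [
    "ComparatorRule",
    "ComparatorPrediction",
    "MissingFieldError",
    "NotEvaluableError",
    "RULES",
    "get_rule",
    "evaluate_rule",
    "benchmark_rules",
]


class MissingFieldError(ValueError):
    """The exam lacks measurements the rule requires; never a silent negative."""

    def __init__(self, rule_id: str, missing: Sequence[str]):
        self.rule_id = rule_id
        self.missing = tuple(missing)
        super().__init__(
            f"rule {rule_id!r} cannot be evaluated; missing fields: "
            + ", ".join(missing)
        )


class NotEvaluableError(ValueError):
    """The published rule does not state a complete decision procedure."""


@dataclass(frozen=True)
class ComparatorRule:
    rule_id: str
    description: str
    required_fields: tuple[str, ...]
    evaluable: bool = True


@dataclass(frozen=True)
class ComparatorPrediction:
    rule_id: str
    predicted_coao: bool
    detail: Mapping[str, object]


def _require(exam: FetalEchoExam, rule_id: str, fields: Iterable[str]) -> None:
    missing = [f for f in fields if getattr(exam, f) is None]
    if missing:
        raise MissingFieldError(rule_id, missing)


def _ratio(exam: FetalEchoExam, name: str, rule_id: str) -> float:
    r = cardiac_ratios(exam).get(name)
    if r is None:
        num, den = {
            "tv_mv": ("tv_mm", "mv_mm"),
            "pv_av": ("pv_mm", "av_mm"),
            "mpa_aao": ("mpa_mm", "aao_mm"),
            "isthmus_da": ("isthmus_3vt_mm", "da_3vt_mm"),
        }[name]
        raise MissingFieldError(rule_id, [num, den])
    return r


# -- evaluable rules -------------------------------------------------------


def _eval_gomez2013(exam: FetalEchoExam, threshold: float = 0.53) -> ComparatorPrediction:
    # the likelihood-ratio score itself, thresholded at its published
    # best-balance operating point (predicted risk >= 53%)
    result = score_exam(exam, default_model())
    return ComparatorPrediction(
        rule_id="gomez2013",
        predicted_coao=result.post_test_probability >= threshold,
        detail={
            "post_test_probability": result.post_test_probability,
            "threshold": threshold,
        },
    )


def _eval_gomez2014_early(exam: FetalEchoExam) -> ComparatorPrediction:
    _require(exam, "gomez2014_early", ["aao_z", "isthmus_3vt_z"])
    aao = exam.aao_z <= -1.1
    isth = exam.isthmus_3vt_z <= -1.2
    return ComparatorPrediction(
        "gomez2014_early", aao and isth, {"aao_z<=-1.1": aao, "isthmus_3vt_z<=-1.2": isth}
    )


def _eval_gomez2014_late(exam: FetalEchoExam) -> ComparatorPrediction:
    tv_mv = _ratio(exam, "tv_mv", "gomez2014_late")
    mpa_aao = _ratio(exam, "mpa_aao", "gomez2014_late")
    a = tv_mv >= 1.48
    b = mpa_aao >= 1.85
    return ComparatorPrediction(
        "gomez2014_late", a and b, {"tv_mv>=1.48": a, "mpa_aao>=1.85": b}
    )


def _eval_marginean2015(exam: FetalEchoExam) -> ComparatorPrediction:
    _require(exam, "marginean2015", ["rv_mm", "lv_mm", "isthmus_3vt_mm"])
    isthmus_da = _ratio(exam, "isthmus_da", "marginean2015")
    rv_lv = exam.rv_mm / exam.lv_mm
    crit = {
        "rv_lv>1.5": rv_lv > 1.5,
        "isthmus_da<0.7": isthmus_da < 0.7,
        "isthmus_3vt_mm<4.2": exam.isthmus_3vt_mm < 4.2,
    }
    return ComparatorPrediction("marginean2015", all(crit.values()), crit)


def _eval_toole2016(exam: FetalEchoExam) -> ComparatorPrediction:
    _require(exam, "toole2016", ["mv_z", "isthmus_ductal_angle_deg"])
    tv_mv = _ratio(exam, "tv_mv", "toole2016")
    isthmus_da = _ratio(exam, "isthmus_da", "toole2016")
    crit = {
        "mv_z<-1.63": exam.mv_z < -1.63,
        "mv_tv<0.75": (1.0 / tv_mv) < 0.75,
        "isthmus_da<0.5": isthmus_da < 0.5,
        "angle<117": exam.isthmus_ductal_angle_deg < 117.0,
    }
    return ComparatorPrediction("toole2016", sum(crit.values()) >= 2, crit)


def _eval_anuwutnavin2016(exam: FetalEchoExam) -> ComparatorPrediction:
    _require(exam, "anuwutnavin2016", ["aao_z", "mv_z", "transverse_arch_z", "vsd"])
    points = {
        "aao_z<=-2 (4pt)": 4 if exam.aao_z <= -2.0 else 0,
        "mv_z<=-2 (2pt)": 2 if exam.mv_z <= -2.0 else 0,
        "transverse_arch_z<=-2 (1pt)": 1 if exam.transverse_arch_z <= -2.0 else 0,
        "vsd (1pt)": 1 if exam.vsd else 0,
    }
    total = sum(points.values())
    detail = dict(points)
    detail["total_points"] = total
    return ComparatorPrediction("anuwutnavin2016", total >= 4, detail)


def _eval_beattie2017(exam: FetalEchoExam) -> ComparatorPrediction:
    _require(exam, "beattie2017", ["aoisth_diastolic_flow_persistence"])
    mpa_aao = _ratio(exam, "mpa_aao", "beattie2017")
    a = mpa_aao <= 0.65
    b = bool(exam.aoisth_diastolic_flow_persistence)
    return ComparatorPrediction(
        "beattie2017",
        a and b,
        {
            "mpa_aao<=0.65": a,
            "diastolic_flow_persistence": b,
            "warning": "MPA/AAo <= 0.65 implemented as printed; direction is "
            "inconsistent with right dominance",
        },
    )


def _fricke_composite(exam: FetalEchoExam) -> float:
    isthmus_da = _ratio(exam, "isthmus_da", "fricke2021")
    tv_mv = _ratio(exam, "tv_mv", "fricke2021")
    return isthmus_da * (1.0 / tv_mv)


def _eval_fricke2021(exam: FetalEchoExam) -> ComparatorPrediction:
    _require(exam, "fricke2021", ["csa_index"])
    composite = _fricke_composite(exam)
    crit = {
        "csa_index<0.78": exam.csa_index < 0.78,
        "isthmus_da_x_mv_tv<0.37": composite < 0.37,
    }
    return ComparatorPrediction("fricke2021", any(crit.values()), crit)


def _eval_fricke2021_csa(exam: FetalEchoExam) -> ComparatorPrediction:
    _require(exam, "fricke2021_csa", ["csa_index"])
    pos = exam.csa_index < 0.78
    return ComparatorPrediction("fricke2021_csa", pos, {"csa_index<0.78": pos})


def _eval_fricke2021_composite(exam: FetalEchoExam) -> ComparatorPrediction:
    composite = _fricke_composite(exam)
    pos = composite < 0.37
    return ComparatorPrediction(
        "fricke2021_composite", pos, {"isthmus_da_x_mv_tv<0.37": pos, "value": composite}
    )


_EVALUATORS: dict[str, Callable[[FetalEchoExam], ComparatorPrediction]] = {
    "gomez2013": _eval_gomez2013,
    "gomez2014_early": _eval_gomez2014_early,
    "gomez2014_late": _eval_gomez2014_late,
    "marginean2015": _eval_marginean2015,
    "toole2016": _eval_toole2016,
    "anuwutnavin2016": _eval_anuwutnavin2016,
    "beattie2017": _eval_beattie2017,
    "fricke2021": _eval_fricke2021,
    "fricke2021_csa": _eval_fricke2021_csa,
    "fricke2021_composite": _eval_fricke2021_composite,
}

RULES: dict[str, ComparatorRule] = {
    "gomez2013": ComparatorRule(
        "gomez2013",
        "Likelihood-ratio multiparameter score, predicted risk >= 53%",
        ("ga_weeks", "aao_z", "isthmus_3vt_z", "pv_mm", "av_mm"),
    ),
    "gomez2014_early": ComparatorRule(
        "gomez2014_early",
        "AAo z <= -1.1 AND isthmus(3VT) z <= -1.2 (early-onset rule)",
        ("aao_z", "isthmus_3vt_z"),
    ),
    "gomez2014_late": ComparatorRule(
        "gomez2014_late",
        "TV/MV >= 1.48 AND MPA/AAo >= 1.85 (late-onset rule)",
        ("tv_mm", "mv_mm", "mpa_mm", "aao_mm"),
    ),
    "marginean2015": ComparatorRule(
        "marginean2015",
        "RV/LV > 1.5 AND isthmus/DA < 0.7 AND isthmus(3VT) < 4.2 mm, all three",
        ("rv_mm", "lv_mm", "isthmus_3vt_mm", "da_3vt_mm"),
    ),
    "toole2016": ComparatorRule(
        "toole2016",
        ">= 2 of: MV z < -1.63, MV/TV < 0.75, isthmus/DA < 0.5, isthmo-ductal angle < 117 deg",
        ("mv_z", "tv_mm", "mv_mm", "isthmus_3vt_mm", "da_3vt_mm", "isthmus_ductal_angle_deg"),
    ),
    "anuwutnavin2016": ComparatorRule(
        "anuwutnavin2016",
        "Points: AAo z<=-2 (4), MV z<=-2 (2), transverse arch z<=-2 (1), VSD (1); positive if >= 4",
        ("aao_z", "mv_z", "transverse_arch_z", "vsd"),
    ),
    "beattie2017": ComparatorRule(
        "beattie2017",
        "MPA/AAo <= 0.65 (as printed) AND diastolic flow persistence at the isthmus",
        ("mpa_mm", "aao_mm", "aoisth_diastolic_flow_persistence"),
    ),
    "fricke2021": ComparatorRule(
        "fricke2021",
        "CSA index < 0.78 OR isthmus/DA x MV/TV < 0.37",
        ("csa_index", "isthmus_3vt_mm", "da_3vt_mm", "tv_mm", "mv_mm"),
    ),
    "fricke2021_csa": ComparatorRule(
        "fricke2021_csa", "CSA index < 0.78 (sub-rule)", ("csa_index",)
    ),
    "fricke2021_composite": ComparatorRule(
        "fricke2021_composite",
        "isthmus/DA x MV/TV < 0.37 (sub-rule)",
        ("isthmus_3vt_mm", "da_3vt_mm", "tv_mm", "mv_mm"),
    ),
    # descriptive-only entries: published parameter lists without a complete
    # decision procedure (no aggregation logic or fitted coefficients)
    "jowett2012": ComparatorRule(
        "jowett2012", "parameter list without combination logic", (), evaluable=False
    ),
    "arya2016": ComparatorRule(
        "arya2016", "angle thresholds without aggregation", (), evaluable=False
    ),
    "patel2018": ComparatorRule(
        "patel2018", "group means only, no decision rule", (), evaluable=False
    ),
    "wang2019": ComparatorRule(
        "wang2019", "two thresholds without stated pairing", (), evaluable=False
    ),
    "morgan2019": ComparatorRule(
        "morgan2019", "fitted model without published coefficients", (), evaluable=False
    ),
    "vigneswaran2020": ComparatorRule(
        "vigneswaran2020", "parameter list without thresholds", (), evaluable=False
    ),
    "freeman2021": ComparatorRule(
        "freeman2021", "parameter list without thresholds", (), evaluable=False
    ),
}


def get_rule(rule_id: str) -> ComparatorRule:
    try:
        return RULES[rule_id]
    except KeyError:
        raise KeyError(f"unknown comparator rule {rule_id!r}") from None


def evaluate_rule(exam: FetalEchoExam, rule: ComparatorRule | str) -> ComparatorPrediction:
    """Evaluate one published rule on an exam.

    Raises :class:`NotEvaluableError` for descriptive-only rules and
    :class:`MissingFieldError` when required measurements are absent.
    """
    if isinstance(rule, str):
        rule = get_rule(rule)
    if not rule.evaluable:
        raise NotEvaluableError(
            f"rule {rule.rule_id!r} is descriptive only ({rule.description})"
        )
    return _EVALUATORS[rule.rule_id](exam)


def benchmark_rules(
    records: Sequence[CohortRecord],
    rules: Iterable[ComparatorRule | str] | None = None,
) -> tuple[dict[str, DiagnosticMetrics], dict[str, str]]:
    """Diagnostic metrics per rule on a labelled cohort.

    Returns (metrics per evaluable rule, skip reasons per skipped rule).
    A rule is skipped — with its reason recorded — when it is descriptive
    only or when any record lacks a required measurement.
    """
    if rules is None:
        rules = [r for r in RULES.values() if r.evaluable]
    results: dict[str, DiagnosticMetrics] = {}
    skipped: dict[str, str] = {}
    for rule in rules:
        if isinstance(rule, str):
            rule = get_rule(rule)
        try:
            preds = [evaluate_rule(r.exam, rule).predicted_coao for r in records]
        except (NotEvaluableError, MissingFieldError) as exc:
            skipped[rule.rule_id] = str(exc)
            continue
        outcomes = [bool(r.outcome_coao) for r in records]
        results[rule.rule_id] = diagnostic_metrics(preds, outcomes)
    return results, skipped
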