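"""Likelihood-ratio multiparameter score for prenatal coarctation of the aorta.

Fetuses referred for cardiac asymmetry with right dominance carry a baseline
(pre-test) odds of postnatally confirmed coarctation of the aorta (CoAo).
Four dichotomised echocardiographic predictors — gestational age at
diagnosis, ascending-aorta z-score, aortic-isthmus z-score in the
three-vessels-and-trachea (3VT) view, and the pulmonary-valve/aortic-valve
diameter ratio — each multiply those odds by a positive likelihood ratio
(LR+) when the criterion is met and by a negative likelihood ratio (LR−)
when it is not:

    post-test odds = pre-test odds × LR1 × LR2 × LR3 × LR4
    post-test probability = odds / (odds + 1)

The default model ships the published cut-offs and likelihood ratios and a
pre-test odds of 41/44 (41 CoAo vs 44 non-CoAo in the derivation cohort).
The pre-test odds is carried at full precision; display layers round it to
0.93.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from importlib import resources
from typing import Iterator, Mapping, Sequence

__all__ = [
    "ParameterId",
    "Direction",
    "ArchFlow",
    "ForamenOvaleFlow",
    "LikelihoodRatioEntry",
    "ScoringModel",
    "FetalEchoExam",
    "EchoProfile",
    "ScoreResult",
    "MissingParameterError",
    "default_model",
    "dichotomize",
    "compute_post_test",
    "score_exam",
    "enumerate_profiles",
    "cardiac_ratios",
    "resolve_gestational_dating",
]


class ParameterId(str, Enum):
    """The four dichotomised predictors of the score."""

    GA_WEEKS = "ga_weeks"
    AAO_ZSCORE = "aao_zscore"
    ISTHMUS_3VT_ZSCORE = "isthmus_3vt_zscore"
    PV_AV_RATIO = "pv_av_ratio"


class Direction(str, Enum):
    """Side of the cut-off on which the criterion counts as positive."""

    LE = "le"  # positive when value <= cutoff (boundary inclusive)
    GE = "ge"  # positive when value >= cutoff (boundary inclusive)


class ArchFlow(str, Enum):
    ANTEGRADE = "antegrade"
    MIXED = "mixed"
    REVERSED = "reversed"


class ForamenOvaleFlow(str, Enum):
    RIGHT_TO_LEFT = "right_to_left"
    LEFT_TO_RIGHT = "left_to_right"
    BIDIRECTIONAL = "bidirectional"


class MissingParameterError(ValueError):
    """A score parameter cannot be resolved from the exam (strict mode)."""

    def __init__(self, parameter: ParameterId, detail: str = ""):
        self.parameter = parameter
        msg = f"cannot resolve score parameter {parameter.value!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


@dataclass(frozen=True)
class LikelihoodRatioEntry:
    """Cut-off and likelihood ratios for one predictor.

    ``lr_positive`` multiplies the odds when the criterion is met,
    ``lr_negative`` when it is not.  Published 95% CIs are stored for
    reporting but are not propagated into probability intervals.
    """

    parameter_id: ParameterId
    cutoff_value: float
    direction: Direction
    lr_positive: float
    lr_negative: float
    lr_positive_ci: tuple[float, float] | None = None
    lr_negative_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lr_positive <= 0 or self.lr_negative <= 0:
            raise ValueError("likelihood ratios must be strictly positive")
        if self.lr_positive <= self.lr_negative:
            raise ValueError(
                "lr_positive must exceed lr_negative for an informative criterion"
            )
        for point, ci in (
            (self.lr_positive, self.lr_positive_ci),
            (self.lr_negative, self.lr_negative_ci),
        ):
            if ci is not None:
                lo, hi = ci
                if not (lo <= point <= hi):
                    raise ValueError(f"CI ({lo}, {hi}) does not contain point {point}")

    def criterion_met(self, value: float) -> bool:
        """Boundary-inclusive dichotomisation of ``value`` at the cut-off."""
        if self.direction is Direction.LE:
            return value <= self.cutoff_value
        return value >= self.cutoff_value


@dataclass(frozen=True)
class ScoringModel:
    """The four likelihood-ratio entries plus the pre-test class counts."""

    entries: tuple[LikelihoodRatioEntry, ...]
    pretest_coao_count: int
    pretest_no_coao_count: int

    def __post_init__(self) -> None:
        ids = [e.parameter_id for e in self.entries]
        if sorted(ids, key=lambda p: p.value) != sorted(
            ParameterId, key=lambda p: p.value
        ):
            raise ValueError("model must contain exactly one entry per parameter")
        if self.pretest_coao_count <= 0 or self.pretest_no_coao_count <= 0:
            raise ValueError("pre-test counts must be strictly positive")

    @property
    def pretest_odds(self) -> float:
        """Exact pre-test odds (counts ratio, not the rounded display value)."""
        return self.pretest_coao_count / self.pretest_no_coao_count

    @property
    def pretest_odds_display(self) -> float:
        return round(self.pretest_odds, 2)

    def entry(self, parameter_id: ParameterId | str) -> LikelihoodRatioEntry:
        pid = ParameterId(parameter_id)
        for e in self.entries:
            if e.parameter_id is pid:
                return e
        raise KeyError(pid)  # unreachable given the invariant

    # -- JSON round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "parameters": [
                {
                    "id": e.parameter_id.value,
                    "cutoff": e.cutoff_value,
                    "direction": e.direction.value,
                    "lr_pos": e.lr_positive,
                    "lr_neg": e.lr_negative,
                    "lr_pos_ci": list(e.lr_positive_ci) if e.lr_positive_ci else None,
                    "lr_neg_ci": list(e.lr_negative_ci) if e.lr_negative_ci else None,
                }
                for e in self.entries
            ],
            "pretest": {
                "coao": self.pretest_coao_count,
                "no_coao": self.pretest_no_coao_count,
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ScoringModel":
        entries = tuple(
            LikelihoodRatioEntry(
                parameter_id=ParameterId(p["id"]),
                cutoff_value=float(p["cutoff"]),
                direction=Direction(p["direction"]),
                lr_positive=float(p["lr_pos"]),
                lr_negative=float(p["lr_neg"]),
                lr_positive_ci=tuple(p["lr_pos_ci"]) if p.get("lr_pos_ci") else None,
                lr_negative_ci=tuple(p["lr_neg_ci"]) if p.get("lr_neg_ci") else None,
            )
            for p in doc["parameters"]
        )
        return cls(
            entries=entries,
            pretest_coao_count=int(doc["pretest"]["coao"]),
            pretest_no_coao_count=int(doc["pretest"]["no_coao"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ScoringModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FetalEchoExam:
    """One fetus's first diagnostic echocardiography for suspected CoAo.

    Gestational age is decimal weeks (weeks + days/7) at the first
    diagnostic scan.  Dimensions are millimetres, inner edge to inner edge;
    z-scores are in reference-SD units.  Fields beyond the four score
    inputs exist so that alternative published rules can be evaluated on
    the same exam.
    """

    ga_weeks: float
    aao_z: float | None = None
    isthmus_3vt_z: float | None = None
    pv_mm: float | None = None
    av_mm: float | None = None
    # additional raw dimensions (mm)
    tv_mm: float | None = None
    mv_mm: float | None = None
    mpa_mm: float | None = None
    aao_mm: float | None = None
    isthmus_3vt_mm: float | None = None
    isthmus_sagittal_mm: float | None = None
    da_3vt_mm: float | None = None
    rv_mm: float | None = None
    lv_mm: float | None = None
    # additional z-scores used by comparator rules
    mv_z: float | None = None
    tv_z: float | None = None
    transverse_arch_z: float | None = None
    # geometry / composite indices
    isthmus_ductal_angle_deg: float | None = None
    csa_index: float | None = None
    # qualitative findings
    plsvc: bool | None = None
    rfop: bool | None = None
    diffuse_arch_hypoplasia: bool | None = None
    contraductal_shelf: bool | None = None
    vsd: bool | None = None
    aoisth_diastolic_flow_persistence: bool | None = None
    arch_flow: ArchFlow | None = None
    fo_flow: ForamenOvaleFlow | None = None
    transaortic_peak_velocity: float | None = None  # cm/s

    _DIAMETER_FIELDS = (
        "pv_mm",
        "av_mm",
        "tv_mm",
        "mv_mm",
        "mpa_mm",
        "aao_mm",
        "isthmus_3vt_mm",
        "isthmus_sagittal_mm",
        "da_3vt_mm",
        "rv_mm",
        "lv_mm",
    )

    def __post_init__(self) -> None:
        if not 11.0 <= self.ga_weeks <= 42.0:
            raise ValueError(
                f"ga_weeks must lie in [11, 42] weeks, got {self.ga_weeks}"
            )
        for name in self._DIAMETER_FIELDS:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be a positive diameter, got {v}")

    @property
    def pv_av_ratio(self) -> float | None:
        if self.pv_mm is None or self.av_mm is None:
            return None
        return self.pv_mm / self.av_mm

    def with_updates(self, **changes) -> "FetalEchoExam":
        return replace(self, **changes)


@dataclass(frozen=True)
class EchoProfile:
    """Dichotomised state of the four score criteria.

    In strict scoring all four booleans are defined; ``None`` marks a
    parameter left unresolved under the explicit neutral-missing mode.
    """

    ga_weeks: bool | None
    aao_zscore: bool | None
    isthmus_3vt_zscore: bool | None
    pv_av_ratio: bool | None

    def __getitem__(self, parameter_id: ParameterId | str) -> bool | None:
        return getattr(self, ParameterId(parameter_id).value)

    def as_dict(self) -> dict[ParameterId, bool | None]:
        return {pid: getattr(self, pid.value) for pid in ParameterId}

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.as_dict().values())

    def items(self) -> Iterator[tuple[ParameterId, bool | None]]:
        return iter(self.as_dict().items())


@dataclass(frozen=True)
class ScoreResult:
    """Post-test odds/probability with the per-parameter LR contributions."""

    post_test_odds: float
    post_test_probability: float
    contributions: Mapping[ParameterId, float]
    profile: EchoProfile
    partial: bool = False

    def probability_percent(self, decimals: int = 0) -> float:
        """Display percent, rounded half-to-even."""
        return round(100.0 * self.post_test_probability, decimals)


def _table1_entries() -> tuple[LikelihoodRatioEntry, ...]:
    with resources.files("coascore.data").joinpath("default_model.json").open() as fh:
        return ScoringModel.from_dict(json.load(fh)).entries


_DEFAULT_MODEL: ScoringModel | None = None


def default_model() -> ScoringModel:
    """The published model: four LR entries and pre-test counts 41/44.

    Loaded from the packaged JSON document, which reproduces the published
    table exactly.
    """
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        with resources.files("coascore.data").joinpath("default_model.json").open() as fh:
            _DEFAULT_MODEL = ScoringModel.from_dict(json.load(fh))
    return _DEFAULT_MODEL


def _resolve_parameter(exam: FetalEchoExam, pid: ParameterId) -> float | None:
    if pid is ParameterId.GA_WEEKS:
        return exam.ga_weeks
    if pid is ParameterId.AAO_ZSCORE:
        return exam.aao_z
    if pid is ParameterId.ISTHMUS_3VT_ZSCORE:
        return exam.isthmus_3vt_z
    if pid is ParameterId.PV_AV_RATIO:
        return exam.pv_av_ratio
    raise KeyError(pid)


def dichotomize(
    exam: FetalEchoExam, model: ScoringModel, *, missing: str = "raise"
) -> EchoProfile:
    """Apply the model's cut-offs to an exam, boundary inclusive.

    ``missing="raise"`` (default, strict) raises :class:`MissingParameterError`
    naming the first unresolvable parameter; ``missing="neutral"`` leaves it
    as ``None`` so the scoring step applies a unit likelihood ratio and
    flags the result as partial.
    """
    if missing not in ("raise", "neutral"):
        raise ValueError("missing must be 'raise' or 'neutral'")
    states: dict[str, bool | None] = {}
    for pid in ParameterId:
        value = _resolve_parameter(exam, pid)
        if value is None:
            if missing == "raise":
                detail = (
                    "pv_mm and av_mm are both required"
                    if pid is ParameterId.PV_AV_RATIO
                    else "value not provided"
                )
                raise MissingParameterError(pid, detail)
            states[pid.value] = None
        else:
            states[pid.value] = model.entry(pid).criterion_met(value)
    return EchoProfile(**states)


def compute_post_test(profile: EchoProfile, model: ScoringModel) -> ScoreResult:
    """Multiply the pre-test odds by each criterion's likelihood ratio.

    Uses the exact pre-test odds (counts ratio) at full precision; the
    rounded two-decimal display value is never used in the arithmetic.
    """
    odds = model.pretest_odds
    contributions: dict[ParameterId, float] = {}
    partial = False
    for pid in ParameterId:
        state = profile[pid]
        entry = model.entry(pid)
        if state is None:
            lr = 1.0
            partial = True
        else:
            lr = entry.lr_positive if state else entry.lr_negative
        contributions[pid] = lr
        odds *= lr
    probability = odds / (odds + 1.0)
    return ScoreResult(
        post_test_odds=odds,
        post_test_probability=probability,
        contributions=contributions,
        profile=profile,
        partial=partial,
    )


def score_exam(
    exam: FetalEchoExam, model: ScoringModel | None = None, *, missing: str = "raise"
) -> ScoreResult:
    """Dichotomise an exam and compute its post-test CoAo probability."""
    if model is None:
        model = default_model()
    return compute_post_test(dichotomize(exam, model, missing=missing), model)


def enumerate_profiles(
    model: ScoringModel,
) -> list[tuple[EchoProfile, ScoreResult]]:
    """All 16 criterion combinations, sorted by probability ascending.

    These are the only probabilities the score can emit, which makes this
    the oracle for any cohort-level analysis of the discrete score.
    """
    out = []
    for combo in itertools.product((False, True), repeat=len(ParameterId)):
        profile = EchoProfile(**{pid.value: state for pid, state in zip(ParameterId, combo)})
        out.append((profile, compute_post_test(profile, model)))
    out.sort(key=lambda pair: pair[1].post_test_probability)
    return out


_RATIO_SPECS = {
    "tv_mv": ("tv_mm", "mv_mm"),
    "pv_av": ("pv_mm", "av_mm"),
    "mpa_aao": ("mpa_mm", "aao_mm"),
    "isthmus_da": ("isthmus_3vt_mm", "da_3vt_mm"),
}


def cardiac_ratios(exam: FetalEchoExam) -> dict[str, float]:
    """Right/left structure ratios; a ratio is omitted when an operand is absent."""
    out: dict[str, float] = {}
    for name, (num_field, den_field) in _RATIO_SPECS.items():
        num = getattr(exam, num_field)
        den = getattr(exam, den_field)
        if num is not None and den is not None and den > 0:
            out[name] = num / den
    return out


def resolve_gestational_dating(
    lmp_ga: float, crl_ga: float, lmp_reliable: bool
) -> float:
    """Choose the gestational dating between last menstrual period and ultrasound.

    The crown–rump-length (ultrasound) dating is used when the LMP is
    unreliable, or when LMP and ultrasound dating disagree by strictly more
    than 7 days; a discordance of exactly 7 days keeps the LMP dating.
    """
    if not lmp_reliable:
        return crl_ga
    if abs(lmp_ga - crl_ga) > 7.0 / 7.0:
        return crl_ga
    return lmp_ga
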