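"""Synthetic cohorts of fetuses with cardiac asymmetry.

The generator emulates the statistical structure the validation analysis
assumes: a two-class cohort (postnatally confirmed CoAo vs not), an
early/late-onset mixture with CoAo strongly enriched among early-onset
referrals, and class-conditional distributions for the z-scores, valve
ratios and qualitative findings.  Raw diameters are back-filled from the
drawn z-scores / ratios through the packaged synthetic reference
equations so that the comparator rules (which consume raw millimetres)
can run on the same records.

Every record consumes a fixed number of pseudo-random draws from a single
seeded stream, in a fixed documented order, so cohorts are bitwise
reproducible and configurations sharing a seed share their underlying
standard-normal draws (location shifts act pointwise).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm as _truncnorm

from .score import ArchFlow, FetalEchoExam, ForamenOvaleFlow, ScoringModel, default_model, score_exam
from .validation import CohortRecord
from .zscores import CardiacStructure, ZScoreReference, synthetic_references, value_from_z

__all__ = [
    "NormalSpec",
    "LogNormalSpec",
    "TruncNormalSpec",
    "ClassSpec",
    "CohortConfig",
    "InvalidConfigError",
    "default_paper_like_config",
    "generate_cohort",
    "apply_inclusion_criteria",
    "config_manifest",
    "EXCLUSION_FLAGS",
]


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise InvalidConfigError("SD must be positive")


@dataclass(frozen=True)
class LogNormalSpec:
    log_mean: float
    log_sd: float

    def __post_init__(self):
        if self.log_sd <= 0:
            raise InvalidConfigError("log-SD must be positive")


@dataclass(frozen=True)
class TruncNormalSpec:
    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.sd <= 0:
            raise InvalidConfigError("SD must be positive")
        if not self.lower < self.upper:
            raise InvalidConfigError("truncation bounds must be ordered")

    def ppf(self, u: float) -> float:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return float(_truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd))


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise InvalidConfigError(f"{name} must lie strictly in (0, 1), got {value}")


@dataclass(frozen=True)
class ClassSpec:
    """Class-conditional generating distributions for one outcome class."""

    early_fraction: float
    aao_z: NormalSpec
    isthmus_3vt_z: NormalSpec
    mv_z: NormalSpec
    transverse_arch_z: NormalSpec
    pv_av: LogNormalSpec
    tv_mv: LogNormalSpec
    mpa_aao: LogNormalSpec
    rv_lv: LogNormalSpec
    isthmus_ductal_angle: NormalSpec
    csa_index: NormalSpec
    vsd_prob: float
    diffuse_arch_hypoplasia_prob: float
    rfop_prob_early: float
    rfop_prob_late: float

    def __post_init__(self):
        _check_fraction("early_fraction", self.early_fraction)
        for name in ("vsd_prob", "diffuse_arch_hypoplasia_prob"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1)")
        for name in ("rfop_prob_early", "rfop_prob_late"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    n: int
    prevalence: float
    seed: int
    ga_early: TruncNormalSpec
    ga_late: TruncNormalSpec
    coao: ClassSpec
    no_coao: ClassSpec
    plsvc_prob: float = 0.145
    arch_flow_probs: tuple[float, float, float] = (0.922, 0.05, 0.028)
    fo_left_to_right_prob: float = 0.006
    transaortic_velocity: NormalSpec = field(
        default_factory=lambda: NormalSpec(100.0, 20.0)
    )

    def __post_init__(self):
        if self.n < 1:
            raise InvalidConfigError("cohort size must be >= 1")
        _check_fraction("prevalence", self.prevalence)
        _check_fraction("plsvc_prob", self.plsvc_prob)
        if abs(sum(self.arch_flow_probs) - 1.0) > 1e-9:
            raise InvalidConfigError("arch_flow_probs must sum to 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "CohortConfig":
        def class_spec(d: Mapping) -> ClassSpec:
            return ClassSpec(
                early_fraction=d["early_fraction"],
                aao_z=NormalSpec(**d["aao_z"]),
                isthmus_3vt_z=NormalSpec(**d["isthmus_3vt_z"]),
                mv_z=NormalSpec(**d["mv_z"]),
                transverse_arch_z=NormalSpec(**d["transverse_arch_z"]),
                pv_av=LogNormalSpec(**d["pv_av"]),
                tv_mv=LogNormalSpec(**d["tv_mv"]),
                mpa_aao=LogNormalSpec(**d["mpa_aao"]),
                rv_lv=LogNormalSpec(**d["rv_lv"]),
                isthmus_ductal_angle=NormalSpec(**d["isthmus_ductal_angle"]),
                csa_index=NormalSpec(**d["csa_index"]),
                vsd_prob=d["vsd_prob"],
                diffuse_arch_hypoplasia_prob=d["diffuse_arch_hypoplasia_prob"],
                rfop_prob_early=d["rfop_prob_early"],
                rfop_prob_late=d["rfop_prob_late"],
            )

        return cls(
            n=int(doc["n"]),
            prevalence=float(doc["prevalence"]),
            seed=int(doc["seed"]),
            ga_early=TruncNormalSpec(**doc["ga_early"]),
            ga_late=TruncNormalSpec(**doc["ga_late"]),
            coao=class_spec(doc["coao"]),
            no_coao=class_spec(doc["no_coao"]),
            plsvc_prob=float(doc.get("plsvc_prob", 0.145)),
            arch_flow_probs=tuple(doc.get("arch_flow_probs", (0.922, 0.05, 0.028))),
            fo_left_to_right_prob=float(doc.get("fo_left_to_right_prob", 0.006)),
            transaortic_velocity=NormalSpec(
                **doc.get("transaortic_velocity", {"mean": 100.0, "sd": 20.0})
            ),
        )


def default_paper_like_config(seed: int = 0, n: int = 179) -> CohortConfig:
    """Cohort conditions emulating the published validation study.

    Prevalence 39/179 = 0.218; early-onset (<= 28 weeks) fraction 34/39 in
    the CoAo class and 34/140 in the non-CoAo class (68/179 overall);
    class-conditional z/ratio distributions chosen so that the four score
    criteria discriminate the classes.  These are calibration choices
    documented in the methods note, not reproductions of patient data.
    """
    return CohortConfig(
        n=n,
        prevalence=0.218,
        seed=seed,
        ga_early=TruncNormalSpec(mean=24.0, sd=3.0, lower=17.0, upper=28.0),
        ga_late=TruncNormalSpec(mean=33.0, sd=2.5, lower=28.1, upper=39.0),
        coao=ClassSpec(
            early_fraction=34 / 39,
            aao_z=NormalSpec(-2.2, 1.0),
            isthmus_3vt_z=NormalSpec(-2.5, 1.0),
            mv_z=NormalSpec(-1.5, 1.0),
            transverse_arch_z=NormalSpec(-1.8, 1.0),
            pv_av=LogNormalSpec(math.log(1.75), 0.15),
            tv_mv=LogNormalSpec(math.log(1.60), 0.12),
            mpa_aao=LogNormalSpec(math.log(1.90), 0.15),
            rv_lv=LogNormalSpec(math.log(1.70), 0.15),
            isthmus_ductal_angle=NormalSpec(105.0, 12.0),
            csa_index=NormalSpec(0.65, 0.15),
            vsd_prob=0.08,
            diffuse_arch_hypoplasia_prob=0.30,
            rfop_prob_early=0.03,
            rfop_prob_late=0.05,
        ),
        no_coao=ClassSpec(
            early_fraction=34 / 140,
            aao_z=NormalSpec(-0.8, 1.0),
            isthmus_3vt_z=NormalSpec(-1.2, 1.2),
            mv_z=NormalSpec(-0.3, 1.0),
            transverse_arch_z=NormalSpec(-0.3, 1.0),
            pv_av=LogNormalSpec(math.log(1.35), 0.18),
            tv_mv=LogNormalSpec(math.log(1.25), 0.12),
            mpa_aao=LogNormalSpec(math.log(1.40), 0.18),
            rv_lv=LogNormalSpec(math.log(1.30), 0.15),
            isthmus_ductal_angle=NormalSpec(125.0, 12.0),
            csa_index=NormalSpec(0.95, 0.20),
            vsd_prob=0.02,
            diffuse_arch_hypoplasia_prob=0.05,
            rfop_prob_early=0.05,
            rfop_prob_late=0.22,
        ),
    )


_MIN_DIAMETER_MM = 0.3  # floor keeping back-filled diameters physically positive


def _mm(structure: CardiacStructure, z: float, ga: float, refs) -> float:
    return max(value_from_z(z, ga, refs[structure]), _MIN_DIAMETER_MM)


def generate_cohort(
    config: CohortConfig,
    model: ScoringModel | None = None,
    zrefs: Mapping[CardiacStructure, ZScoreReference] | None = None,
) -> list[CohortRecord]:
    """Draw a fully populated, scored, labelled cohort.

    Each record's exam carries everything :func:`coascore.score.score_exam`
    and every evaluable comparator rule needs.  The draw order per record
    is fixed (outcome, onset, GA, z-scores, ratios, baselines, angles,
    qualitative findings), so a given (config, seed) is reproducible.
    """
    if model is None:
        model = default_model()
    if zrefs is None:
        zrefs = synthetic_references()
    rng = np.random.default_rng(config.seed)
    records: list[CohortRecord] = []
    for i in range(config.n):
        outcome = rng.random() < config.prevalence
        spec = config.coao if outcome else config.no_coao
        early = rng.random() < spec.early_fraction
        u_ga = rng.random()
        ga = (config.ga_early if early else config.ga_late).ppf(u_ga)

        aao_z = spec.aao_z.mean + spec.aao_z.sd * rng.standard_normal()
        isthmus_z = spec.isthmus_3vt_z.mean + spec.isthmus_3vt_z.sd * rng.standard_normal()
        sagittal_z = isthmus_z + 0.3 * rng.standard_normal()
        mv_z = spec.mv_z.mean + spec.mv_z.sd * rng.standard_normal()
        arch_z = spec.transverse_arch_z.mean + spec.transverse_arch_z.sd * rng.standard_normal()

        pv_av = math.exp(spec.pv_av.log_mean + spec.pv_av.log_sd * rng.standard_normal())
        tv_mv = math.exp(spec.tv_mv.log_mean + spec.tv_mv.log_sd * rng.standard_normal())
        mpa_aao = math.exp(spec.mpa_aao.log_mean + spec.mpa_aao.log_sd * rng.standard_normal())
        rv_lv = math.exp(spec.rv_lv.log_mean + spec.rv_lv.log_sd * rng.standard_normal())

        av_noise = rng.standard_normal()
        lv_noise = rng.standard_normal()
        da_z = rng.standard_normal()
        angle = spec.isthmus_ductal_angle.mean + spec.isthmus_ductal_angle.sd * rng.standard_normal()
        csa = max(spec.csa_index.mean + spec.csa_index.sd * rng.standard_normal(), 0.1)

        u_vsd = rng.random()
        u_plsvc = rng.random()
        u_rfop = rng.random()
        u_arch_flow = rng.random()
        u_fo = rng.random()
        velocity = config.transaortic_velocity.mean + config.transaortic_velocity.sd * rng.standard_normal()
        u_diffuse = rng.random()

        # back-fill raw diameters from z-scores / ratios via the synthetic refs
        aao_mm = _mm(CardiacStructure.AAO, aao_z, ga, zrefs)
        isthmus_mm = _mm(CardiacStructure.ISTHMUS_3VT, isthmus_z, ga, zrefs)
        sagittal_mm = _mm(CardiacStructure.ISTHMUS_SAGITTAL, sagittal_z, ga, zrefs)
        mv_mm = _mm(CardiacStructure.MV, mv_z, ga, zrefs)
        tv_mm = max(tv_mv * mv_mm, _MIN_DIAMETER_MM)
        mpa_mm = max(mpa_aao * aao_mm, _MIN_DIAMETER_MM)
        da_mm = _mm(CardiacStructure.DA, da_z, ga, zrefs)
        av_mm = max(value_from_z(0.0, ga, zrefs[CardiacStructure.AV]) + 0.3 * av_noise, _MIN_DIAMETER_MM)
        pv_mm = max(pv_av * av_mm, _MIN_DIAMETER_MM)
        lv_mm = max(mv_mm * (1.1 + 0.05 * lv_noise), _MIN_DIAMETER_MM)
        rv_mm = max(rv_lv * lv_mm, _MIN_DIAMETER_MM)

        rfop_prob = spec.rfop_prob_early if early else spec.rfop_prob_late
        p_ante, p_mixed, _ = config.arch_flow_probs
        if u_arch_flow < p_ante:
            arch_flow = ArchFlow.ANTEGRADE
        elif u_arch_flow < p_ante + p_mixed:
            arch_flow = ArchFlow.MIXED
        else:
            arch_flow = ArchFlow.REVERSED

        exam = FetalEchoExam(
            ga_weeks=ga,
            aao_z=aao_z,
            isthmus_3vt_z=isthmus_z,
            pv_mm=pv_mm,
            av_mm=av_mm,
            tv_mm=tv_mm,
            mv_mm=mv_mm,
            mpa_mm=mpa_mm,
            aao_mm=aao_mm,
            isthmus_3vt_mm=isthmus_mm,
            isthmus_sagittal_mm=sagittal_mm,
            da_3vt_mm=da_mm,
            rv_mm=rv_mm,
            lv_mm=lv_mm,
            mv_z=mv_z,
            tv_z=None,
            transverse_arch_z=arch_z,
            isthmus_ductal_angle_deg=angle,
            csa_index=csa,
            plsvc=u_plsvc < config.plsvc_prob,
            rfop=u_rfop < rfop_prob,
            diffuse_arch_hypoplasia=u_diffuse < spec.diffuse_arch_hypoplasia_prob,
            contraductal_shelf=False,
            vsd=u_vsd < spec.vsd_prob,
            aoisth_diastolic_flow_persistence=arch_flow is not ArchFlow.ANTEGRADE,
            arch_flow=arch_flow,
            fo_flow=(
                ForamenOvaleFlow.LEFT_TO_RIGHT
                if u_fo < config.fo_left_to_right_prob
                else ForamenOvaleFlow.RIGHT_TO_LEFT
            ),
            transaortic_peak_velocity=max(velocity, 10.0),
        )
        result = score_exam(exam, model)
        records.append(
            CohortRecord(
                record_id=f"SYN-{i:05d}",
                exam=exam,
                predicted_probability=result.post_test_probability,
                outcome_coao=bool(outcome),
            )
        )
    return records


EXCLUSION_FLAGS = (
    "chromosomal_abnormality",
    "growth_restriction",
    "associated_major_chd",
    "extrinsic_compression",
    "lost_follow_up",
)


def apply_inclusion_criteria(rows: Iterable) -> tuple[list, list[tuple[object, str]]]:
    """Keep rows with all exclusion flags false.

    Mirrors the study's eligibility: appropriate growth, no chromosomal
    abnormality, simple (isolated) suspected CoAo, no extrinsic cardiac
    compression, full postnatal follow-up.  Excluded rows carry the first
    matching reason in flag order.
    """
    included: list = []
    excluded: list[tuple[object, str]] = []
    for row in rows:
        reason = next(
            (flag for flag in EXCLUSION_FLAGS if getattr(row, flag, False)), None
        )
        if reason is None:
            included.append(row)
        else:
            excluded.append((row, reason))
    return included, excluded


def config_manifest(config: CohortConfig) -> dict:
    """Reproducibility manifest: the config, its seed, and a content digest."""
    doc = config.to_dict()
    payload = json.dumps(doc, sort_keys=True).encode()
    return {
        "config": doc,
        "seed": config.seed,
        "config_digest": hashlib.sha256(payload).hexdigest(),
    }
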