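"""Gestational-age z-scores for fetal cardiac dimensions.

A z-score expresses a measured dimension as the number of reference
standard deviations it lies from the mean predicted for the fetus's
gestational age.  Published reference equations differ in functional form,
so the module provides a generic framework: a reference is a polynomial
mean and a polynomial SD on either the identity or natural-log scale of
the measurement, valid over a declared predictor range, serialised as
JSON.  The coefficients shipped with the package are synthetic fixtures
for testing and simulation — they are NOT published normative equations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

from .score import FetalEchoExam

__all__ = [
    "CardiacStructure",
    "ZScoreReference",
    "MissingReferenceError",
    "compute_z",
    "value_from_z",
    "attach_zscores",
    "load_references",
    "dump_references",
    "synthetic_references",
]


class CardiacStructure(str, Enum):
    AAO = "aao"
    ISTHMUS_3VT = "isthmus_3vt"
    ISTHMUS_SAGITTAL = "isthmus_sagittal"
    PV = "pv"
    AV = "av"
    TV = "tv"
    MV = "mv"
    MPA = "mpa"
    DA = "da"


class MissingReferenceError(KeyError):
    def __init__(self, structure: CardiacStructure):
        self.structure = structure
        super().__init__(f"no z-score reference available for structure {structure.value!r}")


@dataclass(frozen=True)
class ZScoreReference:
    """Polynomial mean/SD reference for one cardiac structure.

    ``mean_coefficients`` and ``sd_coefficients`` are intercept-first
    polynomial coefficients in the predictor (gestational age in weeks, or
    femur length in mm), evaluated on the transformed measurement scale.
    """

    reference_id: str
    structure: CardiacStructure
    predictor: str  # "ga_weeks" or "femur_length_mm"
    transform: str  # "identity" or "log"
    predictor_range: tuple[float, float]
    mean_coefficients: tuple[float, ...]
    sd_coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.predictor not in ("ga_weeks", "femur_length_mm"):
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        lo, hi = self.predictor_range
        if not lo < hi:
            raise ValueError("predictor range bounds must be ordered")
        grid = np.linspace(lo, hi, 101)
        if np.any(self._sd(grid) <= 0):
            raise ValueError(
                f"SD polynomial of {self.reference_id!r} is not strictly "
                "positive over the declared predictor range"
            )

    def _mean(self, predictor_value):
        return np.polynomial.polynomial.polyval(
            predictor_value, self.mean_coefficients
        )

    def _sd(self, predictor_value):
        return np.polynomial.polynomial.polyval(predictor_value, self.sd_coefficients)

    def _check_predictor(self, predictor_value: float) -> None:
        lo, hi = self.predictor_range
        if not lo <= predictor_value <= hi:
            raise ValueError(
                f"predictor value {predictor_value} outside the declared range "
                f"[{lo}, {hi}] of reference {self.reference_id!r}"
            )

    def to_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "structure": self.structure.value,
            "predictor": self.predictor,
            "transform": self.transform,
            "range": list(self.predictor_range),
            "mean": list(self.mean_coefficients),
            "sd": list(self.sd_coefficients),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ZScoreReference":
        return cls(
            reference_id=doc["reference_id"],
            structure=CardiacStructure(doc["structure"]),
            predictor=doc["predictor"],
            transform=doc["transform"],
            predictor_range=tuple(doc["range"]),
            mean_coefficients=tuple(doc["mean"]),
            sd_coefficients=tuple(doc["sd"]),
        )


def compute_z(value: float, predictor_value: float, ref: ZScoreReference) -> float:
    """z = (t(value) − mean(predictor)) / SD(predictor), t identity or log."""
    ref._check_predictor(predictor_value)
    if value <= 0:
        raise ValueError(f"measured dimension must be positive, got {value}")
    t = math.log(value) if ref.transform == "log" else value
    return float((t - ref._mean(predictor_value)) / ref._sd(predictor_value))


def value_from_z(z: float, predictor_value: float, ref: ZScoreReference) -> float:
    """Inverse of :func:`compute_z`: the dimension at a given z for a predictor."""
    ref._check_predictor(predictor_value)
    t = ref._mean(predictor_value) + z * ref._sd(predictor_value)
    return float(math.exp(t) if ref.transform == "log" else t)


# exam z fields that attach_zscores may populate, with their raw-mm source
_ATTACHABLE = {
    CardiacStructure.AAO: ("aao_z", "aao_mm"),
    CardiacStructure.ISTHMUS_3VT: ("isthmus_3vt_z", "isthmus_3vt_mm"),
    CardiacStructure.MV: ("mv_z", "mv_mm"),
    CardiacStructure.TV: ("tv_z", "tv_mm"),
}


def attach_zscores(
    exam: FetalEchoExam, refs: Mapping[CardiacStructure, ZScoreReference]
) -> FetalEchoExam:
    """Fill empty z-score fields from raw diameters and gestational age.

    An explicitly provided z-score is never overwritten.  A raw diameter
    with no matching reference raises :class:`MissingReferenceError`.
    """
    changes: dict[str, float] = {}
    for structure, (z_field, mm_field) in _ATTACHABLE.items():
        if getattr(exam, z_field) is not None:
            continue
        raw = getattr(exam, mm_field)
        if raw is None:
            continue
        ref = refs.get(structure)
        if ref is None:
            raise MissingReferenceError(structure)
        changes[z_field] = compute_z(raw, exam.ga_weeks, ref)
    return exam.with_updates(**changes) if changes else exam


def load_references(path) -> dict[CardiacStructure, ZScoreReference]:
    with open(path) as fh:
        docs = json.load(fh)
    refs = [ZScoreReference.from_dict(d) for d in docs]
    return {r.structure: r for r in refs}


def dump_references(refs: Iterable[ZScoreReference] | Mapping, path) -> None:
    if isinstance(refs, Mapping):
        refs = refs.values()
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in refs], fh, indent=2)
        fh.write("\n")


_SYNTHETIC: dict[CardiacStructure, ZScoreReference] | None = None


def synthetic_references() -> dict[CardiacStructure, ZScoreReference]:
    """The packaged synthetic reference set (testing and simulation only)."""
    global _SYNTHETIC
    if _SYNTHETIC is None:
        with resources.files("coascore.data").joinpath("synthetic_zrefs.json").open() as fh:
            docs = json.load(fh)
        _SYNTHETIC = {
            (r := ZScoreReference.from_dict(d)).structure: r for d in docs
        }
    return dict(_SYNTHETIC)
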