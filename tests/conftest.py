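import numpy as np
import pytest

from coascore import (
    CohortRecord,
    FetalEchoExam,
    default_model,
    default_paper_like_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture
def complete_exam():
    """An exam with every field a comparator rule might need."""
    return FetalEchoExam(
        ga_weeks=24.0,
        aao_z=-2.1,
        isthmus_3vt_z=-2.4,
        pv_mm=6.0,
        av_mm=3.2,
        tv_mm=11.0,
        mv_mm=7.0,
        mpa_mm=9.5,
        aao_mm=4.5,
        isthmus_3vt_mm=2.0,
        da_3vt_mm=4.0,
        rv_mm=16.0,
        lv_mm=10.0,
        mv_z=-2.2,
        transverse_arch_z=-2.1,
        isthmus_ductal_angle_deg=100.0,
        csa_index=0.6,
        vsd=False,
        aoisth_diastolic_flow_persistence=True,
    )


@pytest.fixture(scope="session")
def paper_like_records():
    """Default study-like synthetic cohort (n=179, fixed seed)."""
    return generate_cohort(default_paper_like_config(seed=20210820))


def toy_records(scores_pos, scores_neg):
    """Minimal labelled records from raw score lists (GA fixed, exam minimal)."""
    exam = FetalEchoExam(ga_weeks=30.0, aao_z=0.0, isthmus_3vt_z=0.0, pv_mm=4.0, av_mm=4.0)
    records = []
    for i, s in enumerate(scores_pos):
        records.append(CohortRecord(f"P{i}", exam, s, outcome_coao=True))
    for i, s in enumerate(scores_neg):
        records.append(CohortRecord(f"N{i}", exam, s, outcome_coao=False))
    return records


@pytest.fixture
def make_records():
    return toy_records
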