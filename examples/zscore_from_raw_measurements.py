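"""Derive z-scores from raw diameters through a reference set.

The score consumes z-scores for the ascending aorta and the aortic
isthmus; when a cohort ships raw millimetre measurements instead, a
z-score reference (polynomial mean and SD against gestational age) fills
them in.  The packaged references are synthetic fixtures - swap in your
own published coefficients via the same JSON format for clinical use.
"""

from coascore import (
    CardiacStructure,
    FetalEchoExam,
    attach_zscores,
    compute_z,
    score_exam,
    synthetic_references,
)

refs = synthetic_references()
aao_ref = refs[CardiacStructure.AAO]
print(f"reference {aao_ref.reference_id}: mean(GA) = "
      f"{aao_ref.mean_coefficients[0]} + {aao_ref.mean_coefficients[1]}*GA mm")

exam = FetalEchoExam(ga_weeks=30.0, aao_mm=4.0, isthmus_3vt_mm=2.6, pv_mm=6.2, av_mm=3.6)
print(f"AAo 4.0 mm at 30 w -> z = {compute_z(4.0, 30.0, aao_ref):.3f}")

exam = attach_zscores(exam, refs)
print(f"attached: aao_z={exam.aao_z:.3f}, isthmus_3vt_z={exam.isthmus_3vt_z:.3f}")
result = score_exam(exam)
print(f"post-test probability: {result.post_test_probability:.4f}")
# Negative z-scores mean the vessel is smaller than expected for
# gestational age; here both left-sided measures are hypoplastic and the
# PV/AV ratio is raised, so the score lands in the high-risk range.
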