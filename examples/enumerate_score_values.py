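"""List every probability the discrete score can emit.

With four dichotomous criteria the score takes exactly 2^4 = 16 values;
this enumeration is the oracle behind the cohort-level analyses.
"""

from coascore import default_model, enumerate_profiles

for profile, result in enumerate_profiles(default_model()):
    states = "".join("+" if v else "-" for v in profile.as_dict().values())
    print(f"GA/AAo/Isthmus/PVAV {states}   "
          f"odds {result.post_test_odds:8.4f}   "
          f"probability {result.post_test_probability:.4f}")
# '+' marks a met criterion (GA <= 28 w, AAo z <= -1.5, isthmus z <= -2,
# PV/AV >= 1.6). Values range from ~2.6% (no criterion met) to ~97.3%
# (all four met); only the all-positive profile exceeds 96%.
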