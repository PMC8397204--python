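"""Score one fetus's first diagnostic echocardiography.

Builds an exam for a fetus referred at 24 weeks with a small ascending
aorta and isthmus and a raised PV/AV ratio, then prints the per-parameter
likelihood-ratio contributions and the post-test probability of
postnatally confirmed coarctation.
"""

from coascore import FetalEchoExam, default_model, score_exam

exam = FetalEchoExam(
    ga_weeks=24.0,       # decimal weeks at the first diagnostic scan
    aao_z=-2.1,          # ascending-aorta z-score
    isthmus_3vt_z=-2.4,  # aortic-isthmus z-score, 3VT view
    pv_mm=6.0,           # pulmonary-valve diameter
    av_mm=3.2,           # aortic-valve diameter -> PV/AV = 1.875
)

model = default_model()
result = score_exam(exam, model)

print(f"pre-test odds : {model.pretest_odds:.4f} (displayed {model.pretest_odds_display})")
for pid, lr in result.contributions.items():
    met = result.profile[pid]
    print(f"  {pid.value:<20s} criterion {'met    ' if met else 'not met'}  LR applied = {lr}")
print(f"post-test odds        : {result.post_test_odds:.4f}")
print(f"post-test probability : {result.post_test_probability:.4f} "
      f"({result.probability_percent()}%)")
# Each met criterion multiplies the odds by its LR+; each unmet one by its
# LR-. A probability this high puts the fetus in the top risk band, where
# postnatal confirmation of coarctation is very likely.
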