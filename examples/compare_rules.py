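"""Benchmark alternative published coarctation predictors on one cohort.

Evaluates every fully specified rule (threshold combinations, point
scores, composite indices) on the same synthetic cohort and prints each
rule's sensitivity and specificity.  Rules published without a complete
decision procedure are reported as skipped rather than guessed at.
"""

from coascore import benchmark_rules, default_paper_like_config, generate_cohort

records = generate_cohort(default_paper_like_config(seed=1))
results, skipped = benchmark_rules(records)

print(f"{'rule':<22s} {'Sn':>6s} {'Sp':>6s}")
for rule_id, m in sorted(results.items()):
    print(f"{rule_id:<22s} {100 * m.sensitivity.value:5.1f}% {100 * m.specificity.value:5.1f}%")
for rule_id, reason in skipped.items():
    print(f"{rule_id:<22s} skipped: {reason}")
# The synthetic generator is calibrated to the likelihood-ratio score's
# inputs, so comparator numbers here describe behaviour on *these*
# conditions only - they are not reproductions of the rules' source cohorts.
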