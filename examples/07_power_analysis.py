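"""Post-hoc power and required effect sizes for one-sided rank tests.

Mann-Whitney power is computed from the noncentral t distribution after
scaling Cohen's d by sqrt(A.R.E.) (3/pi for a normal parent); the same
machinery inverts to the effect size needed for 80% power.  Fisher-exact
power for two proportions is computed by full binomial enumeration.
"""

from isocohort import PowerSpec, fisher_power, wmw_power, wmw_required_d

designs = [
    ("inbreeding, 36 cases vs 176 controls, d = 0.43", PowerSpec(36, 176, 0.43)),
    ("homozygous load, 36 vs 107, d = 0.68", PowerSpec(36, 107, 0.68)),
    ("polygenic score, 36 vs 176, d = 0.45", PowerSpec(36, 176, 0.45)),
    ("score by ID status, 12 vs 24, d = 0.80", PowerSpec(12, 24, 0.80)),
]
for label, spec in designs:
    print(f"{label}: achieved power {wmw_power(spec):.2f}")

for n1, n2 in ((36, 176), (36, 107), (12, 24)):
    d = wmw_required_d(n1, n2, target_power=0.8)
    print(f"required d for 80% power with {n1} vs {n2}: {d:.2f}")

p = fisher_power(0.25, 0.05, 36, 107, alpha=0.05, tails=1)
print(f"Fisher power to detect carrier proportions 25% vs 5% (36 vs 107): {p:.2f}")
# Achieved power near 0.75-0.96 for the observed effects means moderate
# true effects are detectable at these sample sizes; effects below the
# required d would likely be missed.
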