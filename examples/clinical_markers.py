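"""Postprandial marker derivation on a simulated four-arm crossover trial.

Generates the trial table (50 subjects x 4 arms x 3 markers sampled at
0/3/6 h), normalizes each series to its own baseline, integrates the
trapezoidal AUC and compares arms with the permutation repeated-measures
ANOVA.
"""

from phytonet import SyntheticSpec, compare_arms, generate_clinical
from phytonet.clinical import auc_table, marker_responses

table, truth = generate_clinical(SyntheticSpec(seed=42))
responses = marker_responses(table)  # ratio-to-baseline, then trapezoid AUC
aucs = auc_table(responses)

for marker in ("TG", "closure_time"):
    comp = compare_arms(aucs, marker, n_permutations=2000, seed=0)
    means = "  ".join(
        f"{arm}={comp.means[arm]:.2f}{comp.letters[arm]}" for arm in comp.arms
    )
    print(f"{marker}: {means}")
    print(f"  F = {comp.f_statistic:.1f}, permutation p = {comp.p_permutation:.4f}")
# Mean AUCs are in baseline-ratio x hours; arms sharing a letter are not
# distinguishable at alpha = 0.05. The planted dose response suppresses the
# TG excursion (placebo highest) and elongates the platelet closure time
# (top dose highest), and both orderings are recovered.
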