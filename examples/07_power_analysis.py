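"""Minimal detectable difference: what could this experiment have seen?

Given a control dataset of per-image FRET indices, the permutation power
analysis estimates, for every sample size k, the smallest mean difference
a Welch test at alpha = 0.05 would detect with 80% power.  A closed-form
noncentral-t computation serves as the independent oracle.
"""

import numpy as np

from fretion import SampleSet, mdd_closed_form, mdd_permutation

rng = np.random.default_rng(0)
control = SampleSet("control", rng.normal(0.24, 0.008, 20))
print(f"dataset: n={control.n}, mean={control.mean:.4f}, sd={control.sd:.4f}")

curve = mdd_permutation(control, alpha=0.05, power=0.8,
                        n_permutations=2000, seed=1)

print(f"\n{'k':>4s} {'MDD (index)':>12s} {'MDD (% mean)':>13s} {'oracle':>10s}")
for k in (5, 10, 15, 20):
    row = curve.table.loc[curve.table["k"] == k].iloc[0]
    oracle = mdd_closed_form(control.sd, k)
    print(f"{k:4d} {row['mdd_units']:12.4f} {row['mdd_percent']:12.1f}% "
          f"{oracle:10.4f}")
print()
print("The detectable difference shrinks with sample size and tracks the")
print("noncentral-t oracle; at n=20 per arm, changes of a few percent of")
print("the mean index are resolvable — anything smaller is invisible.")
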