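"""Truth-free mixing diagnostic: cross-validate the phasing across subsets.

Phase random subsets of the cohort and count phase flips between runs for
individuals present in both.  Windows where flips pile up mark regions whose
phase rests on too few informative individuals — without needing any truth.
Here one individual is given a genotype-identical partner, and its flip
count stands out.
"""

import numpy as np

import mirrorphase as mp

spec = mp.ScenarioSpec(name="parents_only", n_parents=12, n_markers=100,
                       seed=8)
truth = mp.build_scenario(spec)
dosage = truth.genotypes.dosage.copy()
dosage[1] = dosage[0]  # individuals 0 and 1 now share genotypes everywhere
genotypes = mp.GenotypeMatrix(dosage=dosage)

flips = mp.crossval_flip_rate(
    genotypes, mp.PhasingConfig(n_iterations=8, mode="original", seed=1),
    k_subsets=3, holdout_fraction=0.25, window=25, seed=2)

per_ind = flips.groupby("individual")["flips"].sum()
print("phase flips between subset runs, per individual:")
for ind, count in per_ind.items():
    tag = "  <- genotype-duplicated pair" if ind in (0, 1) else ""
    print(f"  individual {ind:2d}: {count:3d} flips{tag}")
dup = per_ind.reindex([0, 1]).fillna(0).mean()
rest = per_ind.drop([0, 1], errors="ignore").median()
print(f"\nduplicated pair mean: {dup:.1f} flips; cohort median: {rest:.1f}")
print("High, unstable flip counts flag exactly the individuals whose phase")
print("the chain cannot anchor — the lock-in signature, detected truth-free.")
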