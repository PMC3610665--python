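"""Genotype-sharing run statistics across the four study designs.

Double sharing (identical genotypes over a region) is the lock-in hazard;
single sharing (no opposing homozygotes) is what copy-model phasing needs to
work at all.  Best-match lengths answer: from a random marker of a random
individual, how long is the longest run shared with someone else?
"""

import mirrorphase as mp

for name in ("parents_only", "with_children", "sibling_twins_half",
             "twins_all"):
    spec = mp.ScenarioSpec(name=name, n_parents=16, n_markers=300, seed=5)
    truth = mp.build_scenario(spec)
    _, double = mp.best_match_stats(truth.genotypes, "double")
    _, single = mp.best_match_stats(truth.genotypes, "single")
    print(f"{name:20s} N={truth.n_individuals:2d}  "
          f"double: mean {double['mean_best_match']:6.1f}, "
          f"longest {double['longest_run']:3d}   "
          f"single: mean {single['mean_best_match']:6.1f}")

print()
print("Twins push the mean double-sharing run to the full chromosome —")
print("the condition under which the plain sampler stops mixing.  Unrelated")
print("parents still show long single-sharing runs (the useful signal) but")
print("only short double-sharing ones.")
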