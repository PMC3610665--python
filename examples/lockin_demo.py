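"""The lock-in failure mode and the mirror-subtraction remedy.

Builds a cohort where every parent has a monozygotic twin (chromosome-wide
double genotype sharing), phases it with the plain backward sampler and with
mirror subtraction, and scores switch errors for the original parents
against the simulated truth.
"""

import numpy as np

import mirrorphase as mp

spec = mp.ScenarioSpec(name="twins_all", n_parents=16, n_markers=300, seed=1)
truth = mp.mask_every_second(mp.build_scenario(spec))
print(f"cohort: {truth.n_individuals} individuals "
      f"({spec.n_parents} parents, each with an identical twin), "
      f"{spec.n_markers} markers, every second marker masked")

for mode in ("original", "mirror"):
    cfg = mp.PhasingConfig(n_iterations=25, mode=mode, seed=1)
    result = mp.run_phasing(truth.genotypes, config=cfg)
    reports = mp.cohort_switch_errors(truth.haplotypes, result.haplotypes,
                                      truth.parent_indices(),
                                      truth.typed_markers())
    scored = sum(r.n_scored_sites for r in reports)
    total = mp.total_switch_errors(reports)
    print(f"{mode:8s}: {total:4d} switch errors over {scored} scored "
          f"heterozygous sites ({total / scored:.1%})")

print()
print("Each twin pair can explain the other's genotypes with ANY phase, so")
print("the plain sampler keeps re-copying the partner's random initial")
print("haplotypes — the error rate stays near the random-phase level.")
print("Subtracting each template pair's mirror weight removes exactly that")
print("uninformative mass, and the chain phases from the rest of the cohort.")
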