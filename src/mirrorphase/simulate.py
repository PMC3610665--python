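"""Synthetic cohorts with controlled double genotype sharing.

Founder haplotypes are mosaics of a small ancestral pool, which creates the
long single-haplotype-sharing tracts that copy-model phasing relies on.  On
top of the founder ("parents") cohort, three augmentations recreate the
conditions under which chain lock-in appears: trio children (double sharing
over the ~25% of the genome where siblings inherit the same two parental
haplotypes — here latent, between child and the couple), monozygotic
duplicates of half the parents (sibling-equivalent, chromosome-length double
sharing for half the cohort), and duplicates of every parent (the extreme
case).  Twins are copied at the *genotype* level after error injection, so
twin pairs are exactly identical by state at every marker.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, InputError, MarkerMap

SCENARIOS = ("parents_only", "with_children", "sibling_twins_half", "twins_all")


@dataclass
class ScenarioSpec:
    """Configuration of one synthetic dataset.

    Defaults give a dense-chip-like panel: 0.01 cM between adjacent markers,
    an ancestral pool of 8 haplotypes and a per-interval mosaic switch rate
    of 0.005, i.e. founder template tracts on the scale of a couple of cM —
    long single-haplotype sharing of the kind copy-model phasing needs.
    ``n_reference`` adds extra founder individuals drawn from the same
    ancestral pool that are not part of the study cohort; they serve as the
    phased reference panel for imputation experiments.
    """

    name: str = "parents_only"
    n_parents: int = 30
    n_markers: int = 1000
    ancestral_pool_size: int = 8
    mosaic_switch_rate: float = 0.005
    cm_per_interval: float = 0.01
    genotyping_error: float = 0.0
    seed: int = 0
    n_twins: int | None = None  # sibling_twins_half only; default n_parents // 2
    n_reference: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise InputError(f"unknown scenario {self.name!r}; expected one of {SCENARIOS}")
        if self.n_parents % 2:
            raise InputError("n_parents must be even (parents are paired as couples)")
        if self.ancestral_pool_size < 2:
            raise InputError("ancestral_pool_size must be at least 2")


@dataclass
class TruthSet:
    """A simulated cohort with full truth retained for scoring.

    ``genotypes`` is what the phaser sees (masked entries missing);
    ``truth_dosage`` keeps every genotype, and ``haplotypes`` the true phase.
    ``pedigree`` uses -1 for absent links.
    """

    haplotypes: np.ndarray  # (N, 2, M) int8
    pedigree: pd.DataFrame  # individual, father, mother, twin_of
    genotypes: GenotypeMatrix
    truth_dosage: np.ndarray  # (N, M) int8, never masked
    markers: MarkerMap
    spec: ScenarioSpec
    n_parents: int = 0
    reference_haplotypes: np.ndarray | None = None  # (n_reference, 2, M)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def parent_indices(self) -> np.ndarray:
        """The original parents — the individuals all metrics are reported on."""
        return np.arange(self.n_parents)

    def typed_markers(self) -> np.ndarray:
        """Boolean vector marking unmasked markers (the phase-scoreable ones:
        a marker missing in every individual carries no phase signal)."""
        typed = np.ones(self.markers.n_markers, dtype=bool)
        typed[self.genotypes.mask] = False
        return typed


def simulate_founders(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """(2 * (n_parents + n_reference), M) founder haplotypes: pool mosaics.

    Each haplotype copies one of ``ancestral_pool_size`` i.i.d.
    frequency-0.5 ancestors, jumping to a uniformly drawn ancestor (possibly
    the same) with probability ``mosaic_switch_rate`` per interval, giving
    template tracts of expected length 1 / (rate * (1 - 1/pool)) intervals
    and abundant pairwise single-haplotype sharing.
    """
    pool = (rng.random((spec.ancestral_pool_size, spec.n_markers)) < 0.5
            ).astype(np.int8)
    n_haps = 2 * (spec.n_parents + spec.n_reference)
    templates = np.empty((n_haps, spec.n_markers), dtype=np.int64)
    templates[:, 0] = rng.integers(0, spec.ancestral_pool_size, n_haps)
    jumps = rng.random((n_haps, spec.n_markers - 1)) < spec.mosaic_switch_rate
    draws = rng.integers(0, spec.ancestral_pool_size,
                         (n_haps, spec.n_markers - 1))
    for m in range(1, spec.n_markers):
        templates[:, m] = np.where(jumps[:, m - 1], draws[:, m - 1],
                                   templates[:, m - 1])
    return pool[templates, np.arange(spec.n_markers)[None, :]]


def make_child(parent1: np.ndarray, parent2: np.ndarray, markers: MarkerMap,
               rng: np.random.Generator,
               return_origins: bool = False):
    """One child: a recombinant gamete from each parent.

    Crossovers fall between adjacent markers with the Haldane map-function
    probability (1 - exp(-2 d / 100)) / 2 for d cM of map distance; the
    starting chromatid is a fair coin per gamete.
    """
    parent1 = np.asarray(parent1, dtype=np.int8)
    parent2 = np.asarray(parent2, dtype=np.int8)
    m = parent1.shape[1]
    if parent2.shape[1] != m or markers.n_markers != m:
        raise InputError("parents and marker map disagree on marker count")
    d = np.diff(np.asarray(markers.position_cm, dtype=float))
    cross_p = (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0
    child = np.empty((2, m), dtype=np.int8)
    origins = np.empty((2, m), dtype=np.int8)
    for g, parent in enumerate((parent1, parent2)):
        chrom = np.empty(m, dtype=np.int8)
        chrom[0] = rng.integers(0, 2)
        flips = rng.random(m - 1) < cross_p
        chrom[1:] = (chrom[0] + np.cumsum(flips)) % 2
        child[g] = parent[chrom, np.arange(m)]
        origins[g] = chrom
    if return_origins:
        return child, origins
    return child


def _dosage_with_error(haps: np.ndarray, error: float,
                       rng: np.random.Generator) -> np.ndarray:
    if error <= 0:
        return haps.sum(axis=1).astype(np.int8)
    flips = rng.random(haps.shape) < error
    return np.bitwise_xor(haps, flips.astype(np.int8)).sum(axis=1).astype(np.int8)


def build_scenario(spec: ScenarioSpec) -> TruthSet:
    """Assemble a scenario's truth haplotypes, pedigree and genotypes."""
    rng = np.random.default_rng(spec.seed)
    markers = MarkerMap.uniform(spec.n_markers, spec.cm_per_interval)
    founders = simulate_founders(spec, rng)
    parents = founders[: 2 * spec.n_parents].reshape(spec.n_parents, 2,
                                                     spec.n_markers)
    reference = (founders[2 * spec.n_parents:].reshape(spec.n_reference, 2,
                                                       spec.n_markers)
                 if spec.n_reference else None)

    haps = [parents]
    ped = [{"individual": i, "father": -1, "mother": -1, "twin_of": -1}
           for i in range(spec.n_parents)]
    twin_sources: list[int] = []

    if spec.name == "with_children":
        children = np.stack([
            make_child(parents[2 * c], parents[2 * c + 1], markers, rng)
            for c in range(spec.n_parents // 2)
        ])
        haps.append(children)
        for c in range(spec.n_parents // 2):
            ped.append({"individual": spec.n_parents + c, "father": 2 * c,
                        "mother": 2 * c + 1, "twin_of": -1})
    elif spec.name in ("sibling_twins_half", "twins_all"):
        n_twins = (spec.n_parents if spec.name == "twins_all"
                   else (spec.n_twins if spec.n_twins is not None
                         else spec.n_parents // 2))
        if not 0 < n_twins <= spec.n_parents:
            raise InputError("n_twins must lie in (0, n_parents]")
        twin_sources = list(range(n_twins))
        haps.append(parents[twin_sources].copy())
        for t, src in enumerate(twin_sources):
            ped.append({"individual": spec.n_parents + t, "father": -1,
                        "mother": -1, "twin_of": src})

    haplotypes = np.concatenate(haps, axis=0)
    n = haplotypes.shape[0]
    dosage = _dosage_with_error(haplotypes[:spec.n_parents
                                           + (len(ped) - spec.n_parents
                                              if spec.name == "with_children" else 0)],
                                spec.genotyping_error, rng)
    if twin_sources:
        # twins copy the template's *post-error* genotypes: identity by state
        # holds exactly, as when duplicating real genotype records
        dosage = np.concatenate([dosage, dosage[twin_sources]], axis=0)
    assert dosage.shape[0] == n
    genotypes = GenotypeMatrix(dosage=dosage.copy())
    return TruthSet(
        haplotypes=haplotypes,
        pedigree=pd.DataFrame(ped),
        genotypes=genotypes,
        truth_dosage=dosage.copy(),
        markers=markers,
        spec=spec,
        n_parents=spec.n_parents,
        reference_haplotypes=reference,
    )


def mask_every_second(truth: TruthSet) -> TruthSet:
    """Clear every second marker (odd 0-based indices) for imputation testing.

    The cleared entries become missing in ``genotypes``; ``truth_dosage``
    keeps the original values for scoring.
    """
    m = truth.markers.n_markers
    if m < 2:
        raise InputError("masking needs at least 2 markers")
    mask = np.arange(1, m, 2, dtype=np.int64)
    dosage = truth.truth_dosage.copy()
    dosage[:, mask] = MISSING
    genotypes = GenotypeMatrix(dosage=dosage, mask=mask,
                               sample_ids=truth.genotypes.sample_ids)
    return replace(truth, genotypes=genotypes)


def unmask(truth: TruthSet) -> TruthSet:
    """Inverse of :func:`mask_every_second`: restore the cleared genotypes."""
    genotypes = GenotypeMatrix(dosage=truth.truth_dosage.copy(),
                               sample_ids=truth.genotypes.sample_ids)
    return replace(truth, genotypes=genotypes)
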