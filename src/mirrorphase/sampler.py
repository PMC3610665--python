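"""Backward sampling of template-pair paths, with optional mirror subtraction.

The failure mode this module exists to break: when two study individuals
carry identical genotypes over a long region (siblings share both haplotypes
over ~1/4 of their genome; monozygotic twins everywhere), *any* haplotype
resolution of one dominates the posterior of the other.  The pair copying the
other individual's two haplotypes and its mirror (the same two haplotypes in
swapped order) get equal forward mass, the two individuals keep resampling
each other, and the chain freezes near its random initialization.

The remedy subtracts the mirror pair's weight from each pair's sampling
weight — w'(j,k) = max(w(j,k) - w(mate(j), mate(k)), eps) — before drawing.
A pair that carries no phase information beyond its mirror is floored to a
small eps, so haplotypes from other individuals can be sampled instead.
Only the sampling distribution changes; the model itself is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import backward_sample_kernel, mirror_adjust_kernel
from .model import MISSING, ForwardMatrix, HMMParams, InputError, PoolView

MODES = ("original", "mirror")


@dataclass
class StatePath:
    """A sampled trajectory of ordered template pairs, one per marker."""

    states: np.ndarray  # (M, 2) local pool indices

    @property
    def n_markers(self) -> int:
        return self.states.shape[0]


@dataclass
class SampledHaplotypes:
    """One genotype-consistent haplotype pair read off a sampled path.

    ``mismatch_count`` counts template alleles that conflicted with the
    observed genotype (per allele, at non-missing sites); it feeds the
    miscopy-rate update.  ``switch_count_per_interval`` counts template-index
    changes summed over the two chromatids; it feeds the theta update.
    """

    hap1: np.ndarray
    hap2: np.ndarray
    mismatch_count: int
    switch_count_per_interval: np.ndarray  # (M-1,) int


def mirror_adjust(weights: np.ndarray, mate: np.ndarray,
                  epsilon_rel: float) -> np.ndarray:
    """Mirror-subtract a K x K weight array and renormalize to sum 1.

    For every pair (j, k) whose templates both have mates, the mirror pair's
    weight is subtracted and the result floored at eps_abs = epsilon_rel
    times the total input weight.  Pairs with an unmated template pass
    through unchanged.  No state's weight ever reaches exactly zero: the
    exclusion is numerical, not logical.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InputError("weights must be a square K x K array")
    if np.any(w < 0):
        raise InputError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise InputError("weights must not be all zero")
    out = np.empty_like(w)
    mirror_adjust_kernel(w, np.asarray(mate, dtype=np.int64), epsilon_rel, out)
    return out / out.sum()


def sample_paths(fwd: ForwardMatrix, pool: PoolView, params: HMMParams,
                 mode: str, rng: np.random.Generator, n_samples: int = 1,
                 mirror_full_weight: bool = False,
                 mirror_on_reference: bool = True) -> np.ndarray:
    """Draw ``n_samples`` state paths; returns an (n, M, 2) index array.

    Sampling starts at the last marker from weights proportional to the final
    forward slice, then walks backwards drawing from
    w(j, k) = F[m](j, k) * T(j -> j_next) * T(k -> k_next).  In mirror mode
    the *forward* slice is mirror-adjusted at every marker before the
    transition factor is applied — on the forward probabilities the
    pair/mirror symmetry of a double-sharing competitor holds everywhere, so
    the feedback loop is cancelled no matter which state the walk is in.
    ``mirror_full_weight`` instead adjusts the complete backward weight, a
    comparison variant that is ineffective once a copy pair has been entered
    (the stay transition breaks the symmetry).
    """
    if mode not in MODES:
        raise InputError(f"unknown sampling mode {mode!r}; expected one of {MODES}")
    if fwd.K != pool.K:
        raise InputError("forward matrix and pool disagree on K")
    mate = pool.mate_map(include_fixed=mirror_on_reference)
    paths = np.empty((n_samples, fwd.n_markers, 2), dtype=np.int64)
    backward_sample_kernel(
        fwd.F, np.asarray(params.theta, dtype=float), mate,
        params.epsilon_rel, mode == "mirror", mirror_full_weight,
        rng, paths,
    )
    return paths


def backward_sample(fwd: ForwardMatrix, pool: PoolView, params: HMMParams,
                    mode: str, rng: np.random.Generator,
                    mirror_full_weight: bool = False,
                    mirror_on_reference: bool = True) -> StatePath:
    """Sample one template-pair path (see :func:`sample_paths`)."""
    paths = sample_paths(fwd, pool, params, mode, rng, 1,
                         mirror_full_weight, mirror_on_reference)
    return StatePath(states=paths[0])


def haplotypes_from_path(path: StatePath, pool: PoolView,
                         genotypes_i: np.ndarray,
                         rng: np.random.Generator) -> SampledHaplotypes:
    """Turn a sampled template path into a genotype-consistent haplotype pair.

    Homozygous sites are forced to the genotype's allele; heterozygous sites
    take their orientation from the ordered template alleles when those
    differ, and a fair coin when they agree (a template mismatch — the
    templates cannot explain the het without a miscopy).  Missing sites copy
    the templates.  The output always satisfies hap1 + hap2 = dosage at every
    non-missing marker.
    """
    g = np.asarray(genotypes_i, dtype=np.int8)
    m = len(g)
    if path.n_markers != m:
        raise InputError("path and genotype vector disagree on marker count")
    idx = np.arange(m)
    t1 = pool.alleles[path.states[:, 0], idx].astype(np.int8)
    t2 = pool.alleles[path.states[:, 1], idx].astype(np.int8)
    h1 = t1.copy()
    h2 = t2.copy()

    hom0 = g == 0
    hom2 = g == 2
    het = g == 1
    h1[hom0] = 0
    h2[hom0] = 0
    h1[hom2] = 1
    h2[hom2] = 1
    mismatches = int(np.count_nonzero(t1[hom0]) + np.count_nonzero(t2[hom0])
                     + np.count_nonzero(t1[hom2] == 0)
                     + np.count_nonzero(t2[hom2] == 0))

    informative = het & (t1 != t2)
    h1[informative] = t1[informative]
    h2[informative] = t2[informative]
    ambiguous = np.nonzero(het & (t1 == t2))[0]
    # one stream draw per template-equal het site, in marker order
    for site in ambiguous:
        first = 1 if rng.random() < 0.5 else 0
        h1[site] = first
        h2[site] = 1 - first
        mismatches += 1

    switches = ((path.states[1:, 0] != path.states[:-1, 0]).astype(np.int64)
                + (path.states[1:, 1] != path.states[:-1, 1]))
    out = SampledHaplotypes(hap1=h1, hap2=h2, mismatch_count=mismatches,
                            switch_count_per_interval=switches)
    nonmiss = g != MISSING
    assert np.array_equal((h1 + h2)[nonmiss], g[nonmiss]), \
        "sampled haplotypes inconsistent with genotypes"
    return out
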