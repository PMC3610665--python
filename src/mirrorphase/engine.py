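"""Iterative MCMC phasing driver.

Haplotypes start from a random genotype-consistent initialization.  Each
iteration visits every study individual in a fresh random order, re-samples
its haplotype pair from the pair HMM conditioned on everyone else's current
haplotypes (plus any phased references), and writes the sample back.  The
template-switch probabilities and the miscopy rate are re-estimated from the
sampled paths between iterations.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .model import (MISSING, ConfigurationError, GenotypeMatrix, HMMParams,
                    HaplotypePool, InputError, forward)
from .sampler import backward_sample, haplotypes_from_path

logger = logging.getLogger("mirrorphase")

OUTPUT_RULES = ("final_sample", "consensus")


@dataclass
class PhasingConfig:
    """Knobs of the phasing chain.

    ``mode`` selects the backward-sampling rule: ``"original"`` (plain
    posterior path sampling) or ``"mirror"`` (mirror-subtraction, robust to
    double genotype sharing).  Defaults: 60 iterations covers near-asymptotic
    behavior at desk scale; theta_init 0.01 per interval and e_init 0.005 are
    loose starting values that the per-iteration updates overwrite.
    """

    n_iterations: int = 60
    mode: str = "original"
    seed: int = 0
    theta_init: float = 0.01
    e_init: float = 0.005
    update_params: bool = True
    output_rule: str = "final_sample"
    epsilon_rel: float = 1e-10
    keep_last: int = 10  # ring size for the consensus output rule
    mirror_full_weight: bool = False  # comparison variant; see sampler docs
    mirror_on_reference: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be at least 1")
        if self.mode not in ("original", "mirror"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.output_rule not in OUTPUT_RULES:
            raise InputError(f"unknown output_rule {self.output_rule!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhasingResult:
    """Final haplotypes plus estimated parameters and per-iteration diagnostics.

    ``trace`` has one row per iteration with the total sampled template
    switches, template-vs-output allele mismatches, and the parameter values
    in force *during* that iteration — a stalling chain shows up as switch
    totals that stop moving.
    """

    haplotypes: np.ndarray  # (N, 2, M) int8
    params_final: HMMParams
    trace: pd.DataFrame
    config: PhasingConfig
    sample_ids: list[str]
    samples_kept: list[np.ndarray] | None = None

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]


def initialize_haplotypes(genotypes: GenotypeMatrix,
                          rng: np.random.Generator) -> HaplotypePool:
    """Random genotype-consistent starting haplotypes.

    Homozygous sites are forced; heterozygous sites get a fair-coin
    orientation; missing sites draw each allele from the marker's observed
    alternate-allele frequency (0.5 when nothing is observed).
    """
    n, m = genotypes.dosage.shape
    if n < 2:
        raise ConfigurationError("phasing needs at least 2 study individuals")
    d = genotypes.dosage
    observed = d != MISSING
    with np.errstate(invalid="ignore"):
        counts = observed.sum(axis=0)
        freq = np.where(counts > 0,
                        np.where(observed, d, 0).sum(axis=0) / np.maximum(2 * counts, 1),
                        0.5)
    haps = np.empty((n, 2, m), dtype=np.int8)
    coin = rng.random((n, m)) < 0.5
    miss_draw = rng.random((n, 2, m))
    for c in range(2):
        haps[:, c, :] = np.where(d == 2, 1, 0)
    het = d == 1
    haps[:, 0, :][het] = coin[het]
    haps[:, 1, :][het] = 1 - coin[het]
    miss = d == MISSING
    for c in range(2):
        haps[:, c, :][miss] = (miss_draw[:, c, :] < freq[None, :])[miss]
    return HaplotypePool.from_individuals(haps, fixed=False)


def update_theta(switch_counts: np.ndarray, n_transits: int,
                 floor: float = HMMParams.THETA_FLOOR,
                 ceil: float = HMMParams.THETA_CEIL) -> np.ndarray:
    """Per-interval switch-rate estimate from one iteration's sampled paths.

    theta_m = (c_m + 1/2) / (n_transits + 1), clamped; c_m sums template
    changes over chromatids, n_transits = 2 x individuals updated.  The
    half-count prior keeps early iterations away from degenerate estimates.
    """
    c = np.asarray(switch_counts, dtype=float)
    return np.clip((c + 0.5) / (n_transits + 1), floor, ceil)


def update_error_rate(mismatch_total: int, comparisons_total: int,
                      floor: float = HMMParams.ERROR_FLOOR,
                      ceil: float = HMMParams.ERROR_CEIL) -> float:
    """Miscopy-rate estimate: mismatching template alleles per comparison."""
    return float(np.clip((mismatch_total + 0.5) / (comparisons_total + 1),
                         floor, ceil))


def run_phasing(genotypes: GenotypeMatrix,
                reference: HaplotypePool | None = None,
                config: PhasingConfig | None = None) -> PhasingResult:
    """Run the MCMC phasing chain and return the final haplotype estimate.

    With a ``reference`` pool its (fixed, phased) haplotypes join every
    individual's conditioning pool but are never re-sampled.  The default
    output rule scores the last sampled haplotypes; ``consensus`` majority-
    votes heterozygous orientations over the last ``keep_last`` samples.
    """
    config = config or PhasingConfig()
    n, m = genotypes.dosage.shape
    rng = np.random.default_rng(config.seed)
    pool = initialize_haplotypes(genotypes, rng)
    if reference is not None:
        if reference.n_markers != m:
            raise InputError(
                f"reference pool has {reference.n_markers} markers, study has {m}"
            )
        alleles = np.vstack([pool.alleles, reference.alleles])
        owner = np.concatenate([pool.owner, reference.owner + n])
        ref_mate = np.where(reference.mate >= 0,
                            reference.mate + 2 * n, -1)
        mate = np.concatenate([pool.mate, ref_mate])
        fixed = np.concatenate([pool.fixed, np.ones(reference.n_haplotypes, bool)])
        pool = HaplotypePool(alleles, owner, mate, fixed)

    params = HMMParams.uniform(m, config.theta_init, config.e_init,
                               config.epsilon_rel)
    trace_rows = []
    ring: list[np.ndarray] = []
    for it in range(config.n_iterations):
        perm = rng.permutation(n)
        switch_counts = np.zeros(m - 1, dtype=np.int64)
        mismatches = 0
        comparisons = 0
        for i in perm:
            view = pool.view_excluding(int(i))
            fwd = forward(genotypes.dosage[i], view, params)
            path = backward_sample(
                fwd, view, params, config.mode, rng,
                mirror_full_weight=config.mirror_full_weight,
                mirror_on_reference=config.mirror_on_reference,
            )
            sh = haplotypes_from_path(path, view, genotypes.dosage[i], rng)
            pool.alleles[2 * i] = sh.hap1
            pool.alleles[2 * i + 1] = sh.hap2
            switch_counts += sh.switch_count_per_interval
            mismatches += sh.mismatch_count
            comparisons += 2 * int(np.count_nonzero(genotypes.dosage[i] != MISSING))
        trace_rows.append({
            "iteration": it,
            "switch_total": int(switch_counts.sum()),
            "mismatch_total": mismatches,
            "theta_mean": float(np.mean(params.theta)),
            "error_rate": params.error_rate,
        })
        logger.info("iter %d: %d template switches, %d mismatches, "
                    "theta_mean=%.3g, e=%.3g", it, int(switch_counts.sum()),
                    mismatches, float(np.mean(params.theta)), params.error_rate)
        if config.update_params:
            theta = update_theta(switch_counts, 2 * n)
            if np.any(theta >= HMMParams.THETA_CEIL):
                logger.warning(
                    "theta hit its ceiling at %d interval(s); downstream "
                    "imputation from these estimates may behave poorly",
                    int(np.sum(theta >= HMMParams.THETA_CEIL)))
            params = HMMParams(theta,
                               update_error_rate(mismatches, comparisons),
                               config.epsilon_rel)
        if (config.output_rule == "consensus"
                and it >= config.n_iterations - config.keep_last):
            ring.append(pool.alleles[:2 * n].reshape(n, 2, m).copy())

    final = pool.alleles[:2 * n].reshape(n, 2, m).copy()
    if config.output_rule == "consensus":
        final = consensus_haplotypes(ring)
    return PhasingResult(
        haplotypes=final,
        params_final=params,
        trace=pd.DataFrame(trace_rows),
        config=config,
        sample_ids=list(genotypes.sample_ids),
        samples_kept=ring if config.output_rule == "consensus" else None,
    )


def consensus_haplotypes(samples: list[np.ndarray]) -> np.ndarray:
    """Majority-vote haplotypes over a ring of kept samples.

    Each sample is first aligned to the ring's first sample by the wholesale
    pair orientation that maximizes heterozygous-site agreement; sites then
    vote per allele, ties going to the first sample.
    """
    if not samples:
        raise ConfigurationError("consensus requires at least one kept sample")
    ref = samples[0]
    n, _, m = ref.shape
    votes1 = np.zeros((n, m), dtype=np.int64)
    votes2 = np.zeros((n, m), dtype=np.int64)
    for s in samples:
        aligned = s.copy()
        for i in range(n):
            het = (ref[i, 0] != ref[i, 1]) & (s[i, 0] != s[i, 1])
            if het.any():
                agree = np.mean(s[i, 0, het] == ref[i, 0, het])
                if agree < 0.5:
                    aligned[i] = s[i, ::-1]
        votes1 += aligned[:, 0, :]
        votes2 += aligned[:, 1, :]
    half = len(samples) / 2.0
    out = np.empty_like(ref)
    # strict majority flips an allele away from the first sample; exact ties keep it
    out[:, 0, :] = np.where(votes1 > half, 1, np.where(votes1 < half, 0, ref[:, 0, :]))
    out[:, 1, :] = np.where(votes2 > half, 1, np.where(votes2 < half, 0, ref[:, 1, :]))
    return out
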