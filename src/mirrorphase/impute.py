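"""Minimac-style haploid imputation against a fixed phased panel.

Pre-phasing splits the work: the study cohort is phased on its own, then
each resulting haplotype is treated as error-free and run through a haploid
Li & Stephens chain over the reference panel, which is cheap even for large
panels.  Masked sites emit nothing; their alternate-allele posterior is read
off the state posterior, error-adjusted per template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import haploid_posteriors_kernel
from .model import (MISSING, ConfigurationError, GenotypeMatrix, HMMParams,
                    HaplotypePool, InputError)


@dataclass
class ImputationResult:
    """Posterior dosages and hard calls at the masked markers.

    ``dosage_posterior`` holds P(allele = 1) per study haplotype and masked
    site; ``best_guess`` the hard calls (posterior > 0.5; an exact tie calls
    allele 0); ``error_count`` the allele mismatches against truth when truth
    was supplied, each masked genotype contributing 0, 1 or 2.
    """

    mask: np.ndarray  # masked marker indices, sorted
    dosage_posterior: np.ndarray  # (N, 2, n_masked)
    best_guess: np.ndarray  # (N, 2, n_masked) int8
    error_count: int | None = None

    @property
    def imputed_dosage(self) -> np.ndarray:
        """(N, n_masked) hard-call genotype dosages at the masked sites."""
        return self.best_guess.sum(axis=1).astype(np.int8)


def impute_haplotype(hap: np.ndarray, panel: HaplotypePool,
                     params: HMMParams) -> np.ndarray:
    """Alternate-allele posterior at every site for one study haplotype.

    ``hap`` uses -1 at masked/untyped sites.  The chain copies panel
    haplotypes with per-interval switch probability theta and per-allele
    miscopy rate e; the returned probability at site m is
    sum_j post_m(j) * (a_j (1-e) + (1-a_j) e).
    """
    if panel.n_haplotypes < 1:
        raise ConfigurationError("imputation panel is empty")
    hap = np.asarray(hap, dtype=np.int8)
    m = len(hap)
    if panel.n_markers != m:
        raise InputError("haplotype and panel disagree on marker count")
    post = np.empty((m, panel.n_haplotypes))
    haploid_posteriors_kernel(
        np.ascontiguousarray(panel.alleles), hap,
        np.asarray(params.theta, dtype=float), params.error_rate, post,
    )
    e = params.error_rate
    adj = np.where(panel.alleles == 1, 1.0 - e, e)  # (Kp, M)
    return np.einsum("mj,jm->m", post, adj)


def impute_dataset(haplotypes: np.ndarray, panel: HaplotypePool,
                   mask: np.ndarray, params: HMMParams,
                   truth: GenotypeMatrix | np.ndarray | None = None) -> ImputationResult:
    """Impute every study haplotype at the masked markers.

    ``haplotypes`` is the (N, 2, M) pre-phased study set; alleles at masked
    sites are ignored (re-set to missing before the haploid pass).  ``truth``,
    when given, is the unmasked dosage matrix used for error counting.
    """
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    n, _, m = haplotypes.shape
    mask = np.unique(np.asarray(mask, dtype=np.int64))
    if len(mask) and (mask[0] < 0 or mask[-1] >= m):
        raise InputError("mask indices out of marker range")
    posterior = np.empty((n, 2, len(mask)))
    best = np.empty((n, 2, len(mask)), dtype=np.int8)
    for i in range(n):
        for c in range(2):
            hap = haplotypes[i, c].copy()
            hap[mask] = MISSING
            p = impute_haplotype(hap, panel, params)[mask]
            posterior[i, c] = p
            best[i, c] = (p > 0.5).astype(np.int8)
    result = ImputationResult(mask=mask, dosage_posterior=posterior,
                              best_guess=best)
    if truth is not None:
        truth_dosage = truth.dosage if isinstance(truth, GenotypeMatrix) else np.asarray(truth)
        if truth_dosage.shape != (n, m):
            raise InputError("truth matrix misaligned with study haplotypes")
        td = truth_dosage[:, mask].astype(np.int64)
        imput = result.imputed_dosage.astype(np.int64)
        valid = td != MISSING
        result.error_count = int(np.abs(td - imput)[valid].sum())
    return result
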