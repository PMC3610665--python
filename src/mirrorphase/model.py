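"""Li & Stephens haplotype-pair HMM.

A study individual's unordered genotypes are modelled as an imperfect mosaic
copy of an *ordered pair* of template haplotypes drawn from a pool (the other
study individuals' current haplotypes plus any phased references).  Template
switches between adjacent markers stand in for historical recombination; a
per-allele miscopy rate absorbs genotyping error and mutation.

The pair state space is the full ordered product (K x K states for a pool of
K haplotypes).  Forward probabilities are kept in natural space and
renormalized at every marker; the per-marker scale factors multiply back to
the data likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import pair_forward_kernel

#: Sentinel for a missing genotype dosage.
MISSING: int = -1


class PhasingError(Exception):
    """Base class for errors raised by this package."""


class InputError(PhasingError, ValueError):
    """Malformed or inconsistent user input."""


class ConfigurationError(PhasingError, ValueError):
    """A configuration that cannot be run (e.g. pool too small)."""


class DegenerateLikelihoodError(PhasingError):
    """The forward pass hit a marker where every pair state has zero mass.

    Only possible with a zero miscopy rate; the message names the marker.
    """


@dataclass(frozen=True)
class MarkerMap:
    """Physical and genetic coordinates of the biallelic markers.

    Alleles are coded 0 (reference) / 1 (alternate) throughout the package.
    """

    marker_id: np.ndarray  # dtype=object / str, length M
    position_bp: np.ndarray  # int, strictly increasing
    position_cm: np.ndarray  # float, non-decreasing

    def __post_init__(self) -> None:
        bp = np.asarray(self.position_bp)
        cm = np.asarray(self.position_cm, dtype=float)
        if len(bp) != len(cm) or len(bp) != len(self.marker_id):
            raise InputError("marker map fields must have equal length")
        if len(bp) >= 2:
            if not np.all(np.diff(bp) > 0):
                raise InputError("marker positions (bp) must be strictly increasing")
            if not np.all(np.diff(cm) >= 0):
                raise InputError("marker positions (cM) must be non-decreasing")

    @property
    def n_markers(self) -> int:
        return len(self.position_bp)

    @classmethod
    def uniform(cls, n_markers: int, cm_per_interval: float = 0.01,
                bp_per_interval: int = 10_000) -> "MarkerMap":
        """Evenly spaced map, dense-chip-like by default (0.01 cM between markers)."""
        ids = np.array([f"m{i}" for i in range(n_markers)], dtype=object)
        bp = np.arange(n_markers, dtype=np.int64) * bp_per_interval + 1
        cm = np.arange(n_markers, dtype=float) * cm_per_interval
        return cls(ids, bp, cm)


@dataclass
class GenotypeMatrix:
    """Unordered biallelic dosages, one row per individual.

    ``dosage`` holds {0, 1, 2} with :data:`MISSING` (-1) for untyped or masked
    entries.  ``mask`` lists marker indices that were cleared for imputation
    testing; the cleared truth lives with the caller (e.g. a simulator
    TruthSet), never here.
    """

    dosage: np.ndarray  # (N, M) int8
    mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise InputError("dosage must be an N x M matrix")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            i, m = np.argwhere(bad)[0]
            raise InputError(
                f"invalid dosage {self.dosage[i, m]} at individual {i}, marker {m}; "
                "expected 0, 1, 2 or -1 (missing)"
            )
        self.mask = np.asarray(self.mask, dtype=np.int64)
        if self.sample_ids is None:
            self.sample_ids = [f"ind{i}" for i in range(self.dosage.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]


@dataclass
class HMMParams:
    """Copying-model parameters.

    theta
        Per-interval template-switch probability, length M-1.  Re-estimated
        between MCMC iterations; clamped to [1e-6, 0.5].
    error_rate
        Per-allele miscopy probability; clamped to [1e-4, 0.05] when
        re-estimated.  e = 0 is accepted for exact computations but makes
        genotypes that match no template pair impossible.
    epsilon_rel
        Relative floor used by mirror subtraction: the absolute floor is
        epsilon_rel times the sum of the unadjusted sampling weights.
    """

    theta: np.ndarray
    error_rate: float = 0.005
    epsilon_rel: float = 1e-10

    THETA_FLOOR = 1e-6
    THETA_CEIL = 0.5
    ERROR_FLOOR = 1e-4
    ERROR_CEIL = 0.05

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if np.any((self.theta < 0) | (self.theta >= 1)):
            raise InputError("theta values must lie in [0, 1)")
        if not 0 <= self.error_rate < 0.5:
            raise InputError("error_rate must lie in [0, 0.5)")
        if self.epsilon_rel <= 0:
            raise InputError("epsilon_rel must be positive")

    @classmethod
    def uniform(cls, n_markers: int, theta: float = 0.01,
                error_rate: float = 0.005, epsilon_rel: float = 1e-10) -> "HMMParams":
        return cls(np.full(max(n_markers - 1, 1), theta), error_rate, epsilon_rel)


class HaplotypePool:
    """All haplotypes visible to the sampler: mutable study plus fixed references.

    ``owner`` maps each haplotype to its individual; ``mate`` maps it to the
    other haplotype of the same individual (an involution).  The mate map is
    what the mirror-subtraction rule needs: for a template pair (j, k) the
    *mirror pair* (mate(j), mate(k)) carries the complementary phase, and equal
    forward mass on a pair and its mirror means the match is phase-uninformative.
    """

    def __init__(self, alleles: np.ndarray, owner: np.ndarray, mate: np.ndarray,
                 fixed: np.ndarray) -> None:
        self.alleles = np.asarray(alleles, dtype=np.int8)
        self.owner = np.asarray(owner, dtype=np.int64)
        self.mate = np.asarray(mate, dtype=np.int64)
        self.fixed = np.asarray(fixed, dtype=bool)
        h = self.alleles.shape[0]
        if h < 2:
            raise ConfigurationError("a haplotype pool needs at least 2 haplotypes")
        if not (len(self.owner) == len(self.mate) == len(self.fixed) == h):
            raise InputError("owner/mate/fixed must have one entry per haplotype")
        defined = self.mate >= 0
        j = np.nonzero(defined)[0]
        if np.any(self.mate[j] == j):
            raise InputError("a haplotype cannot be its own mate")
        if np.any(self.mate[self.mate[j]] != j):
            raise InputError("mate map must be an involution")
        if np.any(self.owner[self.mate[j]] != self.owner[j]):
            raise InputError("mates must belong to the same individual")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @classmethod
    def from_individuals(cls, haplotypes: np.ndarray, fixed: bool = False) -> "HaplotypePool":
        """Build a pool from an (N, 2, M) array, pairing mates per individual."""
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        n, two, m = haplotypes.shape
        if two != 2:
            raise InputError("expected an (N, 2, M) haplotype array")
        alleles = haplotypes.reshape(2 * n, m)
        owner = np.repeat(np.arange(n), 2)
        mate = np.arange(2 * n)
        mate[0::2] += 1
        mate[1::2] -= 1
        return cls(alleles, owner, mate, np.full(2 * n, fixed))

    def view_excluding(self, individual: int) -> "PoolView":
        """Conditioning pool for one study individual: everyone else's haplotypes.

        Self-exclusion prevents trivial self-copying; K = H - 2 for a study
        individual whose own pair is in the pool.
        """
        keep = np.nonzero(self.owner != individual)[0]
        return self._make_view(keep)

    def view_all(self) -> "PoolView":
        return self._make_view(np.arange(self.n_haplotypes))

    def _make_view(self, keep: np.ndarray) -> "PoolView":
        local = np.full(self.n_haplotypes, -1, dtype=np.int64)
        local[keep] = np.arange(len(keep))
        mate_local = np.full(len(keep), -1, dtype=np.int64)
        has_mate = self.mate[keep] >= 0
        mate_local[has_mate] = local[self.mate[keep[has_mate]]]
        return PoolView(
            alleles=self.alleles[keep],
            mate=mate_local,
            global_indices=keep,
            fixed=self.fixed[keep],
        )


@dataclass
class PoolView:
    """The K candidate templates visible to one forward/sampling pass."""

    alleles: np.ndarray  # (K, M) int8
    mate: np.ndarray  # (K,) local mate index or -1
    global_indices: np.ndarray
    fixed: np.ndarray

    @property
    def K(self) -> int:
        return self.alleles.shape[0]

    def mate_map(self, include_fixed: bool = True) -> np.ndarray:
        """Mate map used for mirror subtraction.

        With ``include_fixed`` false, reference haplotypes are exempted from
        mirroring (their entries become -1).
        """
        if include_fixed:
            return self.mate
        m = self.mate.copy()
        m[self.fixed] = -1
        m[(m >= 0) & self.fixed[np.maximum(self.mate, 0)]] = -1
        return m


@dataclass
class ForwardMatrix:
    """Scaled forward probabilities over ordered template pairs.

    Each slice ``F[m]`` sums to 1; the product of ``scale`` equals the data
    likelihood of the genotype vector under the pair HMM.
    """

    F: np.ndarray  # (M, K, K)
    scale: np.ndarray  # (M,)

    @property
    def n_markers(self) -> int:
        return self.F.shape[0]

    @property
    def K(self) -> int:
        return self.F.shape[1]

    def log_likelihood(self) -> float:
        return float(np.sum(np.log(self.scale)))


def emission_prob(g: int, a_j: int, a_k: int, e: float) -> float:
    """P(observed dosage g | ordered template alleles a_j, a_k).

    Each observed allele is an independent imperfect copy of its template:
    q(x | a) = 1 - e if x == a else e.  The dosage emission sums q over the
    ordered observed-allele pairs consistent with g.  Missing data emits 1.
    """
    if g == MISSING:
        return 1.0
    if g not in (0, 1, 2):
        raise InputError(f"invalid dosage value {g}")
    q = lambda x, a: 1.0 - e if x == a else e
    if g == 0:
        return q(0, a_j) * q(0, a_k)
    if g == 2:
        return q(1, a_j) * q(1, a_k)
    return q(0, a_j) * q(1, a_k) + q(1, a_j) * q(0, a_k)


def emission_matrix(g: int, alleles_m: np.ndarray, e: float) -> np.ndarray:
    """K x K emission probabilities at one marker for every ordered pair."""
    if g == MISSING:
        k = len(alleles_m)
        return np.ones((k, k))
    q1 = np.where(alleles_m == 1, 1.0 - e, e)  # P(copy allele 1 | template)
    q0 = 1.0 - q1
    if g == 0:
        return np.outer(q0, q0)
    if g == 2:
        return np.outer(q1, q1)
    return np.outer(q0, q1) + np.outer(q1, q0)


def transition_prob(j: int, j2: int, theta_m: float, K: int) -> float:
    """Single-chromatid jump-process transition: stay, or jump to a uniform template.

    The pair transition used by the forward pass and the sampler is the
    product of the two per-chromatid factors.
    """
    if K < 1:
        raise ConfigurationError("pool size must be at least 1")
    return (1.0 - theta_m) * (j == j2) + theta_m / K


def forward(genotypes_i: np.ndarray, pool: PoolView, params: HMMParams) -> ForwardMatrix:
    """Scaled forward pass for one individual over ordered template pairs.

    The transition double sum is evaluated with the rank-1 structure of the
    jump process (row/column sums), so the cost is O(M K^2), not O(M K^4).
    """
    if pool.K < 2:
        raise ConfigurationError(
            f"conditioning pool has {pool.K} haplotype(s); at least 2 are required"
        )
    g = np.asarray(genotypes_i, dtype=np.int8)
    m = len(g)
    if m < 2:
        raise ConfigurationError("the HMM needs at least 2 markers")
    if pool.alleles.shape[1] != m:
        raise InputError("genotype vector and pool disagree on marker count")
    theta = np.asarray(params.theta, dtype=float)
    if len(theta) != m - 1:
        raise InputError("theta must have length M - 1")
    F = np.empty((m, pool.K, pool.K))
    scale = np.empty(m)
    ok = pair_forward_kernel(
        np.ascontiguousarray(pool.alleles), g, theta, params.error_rate, F, scale
    )
    if ok < 0:
        raise DegenerateLikelihoodError(
            f"all pair states have zero probability at marker {-ok - 1} "
            "(genotype inconsistent with every template pair under e = "
            f"{params.error_rate})"
        )
    return ForwardMatrix(F=F, scale=scale)


def forward_backward_posteriors(fwd: ForwardMatrix, pool: PoolView,
                                params: HMMParams,
                                genotypes_i: np.ndarray) -> np.ndarray:
    """Per-marker posterior over ordered pairs, each M-slice summing to 1.

    Mainly an oracle for validating the backward sampler and the basis for
    deterministic diagnostics; the MCMC itself only needs the forward pass.
    """
    m, k, _ = fwd.F.shape
    if pool.K != k:
        raise InputError("pool and forward matrix disagree on K")
    g = np.asarray(genotypes_i, dtype=np.int8)
    if len(g) != m:
        raise InputError("genotype vector and forward matrix disagree on M")
    theta = params.theta
    e = params.error_rate
    post = np.empty_like(fwd.F)
    bwd = np.ones((k, k))
    post[m - 1] = fwd.F[m - 1] * bwd
    post[m - 1] /= post[m - 1].sum()
    for t in range(m - 2, -1, -1):
        th = theta[t]
        em_next = emission_matrix(int(g[t + 1]), pool.alleles[:, t + 1], e)
        a = em_next * bwd
        # apply transition transpose per chromatid (rank-1 jump process)
        b = (1.0 - th) * a + (th / k) * a.sum(axis=0, keepdims=True)
        bwd = (1.0 - th) * b + (th / k) * b.sum(axis=1, keepdims=True)
        bwd /= bwd.max()  # rescale only; posterior slice is normalized below
        post[t] = fwd.F[t] * bwd
        post[t] /= post[t].sum()
    return post
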