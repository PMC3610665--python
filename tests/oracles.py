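"""Independent brute-force oracles used by the test suite.

Every function here evaluates a definition by exhaustive enumeration or a
direct quadratic scan, deliberately sharing no code with the package's
recursive/vectorized implementations.
"""

import numpy as np

from mirrorphase.model import MISSING


def emission_value(g, a_j, a_k, e):
    """Dosage emission by explicit sum over ordered observed-allele pairs."""
    if g == MISSING:
        return 1.0
    total = 0.0
    for x1 in (0, 1):
        for x2 in (0, 1):
            if x1 + x2 == g:
                q1 = 1.0 - e if x1 == a_j else e
                q2 = 1.0 - e if x2 == a_k else e
                total += q1 * q2
    return total


def _pair_path_table(A, g, theta, e):
    """All S^M path probabilities over ordered-pair states, S = K^2.

    Returns (paths_matrix, probs) with paths encoded as state digits; the
    state s maps to the pair (s // K, s % K).
    """
    K, M = A.shape
    S = K * K
    n_paths = S ** M
    idx = np.arange(n_paths)
    digits = np.empty((n_paths, M), dtype=np.int64)
    for m in range(M - 1, -1, -1):
        digits[:, m] = idx % S
        idx = idx // S
    em = np.empty((M, S))
    for m in range(M):
        for s in range(S):
            em[m, s] = emission_value(int(g[m]), int(A[s // K, m]),
                                      int(A[s % K, m]), e)
    trans = np.empty((M - 1, S, S))
    for m in range(M - 1):
        t = theta[m]
        for s in range(S):
            j, k = s // K, s % K
            for s2 in range(S):
                j2, k2 = s2 // K, s2 % K
                tj = (1 - t) * (j == j2) + t / K
                tk = (1 - t) * (k == k2) + t / K
                trans[m, s, s2] = tj * tk
    probs = em[0, digits[:, 0]] / S
    for m in range(1, M):
        probs = probs * trans[m - 1, digits[:, m - 1], digits[:, m]] * em[m, digits[:, m]]
    return digits, probs


def pair_likelihood_and_posteriors(A, g, theta, e):
    """Exhaustive path-sum likelihood and per-marker pair posteriors."""
    K, M = A.shape
    S = K * K
    digits, probs = _pair_path_table(A, g, theta, e)
    lik = probs.sum()
    post = np.empty((M, K, K))
    for m in range(M):
        marg = np.bincount(digits[:, m], weights=probs, minlength=S) / lik
        post[m] = marg.reshape(K, K)
    return lik, post


def pair_path_distribution(A, g, theta, e):
    """Normalized joint probability of every full path (for sampler GOF)."""
    digits, probs = _pair_path_table(A, g, theta, e)
    return digits, probs / probs.sum()


def haploid_posteriors(P, hap, theta, e):
    """Exhaustive haploid path enumeration: per-marker state posteriors."""
    Kp, M = P.shape
    n_paths = Kp ** M
    idx = np.arange(n_paths)
    digits = np.empty((n_paths, M), dtype=np.int64)
    for m in range(M - 1, -1, -1):
        digits[:, m] = idx % Kp
        idx = idx // Kp
    em = np.empty((M, Kp))
    for m in range(M):
        for j in range(Kp):
            if hap[m] == MISSING:
                em[m, j] = 1.0
            else:
                em[m, j] = 1.0 - e if P[j, m] == hap[m] else e
    probs = em[0, digits[:, 0]] / Kp
    for m in range(1, M):
        t = theta[m - 1]
        stay = digits[:, m] == digits[:, m - 1]
        probs = probs * ((1 - t) * stay + t / Kp) * em[m, digits[:, m]]
    lik = probs.sum()
    post = np.empty((M, Kp))
    for m in range(M):
        post[m] = np.bincount(digits[:, m], weights=probs, minlength=Kp) / lik
    return post


def switch_count(true_pair, inferred_pair, scoreable=None):
    """Direct site-by-site agreement walk."""
    t1, t2 = true_pair
    f1, f2 = inferred_pair
    agree_seq = []
    for m in range(len(t1)):
        if scoreable is not None and not scoreable[m]:
            continue
        if t1[m] == t2[m]:
            continue
        if t1[m] + t2[m] != f1[m] + f2[m]:
            continue
        agree_seq.append(t1[m] == f1[m])
    return sum(1 for a, b in zip(agree_seq, agree_seq[1:]) if a != b)


def _condition(a, b, kind, missing_matches=True):
    if a == MISSING or b == MISSING:
        return missing_matches
    if kind == "double":
        return a == b
    return not ((a == 0 and b == 2) or (a == 2 and b == 0))


def maximal_runs(gA, gB, kind, missing_matches=True):
    """O(M^2)-style scan: for every start, extend while the condition holds,
    keep only maximal intervals."""
    M = len(gA)
    runs = []
    for start in range(M):
        if not _condition(gA[start], gB[start], kind, missing_matches):
            continue
        if start > 0 and _condition(gA[start - 1], gB[start - 1], kind,
                                    missing_matches):
            continue  # not left-maximal
        end = start
        while end < M and _condition(gA[end], gB[end], kind, missing_matches):
            end += 1
        runs.append((start, end))
    return runs


def best_match_lengths(dosage, kind, missing_matches=True):
    """Per individual and marker: longest kind-run containing the marker
    against any other individual, by left/right expansion from each site."""
    n, M = dosage.shape
    best = np.zeros((n, M), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            for m in range(M):
                if not _condition(dosage[i, m], dosage[j, m], kind,
                                  missing_matches):
                    continue
                lo = m
                while lo > 0 and _condition(dosage[i, lo - 1], dosage[j, lo - 1],
                                            kind, missing_matches):
                    lo -= 1
                hi = m
                while hi < M - 1 and _condition(dosage[i, hi + 1],
                                                dosage[j, hi + 1], kind,
                                                missing_matches):
                    hi += 1
                best[i, m] = max(best[i, m], hi - lo + 1)
    return best


def imputed_error_recount(truth_at_mask, calls):
    """Per-genotype |difference| sum, the long way."""
    total = 0
    n, m = truth_at_mask.shape
    for i in range(n):
        for j in range(m):
            if truth_at_mask[i, j] == MISSING:
                continue
            total += min(abs(int(truth_at_mask[i, j]) - int(calls[i, j])), 2)
    return total
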