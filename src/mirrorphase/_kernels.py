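"""Numba kernels for the pair-HMM forward pass and the backward samplers.

These are internal: shape/error checking and all user-facing semantics live
in :mod:`mirrorphase.model` and :mod:`mirrorphase.sampler`.  The jump-process
transition is rank-1 (stay with probability 1 - theta, otherwise land on a
uniform template), so every transition sum is computed from row/column sums
in O(K^2) per marker.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _emission_q1(A_col, e, q1):
    # q1[j] = P(copied allele is 1 | template allele A_col[j])
    for j in range(A_col.shape[0]):
        q1[j] = 1.0 - e if A_col[j] == 1 else e


@njit(cache=True)
def _emission_slice(g, q1, out):
    K = q1.shape[0]
    if g < 0:
        for j in range(K):
            for k in range(K):
                out[j, k] = 1.0
        return
    for j in range(K):
        q1j = q1[j]
        q0j = 1.0 - q1j
        for k in range(K):
            q1k = q1[k]
            if g == 0:
                out[j, k] = q0j * (1.0 - q1k)
            elif g == 2:
                out[j, k] = q1j * q1k
            else:
                out[j, k] = q0j * q1k + q1j * (1.0 - q1k)


@njit(cache=True)
def pair_forward_kernel(A, g, theta, e, F, scale):
    """Scaled forward pass over ordered pairs.

    A : (K, M) int8 template alleles; g : (M,) int8 dosages (-1 missing);
    F : (M, K, K) out, each slice normalized; scale : (M,) out.
    Returns 1 on success, -(m+1) if the slice at marker m sums to zero.
    """
    K, M = A.shape
    q1 = np.empty(K)
    em = np.empty((K, K))
    _emission_q1(A[:, 0], e, q1)
    _emission_slice(g[0], q1, em)
    inv_k2 = 1.0 / (K * K)
    s = 0.0
    for j in range(K):
        for k in range(K):
            v = em[j, k] * inv_k2
            F[0, j, k] = v
            s += v
    if s <= 0.0:
        return -1
    scale[0] = s
    inv = 1.0 / s
    for j in range(K):
        for k in range(K):
            F[0, j, k] *= inv

    cs = np.empty(K)
    rs = np.empty(K)
    for m in range(1, M):
        t = theta[m - 1]
        stay = 1.0 - t
        jump = t / K
        # column sums of the previous slice (sum over first chromatid)
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += F[m - 1, j, k]
            cs[k] = acc
        # B = stay * prev + jump * cs  (first chromatid transition), then
        # row sums of B feed the second chromatid transition
        _emission_q1(A[:, m], e, q1)
        _emission_slice(g[m], q1, em)
        s = 0.0
        for j in range(K):
            racc = 0.0
            for k in range(K):
                racc += stay * F[m - 1, j, k] + jump * cs[k]
            rs[j] = racc
        for j in range(K):
            for k in range(K):
                b = stay * F[m - 1, j, k] + jump * cs[k]
                v = em[j, k] * (stay * b + jump * rs[j])
                F[m, j, k] = v
                s += v
        if s <= 0.0:
            return -(m + 1)
        scale[m] = s
        inv = 1.0 / s
        for j in range(K):
            for k in range(K):
                F[m, j, k] *= inv
    return 1


@njit(cache=True)
def mirror_adjust_kernel(w, mate, eps_rel, out):
    """out[j,k] = max(w[j,k] - w[mate[j],mate[k]], eps_abs) on mated pairs.

    eps_abs = eps_rel * sum(w); pairs with an undefined mate pass through.
    ``out`` is NOT normalized here (samplers draw from unnormalized weights).
    """
    K = w.shape[0]
    total = 0.0
    for j in range(K):
        for k in range(K):
            total += w[j, k]
    eps = eps_rel * total
    for j in range(K):
        mj = mate[j]
        for k in range(K):
            mk = mate[k]
            if mj >= 0 and mk >= 0:
                d = w[j, k] - w[mj, mk]
                out[j, k] = d if d > eps else eps
            else:
                out[j, k] = w[j, k]
    return total


@njit(cache=True)
def _draw_pair(w, rng):
    K = w.shape[0]
    total = 0.0
    for j in range(K):
        for k in range(K):
            total += w[j, k]
    r = rng.random() * total
    acc = 0.0
    for j in range(K):
        for k in range(K):
            acc += w[j, k]
            if acc >= r:
                return j, k
    return K - 1, K - 1


@njit(cache=True)
def backward_sample_kernel(F, theta, mate, eps_rel, mirror, full_weight,
                           rng, paths):
    """Sample template-pair paths from the forward matrix, last marker first.

    paths : (n_samples, M, 2) int64 out.  With ``mirror``, the mirror pair's
    forward probability is subtracted from each pair's forward probability
    before the transition factor is applied — on the forward slice the
    pair/mirror symmetry of a double-sharing competitor holds at every
    marker, so the subtraction cancels the feedback loop wherever the chain
    is.  ``full_weight`` instead subtracts on the complete backward weight
    (forward x transition), a comparison variant: the stay-transition breaks
    the mirror symmetry and the adjustment is ineffective once a copy pair
    has been entered.
    """
    n_samples = paths.shape[0]
    M, K, _ = F.shape
    w = np.empty((K, K))
    adj = np.empty((K, K))
    tj = np.empty(K)
    tk = np.empty(K)
    for s in range(n_samples):
        for j in range(K):
            for k in range(K):
                w[j, k] = F[M - 1, j, k]
        if mirror:
            mirror_adjust_kernel(w, mate, eps_rel, adj)
            jn, kn = _draw_pair(adj, rng)
        else:
            jn, kn = _draw_pair(w, rng)
        paths[s, M - 1, 0] = jn
        paths[s, M - 1, 1] = kn
        for m in range(M - 2, -1, -1):
            t = theta[m]
            stay = 1.0 - t
            jump = t / K
            for j in range(K):
                tj[j] = jump + (stay if j == jn else 0.0)
                tk[j] = jump + (stay if j == kn else 0.0)
            if mirror and not full_weight:
                for j in range(K):
                    for k in range(K):
                        w[j, k] = F[m, j, k]
                mirror_adjust_kernel(w, mate, eps_rel, adj)
                for j in range(K):
                    for k in range(K):
                        w[j, k] = adj[j, k] * tj[j] * tk[k]
                jn, kn = _draw_pair(w, rng)
            else:
                for j in range(K):
                    for k in range(K):
                        w[j, k] = F[m, j, k] * tj[j] * tk[k]
                if mirror:
                    mirror_adjust_kernel(w, mate, eps_rel, adj)
                    jn, kn = _draw_pair(adj, rng)
                else:
                    jn, kn = _draw_pair(w, rng)
            paths[s, m, 0] = jn
            paths[s, m, 1] = kn
    return 1


@njit(cache=True)
def haploid_posteriors_kernel(P, hap, theta, e, post):
    """Forward-backward state posteriors for one haploid Li & Stephens chain.

    P : (Kp, M) int8 panel alleles; hap : (M,) int8 study alleles, -1 where
    masked/untyped; post : (M, Kp) out, rows summing to 1.
    """
    Kp, M = P.shape
    f = np.empty((M, Kp))
    for m in range(M):
        t = 0.0 if m == 0 else theta[m - 1]
        stay = 1.0 - t
        jump = t / Kp
        prev_sum = 0.0
        if m > 0:
            for j in range(Kp):
                prev_sum += f[m - 1, j]
        s = 0.0
        for j in range(Kp):
            if hap[m] < 0:
                em = 1.0
            else:
                em = 1.0 - e if P[j, m] == hap[m] else e
            if m == 0:
                v = em / Kp
            else:
                v = em * (stay * f[m - 1, j] + jump * prev_sum)
            f[m, j] = v
            s += v
        inv = 1.0 / s
        for j in range(Kp):
            f[m, j] *= inv
    b = np.ones(Kp)
    a = np.empty(Kp)
    for m in range(M - 1, -1, -1):
        s = 0.0
        for j in range(Kp):
            v = f[m, j] * b[j]
            post[m, j] = v
            s += v
        inv = 1.0 / s
        for j in range(Kp):
            post[m, j] *= inv
        if m > 0:
            t = theta[m - 1]
            stay = 1.0 - t
            jump = t / Kp
            asum = 0.0
            for j in range(Kp):
                if hap[m] < 0:
                    em = 1.0
                else:
                    em = 1.0 - e if P[j, m] == hap[m] else e
                a[j] = em * b[j]
                asum += a[j]
            bmax = 0.0
            for j in range(Kp):
                b[j] = stay * a[j] + jump * asum
                if b[j] > bmax:
                    bmax = b[j]
            for j in range(Kp):
                b[j] /= bmax
    return 1
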