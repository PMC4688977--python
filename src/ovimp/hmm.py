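"""Li-Stephens copying-model HMM kernels.

A target haplotype is modelled as an imperfect mosaic of H reference
haplotypes: hidden state = which reference haplotype is being copied,
switches between adjacent markers with probability
rho_j = 1 - exp(-4 * Ne_eff * d_j / H) (d_j in Morgans), and the copied
allele is mis-read with probability eps. Transitions are uniform over
destination haplotypes: P(h' | h) = (1 - rho) * [h' = h] + rho / H.

Kernels are numba-compiled; observations use -1 for missing (uniform
emission). All arithmetic is in scaled linear space (per-marker
normalisation), which is exact for the forward-backward posteriors.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "switch_probabilities",
    "haploid_forward_backward",
    "haploid_viterbi",
    "diploid_viterbi",
    "diploid_sample",
]


def switch_probabilities(
    pos_cm: np.ndarray, chrom_start: np.ndarray, ne_eff: float, n_haps: int
) -> np.ndarray:
    """Per-interval switch probabilities rho_j (rho[0] and chromosome
    starts are 1: the chain restarts from its stationary distribution,
    making chromosomes exactly independent)."""
    pos_cm = np.asarray(pos_cm, dtype=np.float64)
    d = np.empty(len(pos_cm))
    d[0] = np.inf
    d[1:] = np.maximum(np.diff(pos_cm) / 100.0, 1e-8)  # Morgans; co-located markers get 1e-8
    d[np.asarray(chrom_start, dtype=bool)] = np.inf
    rho = 1.0 - np.exp(-4.0 * ne_eff * d / max(n_haps, 1))
    return rho


@njit(cache=True)
def haploid_forward_backward(obs, ref, rho, eps):
    """Scaled forward-backward for one haploid target.

    obs : (m,) int8, alleles 0/1 or -1 for missing.
    ref : (H, m) int8 reference haplotypes.
    rho : (m,) switch probabilities (rho[0] = 1).
    Returns (gamma, p1, loglik): state posteriors (m, H), posterior
    probability of allele 1 per marker, and the log-likelihood.
    """
    H, m = ref.shape
    gamma = np.empty((m, H))
    fwd = np.empty((m, H))
    scale = np.empty(m)
    loglik = 0.0

    # forward
    for j in range(m):
        if j == 0 or rho[j] >= 1.0:
            base_same = 0.0
            base_any = 1.0 / H
        else:
            base_same = 1.0 - rho[j]
            base_any = rho[j] / H
        if j == 0:
            prev_sum = 1.0
        else:
            prev_sum = 0.0
            for h in range(H):
                prev_sum += fwd[j - 1, h]
        s = 0.0
        for h in range(H):
            if j == 0:
                pred = 1.0 / H
            else:
                pred = base_same * fwd[j - 1, h] + base_any * prev_sum
            if obs[j] < 0:
                e = 1.0
            elif ref[h, j] == obs[j]:
                e = 1.0 - eps
            else:
                e = eps
            fwd[j, h] = pred * e
            s += fwd[j, h]
        if s <= 0.0:
            raise ValueError("zero forward mass: rescale or increase eps")
        scale[j] = s
        loglik += np.log(s)
        for h in range(H):
            fwd[j, h] /= s

    # backward (scaled by the forward scale factors)
    bwd = np.ones(H)
    for h in range(H):
        gamma[m - 1, h] = fwd[m - 1, h] * bwd[h]
    for j in range(m - 1, 0, -1):
        tmp = np.empty(H)
        ssum = 0.0
        for h in range(H):
            if obs[j] < 0:
                e = 1.0
            elif ref[h, j] == obs[j]:
                e = 1.0 - eps
            else:
                e = eps
            tmp[h] = e * bwd[h]
            ssum += tmp[h]
        if rho[j] >= 1.0:
            base_same = 0.0
            base_any = 1.0 / H
        else:
            base_same = 1.0 - rho[j]
            base_any = rho[j] / H
        for h in range(H):
            bwd[h] = (base_same * tmp[h] + base_any * ssum) / scale[j]
        for h in range(H):
            gamma[j - 1, h] = fwd[j - 1, h] * bwd[h]

    p1 = np.empty(m)
    for j in range(m):
        tot = 0.0
        a1 = 0.0
        for h in range(H):
            tot += gamma[j, h]
            if ref[h, j] == 1:
                a1 += gamma[j, h] * (1.0 - eps)
            else:
                a1 += gamma[j, h] * eps
        if tot > 0.0:
            for h in range(H):
                gamma[j, h] /= tot
            a1 /= tot
        p1[j] = a1
    return gamma, p1, loglik


@njit(cache=True)
def haploid_viterbi(obs, ref, rho, eps):
    """Most likely copying path for one haploid target; returns (m,) state indices."""
    H, m = ref.shape
    logv = np.empty(H)
    back = np.empty((m, H), dtype=np.int32)
    for h in range(H):
        if obs[0] < 0:
            e = 1.0
        elif ref[h, 0] == obs[0]:
            e = 1.0 - eps
        else:
            e = eps
        logv[h] = np.log(1.0 / H) + np.log(e)
        back[0, h] = h
    for j in range(1, m):
        if rho[j] >= 1.0:
            l_same = -np.inf
            l_any = np.log(1.0 / H)
        else:
            l_same = np.log(1.0 - rho[j] + rho[j] / H)
            l_any = np.log(rho[j] / H)
        best_prev = 0
        best_val = logv[0]
        for h in range(1, H):
            if logv[h] > best_val:
                best_val = logv[h]
                best_prev = h
        new = np.empty(H)
        for h in range(H):
            stay = logv[h] + l_same
            jump = best_val + l_any
            if stay >= jump:
                new[h] = stay
                back[j, h] = h
            else:
                new[h] = jump
                back[j, h] = best_prev
            if obs[j] < 0:
                e = 1.0
            elif ref[h, j] == obs[j]:
                e = 1.0 - eps
            else:
                e = eps
            new[h] += np.log(e)
        logv = new
    path = np.empty(m, dtype=np.int32)
    best = 0
    for h in range(1, H):
        if logv[h] > logv[best]:
            best = h
    path[m - 1] = best
    for j in range(m - 1, 0, -1):
        path[j - 1] = back[j, path[j]]
    return path


@njit(cache=True)
def _diploid_emission(g, a, b, eps):
    """P(genotype g | copied alleles a, b) with per-allele error eps."""
    pa = (1.0 - eps) if a == 1 else eps   # P(transmit allele 1 | copy a)
    pb = (1.0 - eps) if b == 1 else eps
    if g < 0:
        return 1.0
    if g == 0:
        return (1.0 - pa) * (1.0 - pb)
    if g == 1:
        return pa * (1.0 - pb) + (1.0 - pa) * pb
    return pa * pb


@njit(cache=True)
def diploid_viterbi(gt, ref, rho, eps):
    """Most likely ordered pair of copying paths given unphased genotypes.

    gt : (m,) int8 genotypes 0/1/2, -1 missing.
    ref : (K, m) reference haplotypes (surrogate subset).
    Returns (path1, path2), each (m,) int32.
    """
    K, m = ref.shape
    logv = np.empty((K, K))
    choice = np.empty((m, K, K), dtype=np.uint8)  # 0 stay,1 row-jump,2 col-jump,3 both
    rowarg = np.empty((m, K), dtype=np.int32)
    colarg = np.empty((m, K), dtype=np.int32)
    allarg = np.empty((m, 2), dtype=np.int32)

    for k in range(K):
        for l in range(K):
            e = _diploid_emission(gt[0], ref[k, 0], ref[l, 0], eps)
            logv[k, l] = np.log(e + 1e-300) - 2.0 * np.log(K)

    for j in range(1, m):
        if rho[j] >= 1.0:
            l_same = -np.inf
            l_any = np.log(1.0 / K)
        else:
            l_same = np.log(1.0 - rho[j] + rho[j] / K)
            l_any = np.log(rho[j] / K)
        rowmax = np.empty(K)
        colmax = np.empty(K)
        for k in range(K):
            bi = 0
            for l in range(1, K):
                if logv[k, l] > logv[k, bi]:
                    bi = l
            rowmax[k] = logv[k, bi]
            rowarg[j, k] = bi
        for l in range(K):
            bi = 0
            for k in range(1, K):
                if logv[k, l] > logv[bi, l]:
                    bi = k
            colmax[l] = logv[bi, l]
            colarg[j, l] = bi
        bk, bl = 0, 0
        for k in range(K):
            for l in range(K):
                if logv[k, l] > logv[bk, bl]:
                    bk, bl = k, l
        allarg[j, 0] = bk
        allarg[j, 1] = bl
        allbest = logv[bk, bl]

        new = np.empty((K, K))
        for k in range(K):
            for l in range(K):
                v0 = logv[k, l] + 2.0 * l_same
                v1 = rowmax[k] + l_same + l_any   # paternal stays, maternal jumps
                v2 = colmax[l] + l_any + l_same   # paternal jumps, maternal stays
                v3 = allbest + 2.0 * l_any
                best = v0
                c = 0
                if v1 > best:
                    best = v1
                    c = 1
                if v2 > best:
                    best = v2
                    c = 2
                if v3 > best:
                    best = v3
                    c = 3
                e = _diploid_emission(gt[j], ref[k, j], ref[l, j], eps)
                new[k, l] = best + np.log(e + 1e-300)
                choice[j, k, l] = c
        logv = new

    bk, bl = 0, 0
    for k in range(K):
        for l in range(K):
            if logv[k, l] > logv[bk, bl]:
                bk, bl = k, l
    path1 = np.empty(m, dtype=np.int32)
    path2 = np.empty(m, dtype=np.int32)
    path1[m - 1] = bk
    path2[m - 1] = bl
    for j in range(m - 1, 0, -1):
        k, l = path1[j], path2[j]
        c = choice[j, k, l]
        if c == 0:
            pk, pl = k, l
        elif c == 1:
            pk, pl = k, rowarg[j, k]
        elif c == 2:
            pk, pl = colarg[j, l], l
        else:
            pk, pl = allarg[j, 0], allarg[j, 1]
        path1[j - 1] = pk
        path2[j - 1] = pl
    return path1, path2


@njit(cache=True)
def diploid_sample(gt, ref, rho, eps, unif):
    """Sample an ordered pair of copying paths from the joint posterior
    (forward filtering, backward sampling) given unphased genotypes.

    ``unif`` supplies m i.i.d. U(0,1) draws. Used for the stochastic
    phasing iterations, which escape the poor fixed points that hard
    Viterbi updates can lock into.
    """
    K, m = ref.shape
    f = np.empty((m, K, K))
    # forward filter (normalised per marker)
    s = 0.0
    for k in range(K):
        for l in range(K):
            e = _diploid_emission(gt[0], ref[k, 0], ref[l, 0], eps)
            f[0, k, l] = e
            s += e
    for k in range(K):
        for l in range(K):
            f[0, k, l] /= s
    for j in range(1, m):
        r = rho[j]
        if r >= 1.0:
            a2 = 1.0 / (K * K)
            ss = 0.0
            sa = 0.0
        else:
            ss = (1.0 - r) * (1.0 - r)
            sa = (1.0 - r) * (r / K)
            a2 = (r / K) * (r / K)
        rowsum = np.zeros(K)
        colsum = np.zeros(K)
        tot = 0.0
        for k in range(K):
            for l in range(K):
                v = f[j - 1, k, l]
                rowsum[k] += v
                colsum[l] += v
                tot += v
        s = 0.0
        for k in range(K):
            for l in range(K):
                pred = ss * f[j - 1, k, l] + sa * (rowsum[k] + colsum[l]) + a2 * tot
                e = _diploid_emission(gt[j], ref[k, j], ref[l, j], eps)
                f[j, k, l] = pred * e
                s += f[j, k, l]
        if s <= 0.0:
            raise ValueError("zero forward mass in diploid sampler")
        for k in range(K):
            for l in range(K):
                f[j, k, l] /= s

    path1 = np.empty(m, dtype=np.int32)
    path2 = np.empty(m, dtype=np.int32)
    # sample the final state
    u = unif[m - 1]
    acc = 0.0
    bk, bl = K - 1, K - 1
    done = False
    for k in range(K):
        if done:
            break
        for l in range(K):
            acc += f[m - 1, k, l]
            if acc >= u:
                bk, bl = k, l
                done = True
                break
    path1[m - 1] = bk
    path2[m - 1] = bl
    # backward sampling of predecessors
    for j in range(m - 1, 0, -1):
        r = rho[j]
        k, l = path1[j], path2[j]
        tot = 0.0
        w = np.empty((K, K))
        for k2 in range(K):
            if r >= 1.0:
                tk = 1.0 / K
            else:
                tk = r / K + (1.0 - r) * (1.0 if k2 == k else 0.0)
            for l2 in range(K):
                if r >= 1.0:
                    tl = 1.0 / K
                else:
                    tl = r / K + (1.0 - r) * (1.0 if l2 == l else 0.0)
                w[k2, l2] = f[j - 1, k2, l2] * tk * tl
                tot += w[k2, l2]
        u = unif[j - 1] * tot
        acc = 0.0
        pk, pl = K - 1, K - 1
        done = False
        for k2 in range(K):
            if done:
                break
            for l2 in range(K):
                acc += w[k2, l2]
                if acc >= u:
                    pk, pl = k2, l2
                    done = True
                    break
        path1[j - 1] = pk
        path2[j - 1] = pl
    return path1, path2
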