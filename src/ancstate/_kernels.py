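"""Numba inner loops for the pruning likelihood and the node-marginal downpass.

All kernels take the flat tree arrays from :class:`ancstate.phylo.Phylogeny`,
a stack of per-branch transition matrices ``P`` (entry ``P[v]`` is the matrix
on the branch above node ``v``; the root entry is unused) and a per-node
partial-initialisation array ``mask`` (tip partials at tips, constraint
indicators at internal nodes, ones where unconstrained). Underflow is handled
by per-node rescaling with an accumulated log factor.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def prune_loglik_kernel(postorder, child_flat, child_ptr, P, mask, pi):
    n, k = mask.shape
    part = mask.copy()
    tmp = np.empty(k)
    logscale = 0.0
    for oi in range(n):
        v = postorder[oi]
        c0 = child_ptr[v]
        c1 = child_ptr[v + 1]
        for ci in range(c0, c1):
            c = child_flat[ci]
            for i in range(k):
                acc = 0.0
                for j in range(k):
                    acc += P[c, i, j] * part[c, j]
                tmp[i] = acc
            for i in range(k):
                part[v, i] *= tmp[i]
        if c1 > c0:
            m = 0.0
            for i in range(k):
                if part[v, i] > m:
                    m = part[v, i]
            if m <= 0.0:
                return NEG_INF
            for i in range(k):
                part[v, i] /= m
            logscale += np.log(m)
    root = postorder[n - 1]
    like = 0.0
    for i in range(k):
        like += pi[i] * part[root, i]
    if like <= 0.0:
        return NEG_INF
    return np.log(like) + logscale


@njit(cache=True)
def node_marginals_kernel(postorder, child_flat, child_ptr, P, mask, pi):
    """Marginal state probabilities at every node (one uppass + one downpass).

    Returns ``(ok, marg)``; ``ok`` is False when the total likelihood is 0.
    """
    n, k = mask.shape
    part = mask.copy()
    A = np.zeros((n, k))  # A[c] = P[c] @ part[c], the message child c sends up
    marg = np.zeros((n, k))
    for oi in range(n):
        v = postorder[oi]
        c0 = child_ptr[v]
        c1 = child_ptr[v + 1]
        for ci in range(c0, c1):
            c = child_flat[ci]
            for i in range(k):
                acc = 0.0
                for j in range(k):
                    acc += P[c, i, j] * part[c, j]
                A[c, i] = acc
            for i in range(k):
                part[v, i] *= A[c, i]
        if c1 > c0:
            m = 0.0
            for i in range(k):
                if part[v, i] > m:
                    m = part[v, i]
            if m <= 0.0:
                return False, marg
            for i in range(k):
                part[v, i] /= m
    out = np.zeros((n, k))
    root = postorder[n - 1]
    for i in range(k):
        out[root, i] = pi[i]
    tmpb = np.empty(k)
    for oi in range(n - 1, -1, -1):  # preorder: parents before children
        v = postorder[oi]
        s = 0.0
        for i in range(k):
            marg[v, i] = out[v, i] * part[v, i]
            s += marg[v, i]
        if s <= 0.0:
            return False, marg
        for i in range(k):
            marg[v, i] /= s
        c0 = child_ptr[v]
        c1 = child_ptr[v + 1]
        nc = c1 - c0
        if nc == 0:
            continue
        pre = np.ones((nc + 1, k))
        suf = np.ones((nc + 1, k))
        for t in range(nc):
            c = child_flat[c0 + t]
            for i in range(k):
                pre[t + 1, i] = pre[t, i] * A[c, i]
        for t in range(nc - 1, -1, -1):
            c = child_flat[c0 + t]
            for i in range(k):
                suf[t, i] = suf[t + 1, i] * A[c, i]
        for t in range(nc):
            c = child_flat[c0 + t]
            for i in range(k):
                tmpb[i] = out[v, i] * mask[v, i] * pre[t, i] * suf[t + 1, i]
            mx = 0.0
            for j in range(k):
                acc = 0.0
                for i in range(k):
                    acc += P[c, i, j] * tmpb[i]
                out[c, j] = acc
                if acc > mx:
                    mx = acc
            if mx > 0.0:
                for j in range(k):
                    out[c, j] /= mx
    return True, marg


@njit(cache=True)
def loglik_eig_kernel(Qm, ts, postorder, child_flat, child_ptr, mask, pi):
    """Fused fast path: eigendecomposition transition matrices + pruning.

    Returns ``(ok, loglik, P)``. ``ok`` is 0 when Q looks near-defective or
    V is ill-conditioned (caller must fall back to the expm path).
    """
    k = Qm.shape[0]
    n = ts.shape[0]
    P = np.zeros((n, k, k))
    Qc = Qm.astype(np.complex128)
    lam, V = np.linalg.eig(Qc)
    Vinv = np.linalg.inv(V)
    # reconstruction + 1-norm conditioning guard
    scale = 1.0
    for i in range(k):
        for j in range(k):
            if abs(Qm[i, j]) > scale:
                scale = abs(Qm[i, j])
    err = 0.0
    nv = 0.0
    nvi = 0.0
    for j in range(k):
        sv = 0.0
        svi = 0.0
        for i in range(k):
            acc = 0.0 + 0.0j
            for m in range(k):
                acc += V[i, m] * lam[m] * Vinv[m, j]
            d = abs(acc.real - Qm[i, j]) + abs(acc.imag)
            if d > err:
                err = d
            sv += abs(V[i, j])
            svi += abs(Vinv[i, j])
        if sv > nv:
            nv = sv
        if svi > nvi:
            nvi = svi
    if err > 1e-11 * scale or nv * nvi > 1e8:
        return 0, 0.0, P
    el = np.empty(k, dtype=np.complex128)
    for b in range(n):
        t = ts[b]
        if t == 0.0:
            for i in range(k):
                P[b, i, i] = 1.0
            continue
        for m in range(k):
            el[m] = np.exp(lam[m] * t)
        for i in range(k):
            for j in range(k):
                acc = 0.0 + 0.0j
                for m in range(k):
                    acc += V[i, m] * el[m] * Vinv[m, j]
                p = acc.real
                if p < 0.0:
                    p = 0.0
                elif p > 1.0:
                    p = 1.0
                P[b, i, j] = p
    ll = prune_loglik_kernel(postorder, child_flat, child_ptr, P, mask, pi)
    return 1, ll, P
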