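"""Numba-compiled pruning kernels.

Node-by-node fused loops over (category, state, pattern) with per-node
rescaling; mathematically identical to the vectorized numpy path in
``likelihood.PruningEngine`` (cross-checked by the test suite). Falls back
to the numpy path if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def postorder_pass(P, tipLk, post_internal, child1, child2, n_tips, below, T, clog):
    nn, C, k, npat = below.shape
    for t in range(n_tips):
        for c in range(C):
            for i in range(k):
                for p in range(npat):
                    below[t, c, i, p] = tipLk[t, c, i, p]
            for i in range(k):
                for p in range(npat):
                    acc = 0.0
                    for j in range(k):
                        acc += P[t, c, i, j] * below[t, c, j, p]
                    T[t, c, i, p] = acc
        for p in range(npat):
            clog[t, p] = 0.0
    for idx in range(post_internal.shape[0]):
        v = post_internal[idx]
        c1 = child1[v]
        c2 = child2[v]
        for p in range(npat):
            mx = 0.0
            for c in range(C):
                for i in range(k):
                    pr = T[c1, c, i, p] * T[c2, c, i, p]
                    below[v, c, i, p] = pr
                    if pr > mx:
                        mx = pr
            if mx < 1e-300:
                mx = 1e-300
            inv = 1.0 / mx
            for c in range(C):
                for i in range(k):
                    below[v, c, i, p] *= inv
            clog[v, p] = np.log(mx) + clog[c1, p] + clog[c2, p]
        for c in range(C):
            for i in range(k):
                for p in range(npat):
                    acc = 0.0
                    for j in range(k):
                        acc += P[v, c, i, j] * below[v, c, j, p]
                    T[v, c, i, p] = acc


@njit(cache=True)
def gradient_pass(
    P, QP, cat_rates, below, T, clog, edge_order, parent, sibling,
    n_tips, p_inv, const_pi, weights, freqs, grad,
):
    nn, C, k, npat = below.shape
    A = np.empty((nn, C, k, npat))
    alog = np.zeros((nn, npat))
    flank = np.empty((C, k, npat))
    w1 = 1.0 - p_inv
    # root A = stationary frequencies
    root = -1
    for v in range(nn):
        if parent[v] < 0:
            root = v
    for c in range(C):
        for i in range(k):
            for p in range(npat):
                A[root, c, i, p] = freqs[i]
    for idx in range(edge_order.shape[0]):
        v = edge_order[idx]
        u = parent[v]
        s = sibling[v]
        for c in range(C):
            for i in range(k):
                for p in range(npat):
                    flank[c, i, p] = A[u, c, i, p] * T[s, c, i, p]
        g = 0.0
        for p in range(npat):
            val = 0.0
            dv = 0.0
            for c in range(C):
                r = cat_rates[c]
                for i in range(k):
                    acc = 0.0
                    for j in range(k):
                        acc += QP[v, c, i, j] * below[v, c, j, p]
                    val += flank[c, i, p] * T[v, c, i, p]
                    dv += flank[c, i, p] * acc * r
            val /= C
            dv /= C
            if p_inv > 0.0:
                sv = alog[u, p] + clog[s, p] + clog[v, p]
                msv = -sv
                if msv > 700.0:
                    msv = 700.0
                den = w1 * val + p_inv * const_pi[p] * np.exp(msv)
                num = w1 * dv
            else:
                den = val
                num = dv
            if den < 1e-300:
                den = 1e-300
            g += weights[p] * num / den
        grad[v] = g
        if v >= n_tips:
            for p in range(npat):
                mx = 0.0
                for c in range(C):
                    for j in range(k):
                        acc = 0.0
                        for i in range(k):
                            acc += flank[c, i, p] * P[v, c, i, j]
                        A[v, c, j, p] = acc
                        if acc > mx:
                            mx = acc
                if mx < 1e-300:
                    mx = 1e-300
                inv = 1.0 / mx
                for c in range(C):
                    for j in range(k):
                        A[v, c, j, p] *= inv
                alog[v, p] = alog[u, p] + clog[s, p] + np.log(mx)
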