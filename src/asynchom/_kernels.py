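"""Numba-compiled inner loops for the null-model computations."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bmntd_pairs(weights, present_idx, present_n, dmat):
    """Abundance-weighted beta-mean-nearest-taxon-distance for all plot pairs.

    ``weights``: (P, N) per-plot taxon weights (relative abundances, rows sum
    to 1 over present taxa). ``present_idx``/``present_n``: per plot, the
    indices of present taxa and how many. ``dmat``: (N, N) patristic
    distances.
    """
    p = weights.shape[0]
    out = np.zeros((p, p))
    for a in range(p):
        na = present_n[a]
        for b in range(a + 1, p):
            nb = present_n[b]
            s = 0.0
            for ii in range(na):
                i = present_idx[a, ii]
                best = np.inf
                for jj in range(nb):
                    d = dmat[i, present_idx[b, jj]]
                    if d < best:
                        best = d
                s += weights[a, i] * best
            for jj in range(nb):
                j = present_idx[b, jj]
                best = np.inf
                for ii in range(na):
                    d = dmat[present_idx[a, ii], j]
                    if d < best:
                        best = d
                s += weights[b, j] * best
            out[a, b] = 0.5 * s
            out[b, a] = out[a, b]
    return out


@njit(cache=True)
def bmntd_null_moments(weights, present_idx, present_n, dmat, perms):
    """Mean and sd of the tip-shuffle null beta-MNTD, per plot pair.

    Each row of ``perms`` is one permutation of taxon indices; the shuffled
    distance matrix is ``dmat[perm][:, perm]`` applied implicitly.
    """
    n_null = perms.shape[0]
    p = weights.shape[0]
    acc = np.zeros((p, p))
    acc2 = np.zeros((p, p))
    for r in range(n_null):
        perm = perms[r]
        for a in range(p):
            na = present_n[a]
            for b in range(a + 1, p):
                nb = present_n[b]
                s = 0.0
                for ii in range(na):
                    i = present_idx[a, ii]
                    pi = perm[i]
                    best = np.inf
                    for jj in range(nb):
                        d = dmat[pi, perm[present_idx[b, jj]]]
                        if d < best:
                            best = d
                    s += weights[a, i] * best
                for jj in range(nb):
                    j = present_idx[b, jj]
                    pj = perm[j]
                    best = np.inf
                    for ii in range(na):
                        d = dmat[perm[present_idx[a, ii]], pj]
                        if d < best:
                            best = d
                    s += weights[b, j] * best
                val = 0.5 * s
                acc[a, b] += val
                acc2[a, b] += val * val
    mean = np.zeros((p, p))
    sd = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            m = acc[a, b] / n_null
            var = acc2[a, b] / n_null - m * m
            if var < 0.0:
                var = 0.0
            mean[a, b] = m
            mean[b, a] = m
            sd[a, b] = np.sqrt(var)
            sd[b, a] = sd[a, b]
    return mean, sd
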