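"""Numba-compiled BiSSE pruning likelihood.

The binary-state speciation-extinction likelihood integrates, tip-to-root
along every branch, the coupled ODEs for the extinction probability E_i(t)
and the partial likelihood D_i(t) of a lineage in state i
(Maddison-Midford-Otto pruning):

    E_i' = mu_i - (lambda_i + mu_i + q_i) E_i + q_i E_j + lambda_i E_i^2
    D_i' = -(lambda_i + mu_i + q_i) D_i + q_i D_j + 2 lambda_i E_i D_i

with q_i the transition rate out of state i. At internal nodes
D_i = D_left,i * D_right,i * lambda_i. Branch integration uses an adaptive
Cash-Karp Runge-Kutta 4(5) with absolute/relative tolerance 1e-8, and the
D vector is renormalized per branch with log compensation so large trees do
not underflow.

State index 0 = generalist, 1 = specialist. The rate vector is
``[lambda_g, lambda_s, mu_g, mu_s, t_gs, t_sg]`` (t_gs: generalist ->
specialist).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .exceptions import InvalidArgumentError

ATOL = 1e-10
RTOL = 1e-10

ROOT_WEIGHTED = 0   # root state probabilities proportional to D (default)
ROOT_EQUAL = 1
ROOT_FIXED = 2      # root forced to `root_state`
ROOT_EQUILIBRIUM = 3  # stationary frequencies of the transition process


@njit(cache=True)
def _deriv(y, r, out):
    lam0, lam1, mu0, mu1, q01, q10 = r[0], r[1], r[2], r[3], r[4], r[5]
    e0, e1, d0, d1 = y[0], y[1], y[2], y[3]
    out[0] = mu0 - (lam0 + mu0 + q01) * e0 + q01 * e1 + lam0 * e0 * e0
    out[1] = mu1 - (lam1 + mu1 + q10) * e1 + q10 * e0 + lam1 * e1 * e1
    out[2] = -(lam0 + mu0 + q01) * d0 + q01 * d1 + 2.0 * lam0 * e0 * d0
    out[3] = -(lam1 + mu1 + q10) * d1 + q10 * d0 + 2.0 * lam1 * e1 * d1


@njit(cache=True)
def _integrate(y, tlen, r):
    """Adaptive Cash-Karp RK45 over one branch; modifies y in place."""
    if tlen <= 0.0:
        return True
    maxrate = 0.0
    for k in range(6):
        if r[k] > maxrate:
            maxrate = r[k]
    h = tlen if maxrate <= 0 else min(tlen, 0.5 / maxrate)
    t = 0.0
    k1 = np.empty(4); k2 = np.empty(4); k3 = np.empty(4)
    k4 = np.empty(4); k5 = np.empty(4); k6 = np.empty(4)
    ytmp = np.empty(4)
    y5 = np.empty(4)
    n_reject = 0
    while t < tlen:
        if t + h > tlen:
            h = tlen - t
        _deriv(y, r, k1)
        for i in range(4):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _deriv(ytmp, r, k2)
        for i in range(4):
            ytmp[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _deriv(ytmp, r, k3)
        for i in range(4):
            ytmp[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _deriv(ytmp, r, k4)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                -11.0 / 54.0 * k1[i] + 2.5 * k2[i]
                - 70.0 / 27.0 * k3[i] + 35.0 / 27.0 * k4[i]
            )
        _deriv(ytmp, r, k5)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                1631.0 / 55296.0 * k1[i] + 175.0 / 512.0 * k2[i]
                + 575.0 / 13824.0 * k3[i] + 44275.0 / 110592.0 * k4[i]
                + 253.0 / 4096.0 * k5[i]
            )
        _deriv(ytmp, r, k6)
        err = 0.0
        for i in range(4):
            y5[i] = y[i] + h * (
                37.0 / 378.0 * k1[i] + 250.0 / 621.0 * k3[i]
                + 125.0 / 594.0 * k4[i] + 512.0 / 1771.0 * k6[i]
            )
            y4 = y[i] + h * (
                2825.0 / 27648.0 * k1[i] + 18575.0 / 48384.0 * k3[i]
                + 13525.0 / 55296.0 * k4[i] + 277.0 / 14336.0 * k5[i]
                + 0.25 * k6[i]
            )
            scale = ATOL + RTOL * abs(y5[i])
            e = abs(y5[i] - y4) / scale
            if e > err:
                err = e
        if err <= 1.0 or h <= 1e-14 * tlen:
            t += h
            for i in range(4):
                y[i] = y5[i]
            if err > 0.0:
                fac = 0.9 * err ** -0.2
                if fac > 5.0:
                    fac = 5.0
                h *= fac
            else:
                h *= 5.0
        else:
            n_reject += 1
            fac = 0.9 * err ** -0.25
            if fac < 0.1:
                fac = 0.1
            h *= fac
            if n_reject > 10000:
                return False
    for i in range(4):
        if not np.isfinite(y[i]):
            return False
    return True


@njit(cache=True)
def loglik_kernel(r, is_tip, tip_state, blen, left, right, postorder,
                  root_policy, root_state):
    n_nodes = is_tip.shape[0]
    y = np.zeros((n_nodes, 4))
    logcomp = 0.0
    for idx in range(postorder.shape[0]):
        node = postorder[idx]
        if is_tip[node]:
            y[node, 2] = 1.0 if tip_state[node] == 0 else 0.0
            y[node, 3] = 1.0 if tip_state[node] == 1 else 0.0
        else:
            l = left[node]
            rr = right[node]
            y[node, 0] = 0.5 * (y[l, 0] + y[rr, 0])
            y[node, 1] = 0.5 * (y[l, 1] + y[rr, 1])
            d0 = y[l, 2] * y[rr, 2] * r[0]
            d1 = y[l, 3] * y[rr, 3] * r[1]
            s = d0 + d1
            if s <= 0.0 or not np.isfinite(s):
                return -np.inf
            y[node, 2] = d0 / s
            y[node, 3] = d1 / s
            logcomp += np.log(s)
        if blen[node] > 0.0:
            ok = _integrate(y[node], blen[node], r)
            if not ok:
                return -np.inf
            s = y[node, 2] + y[node, 3]
            if s <= 0.0 or not np.isfinite(s):
                return -np.inf
            y[node, 2] /= s
            y[node, 3] /= s
            logcomp += np.log(s)
    root = postorder[postorder.shape[0] - 1]
    d0 = y[root, 2]
    d1 = y[root, 3]
    if root_policy == 0:
        lik = (d0 * d0 + d1 * d1) / (d0 + d1)
    elif root_policy == 1:
        lik = 0.5 * (d0 + d1)
    elif root_policy == 2:
        lik = d0 if root_state == 0 else d1
    else:
        tot = r[4] + r[5]
        pi0 = r[5] / tot if tot > 0.0 else 0.5
        lik = pi0 * d0 + (1.0 - pi0) * d1
    if lik <= 0.0 or not np.isfinite(lik):
        return -np.inf
    return np.log(lik) + logcomp


def flatten_tree(phylo, tip_states: dict[str, str]):
    """Index a binary rooted tree into flat arrays for the kernel."""
    state_code = {"generalist": 0, "specialist": 1}
    nodes = list(phylo.tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    is_tip = np.zeros(n, dtype=np.bool_)
    tip_state = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    for i, nd in enumerate(nodes):
        children = nd.child_nodes()
        if not children:
            is_tip[i] = True
            label = nd.taxon.label
            if label not in tip_states:
                raise InvalidArgumentError(f"no state for tip {label!r}")
            state = tip_states[label]
            if state not in state_code:
                raise InvalidArgumentError(
                    f"unknown state {state!r} for tip {label!r}"
                )
            tip_state[i] = state_code[state]
        elif len(children) == 2:
            left[i] = index[id(children[0])]
            right[i] = index[id(children[1])]
        else:
            raise InvalidArgumentError(
                "tree must be strictly binary (resolve polytomies first)"
            )
        if nd.parent_node is not None:
            blen[i] = float(nd.edge.length or 0.0)
    postorder = np.arange(n, dtype=np.int64)
    return is_tip, tip_state, blen, left, right, postorder
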