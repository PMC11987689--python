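"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: closed-form
birth-death propagation, matrix-exponential Markov pruning, direct-sum
PERMANOVA F, scipy's one-way ANOVA, and exhaustive permutation
enumerations on tiny inputs.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.stats
from scipy.linalg import expm


# ---------------------------------------------------------------------------
# birth-death x Markov factorization of the state-independent BiSSE limit
# ---------------------------------------------------------------------------


def _bd_g(t: float, lam: float, mu: float) -> float:
    """Unnormalized per-lineage likelihood factor of a birth-death process."""
    r = lam - mu
    ert = np.exp(-r * t)
    return ert / (lam - mu * ert) ** 2


def bd_loglik(phylo, lam: float, mu: float) -> float:
    """Closed-form birth-death log-likelihood by pruning (no conditioning).

    The propagation factor over a branch spanning ages [t1, t2] above the
    present is g(t2)/g(t1); each internal node contributes one speciation
    factor lambda. The root contributes no extra weighting (matches an
    equal-weights root when multiplied by a character likelihood).
    """
    tree = phylo.tree
    age: dict[int, float] = {}
    logl = 0.0
    for node in tree.postorder_node_iter():
        if not node.child_nodes():
            age[id(node)] = 0.0
        else:
            child = node.child_nodes()[0]
            age[id(node)] = age[id(child)] + child.edge.length
            logl += np.log(lam)
        if node.parent_node is not None:
            t1 = age[id(node)]
            t2 = t1 + node.edge.length
            logl += np.log(_bd_g(t2, lam, mu) / _bd_g(t1, lam, mu))
    return logl


def markov_loglik(phylo, states: dict[str, str], q01: float, q10: float) -> float:
    """Two-state Markov character log-likelihood by expm pruning,
    uniform root prior (state 0 = generalist)."""
    q = np.array([[-q01, q01], [q10, -q10]])
    vals: dict[int, np.ndarray] = {}
    for node in phylo.tree.postorder_node_iter():
        if not node.child_nodes():
            vals[id(node)] = (
                np.array([1.0, 0.0])
                if states[node.taxon.label] == "generalist"
                else np.array([0.0, 1.0])
            )
        else:
            l, r = node.child_nodes()
            vals[id(node)] = vals[id(l)] * vals[id(r)]
        if node.parent_node is not None:
            vals[id(node)] = expm(q * node.edge.length) @ vals[id(node)]
    root = vals[id(phylo.tree.seed_node)]
    return float(np.log(0.5 * (root[0] + root[1])))


# ---------------------------------------------------------------------------
# permutation-test oracles (exhaustive enumeration on tiny inputs)
# ---------------------------------------------------------------------------


def anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    groups = [values[labels == g] for g in np.unique(labels)]
    f, _ = scipy.stats.f_oneway(*groups)
    return float(f) if np.isfinite(f) else np.inf


def exhaustive_permutation_p(values: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of all label orderings with ANOVA F >= observed."""
    f_obs = anova_f(values, labels)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(labels))):
        total += 1
        if anova_f(values, labels[list(perm)]) >= f_obs - 1e-12:
            count += 1
    return count / total


def permanova_f_direct(dmat: np.ndarray, labels: np.ndarray) -> float:
    """One-factor pseudo-F from within-group squared-distance sums."""
    n = len(labels)
    d2 = dmat ** 2
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    uniq = np.unique(labels)
    for g in uniq:
        members = np.flatnonzero(labels == g)
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    a = len(uniq)
    ss_between = ss_total - ss_within
    return float((ss_between / (a - 1)) / (ss_within / (n - a)))


def exhaustive_permanova_p(dmat: np.ndarray, labels: np.ndarray) -> float:
    f_obs = permanova_f_direct(dmat, labels)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(labels))):
        total += 1
        if permanova_f_direct(dmat, labels[list(perm)]) >= f_obs - 1e-12:
            count += 1
    return count / total


def mantel_r(x_cond: np.ndarray, y_cond: np.ndarray) -> float:
    xc = x_cond - x_cond.mean()
    yc = y_cond - y_cond.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def exhaustive_mantel_p(pd_mat: np.ndarray, indicator_cond: np.ndarray) -> float:
    """Two-sided exhaustive Mantel p for one class indicator."""
    from scipy.spatial.distance import squareform

    n = pd_mat.shape[0]
    r_obs = -mantel_r(squareform(pd_mat, checks=False), indicator_cond)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        pv = squareform(pd_mat[np.ix_(perm, perm)], checks=False)
        if abs(-mantel_r(pv, indicator_cond)) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total
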