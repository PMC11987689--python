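"""Generalist/specialist classification and state-dependent diversification.

Levins niche width of taxon j over N plots,

    B_j = 1 / sum_i P_{i,j}^2,

uses P_{i,j} = the proportion of taxon j's total abundance found in plot i,
so B ranges from 1 (confined to one plot) to N (perfectly even occupancy).
Taxa at or above a threshold niche width (default 9) are called habitat
generalists, the rest specialists.

The evolutionary rates of the two guilds — state-dependent speciation
(lambda), extinction (mu) and transition (t) rates — are estimated under the
binary-state speciation-extinction (BiSSE) model: an ODE pruning likelihood
(:mod:`._bisse`), a two-stage maximum-likelihood search in log-rate space,
and a slice-sampling MCMC with independent exponential priors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from ._bisse import (
    ROOT_EQUAL,
    ROOT_EQUILIBRIUM,
    ROOT_FIXED,
    ROOT_WEIGHTED,
    flatten_tree,
    loglik_kernel,
)
from .exceptions import (
    ConvergenceError,
    InvalidArgumentError,
    UndefinedValueError,
)
from .io_tables import CommunityTable, Phylogeny

logger = logging.getLogger(__name__)

_ROOT_POLICIES = {
    "weighted": ROOT_WEIGHTED,
    "equal": ROOT_EQUAL,
    "fixed": ROOT_FIXED,
    "equilibrium": ROOT_EQUILIBRIUM,
}

# log-rate search box in unit-height time units (trees are rescaled to
# height 1 before fitting, so e.g. +4.5 means ~90 events per tree depth)
_LOG_BOUNDS = (-9.0, 4.5)


# ---------------------------------------------------------------------------
# niche width
# ---------------------------------------------------------------------------


def niche_width(community: CommunityTable) -> pd.Series:
    """Levins niche width B per taxon; all-zero taxa are omitted and logged."""
    totals = community.abundance.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero taxa omitted from niche width",
                       int(zero.sum()))
    keep = ~zero
    p = community.abundance[:, keep] / totals[keep]
    b = 1.0 / (p ** 2).sum(axis=0)
    taxa = [t for t, k in zip(community.taxon_ids, keep) if k]
    return pd.Series(b, index=pd.Index(taxa, name="taxon_id"), name="B")


@dataclass
class NicheClassification:
    """Per-taxon niche widths with the generalist/specialist split."""

    table: pd.DataFrame          # columns: B, class
    threshold: float
    generalist_fraction: float


def classify_niche(b: pd.Series, threshold: float = 9.0) -> NicheClassification:
    """Split taxa at the threshold niche width; ties (B == threshold) are
    generalists."""
    if threshold < 1:
        raise InvalidArgumentError("threshold must be >= 1 (B is never below 1)")
    cls = np.where(b >= threshold, "generalist", "specialist")
    table = pd.DataFrame({"B": b, "class": cls})
    frac = float((cls == "generalist").mean()) if len(cls) else float("nan")
    return NicheClassification(table=table, threshold=float(threshold),
                               generalist_fraction=frac)


def niche_trait_relation(
    b: pd.Series,
    trait_per_species: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float, int]:
    """Rank correlation between niche width and mean trait per species.

    A positive relationship suggests generalists broaden their functional
    repertoire; a negative one ties functions to specific habitats. Returns
    (Spearman rho, two-sided permutation p, sign).
    """
    shared = b.index.intersection(trait_per_species.index)
    if len(shared) < 3:
        raise InvalidArgumentError("need >= 3 shared taxa")
    x = b.loc[shared].to_numpy()
    y = trait_per_species.loc[shared].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedValueError("constant vector; rank correlation undefined")
    rho = scipy.stats.spearmanr(x, y).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = scipy.stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(rho), float(p), int(np.sign(rho))


# ---------------------------------------------------------------------------
# BiSSE
# ---------------------------------------------------------------------------


@dataclass
class BisseRates:
    """The six BiSSE rates (g = generalist, s = specialist).

    ``t_gs`` is the generalist-to-specialist transition rate, ``t_sg`` the
    reverse.
    """

    lambda_g: float
    lambda_s: float
    mu_g: float
    mu_s: float
    t_gs: float
    t_sg: float

    def validate(self) -> None:
        for name, v in vars(self).items():
            if not np.isfinite(v) or v < 0:
                raise InvalidArgumentError(f"rate {name} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda_g, self.lambda_s, self.mu_g, self.mu_s,
                         self.t_gs, self.t_sg])

    @classmethod
    def from_array(cls, r: np.ndarray) -> "BisseRates":
        return cls(*[float(v) for v in r])


@dataclass
class BisseFit:
    """Maximum-likelihood rates plus optional MCMC samples and diagnostics."""

    ml_rates: BisseRates
    log_likelihood: float
    gradient_norm: float
    converged: bool
    mcmc_samples: pd.DataFrame | None = None
    prior_mean: float | None = None
    n_rejected: int = 0


def _prepare(tree: Phylogeny, tip_states: dict[str, str]):
    if not tree.is_binary():
        raise InvalidArgumentError(
            "tree must be binary; call Phylogeny.resolve_polytomies() first"
        )
    return flatten_tree(tree, tip_states)


def _prepare_scaled(tree: Phylogeny, tip_states: dict[str, str]):
    """Flatten the tree and rescale branch lengths to unit height.

    Rates fitted in scaled time are actual rates times the height H, and the
    scaled log-likelihood exceeds the original by (n_tips - 1) * log(H)
    (the branching-time measure Jacobian). Rescaling keeps the optimizer's
    search box meaningful for trees of any depth and keeps the adaptive
    integrator fast.
    """
    is_tip, tip_state, blen, left, right, postorder = _prepare(tree, tip_states)
    height = _tree_height(tree)
    arrays = (is_tip, tip_state, blen / height, left, right, postorder)
    correction = (tree.n_tips - 1) * np.log(height)
    return arrays, height, correction


def _tree_height(tree: Phylogeny) -> float:
    best = 0.0
    for leaf in tree.tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += float(node.edge.length or 0.0)
            node = node.parent_node
        best = max(best, d)
    if best <= 0:
        raise InvalidArgumentError("tree has zero height")
    return best


def bisse_loglik(
    tree: Phylogeny,
    tip_states: dict[str, str],
    rates: BisseRates,
    root_policy: str = "weighted",
    root_state: str = "generalist",
) -> float:
    """BiSSE log-likelihood of the tip states on the tree.

    ``root_policy``: "weighted" (root state probabilities proportional to
    the partial likelihoods, the common default), "equal", "equilibrium"
    (stationary frequencies of the transition process), or "fixed" (use
    ``root_state``). Returns -inf for impossible data.
    """
    rates.validate()
    if root_policy not in _ROOT_POLICIES:
        raise InvalidArgumentError(f"unknown root policy {root_policy!r}")
    arrays = _prepare(tree, tip_states)
    state_idx = 0 if root_state == "generalist" else 1
    return float(loglik_kernel(rates.as_array(), *arrays,
                               _ROOT_POLICIES[root_policy], state_idx))


def _tree_scale(tree: Phylogeny) -> float:
    """Crude speciation-rate scale: (n - 2) / total branch length (Yule MLE)."""
    total = sum(
        float(e.length or 0.0) for e in tree.tree.preorder_edge_iter()
        if e.head_node is not tree.tree.seed_node
    )
    n = tree.n_tips
    return max((n - 2) / total, 1e-6) if total > 0 else 1.0


def bisse_ml(
    tree: Phylogeny,
    tip_states: dict[str, str],
    restarts: int = 2,
    root_policy: str = "weighted",
    root_state: str = "generalist",
    seed: int | None = None,
) -> BisseFit:
    """Two-stage maximum-likelihood search in log-rate space.

    Stage 1 runs a coarse derivative-free search (Nelder-Mead) from a
    birth-death moment heuristic (and ``restarts`` perturbed copies) to find
    a starting point; stage 2 refines it with box-constrained L-BFGS-B. The
    returned fit carries the finite-difference gradient norm at the optimum
    as a local-optimality diagnostic.
    """
    arrays, height, correction = _prepare_scaled(tree, tip_states)
    policy = _ROOT_POLICIES[root_policy]
    state_idx = 0 if root_state == "generalist" else 1
    lo, hi = _LOG_BOUNDS

    def negloglik(x: np.ndarray) -> float:
        r = np.exp(np.clip(x, lo, hi))
        ll = loglik_kernel(r, *arrays, policy, state_idx)
        return -ll if np.isfinite(ll) else 1e10

    lam0 = _tree_scale(tree) * height  # per unit-height time
    base = np.log(np.array([lam0, lam0, lam0 / 2, lam0 / 2, lam0 / 10, lam0 / 10]))
    rng = np.random.default_rng(seed)
    starts = [base] + [base + rng.normal(0, 0.7, size=6) for _ in range(restarts)]

    stage1_best, stage1_val = None, np.inf
    for x0 in starts:
        res = scipy.optimize.minimize(
            negloglik, x0, method="Nelder-Mead",
            options=dict(maxiter=800, xatol=1e-3, fatol=1e-3),
        )
        if res.fun < stage1_val:
            stage1_best, stage1_val = res.x, res.fun

    res = scipy.optimize.minimize(
        negloglik, stage1_best, method="L-BFGS-B",
        bounds=[(lo, hi)] * 6,
        options=dict(maxiter=500, ftol=1e-12, gtol=1e-8),
    )
    best_x = res.x if res.fun <= stage1_val else stage1_best
    best_ll = -min(res.fun, stage1_val)
    if not np.isfinite(best_ll):
        raise ConvergenceError(
            "BiSSE likelihood non-finite at every point searched",
            best=BisseRates.from_array(np.exp(stage1_best) / height),
            status=str(res.message),
        )

    grad = scipy.optimize.approx_fprime(best_x, negloglik, 1e-6)
    gnorm = float(np.linalg.norm(grad))
    converged = bool(res.success) or gnorm < 1e-2
    if not converged:
        logger.warning("BiSSE ML convergence flag not set (|grad| = %.3g; %s)",
                       gnorm, res.message)
    return BisseFit(
        ml_rates=BisseRates.from_array(np.exp(best_x) / height),
        log_likelihood=float(best_ll - correction),
        gradient_norm=gnorm,
        converged=converged,
    )


def bisse_mcmc(
    tree: Phylogeny,
    tip_states: dict[str, str],
    start: BisseRates,
    steps: int = 1000,
    seed: int | None = None,
    root_policy: str = "weighted",
    root_state: str = "generalist",
    prior_mean: float | None = None,
    use_likelihood: bool = True,
    slice_width: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Coordinate-wise slice sampling over log-rates.

    Priors are independent exponentials on the natural-scale rates; when
    ``prior_mean`` is None it defaults to twice the tree's net-
    diversification heuristic (reported in the returned metadata).
    ``use_likelihood=False`` samples the prior alone (a sampler check).
    Returns one row per step with the six rates and the log posterior.
    """
    start.validate()
    arrays, height, correction = _prepare_scaled(tree, tip_states)
    policy = _ROOT_POLICIES[root_policy]
    state_idx = 0 if root_state == "generalist" else 1
    if prior_mean is None:
        prior_mean = 2.0 * _tree_scale(tree)
    beta = 1.0 / prior_mean

    def logpost(x: np.ndarray) -> float:
        # x holds log-rates in unit-height time; priors act on actual rates
        r_actual = np.exp(x) / height
        lp = float(np.sum(np.log(beta) - beta * r_actual + np.log(r_actual)))
        if not use_likelihood:
            return lp
        ll = loglik_kernel(np.exp(x), *arrays, policy, state_idx)
        return lp + (ll - correction) if np.isfinite(ll) else -np.inf

    rng = np.random.default_rng(seed)
    x = np.log(np.clip(start.as_array() * height, 1e-10, None))
    lp = logpost(x)
    if not np.isfinite(lp):
        raise InvalidArgumentError("log posterior non-finite at start")

    n_rejected = 0
    rows = np.empty((steps, 7))
    for step in range(steps):
        for i in range(6):
            y = lp + np.log(rng.uniform())
            left = x[i] - slice_width * rng.uniform()
            right = left + slice_width
            for _ in range(50):  # stepping out
                if logpost(_with(x, i, left)) <= y:
                    break
                left -= slice_width
            for _ in range(50):
                if logpost(_with(x, i, right)) <= y:
                    break
                right += slice_width
            while True:  # shrinkage
                prop = rng.uniform(left, right)
                cand = _with(x, i, prop)
                lp_cand = logpost(cand)
                if lp_cand > y:
                    x, lp = cand, lp_cand
                    break
                n_rejected += 1
                if prop < x[i]:
                    left = prop
                else:
                    right = prop
                if right - left < 1e-12:
                    break  # numerically stuck; keep current value
        rows[step, :6] = np.exp(x) / height
        rows[step, 6] = lp
    samples = pd.DataFrame(
        rows,
        columns=["lambda_g", "lambda_s", "mu_g", "mu_s", "t_gs", "t_sg",
                 "log_posterior"],
    )
    meta = dict(prior_mean=float(prior_mean), prior_rate=float(beta),
                steps=steps, n_rejected=n_rejected,
                use_likelihood=use_likelihood)
    return samples, meta


def _with(x: np.ndarray, i: int, v: float) -> np.ndarray:
    out = x.copy()
    out[i] = v
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class RateSummary:
    """Derived quantities: net diversification per state, transition ratio."""

    net_generalist: float
    net_specialist: float
    log_transition_ratio: float  # ln(t_gs / t_sg)
    posterior_net_generalist: np.ndarray | None = None
    posterior_net_specialist: np.ndarray | None = None


def summarize_rates(fit: BisseFit) -> RateSummary:
    """Net rates lambda - mu per state and ln(t_gs / t_sg), with posterior
    net-rate draws when MCMC samples are attached."""
    r = fit.ml_rates
    if r.t_sg == 0:
        warnings.warn("t_sg = 0: transition log-ratio is +inf", stacklevel=2)
        ratio = np.inf if r.t_gs > 0 else np.nan
    else:
        ratio = np.log(r.t_gs / r.t_sg) if r.t_gs > 0 else -np.inf
    post_g = post_s = None
    if fit.mcmc_samples is not None and len(fit.mcmc_samples):
        post_g = (fit.mcmc_samples["lambda_g"] - fit.mcmc_samples["mu_g"]).to_numpy()
        post_s = (fit.mcmc_samples["lambda_s"] - fit.mcmc_samples["mu_s"]).to_numpy()
    return RateSummary(
        net_generalist=float(r.lambda_g - r.mu_g),
        net_specialist=float(r.lambda_s - r.mu_s),
        log_transition_ratio=float(ratio),
        posterior_net_generalist=post_g,
        posterior_net_specialist=post_s,
    )
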