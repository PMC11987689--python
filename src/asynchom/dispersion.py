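"""Homogenization testing: distances, ordination, and dispersion statistics.

Community homogenization is operationalized as a reduction of within-group
multivariate dispersion: the mean distance of plots to their group centroid
in principal-coordinate space. This module provides

* Bray-Curtis dissimilarities between plots,
* principal coordinates analysis (Gower double-centering; negative
  eigenvalues retained, no correction),
* the multivariate-dispersion permutation test (PERMDISP sensu Anderson's
  ``betadisper``: distances to group centroids with imaginary-axis handling,
  one-way F, label-permutation p),
* Tukey HSD on the per-plot dispersions with a compact letter display,
* one- and two-factor PERMANOVA on the distance matrix,
* per-group mean-distance summaries (optionally natural-log transformed).

Permutation p-values are (count >= observed + 1) / (n_perm + 1) from seeded
random label permutations, except on tiny inputs where all n! orderings are
no more than n_perm: these are enumerated exhaustively and p = count / n!.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .exceptions import (
    InsufficientSamplesError,
    InvalidDesignError,
    InvalidInputError,
)
from .io_tables import CommunityTable

logger = logging.getLogger(__name__)

_EIG_REL_TOL = 1e-8


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y)."""
    x = table.abundance
    if np.any(x.sum(axis=1) == 0):
        raise InvalidInputError("all-zero plot row; Bray-Curtis undefined")
    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.plot_ids)


def pcoa(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Classical principal coordinates analysis.

    Gower-centers ``-d**2 / 2`` and eigendecomposes. Returns all eigenvalues
    sorted descending (negative ones retained) and the coordinate matrix
    whose column j is ``v_j * sqrt(|eigval_j|)``; columns with negative
    eigenvalues are the "imaginary" axes.
    """
    n = d.shape[0]
    if n < 3:
        raise InsufficientSamplesError("PCoA needs at least 3 samples")
    a = -0.5 * np.asarray(d.data) ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    g = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = eigvecs * np.sqrt(np.abs(eigvals))
    return eigvals, coords


@dataclass
class DispersionResult:
    """Per-sample distances to group centroids and the PERMDISP test."""

    ids: list[str]
    groups: np.ndarray
    distances: np.ndarray          # per-sample distance to own group centroid
    group_means: dict[str, float]
    f_statistic: float
    p_value: float
    eigenvalues: np.ndarray
    coordinates: np.ndarray
    n_permutations: int
    n_floored: int = 0             # squared distances clipped at 0


@dataclass
class PermanovaResult:
    """Pseudo-F partitioning of a distance matrix by one or two factors."""

    terms: list[str]
    pseudo_f: dict[str, float]
    r_squared: dict[str, float]    # includes a "Residual" entry
    p_values: dict[str, float]
    n_permutations: int


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F on ``values`` grouped by integer ``codes``."""
    n = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        sub = values[codes == g]
        ss_between += len(sub) * (sub.mean() - grand) ** 2
        ss_within += ((sub - sub.mean()) ** 2).sum()
    # numerical floor: treat between-group SS at rounding level as exactly 0
    total_scale = max(ss_between + ss_within, (values ** 2).sum(), 1e-300)
    if ss_between <= 1e-10 * total_scale:
        return 0.0
    ms_between = ss_between / (n_groups - 1)
    df_within = n - n_groups
    if ss_within <= 0:
        return np.inf
    return ms_between / (ss_within / df_within)


def _permutation_p(
    stat_fn,
    observed: float,
    n: int,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p for a statistic of a sample ordering.

    When all n! orderings number no more than ``n_perm`` they are enumerated
    exhaustively and p = count / n!; otherwise ``n_perm`` random orderings
    give p = (count + 1) / (n_perm + 1). Ties use a 1e-12 tolerance.
    """
    total = math.factorial(n)
    if total <= n_perm:
        count = 0
        for perm in itertools.permutations(range(n)):
            if stat_fn(np.asarray(perm)) >= observed - 1e-12:
                count += 1
        return count / total
    count = 0
    for _ in range(n_perm):
        if stat_fn(rng.permutation(n)) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def centroid_distances(
    eigvals: np.ndarray, coords: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, int]:
    """Distance of each sample to its group centroid in full PCoA space.

    Axes with negative eigenvalues contribute negatively to the squared
    distance (the imaginary-axis formulation); squared distances are floored
    at zero before the square root, counting how often flooring fired.
    """
    tol = _EIG_REL_TOL * np.abs(eigvals).max() if len(eigvals) else 0.0
    real = eigvals > tol
    imag = eigvals < -tol
    z2 = np.empty(len(codes))
    for g in range(n_groups):
        members = codes == g
        delta = coords[members] - coords[members].mean(axis=0)
        z2[members] = (delta[:, real] ** 2).sum(axis=1) - (
            delta[:, imag] ** 2
        ).sum(axis=1)
    n_floored = int((z2 < 0).sum())
    if n_floored:
        logger.warning("floored %d negative squared centroid distances", n_floored)
    return np.sqrt(np.clip(z2, 0.0, None)), n_floored


def permdisp(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Homogeneity-of-dispersions test (distance to group centroid).

    The F statistic is a one-way ANOVA on the per-sample distances to their
    group centroid; significance comes from freely permuting group labels
    across samples.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != d.shape[0]:
        raise InvalidDesignError("one group label per sample required")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise InvalidDesignError("PERMDISP needs at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = labels[np.argmin(counts)]
        raise InvalidDesignError(f"singleton group {small!r}")

    eigvals, coords = pcoa(d)
    z, n_floored = centroid_distances(eigvals, coords, codes, len(labels))
    f_obs = _anova_f(z, codes, len(labels))

    rng = np.random.default_rng(seed)
    p = _permutation_p(
        lambda order: _anova_f(z, codes[order], len(labels)),
        f_obs, len(codes), n_perm, rng,
    )

    means = {lab: float(z[codes == i].mean()) for i, lab in enumerate(labels)}
    return DispersionResult(
        ids=list(d.ids), groups=groups, distances=z, group_means=means,
        f_statistic=float(f_obs), p_value=float(p), eigenvalues=eigvals,
        coordinates=coords, n_permutations=n_perm, n_floored=n_floored,
    )


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display
# ---------------------------------------------------------------------------


def _maximal_cliques(adjacency: np.ndarray) -> list[frozenset[int]]:
    """Bron-Kerbosch maximal cliques of a small undirected graph."""
    n = adjacency.shape[0]
    neighbors = [frozenset(np.flatnonzero(adjacency[i]) ) - {i} for i in range(n)]
    cliques: list[frozenset[int]] = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        for v in list(p):
            expand(r | {v}, p & neighbors[v], x & neighbors[v])
            p.remove(v)
            x.add(v)

    expand(set(), set(range(n)), set())
    return cliques


def compact_letter_display(
    group_names: list[str], p_matrix: np.ndarray, alpha: float = 0.05
) -> dict[str, str]:
    """Letters such that two groups share one iff not significantly different.

    Groups are vertices, non-significant pairs are edges; each maximal clique
    of that graph gets one letter.
    """
    k = len(group_names)
    adj = (p_matrix >= alpha) | np.eye(k, dtype=bool)
    cliques = _maximal_cliques(adj)
    # stable letter order: clique containing the first group first, etc.
    cliques.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in group_names}
    for letter, clique in zip(alphabet, cliques):
        for i in sorted(clique):
            letters[group_names[i]] += letter
    return letters


def tukey_hsd_dispersion(
    res: DispersionResult, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Studentized-range pairwise test on the distances-to-centroid.

    Returns the symmetric adjusted-p matrix (as a DataFrame) and a compact
    letter display at ``alpha``.
    """
    labels = sorted(set(res.groups))
    samples = [res.distances[res.groups == lab] for lab in labels]
    if len(labels) < 2:
        raise InvalidDesignError("Tukey HSD needs at least 2 groups")
    if all(np.allclose(s, samples[0].mean()) for s in samples):
        # degenerate: identical values everywhere -> no differences
        p = np.ones((len(labels), len(labels)))
    else:
        p = scipy.stats.tukey_hsd(*samples).pvalue
    pm = pd.DataFrame(p, index=labels, columns=labels)
    return pm, compact_letter_display(labels, p, alpha=alpha)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _dummy(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((len(codes), n_levels))
    out[np.arange(len(codes)), codes] = 1.0
    return out


def permanova(
    d: DistanceMatrix,
    factors,
    n_perm: int = 999,
    seed: int | None = None,
    interaction: bool = False,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA (pseudo-F) for 1-2 crossed factors.

    ``factors`` is a sequence of labels (one factor) or a DataFrame / dict of
    up to two label columns. Sums of squares are sequential (terms in the
    given order), so term plus residual R-squared values sum to one.
    Significance comes from freely permuting samples.
    """
    if isinstance(factors, (pd.DataFrame, dict)):
        fdf = pd.DataFrame(factors)
    else:
        fdf = pd.DataFrame({"factor": list(factors)})
    if fdf.shape[1] > 2:
        raise InvalidDesignError("at most two crossed factors supported")
    if len(fdf) != d.shape[0]:
        raise InvalidDesignError("one label per sample required per factor")
    for col in fdf.columns:
        if fdf[col].nunique() < 2:
            raise InvalidDesignError(f"factor {col!r} has a single level")

    n = d.shape[0]
    a = -0.5 * np.asarray(d.data) ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    g_full = centerer @ a @ centerer

    # sequential model terms
    terms: list[str] = list(fdf.columns)
    designs = []
    running = [np.ones((n, 1))]
    for col in terms:
        codes, _ = pd.factorize(fdf[col])
        running.append(_dummy(codes, codes.max() + 1))
        designs.append(np.hstack(running))
    if interaction and len(terms) == 2:
        combo, _ = pd.factorize(
            fdf[terms[0]].astype(str) + "\x1f" + fdf[terms[1]].astype(str)
        )
        running.append(_dummy(combo, combo.max() + 1))
        designs.append(np.hstack(running))
        terms = terms + [f"{terms[0]}:{terms[1]}"]

    hats = [_hat(x) for x in designs]
    df_terms = [int(np.round(np.trace(h))) - 1 for h in hats]  # cumulative df
    df_model = df_terms[-1]
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise InvalidDesignError("saturated design: no residual df")

    def stats_for(g: np.ndarray) -> tuple[np.ndarray, float]:
        ss_total = np.trace(g)
        ss_cum = np.array([np.trace(h @ g) for h in hats])
        ss_terms = np.diff(np.concatenate([[0.0], ss_cum]))
        ss_res = ss_total - ss_cum[-1]
        ms_res = ss_res / df_res
        df_each = np.diff(np.concatenate([[0], df_terms]))
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_terms / df_each) / ms_res if ms_res > 0 else np.full(
                len(ss_terms), np.inf
            )
        return np.nan_to_num(f, nan=0.0, posinf=np.inf), ss_total

    f_obs, ss_total = stats_for(g_full)
    ss_cum = np.array([np.trace(h @ g_full) for h in hats])
    ss_terms = np.diff(np.concatenate([[0.0], ss_cum]))
    ss_res = ss_total - ss_cum[-1]

    rng = np.random.default_rng(seed)
    total = math.factorial(n)
    if total <= n_perm:  # exhaustive enumeration for tiny designs
        counts = np.zeros(len(terms))
        for perm in itertools.permutations(range(n)):
            f_perm, _ = stats_for(g_full[np.ix_(perm, perm)])
            counts += f_perm >= f_obs - 1e-12
        p = counts / total
    else:
        counts = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            f_perm, _ = stats_for(g_full[np.ix_(perm, perm)])
            counts += f_perm >= f_obs - 1e-12
        p = (counts + 1) / (n_perm + 1)

    r2 = {t: float(ss / ss_total) for t, ss in zip(terms, ss_terms)}
    r2["Residual"] = float(ss_res / ss_total)
    return PermanovaResult(
        terms=terms,
        pseudo_f={t: float(f) for t, f in zip(terms, f_obs)},
        r_squared=r2,
        p_values={t: float(pv) for t, pv in zip(terms, p)},
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------


@dataclass
class GroupMeanDistance:
    """Per-group (optionally ln) mean distance-to-centroid with ANOVA letters."""

    group_means: dict[str, float]
    anova_f: float
    anova_p: float
    letters: dict[str, str]
    log_transformed: bool


def group_mean_distance(
    res: DispersionResult, log_transform: bool = False, alpha: float = 0.05
) -> GroupMeanDistance:
    """Summarize dispersions per group, with a one-way ANOVA and letters."""
    z = res.distances.astype(float).copy()
    if log_transform:
        nonpos = z <= 0
        if nonpos.any():
            warnings.warn(
                f"{int(nonpos.sum())} non-positive distance(s) floored at "
                "machine epsilon before log", stacklevel=2,
            )
            z[nonpos] = np.finfo(float).eps
        z = np.log(z)
    labels = sorted(set(res.groups))
    samples = [z[res.groups == lab] for lab in labels]
    means = {lab: float(s.mean()) for lab, s in zip(labels, samples)}
    if all(np.allclose(s, samples[0].mean()) for s in samples):
        f_stat, p_val = 0.0, 1.0
        p_matrix = np.ones((len(labels), len(labels)))
    else:
        f_stat, p_val = scipy.stats.f_oneway(*samples)
        p_matrix = scipy.stats.tukey_hsd(*samples).pvalue
    letters = compact_letter_display(labels, p_matrix, alpha=alpha)
    return GroupMeanDistance(
        group_means=means, anova_f=float(f_stat), anova_p=float(p_val),
        letters=letters, log_transformed=log_transform,
    )
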