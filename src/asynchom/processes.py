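"""Ecological assembly-process estimation from turnover null models.

The framework compares observed phylogenetic turnover between plot pairs to
null expectations and sorts each pair into one of five assembly processes:

* beta-MNTD — abundance-weighted mean distance from each taxon in one plot to
  its nearest phylogenetic relative in the other;
* beta-NTI — the standardized deviation of beta-MNTD from a tip-shuffle null
  (taxa relabeled across the tree's tips);
* RC_bray — abundance-based Raup-Crick: where the observed Bray-Curtis
  dissimilarity falls within a null of randomly reassembled communities that
  preserve each plot's richness and total abundance (species drawn with
  probability proportional to occupancy, individuals proportional to regional
  relative abundance), rescaled to [-1, 1];
* classification — beta-NTI > 2: heterogeneous selection; < -2: homogeneous
  selection; otherwise RC_bray > 0.95: dispersal limitation; < -0.95:
  homogenizing dispersal; in between: drift;
* functional dissimilarity (beta_diss) — sum |lambda_m - lambda_n| /
  sum (lambda_m + lambda_n) over all taxon x trait intensities of two plots,
  paired against beta-NTI in the turnover-coupling table.

A Mantel correlogram against environmental distances serves as the
phylogenetic-signal precheck the framework assumes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, squareform
from skbio import DistanceMatrix

from ._kernels import bmntd_null_moments, bmntd_pairs
from .exceptions import (
    CrossReferenceError,
    InvalidArgumentError,
    InvalidInputError,
    UndefinedValueError,
)
from .io_tables import CommunityTable, Phylogeny, TraitIntensityTable

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95
_TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# beta-MNTD / beta-NTI
# ---------------------------------------------------------------------------


def _presence_arrays(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p, n = weights.shape
    present_n = (weights > 0).sum(axis=1).astype(np.int64)
    present_idx = np.zeros((p, int(present_n.max())), dtype=np.int64)
    for k in range(p):
        idx = np.flatnonzero(weights[k] > 0)
        present_idx[k, : len(idx)] = idx
    return present_idx, present_n


def _weights(community: CommunityTable, abundance_weighted: bool) -> np.ndarray:
    if abundance_weighted:
        return community.relative()
    pres = (community.abundance > 0).astype(float)
    return pres / pres.sum(axis=1, keepdims=True)


def _patristic(community: CommunityTable, tree: Phylogeny) -> np.ndarray:
    missing = set(community.taxon_ids) - set(tree.tip_labels)
    if missing:
        raise CrossReferenceError(
            f"community taxa missing from tree: {sorted(missing)}"
        )
    return tree.patristic_distances(community.taxon_ids).to_numpy()


def beta_mntd(
    community: CommunityTable,
    tree: Phylogeny,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """Between-plot mean nearest-taxon phylogenetic distance."""
    dmat = _patristic(community, tree)
    w = _weights(community, abundance_weighted)
    idx, n = _presence_arrays(w)
    out = bmntd_pairs(w, idx, n, dmat)
    return DistanceMatrix(out, ids=community.plot_ids)


def beta_nti(
    community: CommunityTable,
    tree: Phylogeny,
    n_null: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Standardized beta-MNTD deviation under the tip-shuffle null.

    Null communities relabel taxa across the tree tips (equivalently,
    jointly permute rows and columns of the patristic matrix); the same
    shuffle is applied to every plot pair. Pairs whose null distribution is
    degenerate (sd = 0, e.g. a star tree) are returned as NaN and counted in
    the log.
    """
    if n_null < 99:
        raise InvalidArgumentError("n_null must be >= 99")
    dmat = _patristic(community, tree)
    w = _weights(community, abundance_weighted)
    idx, n = _presence_arrays(w)
    obs = bmntd_pairs(w, idx, n, dmat)

    rng = np.random.default_rng(seed)
    n_taxa = community.n_taxa
    perms = np.stack([rng.permutation(n_taxa) for _ in range(n_null)]).astype(np.int64)
    mean, sd = bmntd_null_moments(w, idx, n, dmat, perms)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    np.fill_diagonal(z, 0.0)
    undefined = ~np.isfinite(z)
    np.fill_diagonal(undefined, False)
    if undefined.any():
        logger.warning(
            "beta-NTI undefined (zero null sd) for %d plot pairs",
            int(undefined.sum() // 2),
        )
        z[undefined] = np.nan
    return pd.DataFrame(z, index=community.plot_ids, columns=community.plot_ids)


# ---------------------------------------------------------------------------
# Raup-Crick (abundance-based, Bray-Curtis)
# ---------------------------------------------------------------------------


def _regional_pool(counts: np.ndarray):
    """Occupancy and regional-abundance weights of the species pool."""
    occupancy = (counts > 0).sum(axis=0).astype(float)
    pool = np.flatnonzero(occupancy > 0)
    occ_w = occupancy[pool] / occupancy[pool].sum()
    regional = counts.sum(axis=0).astype(float)
    reg_w = regional[pool] / regional[pool].sum()
    return pool, occ_w, reg_w


def _null_counts(
    rng: np.random.Generator,
    occ_w: np.ndarray,
    reg_w: np.ndarray,
    richness: int,
    total: int,
    n: int,
) -> np.ndarray:
    """(n, pool) null assemblages with fixed richness and total abundance.

    Weighted sampling without replacement uses exponential sort keys
    (Efraimidis-Spirakis): the r smallest values of Exp(1)/w select species
    with probability proportional to occupancy. Each selected species gets
    one individual; the rest are multinomial with regional weights.
    """
    npool = len(occ_w)
    keys = rng.exponential(size=(n, npool)) / occ_w
    chosen_idx = np.argpartition(keys, richness - 1, axis=1)[:, :richness]
    member = np.zeros((n, npool), dtype=bool)
    np.put_along_axis(member, chosen_idx, True, axis=1)
    out = member.astype(np.int64)
    if total > richness:
        sub = np.where(member, reg_w, 0.0)
        sub /= sub.sum(axis=1, keepdims=True)
        out += rng.multinomial(total - richness, sub)
    return out


def raup_crick_null_draw(
    community: CommunityTable,
    plot_id: str,
    n: int = 1,
    seed: int | None = None,
) -> np.ndarray:
    """Draw ``n`` null assemblages for one plot (full taxon width).

    The same richness/total-abundance constrained draw the Raup-Crick null
    uses; exposed so the null can be checked against itself.
    """
    counts = np.round(community.abundance).astype(np.int64)
    pool, occ_w, reg_w = _regional_pool(counts)
    row = community.plot_ids.index(plot_id)
    rng = np.random.default_rng(seed)
    draws = _null_counts(rng, occ_w, reg_w,
                         int((counts[row] > 0).sum()),
                         int(counts[row].sum()), n)
    out = np.zeros((n, community.n_taxa), dtype=np.int64)
    out[:, pool] = draws
    return out


def raup_crick_bray(
    community: CommunityTable,
    n_null: int = 999,
    seed: int | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Abundance-based Raup-Crick deviation of Bray-Curtis dissimilarity.

    For each plot pair, null communities are reassembled preserving each
    plot's observed richness and total individual count: species are drawn
    without replacement with probability proportional to their occupancy
    across all plots, then the remaining individuals are distributed
    multinomially proportional to regional relative abundances.

        RC = 2 * [(#(null < obs) + 0.5 * #(null = obs)) / n_null] - 1

    Ties use a 1e-12 tolerance. Abundances are treated as individual counts
    (rounded to integers). When ``pairs`` is given only those plot pairs are
    evaluated (the regional pool still uses every plot); other entries are
    NaN.
    """
    if n_null < 99:
        raise InvalidArgumentError("n_null must be >= 99")
    counts = np.round(community.abundance).astype(np.int64)
    if counts.sum() == 0:
        raise InvalidInputError("empty regional pool")
    pool, occ_w, reg_w = _regional_pool(counts)

    p = community.n_plots
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    rng = np.random.default_rng(seed)

    def null_draws(plot: int, n: int) -> np.ndarray:
        return _null_counts(rng, occ_w, reg_w, int(richness[plot]),
                            int(totals[plot]), n)

    if pairs is None:
        wanted = None
    else:
        idx = {pid: i for i, pid in enumerate(community.plot_ids)}
        wanted = {tuple(sorted((idx[a], idx[b]))) for a, b in pairs}

    rc = np.full((p, p), np.nan)
    np.fill_diagonal(rc, 0.0)
    for a in range(p):
        if wanted is not None and not any(a in w for w in wanted):
            continue
        nulls_a = null_draws(a, n_null)
        for b in range(a + 1, p):
            if wanted is not None and (a, b) not in wanted:
                continue
            nulls_b = null_draws(b, n_null)
            obs = braycurtis(counts[a], counts[b])
            sums = nulls_a + nulls_b
            diffs = np.abs(nulls_a - nulls_b)
            null_bc = diffs.sum(axis=1) / sums.sum(axis=1)
            less = (null_bc < obs - _TIE_TOL).sum()
            ties = (np.abs(null_bc - obs) <= _TIE_TOL).sum()
            rc_val = 2.0 * ((less + 0.5 * ties) / n_null) - 1.0
            rc[a, b] = rc[b, a] = rc_val
    return pd.DataFrame(rc, index=community.plot_ids, columns=community.plot_ids)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_pair(bnti: float, rc: float) -> str:
    """Five-way assembly-process call for one plot pair."""
    if np.isnan(bnti):
        raise UndefinedValueError("beta-NTI undefined for this pair")
    if bnti > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


@dataclass
class ProcessSummary:
    """Per-stratum fractions of pairs assigned to each assembly process."""

    fractions: pd.DataFrame       # stratum x process, rows sum to 1
    n_pairs: pd.Series            # analyzed pairs per stratum
    n_undefined: int              # pairs excluded for undefined beta-NTI


def _pair_strata(strata, plot_ids) -> list[str]:
    if strata is None:
        return ["all"] * (len(plot_ids) * (len(plot_ids) - 1) // 2)
    lookup = dict(strata) if not isinstance(strata, dict) else strata
    out = []
    for i, a in enumerate(plot_ids):
        for b in plot_ids[i + 1:]:
            sa, sb = str(lookup[a]), str(lookup[b])
            out.append(sa if sa == sb else "cross")
    return out


def classify_processes(
    bnti: pd.DataFrame,
    rc: pd.DataFrame,
    strata=None,
) -> tuple[pd.DataFrame, ProcessSummary]:
    """Classify every plot pair and summarize fractions per stratum.

    ``strata`` maps plot ids to labels (e.g. disturbance level); pairs whose
    plots sit in different strata are pooled into a "cross" stratum. Pairs
    with undefined beta-NTI are excluded from the fractions and counted.
    """
    if list(bnti.index) != list(rc.index) or list(bnti.columns) != list(rc.columns):
        raise CrossReferenceError("beta-NTI and RC matrices have different ids")
    plot_ids = list(bnti.index)
    rows = []
    pair_strata = _pair_strata(strata, plot_ids)
    k = 0
    n_undef = 0
    for i, a in enumerate(plot_ids):
        for b in plot_ids[i + 1:]:
            z = float(bnti.loc[a, b])
            r = float(rc.loc[a, b])
            if np.isnan(z):
                n_undef += 1
                proc = None
            else:
                proc = classify_pair(z, r)
            rows.append(dict(plot_a=a, plot_b=b, beta_nti=z, rc_bray=r,
                             stratum=pair_strata[k], process=proc))
            k += 1
    table = pd.DataFrame(rows)
    analyzed = table.dropna(subset=["process"])
    frac = (
        analyzed.groupby("stratum")["process"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(PROCESSES), fill_value=0.0)
    )
    n_pairs = analyzed.groupby("stratum").size()
    return table, ProcessSummary(fractions=frac, n_pairs=n_pairs,
                                 n_undefined=n_undef)


# ---------------------------------------------------------------------------
# functional dissimilarity
# ---------------------------------------------------------------------------


def functional_dissimilarity(
    traits: TraitIntensityTable, plot_a: str, plot_b: str
) -> float:
    """beta_diss between two plots over all (taxon, trait) intensities."""
    wide = traits.wide()
    for plot in (plot_a, plot_b):
        if plot not in wide.index:
            raise CrossReferenceError(f"plot {plot!r} absent from trait table")
    x = wide.loc[plot_a].to_numpy()
    y = wide.loc[plot_b].to_numpy()
    denom = (x + y).sum()
    if denom == 0:
        raise UndefinedValueError(
            f"both plots all-zero; beta_diss undefined for ({plot_a}, {plot_b})"
        )
    return float(np.abs(x - y).sum() / denom)


def functional_dissimilarity_matrix(
    traits: TraitIntensityTable, plot_ids=None
) -> DistanceMatrix:
    """All-pairs beta_diss (identically Bray-Curtis on the wide trait matrix)."""
    wide = traits.wide(plot_ids=plot_ids)
    x = wide.to_numpy()
    if np.any(x.sum(axis=1) == 0):
        raise InvalidInputError("a plot has no positive trait intensity")
    p = x.shape[0]
    out = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            out[a, b] = out[b, a] = braycurtis(x[a], x[b])
    return DistanceMatrix(out, ids=list(wide.index))


def turnover_coupling(
    bnti: pd.DataFrame,
    bdiss,
    strata=None,
) -> pd.DataFrame:
    """Pair phylogenetic turnover with functional dissimilarity per plot pair.

    One record per unordered plot pair (P plots -> P*(P-1)/2 rows) carrying
    the pair's beta-NTI, beta_diss, and the stratum labels of both plots.
    """
    bdiss_df = (
        pd.DataFrame(bdiss.data, index=list(bdiss.ids), columns=list(bdiss.ids))
        if isinstance(bdiss, DistanceMatrix) else pd.DataFrame(bdiss)
    )
    if set(bnti.index) != set(bdiss_df.index):
        raise CrossReferenceError("beta-NTI and beta_diss plot ids differ")
    plot_ids = list(bnti.index)
    lookup = dict(strata) if strata is not None else None
    rows = []
    for i, a in enumerate(plot_ids):
        for b in plot_ids[i + 1:]:
            rows.append(dict(
                plot_a=a, plot_b=b,
                beta_nti=float(bnti.loc[a, b]),
                beta_diss=float(bdiss_df.loc[a, b]),
                stratum_a=None if lookup is None else str(lookup[a]),
                stratum_b=None if lookup is None else str(lookup[b]),
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mantel correlogram (phylogenetic-signal precheck)
# ---------------------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else np.nan


def mantel_correlogram(
    phylo_d,
    env_d,
    n_classes: int | str = "auto",
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel correlation per environmental-distance class.

    Distance classes are equal-width bins of the environmental distances
    (Sturges' rule when ``n_classes='auto'``). Within each class the Mantel
    statistic is the (sign-flipped) Pearson correlation between the focal
    distances and the class-membership indicator, so positive r means
    "more similar than average at this environmental distance". P-values
    come from joint row/column permutations of the focal matrix and are
    progressively Holm-corrected (class i adjusted among classes 1..i).
    Classes with fewer than 2 member pairs are dropped with a log message.
    """
    pd_mat = np.asarray(phylo_d.data if hasattr(phylo_d, "data") else phylo_d,
                        dtype=float)
    ed_mat = np.asarray(env_d.data if hasattr(env_d, "data") else env_d,
                        dtype=float)
    if pd_mat.shape != ed_mat.shape:
        raise CrossReferenceError("matrices must share the same samples")
    n = pd_mat.shape[0]
    pv = squareform(pd_mat, checks=False)
    ev = squareform(ed_mat, checks=False)
    n_pairs = len(ev)
    if n_classes == "auto":
        n_classes = int(np.ceil(1 + np.log2(n_pairs)))
    edges = np.linspace(ev.min(), ev.max(), int(n_classes) + 1)
    which = np.clip(np.digitize(ev, edges[1:-1]), 0, int(n_classes) - 1)

    rng = np.random.default_rng(seed)
    exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]
    perm_vs = [squareform(pd_mat[np.ix_(list(p), list(p))], checks=False)
               for p in perms]

    records = []
    for c in range(int(n_classes)):
        member = (which == c).astype(float)
        k = int(member.sum())
        if k < 2:
            logger.warning("mantel correlogram: class %d has %d pairs, dropped",
                           c, k)
            continue
        r_obs = -_pearson(pv, member)
        count = sum(
            1 for v in perm_vs if abs(-_pearson(v, member)) >= abs(r_obs) - _TIE_TOL
        )
        if exhaustive:
            p_val = count / len(perms)
        else:
            p_val = (count + 1) / (n_perm + 1)
        records.append(dict(
            class_index=c,
            d_center=float((edges[c] + edges[c + 1]) / 2),
            n_pairs=k, r=r_obs, p=p_val,
        ))
    out = pd.DataFrame(records)
    # progressive Holm correction: class i corrected among the first i+1 tests
    adj = []
    for i in range(len(out)):
        sub = out["p"].to_numpy()[: i + 1]
        order = np.argsort(sub)
        holm = np.empty_like(sub)
        running = 0.0
        for rank, j in enumerate(order):
            running = max(running, (len(sub) - rank) * sub[j])
            holm[j] = min(1.0, running)
        adj.append(holm[i])
    out["p_adjusted"] = adj
    return out
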