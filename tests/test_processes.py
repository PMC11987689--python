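"""Assembly-process estimation: turnover metrics, null models, classification."""

import numpy as np
import pandas as pd
import pytest

import oracles
from asynchom import processes, synth
from asynchom.exceptions import CrossReferenceError, UndefinedValueError
from asynchom.io_tables import CommunityTable, Phylogeny
from asynchom.processes import (
    beta_mntd,
    beta_nti,
    classify_pair,
    classify_processes,
    functional_dissimilarity,
    functional_dissimilarity_matrix,
    mantel_correlogram,
    raup_crick_bray,
    turnover_coupling,
)
from conftest import make_traits


def star_tree(n, length=1.0):
    import dendropy

    labels = ",".join(f"t{i}:{length}" for i in range(n))
    tree = dendropy.Tree.get(data=f"({labels});", schema="newick",
                             suppress_internal_node_taxa=True)
    return Phylogeny(tree)


class TestBetaMntd:
    def test_identical_communities_zero(self, comb_tree):
        comm = CommunityTable(["a", "b"], ["t1", "t2", "t3", "t4"],
                              np.array([[1.0, 2, 3, 4], [1, 2, 3, 4]]))
        assert beta_mntd(comm, comb_tree)[0, 1] == 0.0

    def test_single_taxon_pair_equals_patristic_distance(self, comb_tree):
        comm = CommunityTable(["a", "b"], ["t1", "t2", "t3", "t4"],
                              np.array([[5.0, 0, 0, 0], [0, 3.0, 0, 0]]))
        # t1 and t2 are sisters one unit from their ancestor
        assert beta_mntd(comm, comb_tree)[0, 1] == pytest.approx(2.0,
                                                                 abs=1e-12)

    def test_linear_in_branch_lengths(self, small_community):
        rates = synth.BisseRates = None  # unused; keep namespace clean
        from asynchom.niche_evo import BisseRates

        tree, _ = synth.simulate_bisse_tree(
            BisseRates(1.0, 1.0, 0.2, 0.2, 0.3, 0.3),
            n_tips=small_community.n_taxa, seed=2,
        )
        d1 = beta_mntd(small_community, tree)
        for edge in tree.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 3.0
        d3 = beta_mntd(small_community, tree)
        np.testing.assert_allclose(d3.data, 3.0 * d1.data, rtol=1e-10)

    def test_missing_taxon_raises(self, comb_tree):
        comm = CommunityTable(["a", "b"], ["t1", "zz"],
                              np.array([[1.0, 1], [1, 1]]))
        with pytest.raises(CrossReferenceError, match="zz"):
            beta_mntd(comm, comb_tree)

    def test_relabeling_taxa_jointly_leaves_beta_nti_invariant(self):
        from asynchom.niche_evo import BisseRates

        design = synth.generate_design(1, 1, 1)
        params = synth.SynthCommunityParams(n_taxa=20, seed=3, n_reads=200)
        comm = synth.generate_communities(design, params)
        tree, _ = synth.simulate_bisse_tree(
            BisseRates(1.0, 1.0, 0.1, 0.1, 0.2, 0.2), n_tips=20, seed=4)
        z1 = beta_nti(comm, tree, n_null=99, seed=5)
        # swap two taxon names everywhere (community columns AND tree tips)
        mapping = {"T0001": "T0002", "T0002": "T0001"}
        new_ids = [mapping.get(t, t) for t in comm.taxon_ids]
        comm2 = CommunityTable(comm.plot_ids, new_ids, comm.abundance)
        for leaf in tree.tree.leaf_node_iter():
            leaf.taxon.label = mapping.get(leaf.taxon.label, leaf.taxon.label)
        z2 = beta_nti(comm2, tree, n_null=99, seed=5)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


class TestBetaNti:
    def test_star_tree_flagged_undefined(self):
        comm = CommunityTable(
            ["a", "b", "c"], [f"t{i}" for i in range(5)],
            np.array([[1.0, 1, 0, 0, 0], [0, 0, 1, 1, 0], [1, 0, 0, 0, 1]]),
        )
        z = beta_nti(comm, star_tree(5), n_null=99, seed=0)
        assert np.isnan(z.iloc[0, 1])

    def test_clade_restricted_communities_give_strongly_negative_bnti(self):
        """Communities confined to one subclade of a birth-death tree are
        phylogenetically clustered: observed beta-MNTD sits far below the
        tip-shuffle null (homogeneous-selection signature)."""
        from asynchom.niche_evo import BisseRates

        tree, _ = synth.simulate_bisse_tree(
            BisseRates(1, 1, 0.2, 0.2, 0.1, 0.1), n_tips=100, seed=9)
        clade = next(
            [leaf.taxon.label for leaf in node.leaf_nodes()]
            for node in tree.tree.postorder_node_iter()
            if 20 <= len(node.leaf_nodes()) <= 40
        )
        all_tips = tree.tip_labels
        rng = np.random.default_rng(0)
        rows, ids = [], []
        for k in range(6):
            ab = dict.fromkeys(all_tips, 0.0)
            for t in rng.choice(clade, size=12, replace=False):
                ab[t] = rng.integers(1, 20)
            rows.append([ab[t] for t in all_tips])
            ids.append(f"p{k}")
        comm = CommunityTable(ids, all_tips, np.array(rows))
        z = beta_nti(comm, tree, n_null=199, seed=1)
        vals = [z.iloc[a, b] for a in range(6) for b in range(a + 1, 6)]
        assert np.median(vals) < -2


class TestRaupCrick:
    def _community_with_backbone(self, extra_rows, n_backbone=10, n_taxa=12):
        """Plots 0..k-1 are custom; backbone plots occupy every taxon."""
        rng = np.random.default_rng(7)
        backbone = rng.integers(5, 30, size=(n_backbone, n_taxa)).astype(float)
        ab = np.vstack([np.asarray(extra_rows, dtype=float), backbone])
        ids = [f"x{i}" for i in range(len(extra_rows))] + \
            [f"b{i}" for i in range(n_backbone)]
        return CommunityTable(ids, [f"t{i}" for i in range(n_taxa)], ab)

    def test_observed_above_all_nulls_gives_plus_one(self):
        # full-richness plots with opposite dominance: the null (which must
        # also use all 12 taxa, with near-even regional weights) can never be
        # as dissimilar as the observed pair
        a = [989.0] + [1.0] * 11
        b = [1.0, 989.0] + [1.0] * 10
        comm = self._community_with_backbone([a, b])
        rc = raup_crick_bray(comm, n_null=99, seed=0, pairs=[("x0", "x1")])
        assert rc.loc["x0", "x1"] == pytest.approx(1.0, abs=1e-12)

    def test_observed_below_all_nulls_gives_minus_one(self):
        # two identical full-pool plots: obs dissimilarity ~ 0
        row = [20.0] * 12
        comm = self._community_with_backbone([row, row])
        rc = raup_crick_bray(comm, n_null=99, seed=0, pairs=[("x0", "x1")])
        assert rc.loc["x0", "x1"] == pytest.approx(-1.0, abs=1e-12)

    def test_null_resampled_pairs_center_at_zero(self):
        """Observed plots drawn from the null itself: RC is centered at 0
        (10 quick seeds; the acceptance suite runs 50)."""
        design = synth.generate_design(zones=2, parks_per_age=2, forest_reps=2)
        params = synth.SynthCommunityParams(n_taxa=60, seed=4, n_reads=500)
        base = synth.generate_communities(design, params)
        vals = []
        for s in range(10):
            ab = base.abundance.copy()
            ab[0] = processes.raup_crick_null_draw(base, base.plot_ids[0],
                                                   seed=1000 + s)[0]
            ab[1] = processes.raup_crick_null_draw(base, base.plot_ids[1],
                                                   seed=2000 + s)[0]
            comm = CommunityTable(base.plot_ids, base.taxon_ids, ab)
            rc = raup_crick_bray(comm, n_null=199, seed=s,
                                 pairs=[(base.plot_ids[0], base.plot_ids[1])])
            vals.append(rc.iloc[0, 1])
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals)) + 0.15

    def test_determinism(self, small_community):
        rc1 = raup_crick_bray(small_community, n_null=99, seed=9,
                              pairs=[(small_community.plot_ids[0],
                                      small_community.plot_ids[1])])
        rc2 = raup_crick_bray(small_community, n_null=99, seed=9,
                              pairs=[(small_community.plot_ids[0],
                                      small_community.plot_ids[1])])
        assert rc1.iloc[0, 1] == rc2.iloc[0, 1]


class TestClassification:
    @pytest.mark.parametrize("bnti, rc, expected", [
        (-3.0, 0.0, "homogeneous_selection"),
        (3.0, 0.0, "heterogeneous_selection"),
        (0.0, 0.0, "drift"),
        (1.9, 0.96, "dispersal_limitation"),
        (-1.0, -0.99, "homogenizing_dispersal"),
        (2.0, 0.5, "drift"),          # boundary: |bnti| must exceed 2
        (0.0, 0.95, "drift"),         # boundary: rc must exceed 0.95
    ])
    def test_threshold_rules(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_fractions_partition_each_stratum(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(10)]
        z = rng.normal(scale=2, size=(10, 10))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        rc = np.clip((rng.random((10, 10)) * 2 - 1), -1, 1)
        rc = (rc + rc.T) / 2
        np.fill_diagonal(rc, 0)
        strata = {pid: ("x" if i < 5 else "y") for i, pid in enumerate(ids)}
        table, summary = classify_processes(
            pd.DataFrame(z, index=ids, columns=ids),
            pd.DataFrame(rc, index=ids, columns=ids),
            strata=strata,
        )
        assert len(table) == 45
        np.testing.assert_allclose(summary.fractions.sum(axis=1), 1.0,
                                   atol=1e-12)
        assert set(summary.fractions.index) <= {"x", "y", "cross"}

    def test_undefined_pairs_counted_separately(self):
        ids = ["a", "b", "c"]
        z = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        z.loc["a", "b"] = z.loc["b", "a"] = np.nan
        rc = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        table, summary = classify_processes(z, rc)
        assert summary.n_undefined == 1
        assert summary.n_pairs.sum() == 2


class TestFunctionalDissimilarity:
    def test_identical_tables_zero(self):
        traits = make_traits([
            ("p1", "a", "tr", 2.0), ("p2", "a", "tr", 2.0),
        ])
        assert functional_dissimilarity(traits, "p1", "p2") == 0.0

    def test_disjoint_support_one(self):
        traits = make_traits([
            ("p1", "a", "tr", 2.0), ("p2", "b", "tr", 3.0),
        ])
        assert functional_dissimilarity(traits, "p1", "p2") == \
            pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        traits = make_traits([
            ("p1", "a", "tr", 2.0),               # lambda_m = (2, 0)
            ("p2", "a", "tr", 1.0), ("p2", "b", "tr", 1.0),  # (1, 1)
        ])
        assert functional_dissimilarity(traits, "p1", "p2") == \
            pytest.approx(0.5, abs=1e-12)

    def test_both_plots_empty_undefined(self):
        traits = make_traits([
            ("p1", "a", "tr", 0.0), ("p2", "a", "tr", 0.0),
            ("p3", "a", "tr", 1.0),
        ])
        with pytest.raises(UndefinedValueError):
            functional_dissimilarity(traits, "p1", "p2")


class TestTurnoverCoupling:
    @pytest.mark.parametrize("n_plots, expected", [(3, 3), (40, 780)])
    def test_pair_counts(self, n_plots, expected):
        ids = [f"p{i}" for i in range(n_plots)]
        z = pd.DataFrame(np.zeros((n_plots, n_plots)), index=ids, columns=ids)
        out = turnover_coupling(z, z)
        assert len(out) == expected

    def test_mismatched_ids_rejected(self):
        za = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        zb = pd.DataFrame(np.zeros((3, 3)), index=list("abd"), columns=list("abd"))
        with pytest.raises(CrossReferenceError):
            turnover_coupling(za, zb)

    def test_beta_diss_matrix_matches_pairwise_function(self, small_traits):
        plots = small_traits.plot_ids[:5]
        mat = functional_dissimilarity_matrix(small_traits, plot_ids=plots)
        for i, a in enumerate(plots):
            for b in plots[i + 1:]:
                assert mat[a, b] == pytest.approx(
                    functional_dissimilarity(small_traits, a, b), abs=1e-12)


class TestMantelCorrelogram:
    def test_perfect_signal_first_class_significant(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        out = mantel_correlogram(d, d, n_perm=199, seed=0)
        first = out.iloc[0]
        assert first["r"] > 0
        assert first["p_adjusted"] < 0.05

    def test_exhaustive_oracle_agreement_on_five_samples(self):
        rng = np.random.default_rng(4)
        from scipy.spatial.distance import pdist, squareform

        pd_mat = squareform(pdist(rng.normal(size=(5, 2))))
        ed_mat = squareform(pdist(rng.normal(size=(5, 2))))
        out = mantel_correlogram(pd_mat, ed_mat, n_classes=2, n_perm=999,
                                 seed=0)
        ev = squareform(ed_mat, checks=False)
        edges = np.linspace(ev.min(), ev.max(), 3)
        for _, row in out.iterrows():
            c = int(row["class_index"])
            member = (np.clip(np.digitize(ev, edges[1:-1]), 0, 1) == c)
            p_ex = oracles.exhaustive_mantel_p(pd_mat, member.astype(float))
            assert row["p"] == pytest.approx(p_ex, abs=1e-12)
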