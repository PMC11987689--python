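"""Shared fixtures: small synthetic datasets and hand-built toy objects."""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd
import pytest

from asynchom import niche_evo, synth
from asynchom.io_tables import (
    CommunityTable,
    Phylogeny,
    TraitIntensityTable,
)


@pytest.fixture(scope="session")
def small_design():
    """2 zones x (2 park reps + 2 forest reps): 32 plots."""
    return synth.generate_design(zones=2, parks_per_age=2, forest_reps=2)


@pytest.fixture(scope="session")
def small_community(small_design):
    params = synth.SynthCommunityParams(n_taxa=60, seed=42, n_reads=800)
    return synth.generate_communities(small_design, params)


@pytest.fixture(scope="session")
def small_traits(small_community):
    return synth.generate_trait_intensities(
        small_community, n_traits=5, redundancy=0.5, seed=7
    )


@pytest.fixture
def toy_community():
    """Three plots, four taxa, hand-set abundances."""
    return CommunityTable(
        ["p1", "p2", "p3"],
        ["t1", "t2", "t3", "t4"],
        np.array([
            [1.0, 1.0, 1.0, 1.0],
            [9.0, 16.0, 0.0, 0.0],
            [0.0, 0.0, 2.0, 3.0],
        ]),
    )


@pytest.fixture
def comb_tree():
    """4-tip comb (caterpillar) tree with unit branch lengths."""
    tree = dendropy.Tree.get(
        data="(((t1:1,t2:1):1,t3:1):1,t4:1);", schema="newick",
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )
    return Phylogeny(tree)


def make_traits(records) -> TraitIntensityTable:
    """records: iterable of (plot, taxon, trait, intensity)."""
    return TraitIntensityTable(pd.DataFrame(
        records, columns=["plot_id", "taxon_id", "trait_id", "intensity"]
    ))


@pytest.fixture(scope="session")
def bisse_tree_200():
    """One 200-tip simulated tree + states, reused across rate tests."""
    true = niche_evo.BisseRates(1.0, 0.5, 0.2, 0.1, 0.1, 0.1)
    tree, states = synth.simulate_bisse_tree(true, n_tips=200, seed=71)
    return true, tree, states
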