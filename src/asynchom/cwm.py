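"""Community-weighted mean (CWM) trait integration.

A plot-level trait value aggregates per-taxon functional-gene intensities
weighted by taxon abundance:

    CWM_{j,k} = sum_i w_{i,k} * lambda_{i,j,k}

where lambda_{i,j,k} is the mean intensity of trait j for taxon i in plot k
and w is either the raw abundance phi_{i,k} (``raw_abundance`` mode, the
unnormalized sum) or the plot-relative abundance phi / sum(phi)
(``relative_abundance``, the default — the weighting the CWM literature uses).
A taxon present in a plot but lacking any intensity record contributes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .io_tables import CommunityTable, TraitIntensityTable

logger = logging.getLogger(__name__)

Weighting = Literal["relative_abundance", "raw_abundance"]


@dataclass
class CwmMatrix:
    """Plot x trait matrix of community-weighted means."""

    plot_ids: list[str]
    trait_ids: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.plot_ids, name="plot_id"),
            columns=self.trait_ids,
        )


@dataclass
class TraitPerSpecies:
    """Per-taxon trait summaries over the plots where the taxon was measured."""

    scalar: pd.Series       # taxon -> mean intensity over all its records
    per_trait: pd.DataFrame  # taxon x trait mean intensities


def compute_cwm(
    community: CommunityTable,
    traits: TraitIntensityTable,
    weighting: Weighting = "relative_abundance",
) -> CwmMatrix:
    """Integrate abundances and trait intensities into plot-level CWM values."""
    traits.validate_against(community)
    if weighting not in ("relative_abundance", "raw_abundance"):
        raise ValueError(f"unknown weighting {weighting!r}")

    trait_ids = traits.trait_ids
    wide = traits.wide(plot_ids=community.plot_ids)  # plot x (taxon, trait)
    weights = (
        community.relative()
        if weighting == "relative_abundance"
        else community.abundance
    )
    w_df = pd.DataFrame(weights, index=community.plot_ids,
                        columns=community.taxon_ids)

    values = np.zeros((community.n_plots, len(trait_ids)))
    for j, trait in enumerate(trait_ids):
        lam = wide.xs(trait, axis=1, level="trait_id")  # plot x taxon subset
        w_sub = w_df.loc[:, lam.columns]
        values[:, j] = (w_sub.to_numpy() * lam.to_numpy()).sum(axis=1)
    return CwmMatrix(list(community.plot_ids), trait_ids, values)


def trait_per_species(traits: TraitIntensityTable) -> TraitPerSpecies:
    """Mean trait intensity per taxon, over plots with records only.

    Zeros arising from absence are excluded: only the taxon's actual
    intensity records enter the mean. Taxa with no records are omitted.
    """
    if traits.data.empty:
        raise InvalidInputError("empty trait table")
    scalar = (
        traits.data.groupby("taxon_id")["intensity"].mean().sort_index()
    )
    per_trait = (
        traits.data.pivot_table(
            index="taxon_id", columns="trait_id", values="intensity",
            aggfunc="mean",
        )
        .sort_index()
    )
    return TraitPerSpecies(scalar=scalar, per_trait=per_trait)
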