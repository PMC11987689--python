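"""Tabular and tree I/O, validation, and preprocessing transforms.

The pipeline's in-memory containers live here:

* :class:`CommunityTable` — plot x taxon abundance matrix (the phi_{i,k} of the
  community-weighted-mean calculation and the P_{i,j} inputs of niche width).
* :class:`TraitIntensityTable` — long-format (plot, taxon, trait) -> mean gene
  intensity records (the lambda_{i,j,k} of the trait integration).
* :class:`Phylogeny` — rooted tree with branch lengths whose tips name taxa.
* :class:`SampleMetadata` — plot -> (zone, disturbance, plant_type, replicate).

Preprocessing mirrors a standard microbial-community workflow: Hellinger and
z-score normalization, an occupancy-based rare-taxon filter ("fewer than 10 %
of all study plots" removed), averaging of vegetation types within a park, and
an optional taxonomic rank collapse.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .exceptions import (
    CrossReferenceError,
    EmptyResultError,
    FormatError,
    InvalidArgumentError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

ZONES = ("boreal", "temperate", "tropical")
DISTURBANCES = ("reference_forest", "old_park", "young_park")
PLANT_TYPES = ("recalcitrant_tree", "labile_tree", "lawn")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CommunityTable:
    """Plot x taxon abundance matrix with validated, unique string ids."""

    plot_ids: list[str]
    taxon_ids: list[str]
    abundance: np.ndarray  # shape (n_plots, n_taxa), non-negative

    def __post_init__(self) -> None:
        self.plot_ids = [str(p) for p in self.plot_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.abundance.ndim != 2:
            raise FormatError("abundance must be a 2-D plot x taxon matrix")
        n_p, n_t = self.abundance.shape
        if n_p != len(self.plot_ids) or n_t != len(self.taxon_ids):
            raise FormatError(
                f"shape {self.abundance.shape} does not match "
                f"{len(self.plot_ids)} plots x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.plot_ids)) != n_p:
            raise FormatError("duplicate plot ids")
        if len(set(self.taxon_ids)) != n_t:
            raise FormatError("duplicate taxon ids")
        if not np.all(np.isfinite(self.abundance)):
            i, j = np.argwhere(~np.isfinite(self.abundance))[0]
            raise FormatError(
                f"non-finite abundance at plot {self.plot_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        neg = np.argwhere(self.abundance < 0)
        if len(neg):
            i, j = neg[0]
            raise FormatError(
                f"negative abundance at plot {self.plot_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        zero_rows = np.where(self.abundance.sum(axis=1) == 0)[0]
        if len(zero_rows):
            raise FormatError(
                f"plot {self.plot_ids[zero_rows[0]]!r} has zero total abundance"
            )

    # -- conversions -------------------------------------------------------
    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=pd.Index(self.plot_ids, name="plot_id"),
            columns=self.taxon_ids,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def relative(self) -> np.ndarray:
        """Row-normalized abundances (each plot sums to 1)."""
        return self.abundance / self.abundance.sum(axis=1, keepdims=True)

    def subset_taxa(self, taxa: Sequence[str]) -> "CommunityTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return CommunityTable(self.plot_ids, list(taxa), self.abundance[:, idx])


@dataclass
class TraitIntensityTable:
    """Long-format mean gene-intensity records keyed by (plot, taxon, trait)."""

    data: pd.DataFrame = field(repr=False)

    COLUMNS = ("plot_id", "taxon_id", "trait_id", "intensity")

    def __post_init__(self) -> None:
        df = self.data
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"trait table missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
        if (df["intensity"] < 0).any():
            bad = df.loc[df["intensity"] < 0].iloc[0]
            raise FormatError(
                f"negative intensity for plot {bad.plot_id!r}, "
                f"taxon {bad.taxon_id!r}, trait {bad.trait_id!r}"
            )
        if df.duplicated(["plot_id", "taxon_id", "trait_id"]).any():
            raise FormatError("duplicate (plot, taxon, trait) keys in trait table")
        for col in ("plot_id", "taxon_id", "trait_id"):
            df[col] = df[col].astype(str)
        self.data = df.reset_index(drop=True)

    @property
    def plot_ids(self) -> list[str]:
        return sorted(self.data["plot_id"].unique())

    @property
    def taxon_ids(self) -> list[str]:
        return sorted(self.data["taxon_id"].unique())

    @property
    def trait_ids(self) -> list[str]:
        return sorted(self.data["trait_id"].unique())

    def validate_against(self, community: CommunityTable) -> None:
        """Every trait-table plot and taxon must resolve in the community."""
        unknown_p = set(self.data["plot_id"]) - set(community.plot_ids)
        if unknown_p:
            raise CrossReferenceError(
                f"trait-table plots absent from community table: {sorted(unknown_p)}"
            )
        unknown_t = set(self.data["taxon_id"]) - set(community.taxon_ids)
        if unknown_t:
            raise CrossReferenceError(
                f"trait-table taxa absent from community table: {sorted(unknown_t)}"
            )

    def wide(self, plot_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Pivot to a plot x (taxon, trait) matrix; absences are zero.

        Row order follows ``plot_ids`` when given (plots without any record
        get all-zero rows), otherwise the table's own sorted plot ids.
        """
        piv = self.data.pivot_table(
            index="plot_id", columns=["taxon_id", "trait_id"],
            values="intensity", fill_value=0.0, aggfunc="sum",
        )
        if plot_ids is not None:
            piv = piv.reindex(pd.Index(plot_ids, name="plot_id"), fill_value=0.0)
        return piv.astype(float)


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths; tip labels name taxa."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate tip labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise FormatError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'!r}"
                )
            if edge.length < 0:
                raise FormatError("negative branch length in tree")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self.tree.preorder_node_iter()
            if not n.is_leaf()
        )

    def resolve_polytomies(self, rng: np.random.Generator | None = None) -> bool:
        """Resolve polytomies to binary with zero-length branches.

        Returns True when any resolution happened (flagged for callers that
        need strictly binary trees, e.g. diversification-rate fitting).
        """
        if self.is_binary():
            return False
        self.tree.resolve_polytomies(limit=2, update_bipartitions=False)
        for edge in self.tree.preorder_edge_iter():
            if edge.length is None and edge.head_node is not self.tree.seed_node:
                edge.length = 0.0
        logger.warning("tree polytomies resolved to binary with zero-length branches")
        return True

    def patristic_distances(self, taxa: Sequence[str] | None = None) -> pd.DataFrame:
        """Symmetric taxon x taxon matrix of path (patristic) distances."""
        taxa = list(taxa) if taxa is not None else self.tip_labels
        missing = set(taxa) - set(self.tip_labels)
        if missing:
            raise CrossReferenceError(
                f"taxa missing from tree tips: {sorted(missing)}"
            )
        pdm = self.tree.phylogenetic_distance_matrix()
        by_label = {t.label: t for t in self.tree.taxon_namespace}
        n = len(taxa)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(by_label[taxa[i]], by_label[taxa[j]])
                out[i, j] = out[j, i] = d
        return pd.DataFrame(out, index=taxa, columns=taxa)


@dataclass
class SampleMetadata:
    """Per-plot design metadata: zone, disturbance, plant type, replicate."""

    data: pd.DataFrame = field(repr=False)

    COLUMNS = ("plot_id", "zone", "disturbance", "plant_type", "replicate")

    def __post_init__(self) -> None:
        df = self.data
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        if df["plot_id"].duplicated().any():
            dup = df.loc[df["plot_id"].duplicated(), "plot_id"].iloc[0]
            raise FormatError(f"duplicate plot_id {dup!r} in metadata")
        df["plot_id"] = df["plot_id"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        self.data = df.set_index("plot_id", drop=False)

    def validate_against(self, community: CommunityTable) -> None:
        plots = set(community.plot_ids)
        have = set(self.data["plot_id"])
        if plots - have:
            raise CrossReferenceError(
                f"community plots without metadata: {sorted(plots - have)}"
            )

    def column_for(self, plot_ids: Sequence[str], column: str) -> np.ndarray:
        return self.data.loc[list(plot_ids), column].to_numpy()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

Orientation = Literal["plots_as_rows", "taxa_as_rows"]


def read_community(
    path: str | Path, orientation: Orientation = "plots_as_rows"
) -> CommunityTable:
    """Read a community table from TSV (or BIOM-style JSON by extension).

    ``orientation`` describes the file; the in-memory table is always
    normalized to plots-as-rows.
    """
    path = Path(path)
    if path.suffix.lower() in {".biom", ".json"}:
        return _read_biom_json(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nn = bad.isna() & df[col].notna()
        if nn.any():
            raise FormatError(
                f"non-numeric cell at row {nn.idxmax()!r}, column {col!r} in {path}"
            )
    df = df.astype(float)
    if orientation == "taxa_as_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CommunityTable.from_dataframe(df)


def write_community(table: CommunityTable, path: str | Path) -> None:
    """Write the canonical plots-as-rows TSV (round-trips byte-identically)."""
    df = table.to_dataframe()
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t", lineterminator="\n")


def _read_biom_json(path: Path) -> CommunityTable:
    """Minimal BIOM-style JSON reader (dense or sparse ``data``)."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        taxa = [r["id"] for r in doc["rows"]]
        plots = [c["id"] for c in doc["columns"]]
        n_r, n_c = doc["shape"]
        mat = np.zeros((n_r, n_c))
        if doc.get("matrix_type", "dense") == "sparse":
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed BIOM JSON {path}: {exc}") from exc
    # BIOM convention: rows are observations (taxa), columns are samples.
    return CommunityTable(plots, taxa, mat.T)


def read_traits(path: str | Path) -> TraitIntensityTable:
    df = pd.read_csv(path, sep="\t")
    return TraitIntensityTable(df)


def write_traits(traits: TraitIntensityTable, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        traits.data.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        meta.data.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tree(path: str | Path) -> Phylogeny:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick",
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )
    return Phylogeny(tree)


def write_tree(phylo: Phylogeny, path: str | Path) -> None:
    phylo.tree.write(
        path=str(path), schema="newick",
        unquoted_underscores=True, suppress_rooting=True,
    )


def read_tip_states(path: str | Path) -> dict[str, str]:
    """Read ``tip_id<TAB>state`` with a header line."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_tip_states(states: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("tip_id\tstate\n")
        for tip, st in states.items():
            fh.write(f"{tip}\t{st}\n")


# ---------------------------------------------------------------------------
# transforms & filters
# ---------------------------------------------------------------------------


def hellinger_transform(table: CommunityTable) -> CommunityTable:
    """Square root of row-relative abundances; each row's squares sum to 1."""
    totals = table.abundance.sum(axis=1)
    if np.any(totals == 0):
        raise InvalidInputError("all-zero plot row; Hellinger undefined")
    out = np.sqrt(table.abundance / totals[:, None])
    return CommunityTable(table.plot_ids, table.taxon_ids, out)


def zscore_transform(matrix: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Column-wise z-scores (sample sd, ddof=1).

    Zero-variance columns map to zeros with a warning, so degenerate
    synthetic inputs keep flowing through the pipeline.
    """
    values = np.asarray(matrix, dtype=float)
    if values.shape[0] < 2:
        raise InvalidInputError("z-score needs at least 2 rows")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance column(s) mapped to zeros",
            stacklevel=2,
        )
    sd_safe = np.where(zero, 1.0, sd)
    out = (values - mean) / sd_safe
    out[:, zero] = 0.0
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def rare_taxon_filter(
    table: CommunityTable, min_occupancy_fraction: float = 0.10
) -> CommunityTable:
    """Drop taxa occupying fewer than ``min_occupancy_fraction`` of plots.

    "Fewer than" is read literally: a taxon is removed iff its occupancy
    count is strictly below ``fraction * n_plots``. With 120 plots and the
    default 10 % the cutoff is therefore "present in < 12 plots".
    """
    if not 0 < min_occupancy_fraction <= 1:
        raise InvalidArgumentError("min_occupancy_fraction must be in (0, 1]")
    occupancy = (table.abundance > 0).sum(axis=0)
    keep = occupancy >= min_occupancy_fraction * table.n_plots
    if not keep.any():
        raise EmptyResultError("rare-taxon filter removed every taxon")
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    return CommunityTable(table.plot_ids, kept, table.abundance[:, keep])


def average_within_park(
    table: CommunityTable, metadata: SampleMetadata
) -> tuple[CommunityTable, SampleMetadata]:
    """Average vegetation types within each park (zone x disturbance x replicate).

    Mirrors the study design's focus on urbanization: plant-type plots inside
    one park are collapsed to their mean abundance profile.
    """
    metadata.validate_against(table)
    df = table.to_dataframe()
    keys = metadata.data.loc[table.plot_ids, ["zone", "disturbance", "replicate"]]
    group_id = (
        keys["zone"].astype(str) + "|" + keys["disturbance"].astype(str)
        + "|" + keys["replicate"].astype(str)
    )
    averaged = df.groupby(group_id.to_numpy()).mean()
    new_ids = [g.replace("|", "_") for g in averaged.index]
    meta_rows = []
    for g in averaged.index:
        zone, dist, rep = g.split("|")
        meta_rows.append(
            dict(plot_id=g.replace("|", "_"), zone=zone, disturbance=dist,
                 plant_type="averaged", replicate=int(rep))
        )
    out_table = CommunityTable(new_ids, list(averaged.columns), averaged.to_numpy())
    return out_table, SampleMetadata(pd.DataFrame(meta_rows))


def collapse_taxa(
    table: CommunityTable, mapping: Mapping[str, str]
) -> CommunityTable:
    """Sum abundances into higher-rank groups (e.g. strain -> genus).

    Taxa absent from ``mapping`` keep their own id.
    """
    df = table.to_dataframe()
    groups = [mapping.get(t, t) for t in df.columns]
    collapsed = df.T.groupby(pd.Index(groups, name="taxon")).sum().T
    return CommunityTable.from_dataframe(collapsed)
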