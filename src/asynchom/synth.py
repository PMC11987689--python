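"""Synthetic study designs, communities, traits, and state-dependent trees.

Everything downstream of raw sequencing is testable without downloads: this
module emulates

* the field design — three climatic zones, each with young parks, old parks
  and a reference forest; three plant types in parks (recalcitrant trees,
  labile trees, lawns) but no lawns in forests; 120 plots by default;
* abundance tables whose within-group compositional dispersion shrinks
  along the disturbance gradient (the homogenization signal), via per-group
  Dirichlet-multinomial sampling where the homogenization factor scales the
  Dirichlet concentration inversely;
* functional-gene intensity tables with a single redundancy knob blending a
  shared trait profile with taxon-specific ones;
* binary-state (generalist/specialist) birth-death trees simulated forward
  with Gillespie event sampling, conditioned on survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Literal, Mapping

import dendropy
import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, SimulationFailedError
from .io_tables import (
    PLANT_TYPES,
    ZONES,
    CommunityTable,
    Phylogeny,
    SampleMetadata,
    TraitIntensityTable,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlotRecord:
    plot_id: str
    zone: str
    disturbance: str
    plant_type: str
    replicate: int


@dataclass
class StudyDesign:
    """The sampled plots of one synthetic campaign."""

    plots: list[PlotRecord]

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("duplicate plot ids in design")
        for p in self.plots:
            if p.disturbance == "reference_forest" and p.plant_type == "lawn":
                raise InvalidArgumentError(
                    f"{p.plot_id}: lawns do not occur in reference forests"
                )

    @property
    def plot_ids(self) -> list[str]:
        return [p.plot_id for p in self.plots]

    def __len__(self) -> int:
        return len(self.plots)

    def to_metadata(self) -> SampleMetadata:
        return SampleMetadata(pd.DataFrame([vars(p) for p in self.plots]))


def generate_design(
    zones: int = 3,
    parks_per_age: int = 5,
    forest_reps: int = 5,
    seed: int = 0,
) -> StudyDesign:
    """Enumerate the plots of the zone x disturbance x plant-type scheme.

    Per zone: ``parks_per_age`` replicates of each of the 3 plant types in
    young and in old parks, plus ``forest_reps`` replicates of the 2 tree
    types in the reference forest — so the default (3, 5, 5) yields
    3 * (2*5*3 + 5*2) = 120 plots. ``seed`` is accepted for interface
    symmetry; the enumeration itself is deterministic.
    """
    for name, v in (("zones", zones), ("parks_per_age", parks_per_age),
                    ("forest_reps", forest_reps)):
        if v < 1:
            raise InvalidArgumentError(f"{name} must be >= 1, got {v}")
    if zones > len(ZONES):
        raise InvalidArgumentError(f"at most {len(ZONES)} zones supported")

    plots: list[PlotRecord] = []
    for zone in ZONES[:zones]:
        for disturbance in ("young_park", "old_park"):
            for plant_type in PLANT_TYPES:
                for rep in range(1, parks_per_age + 1):
                    plots.append(PlotRecord(
                        f"{zone}.{disturbance}.{plant_type}.r{rep}",
                        zone, disturbance, plant_type, rep,
                    ))
        for plant_type in ("recalcitrant_tree", "labile_tree"):
            for rep in range(1, forest_reps + 1):
                plots.append(PlotRecord(
                    f"{zone}.reference_forest.{plant_type}.r{rep}",
                    zone, "reference_forest", plant_type, rep,
                ))
    return StudyDesign(plots)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

DEFAULT_HOMOGENIZATION = {
    "reference_forest": 1.0,
    "old_park": 0.6,
    "young_park": 0.3,
}


@dataclass
class SynthCommunityParams:
    """Knobs of the Dirichlet-multinomial community generator.

    ``homogenization_factors`` multiply the within-group dispersion per
    disturbance level (smaller = more homogenized); they scale the Dirichlet
    concentration inversely. The defaults emulate a disturbance gradient
    with dispersion shrinking from reference forests to young parks.
    """

    n_taxa: int = 200
    base_dispersion: float = 1.0
    homogenization_factors: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_HOMOGENIZATION)
    )
    generalist_fraction: float = 0.5
    abundance_model: Literal["lognormal", "gamma"] = "lognormal"
    seed: int = 0
    n_reads: int = 2000
    concentration_scale: float = 50.0
    specialist_background: float = 0.02

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise InvalidArgumentError("n_taxa must be >= 2")
        if self.base_dispersion <= 0:
            raise InvalidArgumentError("base_dispersion must be positive")
        if not 0 <= self.generalist_fraction <= 1:
            raise InvalidArgumentError("generalist_fraction must be in [0, 1]")
        if self.abundance_model not in ("lognormal", "gamma"):
            raise InvalidArgumentError(
                f"unknown abundance_model {self.abundance_model!r}"
            )
        for dist, f in self.homogenization_factors.items():
            if not 0 < f <= 1:
                raise InvalidArgumentError(
                    f"homogenization factor for {dist!r} must be in (0, 1]"
                )


def taxon_ids(n_taxa: int) -> list[str]:
    width = max(4, len(str(n_taxa)))
    return [f"T{i + 1:0{width}d}" for i in range(n_taxa)]


def generate_communities(
    design: StudyDesign,
    params: SynthCommunityParams,
    generalist_mask: np.ndarray | None = None,
) -> CommunityTable:
    """Sample plot x taxon count tables from the per-group Dirichlet model.

    Each (zone, disturbance) group receives a mean composition: generalist
    taxa share a regional profile everywhere, specialist taxa are boosted in
    their home group and near-absent elsewhere. Plot compositions are drawn
    from a Dirichlet around the group mean with concentration
    ``concentration_scale / (base_dispersion * homogenization_factor)``,
    then counts from a multinomial with ``n_reads`` reads.
    """
    if len(design) == 0:
        raise InvalidArgumentError("empty design")
    rng = np.random.default_rng(params.seed)
    n = params.n_taxa
    taxa = taxon_ids(n)

    if params.abundance_model == "lognormal":
        regional = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    else:
        regional = rng.gamma(shape=2.0, scale=1.0, size=n)

    if generalist_mask is None:
        n_gen = int(round(params.generalist_fraction * n))
        generalist_mask = np.zeros(n, dtype=bool)
        generalist_mask[rng.choice(n, size=n_gen, replace=False)] = True
    else:
        generalist_mask = np.asarray(generalist_mask, dtype=bool)
        if generalist_mask.shape != (n,):
            raise InvalidArgumentError("generalist_mask length must equal n_taxa")

    groups = sorted({(p.zone, p.disturbance) for p in design.plots})
    specialist_idx = np.flatnonzero(~generalist_mask)
    home = {g: [] for g in groups}
    for k, i in enumerate(specialist_idx):  # round-robin home-group assignment
        home[groups[k % len(groups)]].append(i)

    group_mean: dict[tuple[str, str], np.ndarray] = {}
    for g in groups:
        m = regional.copy()
        m[specialist_idx] *= params.specialist_background
        own = np.asarray(home[g], dtype=int)
        if len(own):
            m[own] = regional[own] * 5.0
        group_mean[g] = m / m.sum()

    abundance = np.zeros((len(design), n), dtype=float)
    for row, plot in enumerate(design.plots):
        g = (plot.zone, plot.disturbance)
        factor = params.homogenization_factors.get(plot.disturbance, 1.0)
        conc = params.concentration_scale / (params.base_dispersion * factor)
        p = rng.dirichlet(group_mean[g] * conc)
        abundance[row] = rng.multinomial(params.n_reads, p)
        if abundance[row].sum() == 0:  # pragma: no cover - n_reads >= 1
            abundance[row, rng.integers(n)] = 1
    return CommunityTable(design.plot_ids, taxa, abundance)


# ---------------------------------------------------------------------------
# trait intensities
# ---------------------------------------------------------------------------


def generate_trait_intensities(
    community: CommunityTable,
    n_traits: int = 10,
    redundancy: float = 0.5,
    seed: int = 0,
) -> TraitIntensityTable:
    """Log-normal per-taxon trait profiles, masked by presence per plot.

    ``redundancy`` blends a single shared trait profile (1.0: every taxon
    identical, maximal functional redundancy) with independent taxon-specific
    profiles (0.0). A taxon only has intensity records in plots where it is
    present (abundance > 0).
    """
    if n_traits < 1:
        raise InvalidArgumentError("n_traits must be >= 1")
    if not 0 <= redundancy <= 1:
        raise InvalidArgumentError("redundancy must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_taxa = community.n_taxa
    shared = rng.lognormal(mean=0.0, sigma=1.0, size=n_traits)
    specific = rng.lognormal(mean=0.0, sigma=1.0, size=(n_taxa, n_traits))
    profile = redundancy * shared[None, :] + (1.0 - redundancy) * specific

    records = []
    trait_names = [f"trait{j + 1:03d}" for j in range(n_traits)]
    present = community.abundance > 0
    for k, plot in enumerate(community.plot_ids):
        idx = np.flatnonzero(present[k])
        if not len(idx):
            continue
        block = pd.DataFrame({
            "plot_id": plot,
            "taxon_id": np.repeat([community.taxon_ids[i] for i in idx], n_traits),
            "trait_id": np.tile(trait_names, len(idx)),
            "intensity": profile[idx].ravel(),
        })
        records.append(block)
    return TraitIntensityTable(pd.concat(records, ignore_index=True))


# ---------------------------------------------------------------------------
# binary-state birth-death tree simulation
# ---------------------------------------------------------------------------

STATES = ("generalist", "specialist")


def simulate_bisse_tree(
    rates,
    n_tips: int,
    root_state: str = "generalist",
    seed: int = 0,
    max_attempts: int = 100,
    tip_prefix: str = "T",
) -> tuple[Phylogeny, dict[str, str]]:
    """Forward Gillespie simulation of a two-state birth-death tree.

    Lineages speciate, go extinct, and flip state at the six state-dependent
    rates. The simulation stops the instant the extant count reaches
    ``n_tips`` plus one further exponential waiting time (so terminal
    branches have positive length), conditioned on survival: attempts where
    the clade dies before reaching ``n_tips`` are retried up to
    ``max_attempts`` times.

    Returns a rooted binary crown-group phylogeny of exactly ``n_tips``
    extant tips plus their states.
    """
    from .niche_evo import BisseRates  # local import avoids a cycle

    if not isinstance(rates, BisseRates):
        rates = BisseRates(*rates)
    rates.validate()
    if n_tips < 3:
        raise InvalidArgumentError("n_tips must be >= 3")
    if root_state not in STATES:
        raise InvalidArgumentError(f"unknown root state {root_state!r}")
    rng = np.random.default_rng(seed)

    lam = {"generalist": rates.lambda_g, "specialist": rates.lambda_s}
    mu = {"generalist": rates.mu_g, "specialist": rates.mu_s}
    trans = {"generalist": rates.t_gs, "specialist": rates.t_sg}
    other = {"generalist": "specialist", "specialist": "generalist"}

    for attempt in range(1, max_attempts + 1):
        result = _one_attempt(lam, mu, trans, other, n_tips, root_state, rng)
        if result is not None:
            tree, states = result
            width = max(4, len(str(n_tips)))
            labels = {}
            namespace = dendropy.TaxonNamespace()
            for i, leaf in enumerate(tree.leaf_node_iter()):
                name = f"{tip_prefix}{i + 1:0{width}d}"
                leaf.taxon = namespace.new_taxon(label=name)
                labels[name] = states[id(leaf)]
            tree.taxon_namespace = namespace
            return Phylogeny(tree), labels
    raise SimulationFailedError(
        f"clade went extinct in all {max_attempts} attempts", attempts=max_attempts
    )


def _one_attempt(lam, mu, trans, other, n_tips, root_state, rng):
    """One conditioned simulation attempt; None when the clade dies."""
    root = dendropy.Node()
    # lineage record: [node, state, birth_time]
    extant = [[root, root_state, 0.0]]
    t = 0.0
    max_events = 500 * n_tips + 10000
    for _ in range(max_events):
        rate_each = [lam[s] + mu[s] + trans[s] for _, s, _ in extant]
        total = float(np.sum(rate_each))
        if total <= 0:
            # absorbing: no events can happen; cannot ever reach n_tips
            return None
        dt = rng.exponential(1.0 / total)
        t += dt
        if len(extant) >= n_tips:
            break  # stop just before the next event fires
        k = rng.choice(len(extant), p=np.asarray(rate_each) / total)
        node, state, born = extant[k]
        u = rng.uniform() * rate_each[k]
        if u < lam[state]:  # speciation
            node.edge.length = t - born
            children = [dendropy.Node(), dendropy.Node()]
            for ch in children:
                node.add_child(ch)
            extant.pop(k)
            extant.append([children[0], state, t])
            extant.append([children[1], state, t])
        elif u < lam[state] + mu[state]:  # extinction
            node.edge.length = t - born
            extant.pop(k)
            _prune_dead(node)
            if not extant:
                return None
        else:  # state transition
            extant[k][1] = other[state]
    else:
        return None  # runaway (e.g. rates that never reach n_tips)

    if len(extant) < n_tips:
        return None
    states = {}
    for node, state, born in extant:
        node.edge.length = t - born
        states[id(node)] = state
    tree = dendropy.Tree()
    tree.seed_node = _find_root(extant[0][0])
    _suppress_unifurcations(tree.seed_node, states)
    # drop the stem: start the clock at the crown split
    while len(tree.seed_node.child_nodes()) == 1:
        child = tree.seed_node.child_nodes()[0]
        child.parent_node = None
        child.edge.length = None
        tree.seed_node = child
    return tree, states


def _find_root(node):
    while node.parent_node is not None:
        node = node.parent_node
    return node


def _prune_dead(node) -> None:
    """Remove an extinct leaf and any newly-empty ancestors."""
    while node.parent_node is not None and not node.child_nodes():
        parent = node.parent_node
        parent.remove_child(node)
        node = parent


def _suppress_unifurcations(root, states) -> None:
    """Iterative postorder merge of single-child nodes (deep trees safe)."""
    stack = [(root, False)]
    while stack:
        node, visited = stack.pop()
        if not visited:
            stack.append((node, True))
            for child in node.child_nodes():
                stack.append((child, False))
            continue
        children = node.child_nodes()
        if len(children) == 1 and node.parent_node is not None:
            child = children[0]
            child.edge.length = (
                (child.edge.length or 0.0) + (node.edge.length or 0.0)
            )
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
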