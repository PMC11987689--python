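"""Single-config orchestration of the full analysis.

``run_pipeline`` drives synth (or user data) -> preprocessing -> dispersion
tests -> CWM -> assembly processes -> niche/BiSSE from one
:class:`RunConfig`, writes every stage's tables under the output directory,
and returns a machine-readable :class:`RunReport`. Stage seeds are derived
from a single master seed through ``numpy.random.SeedSequence.spawn`` in a
fixed stage order, so a rerun with the same config reproduces every number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import cwm as cwm_mod
from . import dispersion as disp_mod
from . import io_tables, niche_evo, processes, synth
from .exceptions import AsynchomError
from .io_tables import CommunityTable, Phylogeny

logger = logging.getLogger(__name__)

_STAGES = ("synth_design", "synth_tree", "synth_community", "synth_traits",
           "dispersion", "permanova", "processes_bnti", "processes_rc",
           "niche", "bisse")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Defaults emulate the study design (120 plots); null-model replicate
    counts and the classification thresholds are explicit so the report can
    echo them.
    """

    # synth design (ignored when input paths are given)
    zones: int = 3
    parks_per_age: int = 5
    forest_reps: int = 5
    n_taxa: int = 200
    n_traits: int = 10
    redundancy: float = 0.5
    community: dict = field(default_factory=dict)  # SynthCommunityParams overrides
    tree_rates: dict = field(default_factory=lambda: dict(
        lambda_g=1.0, lambda_s=1.0, mu_g=0.2, mu_s=0.2, t_gs=0.1, t_sg=0.1))
    # user data (all four required together; overrides synth)
    community_path: str | None = None
    traits_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    # preprocessing
    occupancy_fraction: float = 0.10
    average_within_park: bool = False
    # null models / tests
    n_permutations: int = 999
    n_null: int = 99
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    niche_threshold: float = 9.0
    mcmc_steps: int = 0
    # bookkeeping
    seed: int = 0
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise AsynchomError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def normalized(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.normalized(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage status plus the run's headline statistics."""

    config: dict
    config_hash: str
    version: str
    stages: dict[str, str]
    warnings: list[str]
    headline: dict[str, Any]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = dataclasses.asdict(self)
        text = json.dumps(doc, indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_STAGES, children)}


def _prune_tree(tree: Phylogeny, taxa: list[str]) -> Phylogeny:
    keep = set(taxa)
    clone = dendropy.Tree(tree.tree)
    drop = [t for t in clone.taxon_namespace if t.label not in keep]
    if drop:
        clone.prune_taxa(drop, suppress_unifurcations=True)
    while len(clone.seed_node.child_nodes()) == 1:
        child = clone.seed_node.child_nodes()[0]
        child.parent_node = None
        child.edge.length = None
        clone.seed_node = child
    return Phylogeny(clone)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage; on stage failure the report records the error
    and the outputs produced so far are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stages: dict[str, str] = {}
    headline: dict[str, Any] = {}
    caught: list[str] = []

    def record(stage: str, status: str = "ok") -> None:
        stages[stage] = status

    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            _run_stages(config, out, seeds, record, headline)
        caught = sorted({str(w.message) for w in wlist})
    except AsynchomError as exc:
        failed = next((s for s in _STAGES if s not in stages), "unknown")
        stages[failed] = f"error: {exc}"
        logger.error("stage %s failed: %s", failed, exc)

    report = RunReport(
        config=config.normalized(),
        config_hash=config.config_hash(),
        version=_version(),
        stages=stages,
        warnings=caught,
        headline=headline,
    )
    report.to_json(out / "report.json")
    return report


def _version() -> str:
    from . import __version__

    return __version__


def _run_stages(config, out, seeds, record, headline) -> None:
    # ---- inputs ----------------------------------------------------------
    if config.community_path:
        community = io_tables.read_community(config.community_path)
        traits = io_tables.read_traits(config.traits_path)
        tree = io_tables.read_tree(config.tree_path)
        metadata = io_tables.read_metadata(config.metadata_path)
        tip_states_true = None
        for s in ("synth_design", "synth_tree", "synth_community",
                  "synth_traits"):
            record(s, "skipped (user data)")
    else:
        design = synth.generate_design(
            config.zones, config.parks_per_age, config.forest_reps,
            seed=seeds["synth_design"],
        )
        metadata = design.to_metadata()
        record("synth_design")

        rates = niche_evo.BisseRates(**config.tree_rates)
        tree, tip_states_true = synth.simulate_bisse_tree(
            rates, n_tips=config.n_taxa, seed=seeds["synth_tree"],
        )
        record("synth_tree")

        taxa = synth.taxon_ids(config.n_taxa)
        mask = np.array(
            [tip_states_true[t] == "generalist" for t in taxa], dtype=bool
        )
        params = synth.SynthCommunityParams(
            n_taxa=config.n_taxa, seed=seeds["synth_community"],
            **config.community,
        )
        community = synth.generate_communities(design, params,
                                               generalist_mask=mask)
        record("synth_community")

        traits = synth.generate_trait_intensities(
            community, n_traits=config.n_traits,
            redundancy=config.redundancy, seed=seeds["synth_traits"],
        )
        record("synth_traits")

        io_tables.write_community(community, out / "community.tsv")
        io_tables.write_traits(traits, out / "traits.tsv")
        io_tables.write_metadata(metadata, out / "metadata.tsv")
        io_tables.write_tree(tree, out / "tree.nwk")
        io_tables.write_tip_states(tip_states_true, out / "tip_states.tsv")

    # ---- preprocessing ---------------------------------------------------
    metadata.validate_against(community)
    filtered = io_tables.rare_taxon_filter(community, config.occupancy_fraction)
    if config.average_within_park:
        filtered, metadata = io_tables.average_within_park(filtered, metadata)
    groups = metadata.column_for(filtered.plot_ids, "disturbance")

    # ---- dispersion ------------------------------------------------------
    hel = io_tables.hellinger_transform(filtered)
    bray = disp_mod.bray_curtis(hel)
    disp = disp_mod.permdisp(bray, groups, n_perm=config.n_permutations,
                             seed=seeds["dispersion"])
    _, letters = disp_mod.tukey_hsd_dispersion(disp)
    gmd = disp_mod.group_mean_distance(disp, log_transform=True)
    record("dispersion")

    perma = disp_mod.permanova(bray, groups, n_perm=config.n_permutations,
                               seed=seeds["permanova"])
    record("permanova")

    pd.DataFrame({
        "plot_id": disp.ids, "group": disp.groups,
        "distance_to_centroid": disp.distances,
    }).to_csv(out / "dispersion_distances.tsv", sep="\t", index=False)
    pd.DataFrame(
        disp.coordinates[:, :4],
        index=pd.Index(disp.ids, name="plot_id"),
        columns=[f"PCo{i + 1}" for i in range(4)],
    ).to_csv(out / "ordination_coordinates.tsv", sep="\t")

    # ---- CWM -------------------------------------------------------------
    cwm_matrix = cwm_mod.compute_cwm(filtered, _restrict_traits(traits, filtered))
    cwm_matrix.to_dataframe().to_csv(out / "cwm.tsv", sep="\t")
    tps = cwm_mod.trait_per_species(_restrict_traits(traits, filtered))

    # ---- assembly processes ---------------------------------------------
    strata = dict(zip(filtered.plot_ids,
                      metadata.column_for(filtered.plot_ids, "disturbance")))
    bnti = processes.beta_nti(filtered, tree, n_null=config.n_null,
                              seed=seeds["processes_bnti"])
    record("processes_bnti")
    rc = processes.raup_crick_bray(filtered, n_null=config.n_null,
                                   seed=seeds["processes_rc"])
    record("processes_rc")
    pair_table, summary = processes.classify_processes(bnti, rc, strata=strata)
    bdiss = processes.functional_dissimilarity_matrix(
        _restrict_traits(traits, filtered), plot_ids=filtered.plot_ids
    )
    coupling = processes.turnover_coupling(bnti, bdiss, strata=strata)
    pair_out = pair_table.merge(
        coupling[["plot_a", "plot_b", "beta_diss"]], on=["plot_a", "plot_b"]
    )
    pair_out.to_csv(out / "pair_turnover.tsv", sep="\t", index=False)
    summary.fractions.to_csv(out / "process_fractions.tsv", sep="\t")

    # ---- niche / BiSSE ---------------------------------------------------
    b = niche_evo.niche_width(filtered)
    niche = niche_evo.classify_niche(b, threshold=config.niche_threshold)
    niche.table.to_csv(out / "niche.tsv", sep="\t")
    rho, rho_p, sign = niche_evo.niche_trait_relation(
        b, tps.scalar, seed=seeds["niche"]
    )
    record("niche")

    fit_summary = None
    tip_states_fit = {t: c for t, c in niche.table["class"].items()}
    fit_tree = _prune_tree(tree, list(tip_states_fit))
    if fit_tree.n_tips >= 10:
        fit = niche_evo.bisse_ml(fit_tree, tip_states_fit,
                                 seed=seeds["bisse"])
        if config.mcmc_steps > 0:
            samples, meta = niche_evo.bisse_mcmc(
                fit_tree, tip_states_fit, start=fit.ml_rates,
                steps=config.mcmc_steps, seed=seeds["bisse"],
            )
            fit.mcmc_samples = samples
            samples.to_csv(out / "bisse_mcmc.tsv", sep="\t", index=False)
        rs = niche_evo.summarize_rates(fit)
        fit_summary = dict(
            rates=dataclasses.asdict(fit.ml_rates),
            log_likelihood=fit.log_likelihood,
            net_generalist=rs.net_generalist,
            net_specialist=rs.net_specialist,
            log_transition_ratio=rs.log_transition_ratio,
        )
        (out / "bisse_ml.json").write_text(
            json.dumps(fit_summary, indent=2, default=_jsonable) + "\n"
        )
        record("bisse")
    else:
        record("bisse", "skipped (fewer than 10 classified taxa)")

    headline.update(
        n_plots=filtered.n_plots,
        n_taxa_retained=filtered.n_taxa,
        n_pair_records=len(coupling),
        dispersion_group_means=disp.group_means,
        dispersion_f=disp.f_statistic,
        dispersion_p=disp.p_value,
        dispersion_letters=letters,
        log_group_means=gmd.group_means,
        permanova_p=perma.p_values,
        permanova_r2=perma.r_squared,
        process_fractions=summary.fractions.to_dict(),
        n_undefined_bnti_pairs=summary.n_undefined,
        generalist_fraction=niche.generalist_fraction,
        niche_trait_rho=rho,
        niche_trait_p=rho_p,
        niche_trait_sign=sign,
        bisse=fit_summary,
    )


def _restrict_traits(traits, community: CommunityTable):
    """Drop trait records for plots/taxa removed by preprocessing."""
    df = traits.data
    keep = df["plot_id"].isin(community.plot_ids) & df["taxon_id"].isin(
        community.taxon_ids
    )
    return io_tables.TraitIntensityTable(df.loc[keep].reset_index(drop=True))
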