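"""End-to-end orchestration of the co-occurrence analysis.

One call runs the whole study: obtain an OTU table (from disk or the
synthetic generator), filter and rarefy it, compute community statistics,
score MIC associations and call edges per management group and for the
pooled set of samples, select keystone taxa, compare group networks, and
attribute keystone abundance to soil covariates. Each stage draws its seed
deterministically from the global seed, so any stage can be reproduced in
isolation; a manifest records parameters, seeds, and the samples entering
every network.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from rhizonet import community, compare, drivers, keystone, network, otu
from rhizonet.mic import (
    MicConfig,
    classify_edges,
    mic_matrix,
    null_mic_distribution,
    permutation_pvalues,
)
from rhizonet.simulate import SimConfig, generate_study, write_study

logger = logging.getLogger("rhizonet")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "infer_network"]


@dataclass
class PipelineConfig:
    """Inputs and tuning for :func:`run_pipeline`.

    Either the three table paths or a ``simulate`` block must be given.
    ``n_permutations`` controls the shared MIC null depth; group-level
    networks at ~20 samples need a deep null tail (the BH threshold sits
    far out in the null distribution when thousands of pairs are tested).
    """

    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    simulate: SimConfig | None = None
    group_column: str = "system"
    rarefy_depth: int = 1000
    global_frac: float = 0.001
    sample_frac: float = 0.005
    min_prevalence: int = 2
    alpha: float = 0.05
    n_permutations: int = 9999
    stat_permutations: int = 999
    overall_criteria: keystone.KeystoneCriteria = field(
        default_factory=lambda: keystone.KeystoneCriteria(
            **keystone.OVERALL_CRITERIA_PARAMS
        )
    )
    group_criteria: keystone.KeystoneCriteria = field(
        default_factory=lambda: keystone.KeystoneCriteria(
            **keystone.PER_SYSTEM_CRITERIA_PARAMS
        )
    )
    rf_trees: int = 300
    rf_permutations: int = 99
    rf_alpha: float = 0.01
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and self.counts_path is None:
            raise ValueError(
                "configuration needs either input table paths or a simulate block"
            )


@dataclass
class PipelineResult:
    table: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    diversity: pd.DataFrame
    permanova: community.PermutationTestResult
    permdisp: community.PermutationTestResult
    indicators: pd.DataFrame
    associations: dict  # level -> association DataFrame
    networks: dict  # level -> nx.Graph
    topologies: dict  # level -> TopologySummary
    keystones: dict  # level -> KeystoneReport
    influence: dict  # level -> {order: influence}
    attribute_tests: pd.DataFrame
    farm_connectivity: pd.DataFrame
    intensity_fit: dict | None
    driver_report: drivers.RfDriverReport | None
    truth: object | None
    manifest: dict


def _stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([root, abs(hash(stage)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def infer_network(
    table: pd.DataFrame,
    cfg: MicConfig,
    taxonomy: pd.DataFrame | None = None,
    alpha: float = 0.05,
    null: np.ndarray | None = None,
):
    """MIC associations -> permutation p-values -> BH -> graph, in one step."""
    assoc = mic_matrix(table, cfg)
    assoc = permutation_pvalues(assoc, table, cfg, null=null)
    assoc = classify_edges(assoc, cfg)
    net = network.build_network(assoc, alpha, taxonomy)
    return assoc, net


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- input ------------------------------------------------------------
    truth = None
    if config.simulate is not None:
        table, taxonomy, metadata, truth = generate_study(config.simulate)
        logger.info("simulated study: %s samples x %s OTUs", *table.shape)
        if outdir:
            write_study(outdir / "input", table, taxonomy, metadata, truth)
    else:
        table = otu.read_counts(config.counts_path)
        taxonomy = otu.read_taxonomy(config.taxonomy_path)
        metadata = otu.read_metadata(config.metadata_path)
    if config.group_column not in metadata.columns:
        raise ValueError(f"metadata lacks group column {config.group_column!r}")

    # --- filtering and rarefaction ----------------------------------------
    table = otu.filter_low_abundance(table, config.global_frac, config.sample_frac)
    # filtering can leave rows a little short of the nominal depth (the
    # removed rare OTUs carried reads); rarefy everything to the deepest
    # common depth so samples stay comparable
    depth = int(min(config.rarefy_depth, table.sum(axis=1).min()))
    if depth < config.rarefy_depth:
        logger.info("rarefying to %d reads (deepest common depth)", depth)
    table = otu.rarefy(table, depth, _stage_seed(config.seed, "rarefy"))
    table = otu.prevalence_filter(table, config.min_prevalence)
    groups = metadata.loc[table.index, config.group_column]

    # --- community statistics ---------------------------------------------
    div = community.alpha_diversity(table)
    bc = community.bray_curtis(table)
    perma = community.permanova(
        bc, groups, config.stat_permutations, _stage_seed(config.seed, "permanova")
    )
    disp = community.permdisp(
        bc, groups, config.stat_permutations, _stage_seed(config.seed, "permdisp")
    )
    indic = community.indicator_species(
        table, groups, config.stat_permutations, _stage_seed(config.seed, "indval")
    )

    # --- networks: pooled + per group -------------------------------------
    levels = {"pooled": table.index}
    for g in sorted(groups.unique()):
        levels[g] = table.index[groups == g]
    associations, networks, topologies, keystones_, influence = {}, {}, {}, {}, {}
    attrs_by_group = {}
    nulls_by_n: dict[int, np.ndarray] = {}
    for level, samples in levels.items():
        sub = table.loc[samples]
        sub = sub.loc[:, (sub.to_numpy() > 0).sum(axis=0) >= config.min_prevalence]
        cfg = MicConfig(
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=_stage_seed(config.seed, f"mic-{len(samples)}"),
        )
        n = len(samples)
        if n not in nulls_by_n:  # null depends on the sample size only
            rng = np.random.default_rng(cfg.seed)
            nulls_by_n[n] = null_mic_distribution(sub, cfg, rng)
        assoc, net = infer_network(sub, cfg, taxonomy, config.alpha, nulls_by_n[n])
        associations[level] = assoc
        networks[level] = net
        if net.number_of_nodes() == 0:
            logger.warning("level %s: no significant edges", level)
            topologies[level] = None
            keystones_[level] = keystone.select_keystones(
                pd.DataFrame(columns=["degree", "closeness", "betweenness"]),
                config.group_criteria,
            )
            influence[level] = {}
            continue
        topologies[level] = network.topology_summary(net)
        node_attrs = network.node_centralities(net)
        crit = config.overall_criteria if level == "pooled" else config.group_criteria
        keystones_[level] = keystone.select_keystones(node_attrs, crit, taxonomy)
        influence[level] = keystone.proportional_influence(net, taxonomy)
        if level != "pooled":
            attrs_by_group[level] = node_attrs

    # --- cross-group comparison -------------------------------------------
    if len(attrs_by_group) >= 2:
        ks_tests = compare.pairwise_attribute_tests(
            attrs_by_group, "degree", seed=_stage_seed(config.seed, "ks")
        )
    else:
        ks_tests = pd.DataFrame()
    conn_frames = []
    for g, samples in levels.items():
        if g == "pooled" or networks[g].number_of_nodes() == 0:
            continue
        conn_frames.append(
            compare.farm_subgraph_connectivity(
                networks[g], table.loc[samples], metadata
            )
        )
    farm_conn = (
        pd.concat(conn_frames) if conn_frames else pd.DataFrame(
            columns=["connectivity", "system", "intensity"]
        )
    )
    intensity_fit = None
    if len(farm_conn) >= 3 and farm_conn["intensity"].notna().any():
        try:
            intensity_fit = compare.connectivity_vs_intensity(farm_conn)
        except ValueError as exc:
            logger.warning("intensity regression skipped: %s", exc)

    # --- drivers ------------------------------------------------------------
    driver_report = None
    recovered = sorted(
        {o for lvl, rep in keystones_.items() if lvl != "pooled" for o in rep.otus},
        key=str,
    )
    covariate_cols = [
        c
        for c in metadata.columns
        if c not in (config.group_column, "region", "intensity_index")
        and pd.api.types.is_numeric_dtype(metadata[c])
    ]
    if recovered and len(covariate_cols) >= 2:
        response = drivers.keystone_abundance_response(table, recovered)
        driver_report = drivers.rf_permutation_significance(
            metadata.loc[table.index, covariate_cols],
            response,
            n_perm=config.rf_permutations,
            n_trees=config.rf_trees,
            alpha=config.rf_alpha,
            seed=_stage_seed(config.seed, "rf"),
        )

    manifest = {
        "seed": config.seed,
        "alpha": config.alpha,
        "n_permutations": config.n_permutations,
        "rarefy_depth": config.rarefy_depth,
        "group_column": config.group_column,
        "levels": {k: list(map(str, v)) for k, v in levels.items()},
        "n_otus_analyzed": int(table.shape[1]),
        "keystone_counts": {k: len(v.otus) for k, v in keystones_.items()},
        "edge_counts": {
            k: (networks[k].number_of_edges() if networks[k] is not None else 0)
            for k in networks
        },
    }
    result = PipelineResult(
        table=table,
        taxonomy=taxonomy,
        metadata=metadata,
        diversity=div,
        permanova=perma,
        permdisp=disp,
        indicators=indic,
        associations=associations,
        networks=networks,
        topologies=topologies,
        keystones=keystones_,
        influence=influence,
        attribute_tests=ks_tests,
        farm_connectivity=farm_conn,
        intensity_fit=intensity_fit,
        driver_report=driver_report,
        truth=truth,
        manifest=manifest,
    )
    if outdir:
        _write_reports(result, outdir)
    return result


def _write_reports(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.diversity.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    res.indicators.to_csv(outdir / "indicator_species.tsv", sep="\t")
    for level, assoc in res.associations.items():
        assoc.to_csv(outdir / f"associations_{level}.tsv", sep="\t", index=False)
        net = res.networks[level]
        if net.number_of_nodes():
            network.write_graphml(net, outdir / f"network_{level}.graphml")
            network.write_sif(net, outdir / f"network_{level}.sif")
        rep = res.keystones[level]
        rep.keystones.to_csv(outdir / f"keystones_{level}.tsv", sep="\t")
    if len(res.attribute_tests):
        res.attribute_tests.to_csv(outdir / "ks_tests.tsv", sep="\t", index=False)
    res.farm_connectivity.to_csv(outdir / "farm_connectivity.tsv", sep="\t")
    if res.driver_report is not None:
        res.driver_report.importance.to_csv(outdir / "drivers.tsv", sep="\t")
    summary = dict(res.manifest)
    summary["permanova"] = asdict(res.permanova)
    summary["permdisp"] = asdict(res.permdisp)
    if res.intensity_fit:
        summary["intensity_fit"] = res.intensity_fit
    (outdir / "manifest.json").write_text(json.dumps(summary, indent=2))
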