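"""End-to-end orchestration: one network and keystone report per land use.

The canonical stage order, run independently per group level (natural and
cultivated samples are never pooled into one network):

    archaea removal -> rarefaction -> top-N selection -> SparCC ->
    permutation p-values -> thresholded network -> modules -> Zi-Pi roles ->
    module eigengenes -> module-trait correlations -> GS/MM -> hub genes ->
    keystone report

Every stage logs its in/out counts; a run writes all tables plus a JSON
manifest (seed, configuration, SHA-256 of every numeric output) so a rerun
with the same seed can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .modtrait import (
    EigengeneSet,
    gene_scores,
    keystone_report,
    module_eigengene,
    module_trait_correlation,
)
from .otu import (
    DEFAULT_RAREFACTION_DEPTH,
    DEFAULT_TOP_N,
    OtuTable,
    relative_abundance,
    remove_archaea,
    top_abundant,
    rarefy,
)
from .sparcc import CorrelationNetwork, SparccConfig, build_network, permutation_pvalues, sparcc
from .stats import pearson_with_p  # re-exported: the shared correlation test
from .topology import ModulePartition, detect_modules, node_roles, topology_summary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GroupResult", "run_stages", "run_group_analysis", "pearson_with_p"]


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full analysis run."""

    rarefaction_depth: int | None = DEFAULT_RAREFACTION_DEPTH
    top_n: int = DEFAULT_TOP_N
    sparcc: SparccConfig = field(default_factory=SparccConfig)
    group_var: str = "land_use"
    gs_trait: str = "CMR"
    trait_names: tuple[str, ...] | None = None  # None = every trait column
    module_method: str = "greedy"
    seed: int = 0

    def resolved_sparcc(self) -> SparccConfig:
        return dataclasses.replace(self.sparcc, seed=self.seed)


@dataclass
class GroupResult:
    """All artifacts of one group-level analysis."""

    group: str
    table: OtuTable
    network: CorrelationNetwork
    partition: ModulePartition
    roles: pd.DataFrame
    eigengenes: EigengeneSet
    module_trait: pd.DataFrame
    scores: pd.DataFrame
    keystones: pd.DataFrame
    summary: dict


def run_stages(
    table: OtuTable,
    traits: pd.DataFrame,
    config: RunConfig = RunConfig(),
    annotations: pd.Series | None = None,
    group: str = "all",
) -> GroupResult:
    """Run the full stage sequence on one sample group."""
    table = remove_archaea(table)
    if config.rarefaction_depth is not None:
        table = rarefy(table, config.rarefaction_depth, seed=config.seed)
        if table.n_samples < 3:
            raise RuntimeError(
                f"stage 'rarefy' left {table.n_samples} samples; "
                "lower the rarefaction depth"
            )
    table = top_abundant(table, config.top_n)
    scfg = config.resolved_sparcc()
    rho = sparcc(table, scfg)
    pvals = permutation_pvalues(table, rho, scfg)
    network = build_network(rho, pvals, scfg)
    partition = detect_modules(network, seed=config.seed, method=config.module_method)
    roles = node_roles(network, partition)
    fractions = relative_abundance(table)
    eigs = module_eigengene(fractions, partition)
    trait_cols = list(config.trait_names) if config.trait_names else list(traits.columns)
    trait_view = traits.loc[:, trait_cols]
    mt = module_trait_correlation(eigs, trait_view)
    scores = gene_scores(fractions, eigs, trait_view, partition, config.gs_trait)
    keystones = keystone_report(scores, roles, annotations, taxonomy=table.taxonomy)
    summary = topology_summary(network, partition)
    summary["group"] = group
    summary["n_keystones"] = int(keystones["keystone"].sum())
    return GroupResult(
        group=group,
        table=table,
        network=network,
        partition=partition,
        roles=roles,
        eigengenes=eigs,
        module_trait=mt,
        scores=scores,
        keystones=keystones,
        summary=summary,
    )


def run_group_analysis(
    table: OtuTable,
    metadata: pd.DataFrame,
    traits: pd.DataFrame,
    config: RunConfig = RunConfig(),
    annotations: pd.Series | None = None,
    outdir: str | Path | None = None,
) -> dict[str, GroupResult]:
    """One independent analysis per level of ``config.group_var``.

    Returns ``{group level: GroupResult}``; with ``outdir`` set, all
    tables, GraphML networks, and a run manifest are written under
    ``outdir/<group>/``. A stage failure aborts with the stage named;
    outputs of earlier groups are preserved.
    """
    if config.group_var not in metadata.columns:
        raise KeyError(f"grouping variable {config.group_var!r} not in metadata")
    results: dict[str, GroupResult] = {}
    for level in sorted(metadata[config.group_var].unique()):
        samples = metadata.index[metadata[config.group_var] == level]
        sub = table.subset_samples(samples)
        sub_traits = traits.loc[traits.index.intersection(samples)]
        logger.info("group %s: %d samples", level, sub.n_samples)
        try:
            result = run_stages(sub, sub_traits, config, annotations, group=str(level))
        except Exception as err:
            raise RuntimeError(f"group {level!r} failed: {err}") from err
        results[str(level)] = result
        if outdir is not None:
            write_group_outputs(result, Path(outdir) / str(level))
    if outdir is not None:
        _write_manifest(results, config, Path(outdir))
    return results


def write_group_outputs(result: GroupResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.table.write(outdir / "filtered_counts.tsv", outdir / "taxonomy.tsv")
    result.network.rho.to_csv(outdir / "sparcc_rho.tsv", sep="\t")
    result.network.pval.to_csv(outdir / "sparcc_pvalues.tsv", sep="\t")
    result.network.edge_list().to_csv(outdir / "edges.tsv", sep="\t", index=False)
    result.network.write_graphml(outdir / "network.graphml")
    result.roles.to_csv(outdir / "node_roles.tsv", sep="\t")
    result.eigengenes.as_frame().to_csv(outdir / "eigengenes.tsv", sep="\t")
    result.module_trait.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
    result.scores.to_csv(outdir / "gene_scores.tsv", sep="\t")
    result.keystones.to_csv(outdir / "keystone_report.tsv", sep="\t")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    with open(outdir / "provenance.txt", "w") as fh:
        fh.write("\n".join(result.table.provenance) + "\n")


def _write_manifest(results: dict[str, GroupResult], config: RunConfig, outdir: Path) -> None:
    files = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            files[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    manifest = {
        "peatnet_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "groups": sorted(results),
        "outputs_sha256": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
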