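"""Module eigengenes, trait associations, and keystone-taxon screening.

A module eigengene is the first principal component of its members'
standardized relative abundances across samples — one representative
profile per module. Because principal components are sign-ambiguous, the
eigengene is oriented to correlate positively with the mean standardized
member profile, so reported module-trait correlation signs are meaningful.

Per-taxon screening follows the weighted-co-expression vocabulary:

* GS (gene significance): correlation of a taxon's abundance with an
  external trait (default the carbon mineralization rate, CMR);
* MM (module membership): correlation of a taxon's abundance with its own
  module's eigengene.

A taxon is a *hub gene* when both GS and MM are significant (p < 0.05,
raw). A taxon is *keystone* when it is a hub gene OR a critical node
(module hub / connector / network hub by Zi-Pi) AND carries a
carbon-metabolism function flag — the flag is user-supplied annotation
(literature-based), never computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import pearson_matrix, pearson_with_p, star_band
from .topology import CRITICAL_ROLES, ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "Eigengene",
    "EigengeneSet",
    "module_eigengene",
    "module_trait_correlation",
    "gene_scores",
    "hub_genes",
    "keystone_report",
]


@dataclass
class Eigengene:
    """First principal component of one module's member abundances."""

    scores: pd.Series  # one score per sample, unit Euclidean norm
    variance_explained: float
    members: list[str]
    dropped: list[str]


class EigengeneSet(dict):
    """module index -> :class:`Eigengene`; skipped modules are absent."""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f"ME{m}": e.scores for m, e in sorted(self.items())})


def _standardize_rows(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sd = X.std(axis=1, ddof=0)
    constant = list(X.index[sd == 0])
    X = X.loc[sd > 0]
    return X.sub(X.mean(axis=1), axis=0).div(sd[sd > 0], axis=0), constant


def module_eigengene(
    rel_abundance: pd.DataFrame, part: ModulePartition
) -> EigengeneSet:
    """Eigengene per module from a relative-abundance table (taxa x samples).

    Member abundances are standardized per taxon (mean 0, sd 1 across
    samples); the eigengene is the first left singular vector of the
    samples x members matrix, unit-norm, sign-anchored to the mean member
    profile. Constant-abundance members are dropped with a warning; a
    module left with fewer than 2 members is skipped and reported.
    """
    if rel_abundance.shape[1] < 3:
        raise ValueError("need >= 3 samples for an eigengene")
    out = EigengeneSet()
    for module in sorted(set(part.assignments.values())):
        members = [m for m in part.members(module) if m in rel_abundance.index]
        X, dropped = _standardize_rows(rel_abundance.loc[members])
        if dropped:
            logger.warning(
                "module %d: dropped %d constant members (%s...)",
                module,
                len(dropped),
                dropped[0],
            )
        if X.shape[0] < 2:
            logger.warning("module %d reduced below 2 members; skipped", module)
            continue
        # samples x members
        U, s, _ = np.linalg.svd(X.to_numpy().T, full_matrices=False)
        scores = U[:, 0]
        mean_profile = X.to_numpy().mean(axis=0)
        if np.dot(scores, mean_profile) < 0:
            scores = -scores
        out[module] = Eigengene(
            scores=pd.Series(scores, index=rel_abundance.columns, name=f"ME{module}"),
            variance_explained=float(s[0] ** 2 / (s**2).sum()),
            members=list(X.index),
            dropped=dropped,
        )
    return out


def module_trait_correlation(
    eigs: EigengeneSet, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r/p between every module eigengene and every trait.

    Samples are aligned on the trait index; missing trait values are
    dropped pairwise (logged). Associations with fewer than 3 complete
    pairs are marked not-computable (NaN). Output is long-form with
    columns module, trait, r, p, stars, n.
    """
    rows = []
    for module, eig in sorted(eigs.items()):
        common = eig.scores.index.intersection(traits.index)
        if len(common) < len(eig.scores):
            logger.warning(
                "module %d: %d samples lack trait rows",
                module,
                len(eig.scores) - len(common),
            )
        for trait in traits.columns:
            res = pearson_with_p(eig.scores.loc[common], traits.loc[common, trait])
            rows.append(
                {
                    "module": module,
                    "trait": trait,
                    "r": res.r,
                    "p": res.p,
                    "stars": star_band(res.p),
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def gene_scores(
    rel_abundance: pd.DataFrame,
    eigs: EigengeneSet,
    traits: pd.DataFrame,
    part: ModulePartition,
    trait_name: str = "CMR",
) -> pd.DataFrame:
    """GS and MM per partitioned taxon.

    GS correlates each taxon's abundance with ``traits[trait_name]``; MM
    correlates it with its own module's eigengene. Both are computed on
    the same aligned sample set. Constant taxa get NaN scores (flagged in
    the ``constant`` column) rather than raising.
    """
    if trait_name not in traits.columns:
        raise KeyError(f"trait {trait_name!r} not in trait table")
    taxa = [t for t in sorted(part.assignments) if t in rel_abundance.index]
    samples = rel_abundance.columns.intersection(traits.index)
    X = rel_abundance.loc[taxa, samples].to_numpy()
    trait = traits.loc[samples, trait_name].to_numpy(dtype=float)
    gs_r, gs_p = pearson_matrix(X, trait)
    records = []
    for i, taxon in enumerate(taxa):
        module = part.assignments[taxon]
        if module in eigs:
            eig = eigs[module].scores.loc[samples].to_numpy()
            mm = pearson_with_p(X[i], eig)
            mm_r, mm_p = mm.r, mm.p
        else:
            mm_r = mm_p = np.nan
        records.append(
            {
                "module": module,
                "gs_r": gs_r[i, 0],
                "gs_p": gs_p[i, 0],
                "mm_r": mm_r,
                "mm_p": mm_p,
                "constant": bool(np.isnan(gs_r[i, 0]) and X[i].std() == 0),
            }
        )
    return pd.DataFrame(records, index=pd.Index(taxa, name="taxon"))


def hub_genes(scores: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Hub-gene flag: GS p < alpha AND MM p < alpha (raw p-values).

    NaN p-values (constant taxa, skipped modules) never qualify.
    """
    with np.errstate(invalid="ignore"):
        flag = (scores["gs_p"] < alpha) & (scores["mm_p"] < alpha)
    flag = flag.fillna(False).astype(bool)
    flag.name = "hub_gene"
    return flag


def keystone_report(
    scores: pd.DataFrame,
    roles: pd.DataFrame,
    annotations: pd.Series | None = None,
    taxonomy: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keystone screening with a full evidence trail per candidate.

    ``keystone = (hub_gene OR critical_node) AND function_flag`` where
    critical nodes are module hubs, connectors, and network hubs, and
    ``function_flag`` is the user-supplied carbon-metabolism annotation.
    Taxa absent from the annotation table pass the function gate with a
    warning flag (``function_annotated = False``), so an un-annotated run
    still surfaces every structural candidate.
    """
    taxa = scores.index
    hubs = hub_genes(scores, alpha=alpha)
    critical = roles["role"].reindex(taxa).isin(CRITICAL_ROLES).fillna(False)
    if annotations is None:
        annotations = pd.Series(dtype=bool)
    annotated = taxa.isin(annotations.index)
    function_flag = pd.Series(True, index=taxa)
    function_flag[annotated] = annotations.reindex(taxa)[annotated].astype(bool)
    if (~annotated).any():
        logger.warning(
            "%d taxa lack a C-metabolism annotation; treated as passing "
            "the function gate (flagged)",
            int((~annotated).sum()),
        )
    report = pd.DataFrame(
        {
            "module": scores["module"],
            "role": roles["role"].reindex(taxa).fillna("unclassified"),
            "gs_r": scores["gs_r"],
            "gs_p": scores["gs_p"],
            "mm_r": scores["mm_r"],
            "mm_p": scores["mm_p"],
            "hub_gene": hubs,
            "critical_node": critical,
            "function_flag": function_flag,
            "function_annotated": pd.Series(annotated, index=taxa),
        }
    )
    report["keystone"] = (report["hub_gene"] | report["critical_node"]) & report[
        "function_flag"
    ]
    if taxonomy is not None:
        report.insert(0, "taxonomy", taxonomy.reindex(taxa))
    return report
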