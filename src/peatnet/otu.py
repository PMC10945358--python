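"""OTU count tables: container, I/O, filtering, and rarefaction.

The :class:`OtuTable` is the object every downstream stage consumes: an
integer count matrix (taxa as rows, samples as columns), a taxonomy lineage
per taxon, and a free-text provenance log that records what each filter did
(counts in/out), so a finished analysis can narrate exactly how many taxa
and reads each step removed.

Taxonomy dialects: lineages are semicolon-delimited 7-rank strings; both
Greengenes-style rank prefixes (``d__Bacteria;p__...``) and bare SILVA-style
names (``Bacteria;Proteobacteria;...``) are accepted wherever a rank is
matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "read_counts",
    "read_taxonomy",
    "read_metadata",
    "read_traits",
    "write_traits",
    "rarefy",
    "remove_archaea",
    "top_abundant",
    "relative_abundance",
    "DEFAULT_RAREFACTION_DEPTH",
    "DEFAULT_TOP_N",
]

#: Community-standard defaults for this pipeline: rarefy each sample to a
#: common depth, then network the most abundant taxa.
DEFAULT_RAREFACTION_DEPTH = 39575
DEFAULT_TOP_N = 2000


@dataclass
class OtuTable:
    """Integer OTU counts with taxonomy and a processing log.

    ``counts`` is taxa x samples; ``taxonomy`` maps taxon ID to a
    semicolon-delimited lineage (missing entries are filled with
    ``"Unassigned"``). Validation rejects duplicate IDs, negative counts,
    and non-integer counts.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate taxon IDs in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in count table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        self.counts.index.name = "taxon_id"
        self.counts.columns.name = None
        if self.taxonomy is None:
            self.taxonomy = pd.Series("Unassigned", index=self.counts.index, name="taxonomy")
        else:
            self.taxonomy = self.taxonomy.reindex(self.counts.index).fillna("Unassigned")
            self.taxonomy.name = "taxonomy"

    # -- basic views -----------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def log(self, message: str) -> None:
        logger.info(message)
        self.provenance.append(message)

    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = [s for s in sample_ids if s in self.counts.columns]
        return OtuTable(
            self.counts.loc[:, sample_ids].copy(),
            self.taxonomy.copy(),
            list(self.provenance) + [f"subset to {len(sample_ids)} samples"],
        )

    def _replace_counts(self, counts: pd.DataFrame, message: str) -> "OtuTable":
        table = OtuTable(counts, self.taxonomy.reindex(counts.index), list(self.provenance))
        table.log(message)
        return table

    # -- I/O -------------------------------------------------------------
    def write(self, counts_path, taxonomy_path=None) -> None:
        """Write counts (and optionally taxonomy) as tab-separated tables."""
        out = self.counts.copy()
        out.index.name = "taxon_id"
        out.to_csv(counts_path, sep="\t")
        if taxonomy_path is not None:
            tax = self.taxonomy.to_frame()
            tax.index.name = "taxon_id"
            tax.to_csv(taxonomy_path, sep="\t")


def read_counts(counts_path, taxonomy_path=None) -> OtuTable:
    """Read a taxa-as-rows tab-separated OTU table (first column = taxon ID)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    table = OtuTable(counts, taxonomy)
    table.log(
        f"read {table.n_taxa} taxa x {table.n_samples} samples from {Path(counts_path).name}"
    )
    return table


def read_taxonomy(path) -> pd.Series:
    tax = pd.read_csv(path, sep="\t", index_col=0)
    series = tax.iloc[:, 0].astype(str)
    series.index = series.index.astype(str)
    return series


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata (sample_id, site, land_use, plot, depth)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample IDs in metadata")
    return meta


def read_traits(path) -> pd.DataFrame:
    traits = pd.read_csv(path, sep="\t", index_col=0)
    traits.index = traits.index.astype(str)
    return traits


def write_traits(traits: pd.DataFrame, path) -> None:
    out = traits.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# -- filters -------------------------------------------------------------

def rarefy(table: OtuTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int = 0) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each sample is drawn from the multivariate hypergeometric distribution
    over its taxon counts, so rarefied counts never exceed the originals and
    sum exactly to ``depth``. Samples whose total is below ``depth`` cannot
    be rarefied and are dropped (recorded loudly in provenance).
    Deterministic under a fixed ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals.index[totals >= depth]
    dropped = sorted(set(table.samples) - set(keep))
    new = {}
    for sample in keep:
        col = table.counts[sample].to_numpy()
        if totals[sample] == depth:
            new[sample] = col
        else:
            new[sample] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(new, index=table.counts.index, columns=keep)
    message = f"rarefied to {depth} reads/sample; dropped {len(dropped)} samples below depth"
    if dropped:
        message += f" ({', '.join(dropped)})"
    return table._replace_counts(counts, message)


def _domain_of(lineage: str) -> str:
    first = str(lineage).split(";")[0].strip()
    for prefix in ("d__", "k__", "D_0__"):
        if first.startswith(prefix):
            first = first[len(prefix):]
    return first.strip().lower()


def remove_archaea(table: OtuTable) -> OtuTable:
    """Drop taxa whose lineage domain is Archaea (any prefix dialect).

    The removed-taxon count and the fraction of reads they carried are
    logged, mirroring how amplicon studies report the archaeal share before
    a bacteria-only analysis.
    """
    is_archaea = table.taxonomy.map(_domain_of) == "archaea"
    removed = is_archaea.sum()
    total_reads = table.counts.to_numpy().sum()
    removed_reads = table.counts.loc[is_archaea].to_numpy().sum()
    frac = removed_reads / total_reads if total_reads else 0.0
    counts = table.counts.loc[~is_archaea]
    return table._replace_counts(
        counts,
        f"removed {removed} archaeal taxa carrying {frac:.1%} of reads",
    )


def top_abundant(table: OtuTable, n: int = DEFAULT_TOP_N) -> OtuTable:
    """Keep the ``n`` taxa with the highest total counts across samples.

    Ties at the cutoff are broken by taxon ID (lexicographic ascending), so
    selection is deterministic and repeatable. If ``n`` exceeds the table
    size the full table is returned.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    totals = table.counts.sum(axis=1)
    order = sorted(totals.index, key=lambda t: (-totals[t], t))
    chosen = order[: min(n, len(order))]
    retained = totals[chosen].sum() / totals.sum() if totals.sum() else 0.0
    counts = table.counts.loc[chosen]
    return table._replace_counts(
        counts,
        f"kept top {len(chosen)} of {table.n_taxa} taxa ({retained:.1%} of reads)",
    )


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample fractions (taxa x samples); each column sums to 1."""
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero samples cannot be normalised: {bad}")
    return table.counts / totals
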