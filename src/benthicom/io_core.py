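"""Reading, validation, and writing of the tabular and tree formats used
throughout the pipeline, plus taxon filtering and taxonomy bookkeeping.

Community tables are samples x taxa integer count matrices.  On disk they
follow the dominant amplicon dialect: tab-separated, taxa as rows, sample
identifiers in the header; an explicit flag flips the orientation (no
sniffing).  Counts are stored as integers everywhere; relative abundances
are always derived on demand and never persisted, which avoids
double-normalisation bugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("bacteria", "fungi", "protist")
RANKS = ("phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "Unclassified"


class ValidationError(ValueError):
    """Raised when an input table or tree violates a structural invariant."""


def _check_unique(values: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise ValidationError(f"duplicate {what} identifier: {v!r}")
        seen.add(v)


@dataclass
class CommunityTable:
    """Samples x taxa count matrix for one domain (bacteria, fungi, protist).

    ``data`` holds nonnegative integer counts with sample identifiers on the
    index and taxon identifiers on the columns.  Row and column order is
    preserved from the source and is semantically meaningful only for
    reproducibility (all statistics are order-invariant).
    """

    data: pd.DataFrame
    domain: str = "bacteria"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValidationError(
                f"unknown domain {self.domain!r}; expected one of {DOMAINS}"
            )
        _check_unique(list(self.data.index.astype(str)), "sample")
        _check_unique(list(self.data.columns.astype(str)), "taxon")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValidationError(
                f"non-integer count at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(np.int64)
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise ValidationError(f"samples with zero total count: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised abundances (each sample sums to 1)."""
        return self.data.div(self.data.sum(axis=1), axis=0)


@dataclass
class TaxonomyMap:
    """taxon_id -> ranked lineage (phylum .. genus); unmapped taxa resolve to
    ``Unclassified`` at every rank."""

    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def get(self, taxon_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineages.get(taxon_id, {}).get(rank, UNCLASSIFIED)

    @classmethod
    def from_lineage_strings(cls, mapping: Mapping[str, str]) -> "TaxonomyMap":
        """Build from semicolon-delimited lineage strings ordered phylum-first."""
        lineages = {}
        for taxon, lineage in mapping.items():
            if taxon in lineages:
                raise ValidationError(f"duplicate taxon in taxonomy: {taxon!r}")
            parts = [p.strip() for p in lineage.split(";") if p.strip()]
            lineages[taxon] = dict(zip(RANKS, parts))
        return cls(lineages)


@dataclass
class SampleMetadata:
    """Per-sample group label and sediment chemistry values (µg/g)."""

    frame: pd.DataFrame  # index: sample_id; columns: "group" + chemistry

    def __post_init__(self) -> None:
        if "group" not in self.frame.columns:
            raise ValidationError("metadata must contain a 'group' column")
        _check_unique(list(self.frame.index.astype(str)), "sample")

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    def group_labels(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def require_two_groups(self) -> tuple[str, str]:
        labels = self.group_labels()
        if len(labels) != 2:
            raise ValidationError(
                f"two-group comparison requires exactly 2 group labels, got {labels}"
            )
        return labels[0], labels[1]

    def check_covers(self, table: CommunityTable) -> None:
        missing = set(table.sample_ids) - set(self.frame.index)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)}")


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths, tips labelled by taxon identifiers."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        _check_unique(labels, "tip")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length in tree")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# readers / writers


def read_community_table(
    path: str | Path, domain: str, taxa_as_rows: bool = True
) -> CommunityTable:
    """Read a tab-separated count table.

    First column holds taxon IDs and the header row sample IDs when
    ``taxa_as_rows`` (the default dialect); the flag flips orientation.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(list(raw.index.astype(str)), "taxon" if taxa_as_rows else "sample")
    _check_unique(list(raw.columns.astype(str)), "sample" if taxa_as_rows else "taxon")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"non-numeric count at row {raw.index[bad[0]]!r}, "
            f"column {raw.columns[bad[1]]!r} in {path}"
        )
    frame = numeric.T if taxa_as_rows else numeric
    frame.index.name = None
    frame.columns.name = None
    return CommunityTable(data=frame, domain=domain)


def write_community_table(
    table: CommunityTable, path: str | Path, taxa_as_rows: bool = True
) -> None:
    frame = table.data.T if taxa_as_rows else table.data
    frame.to_csv(path, sep="\t", index_label="taxon_id" if taxa_as_rows else "sample_id")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Two-column TSV: taxon_id <TAB> semicolon-delimited lineage (phylum first)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise ValidationError(f"taxonomy file {path} needs >= 2 columns")
    taxa = raw.iloc[:, 0]
    if taxa.duplicated().any():
        dup = taxa[taxa.duplicated()].iloc[0]
        raise ValidationError(f"duplicate taxon in taxonomy: {dup!r}")
    return TaxonomyMap.from_lineage_strings(
        dict(zip(taxa, raw.iloc[:, 1].fillna("")))
    )


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    rows = []
    for taxon, lineage in taxonomy.lineages.items():
        parts = [lineage.get(r, "") for r in RANKS]
        while parts and parts[-1] == "":
            parts.pop()
        rows.append((taxon, ";".join(parts)))
    pd.DataFrame(rows, columns=["taxon_id", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(frame=frame)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_newick(path: str | Path) -> PhyloTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return PhyloTree(tree=tree)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# filtering / aggregation


def filter_prevalence_abundance(
    table: CommunityTable,
    min_prevalence: float = 0.25,
    top_n: int | None = 50,
) -> CommunityTable:
    """Restrict the taxon universe by prevalence, then (optionally) keep the
    ``top_n`` most abundant retained taxa.

    A taxon is retained when present (count > 0) in at least
    ``min_prevalence`` of samples.  Abundance ties at the ``top_n`` cut are
    broken by lexical taxon-id order so the result is deterministic.
    The sample set is never changed.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValidationError("min_prevalence must be in [0, 1]")
    prevalence = (table.data > 0).mean(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index
    if top_n is not None and len(keep) > top_n:
        totals = table.data[keep].sum(axis=0)
        order = sorted(keep, key=lambda t: (-totals[t], t))
        keep = pd.Index(order[:top_n])
    if len(keep) == 0:
        raise ValidationError(
            f"prevalence filter at {min_prevalence} removed every taxon"
        )
    kept = [t for t in table.taxon_ids if t in set(keep)]
    logger.info(
        "filter_prevalence_abundance(%s): %d -> %d taxa (min_prevalence=%.3g, top_n=%s)",
        table.domain, table.n_taxa, len(kept), min_prevalence, top_n,
    )
    return CommunityTable(data=table.data[kept], domain=table.domain)


def aggregate_to_rank(
    table: CommunityTable, taxonomy: TaxonomyMap, rank: str = "phylum"
) -> CommunityTable:
    """Sum counts within each lineage value at ``rank``.

    Unmapped taxa pool into ``Unclassified`` so per-sample totals are
    conserved exactly (integer arithmetic).  Output columns are ordered by
    descending total abundance.
    """
    groups = pd.Series(
        [taxonomy.get(t, rank) for t in table.taxon_ids], index=table.taxon_ids
    )
    agg = table.data.T.groupby(groups).sum().T
    order = agg.sum(axis=0).sort_values(ascending=False, kind="stable").index
    return CommunityTable(data=agg[order], domain=table.domain)


def patristic_distances(
    tree: PhyloTree, taxa: Iterable[str] | None = None
) -> pd.DataFrame:
    """Symmetric matrix of sum-of-branch-length path distances between tips."""
    tips = tree.tip_labels
    if taxa is None:
        taxa = tips
    taxa = list(taxa)
    missing = sorted(set(taxa) - set(tips))
    if missing:
        raise ValidationError(f"taxa missing from tree tips: {missing}")
    pdm = tree.tree.phylogenetic_distance_matrix()
    leaf_by_label = {
        leaf.taxon.label: leaf.taxon for leaf in tree.tree.leaf_node_iter()
    }
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaf_by_label[taxa[i]], leaf_by_label[taxa[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=taxa, columns=taxa)
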