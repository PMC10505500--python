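"""Reading taxonomic classifications into lowest-level count tables.

Two input routes are supported:

* the RDP Classifier's hierarchical count file — tab-separated with columns
  ``taxid, lineage, name, rank`` followed by one count column per sample,
  where counts are cumulative down the taxonomy (a genus's reads are also
  counted in its family, order, ... up to Root) and the lineage is a
  semicolon-delimited alternating name/rank path ending at the row's node;
* generic OTU/ASV count + taxonomy tables as exported from amplicon
  pipelines (one taxonomy column per rank, empty cell = unassigned).

Both routes produce a :class:`ClassificationTable` of *lowest-level*
classifications: each read is counted exactly once, at the deepest rank
between phylum and the configured lowest rank at which it was assigned.
Domain-level residuals and nonprokaryotic lineages (Chloroplast,
Mitochondria, Eukaryota by default) are removed, and the removed totals are
kept on the table for accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RANKS",
    "DEFAULT_FILTER_TERMS",
    "TaxonRecord",
    "ClassificationTable",
    "MalformedHierarchyError",
    "read_rdp_hierarchy",
    "taxa_counts_from_tables",
]

#: Taxonomic ranks from shallowest to deepest.
RANKS: tuple[str, ...] = (
    "rootrank", "domain", "phylum", "class", "order", "family", "genus", "species",
)
_RANK_DEPTH = {rank: i for i, rank in enumerate(RANKS)}

#: Lineage names removed by default (nonprokaryotic 16S signals).
DEFAULT_FILTER_TERMS: frozenset[str] = frozenset({"Chloroplast", "Mitochondria", "Eukaryota"})


class MalformedHierarchyError(ValueError):
    """A hierarchical count file violates the cumulative-count contract."""


@dataclass(frozen=True)
class TaxonRecord:
    """One classified taxon: rank, name and full lineage from domain down."""

    rank: str
    name: str
    lineage: tuple[tuple[str, str], ...]  # ordered (rank, name) pairs

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("taxon name must be non-empty")
        if self.rank not in _RANK_DEPTH:
            raise ValueError(f"unknown rank label: {self.rank!r}")
        depths = [_RANK_DEPTH[r] for r, _ in self.lineage]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError(f"lineage ranks do not strictly descend: {self.lineage}")

    def lineage_str(self) -> str:
        return ";".join(f"{name};{rank}" for rank, name in self.lineage)

    @classmethod
    def from_lineage_str(cls, rank: str, name: str, lineage: str) -> "TaxonRecord":
        parts = lineage.split(";") if lineage else []
        if len(parts) % 2 != 0:
            raise ValueError(f"lineage has an odd number of fields: {lineage!r}")
        pairs = tuple((parts[i + 1], parts[i]) for i in range(0, len(parts), 2))
        return cls(rank=rank, name=name, lineage=pairs)


@dataclass
class ClassificationTable:
    """Lowest-level taxon records with a row x sample matrix of counts.

    ``dropped`` accumulates per-sample totals removed on the way here, keyed
    by reason (``domain-level``, ``filtered``, ``unassigned``) so that count
    conservation can be audited.
    """

    records: list[TaxonRecord]
    counts: pd.DataFrame  # rows align with records; columns = sample names
    dropped: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.records) != len(self.counts):
            raise ValueError("records and counts row counts differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        keys = [(r.rank, r.name, r.lineage) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (rank, name, lineage) rows")

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    def pooled(self) -> "ClassificationTable":
        """Pool rows sharing (rank, name, lineage) by summing counts.

        Idempotent: a table built by this module is already pooled.
        """
        index: dict[tuple, int] = {}
        records: list[TaxonRecord] = []
        rows: list[np.ndarray] = []
        for rec, (_, cnt) in zip(self.records, self.counts.iterrows()):
            key = (rec.rank, rec.name, rec.lineage)
            if key in index:
                rows[index[key]] = rows[index[key]] + cnt.to_numpy(dtype=float)
            else:
                index[key] = len(records)
                records.append(rec)
                rows.append(cnt.to_numpy(dtype=float))
        counts = pd.DataFrame(rows, columns=self.counts.columns)
        return ClassificationTable(records=records, counts=counts, dropped=self.dropped)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "rank": [r.rank for r in self.records],
                "name": [r.name for r in self.records],
                "lineage": [r.lineage_str() for r in self.records],
            }
        )
        out = pd.concat([df, self.counts.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClassificationTable":
        df = pd.read_csv(path, sep="\t", dtype={"rank": str, "name": str, "lineage": str})
        for col in ("rank", "name", "lineage"):
            if col not in df.columns:
                raise ValueError(f"classification TSV is missing the {col!r} column")
        records = [
            TaxonRecord.from_lineage_str(row["rank"], row["name"], row["lineage"])
            for _, row in df.iterrows()
        ]
        counts = df.drop(columns=["rank", "name", "lineage"]).astype(float)
        return cls(records=records, counts=counts)


# ---------------------------------------------------------------------------
# RDP hierarchical files


def _validate_lowest_rank(lowest_rank: str, keep_species: bool) -> int:
    allowed = {"genus", "family", "order", "class"}
    if lowest_rank not in allowed:
        raise ValueError(f"lowest_rank must be one of {sorted(allowed)}, got {lowest_rank!r}")
    return _RANK_DEPTH["species"] if keep_species else _RANK_DEPTH[lowest_rank]


def read_rdp_hierarchy(
    path,
    filter_terms: Iterable[str] = DEFAULT_FILTER_TERMS,
    lowest_rank: str = "genus",
    keep_species: bool = False,
) -> ClassificationTable:
    """Parse an RDP hierarchical count file into lowest-level counts.

    Cumulative node counts are decomposed so each read is counted once, at
    its deepest retained rank: the lowest-level count of a node is its
    cumulative count minus the cumulative counts of its direct children
    (children deeper than ``lowest_rank`` are collapsed into the node
    instead of subtracted).  Rows whose lineage contains any of
    ``filter_terms`` are removed entirely; domain- and root-level residuals
    are dropped.  The removed per-sample totals are recorded on the result's
    ``dropped`` frame.
    """
    max_depth = _validate_lowest_rank(lowest_rank, keep_species)
    filter_terms = set(filter_terms)

    df = pd.read_csv(path, sep="\t", dtype={"taxid": str, "lineage": str, "name": str, "rank": str})
    expected = ["taxid", "lineage", "name", "rank"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"RDP file must start with columns {expected}, got {list(df.columns[:4])}")
    sample_names = list(df.columns[4:])
    if not sample_names:
        raise ValueError("RDP file has no sample count columns")

    nodes: dict[tuple, TaxonRecord] = {}
    counts: dict[tuple, np.ndarray] = {}
    for _, row in df.iterrows():
        rec = TaxonRecord.from_lineage_str(row["rank"], row["name"], row["lineage"])
        if not rec.lineage or rec.lineage[-1] != (rec.rank, rec.name):
            raise ValueError(
                f"lineage does not end at the row's own node: {row['name']!r} ({row['rank']})"
            )
        key = rec.lineage
        if key in nodes:
            raise MalformedHierarchyError(f"duplicate node: {rec.name!r} ({rec.rank})")
        vals = row[sample_names].to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError(f"negative count for node {rec.name!r}")
        nodes[key] = rec
        counts[key] = vals

    children: dict[tuple, list[tuple]] = {key: [] for key in nodes}
    for key in nodes:
        if len(key) == 1:
            continue
        parent = key[:-1]
        if parent not in nodes:
            raise MalformedHierarchyError(
                f"node {nodes[key].name!r} ({nodes[key].rank}) has no parent row in the file"
            )
        children[parent].append(key)

    roots = [key for key in nodes if len(key) == 1]
    total = sum((counts[k] for k in roots), np.zeros(len(sample_names)))

    # remove filtered subtrees; tally their cumulative counts at the topmost
    # filtered node so each filtered read is counted once
    def is_filtered(key: tuple) -> bool:
        return any(name in filter_terms for _, name in key)

    filtered_total = np.zeros(len(sample_names))
    for key in list(nodes):
        if is_filtered(key) and not is_filtered(key[:-1]):
            filtered_total += counts[key]

    live = {key for key in nodes if not is_filtered(key)}

    records: list[TaxonRecord] = []
    rows: list[np.ndarray] = []
    domain_total = np.zeros(len(sample_names))
    for key in nodes:  # file order
        if key not in live:
            continue
        rec = nodes[key]
        depth = _RANK_DEPTH[rec.rank]
        if depth > max_depth:
            continue  # collapsed upward into its retained ancestor
        residual = counts[key].copy()
        for child in children[key]:
            child_depth = _RANK_DEPTH[nodes[child].rank]
            if child in live and child_depth > max_depth:
                continue  # collapsed: its reads stay in this node's residual
            residual -= counts[child]
        if (residual < -1e-9).any():
            raise MalformedHierarchyError(
                f"children counts exceed parent count at node {rec.name!r} ({rec.rank})"
            )
        residual = np.clip(residual, 0.0, None)
        if depth < _RANK_DEPTH["phylum"]:
            domain_total += residual
            continue
        if residual.sum() == 0:
            continue
        trimmed = tuple(p for p in rec.lineage if p[0] != "rootrank")
        records.append(TaxonRecord(rank=rec.rank, name=rec.name, lineage=trimmed))
        rows.append(residual)

    counts_df = pd.DataFrame(rows if rows else np.empty((0, len(sample_names))), columns=sample_names)
    dropped = pd.DataFrame(
        [domain_total, filtered_total], index=["domain-level", "filtered"], columns=sample_names
    )
    table = ClassificationTable(records=records, counts=counts_df, dropped=dropped)

    retained = counts_df.to_numpy().sum(axis=0) if len(counts_df) else np.zeros(len(sample_names))
    if not np.allclose(retained + domain_total + filtered_total, total):
        raise MalformedHierarchyError("count decomposition does not conserve the input total")
    logger.info(
        "read %d lowest-level taxa from %s (%d samples); dropped %s domain-level and %s filtered reads",
        len(records), path, len(sample_names), domain_total.sum(), filtered_total.sum(),
    )
    return table


# ---------------------------------------------------------------------------
# OTU/ASV count + taxonomy tables


def taxa_counts_from_tables(
    otu_counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    lowest_rank: str = "genus",
    keep_species: bool = False,
) -> ClassificationTable:
    """Pool an OTU/ASV count table by lowest-level taxonomic assignment.

    ``otu_counts`` is OTU x sample; ``taxonomy`` is OTU x rank with one
    column per rank (domain..species) and empty cells for unassigned ranks.
    Each OTU is classified at its deepest non-empty rank between
    ``lowest_rank`` and phylum; OTUs sharing (rank, name) are pooled.  OTUs
    with no assignment at phylum or below are dropped and tallied under
    ``unassigned`` on the result.
    """
    max_depth = _validate_lowest_rank(lowest_rank, keep_species)
    if set(otu_counts.index).isdisjoint(taxonomy.index):
        raise ValueError("OTU count and taxonomy tables share no row identifiers")
    missing = set(otu_counts.index) - set(taxonomy.index)
    if missing:
        raise ValueError(f"OTUs missing from the taxonomy table: {sorted(missing)[:5]}")
    if (otu_counts.to_numpy() < 0).any():
        raise ValueError("OTU counts must be non-negative")

    rank_cols = [r for r in RANKS if r in taxonomy.columns]
    if "phylum" not in rank_cols:
        raise ValueError("taxonomy table must include a 'phylum' column")
    candidate = [r for r in rank_cols if _RANK_DEPTH["phylum"] <= _RANK_DEPTH[r] <= max_depth]

    tax = taxonomy.reindex(otu_counts.index)
    sample_names = list(otu_counts.columns)
    pooled: dict[tuple, np.ndarray] = {}
    pooled_rec: dict[tuple, TaxonRecord] = {}
    unassigned = np.zeros(len(sample_names))

    def cell(row, rank: str) -> str:
        val = row.get(rank)
        return "" if pd.isna(val) else str(val).strip()

    for otu, row in tax.iterrows():
        assigned_rank = None
        for rank in reversed(candidate):  # deepest first
            if cell(row, rank):
                assigned_rank = rank
                break
        vals = otu_counts.loc[otu].to_numpy(dtype=float)
        if assigned_rank is None:
            unassigned += vals
            continue
        lineage = tuple(
            (r, cell(row, r))
            for r in rank_cols
            if _RANK_DEPTH[r] <= _RANK_DEPTH[assigned_rank] and cell(row, r)
        )
        rec = TaxonRecord(rank=assigned_rank, name=cell(row, assigned_rank), lineage=lineage)
        key = (rec.rank, rec.name, rec.lineage)
        if key in pooled:
            pooled[key] += vals
        else:
            pooled[key] = vals
            pooled_rec[key] = rec

    records = list(pooled_rec.values())
    counts = pd.DataFrame(
        [pooled[(r.rank, r.name, r.lineage)] for r in records] if records
        else np.empty((0, len(sample_names))),
        columns=sample_names,
    )
    dropped = pd.DataFrame([unassigned], index=["unassigned"], columns=sample_names)
    if unassigned.sum() > 0:
        logger.info("dropped %s reads from OTUs with no assignment at phylum or below", unassigned.sum())
    return ClassificationTable(records=records, counts=counts, dropped=dropped)
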