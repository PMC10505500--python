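"""Mapping classified taxa to reference-proteome taxa.

Automatic matching is exact on (rank, name) after whitespace trimming; no
fuzzy matching is attempted, because a silently wrong hit corrupts the
community composition.  The sanctioned escape hatch is the manual-mapping
ledger: an ordered, auditable list of (source rank, source name) ->
(target rank, target name) rules, each with a note saying why.  A small
default ledger ships with the package and can be replaced or extended at
call time.  Unmapped taxa are excluded from downstream aggregation (never
redistributed); count-weighted unmapped percentages make the loss visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .ingest import ClassificationTable
from .refdb import ReferenceProteomeDB

logger = logging.getLogger(__name__)

__all__ = ["MappingRule", "MappingLedger", "TaxonMapping", "map_taxa", "default_ledger"]


@dataclass(frozen=True)
class MappingRule:
    source_rank: str
    source_name: str
    target_rank: str
    target_name: str
    note: str = ""


@dataclass
class MappingLedger:
    """Ordered manual-mapping rules keyed by (source rank, source name)."""

    rules: list[MappingRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.source_rank, r.source_name) for r in self.rules]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate source (rank, name) keys in mapping ledger")

    def lookup(self, rank: str, name: str) -> MappingRule | None:
        for rule in self.rules:
            if rule.source_rank == rank and rule.source_name == name:
                return rule
        return None

    def extended(self, other: "MappingLedger") -> "MappingLedger":
        """New ledger with ``other``'s rules first (overriding same-source rules)."""
        seen = {(r.source_rank, r.source_name) for r in other.rules}
        kept = [r for r in self.rules if (r.source_rank, r.source_name) not in seen]
        return MappingLedger(rules=list(other.rules) + kept)

    @classmethod
    def from_tsv(cls, path) -> "MappingLedger":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        required = ["source_rank", "source_name", "target_rank", "target_name"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"ledger file is missing the {col!r} column")
        rules = [
            MappingRule(
                source_rank=row["source_rank"].strip(),
                source_name=row["source_name"].strip(),
                target_rank=row["target_rank"].strip(),
                target_name=row["target_name"].strip(),
                note=str(row.get("note", "")).strip(),
            )
            for _, row in df.iterrows()
        ]
        return cls(rules=rules)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "source_rank": [r.source_rank for r in self.rules],
                "source_name": [r.source_name for r in self.rules],
                "target_rank": [r.target_rank for r in self.rules],
                "target_name": [r.target_name for r in self.rules],
                "note": [r.note for r in self.rules],
            }
        ).to_csv(path, sep="\t", index=False)


def default_ledger() -> MappingLedger:
    """The packaged default manual-mapping ledger."""
    text = resources.files("commchem.data").joinpath("default_ledger.tsv").read_text("utf-8")
    return MappingLedger.from_tsv(StringIO(text))


@dataclass
class TaxonMapping:
    """Result of mapping a :class:`ClassificationTable` against a reference DB.

    ``targets`` aligns with the table's rows; ``None`` marks an unmapped row.
    Percentages are count-weighted shares of the table's total counts.
    """

    targets: list[tuple[str, str] | None]
    unmapped_percent: float
    unmapped_percent_by_sample: pd.Series
    top_unmapped: pd.DataFrame  # columns rank, name, percent; sorted descending
    rules_used: list[MappingRule] = field(default_factory=list)

    @property
    def mapped_mask(self) -> np.ndarray:
        return np.array([t is not None for t in self.targets])


def map_taxa(
    ct: ClassificationTable,
    refdb: ReferenceProteomeDB,
    ledger: MappingLedger | None = None,
    use_default_ledger: bool = True,
) -> TaxonMapping:
    """Resolve each classified taxon to a reference-proteome entry.

    For each row, an exact (rank, name) match in ``refdb`` is tried first;
    failing that, the first matching ledger rule is applied and its target
    matched (a rule whose target is absent from ``refdb`` is an error).
    Rows resolving neither way are marked unmapped and reported.
    """
    if len(refdb) == 0:
        raise ValueError("reference proteome database is empty")
    active = default_ledger() if use_default_ledger else MappingLedger()
    if ledger is not None:
        active = active.extended(ledger)

    targets: list[tuple[str, str] | None] = []
    rules_used: list[MappingRule] = []
    for rec in ct.records:
        name = rec.name.strip()
        if (rec.rank, name) in refdb:
            targets.append((rec.rank, name))
            continue
        rule = active.lookup(rec.rank, name)
        if rule is not None:
            if (rule.target_rank, rule.target_name) not in refdb:
                raise ValueError(
                    f"ledger rule ({rule.source_rank}, {rule.source_name!r}) -> "
                    f"({rule.target_rank}, {rule.target_name!r}) targets a taxon "
                    "absent from the reference database"
                )
            targets.append((rule.target_rank, rule.target_name))
            rules_used.append(rule)
            logger.info(
                "manual mapping: (%s) %s -> (%s) %s  [%s]",
                rule.source_rank, rule.source_name, rule.target_rank, rule.target_name, rule.note,
            )
            continue
        targets.append(None)

    counts = ct.counts.to_numpy(dtype=float)
    total = counts.sum()
    unmapped_rows = np.array([t is None for t in targets])
    if total > 0:
        unmapped_pct = 100.0 * counts[unmapped_rows].sum() / total
    else:
        unmapped_pct = 0.0

    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        by_sample = np.where(
            col_tot > 0, 100.0 * counts[unmapped_rows].sum(axis=0) / col_tot, 0.0
        )
    by_sample = pd.Series(by_sample, index=ct.sample_names, name="unmapped_percent")

    rows = []
    for i, rec in enumerate(ct.records):
        if unmapped_rows[i]:
            pct = 100.0 * counts[i].sum() / total if total > 0 else 0.0
            rows.append({"rank": rec.rank, "name": rec.name, "percent": pct})
    top = (
        pd.DataFrame(rows, columns=["rank", "name", "percent"])
        .sort_values("percent", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    for _, row in top.head(5).iterrows():
        logger.info("unmapped: (%s) %s — %.2f%% of reads", row["rank"], row["name"], row["percent"])
    logger.info("overall unmapped: %.2f%% of reads", unmapped_pct)

    return TaxonMapping(
        targets=targets,
        unmapped_percent=float(unmapped_pct),
        unmapped_percent_by_sample=by_sample,
        top_unmapped=top,
        rules_used=rules_used,
    )
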