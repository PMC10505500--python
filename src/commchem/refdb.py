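"""Building, reading and writing per-taxon reference proteomes.

A reference proteome is the mean amino-acid composition of one protein from
the genomes assigned to a taxon.  The builder consumes local protein FASTA
files plus GTDB-style taxonomy strings
(``d__...;p__...;c__...;o__...;f__...;g__...;s__...``); it never downloads
anything.  For each genome the mean per-protein composition is its total
residue counts divided by its protein count; for each taxon at every rank of
its lineage the composition is by default the *unweighted* mean over member
genomes' per-genome means, so heavily sequenced lineages do not dominate
(``weight_by_proteins=True`` gives the protein-count-weighted alternative).

The on-disk form is a TSV with columns ``rank, name, n_genomes, n_proteins``
followed by the 20 amino-acid columns ``Ala..Val``; it round-trips
losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chem import AminoAcidComposition, UnknownAminoAcidError, canonical_aa
from .constants import AA_CODES

__all__ = [
    "GTDB_RANK_PREFIXES",
    "RefEntry",
    "ReferenceProteomeDB",
    "count_fasta_proteins",
    "parse_gtdb_taxonomy",
    "build_reference_proteomes",
    "read_refdb",
    "write_refdb",
]

#: GTDB rank prefixes in lineage order.
GTDB_RANK_PREFIXES: tuple[tuple[str, str], ...] = (
    ("d__", "domain"),
    ("p__", "phylum"),
    ("c__", "class"),
    ("o__", "order"),
    ("f__", "family"),
    ("g__", "genus"),
    ("s__", "species"),
)


@dataclass
class RefEntry:
    """Mean per-protein composition of one taxon, with provenance."""

    composition: AminoAcidComposition  # chains = 1 (per-protein mean)
    n_genomes: int
    n_proteins: int

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")


@dataclass
class ReferenceProteomeDB:
    """Per-(rank, name) reference proteome compositions."""

    entries: dict[tuple[str, str], RefEntry] = field(default_factory=dict)
    source: str = ""
    version: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries

    def __getitem__(self, key: tuple[str, str]) -> RefEntry:
        return self.entries[key]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries)

    def taxa_at_rank(self, rank: str) -> list[str]:
        return [name for (r, name) in self.entries if r == rank]


def count_fasta_proteins(path) -> tuple[AminoAcidComposition, int]:
    """Sum residue counts over all records of a protein FASTA.

    Returns the total composition (``chains`` = number of records) and the
    record count.  Non-standard residues (B, Z, X, U, ...) are rejected with
    the record and character named: reference compositions are curated, and
    silently dropping residues would bias the metrics.
    """
    counts: dict[str, float] = {}
    n_proteins = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_proteins += 1
        for ch in str(record.seq):
            try:
                code3 = canonical_aa(ch)
            except UnknownAminoAcidError:
                raise UnknownAminoAcidError(
                    f"non-standard residue {ch!r} in record {record.id!r} of {path}"
                ) from None
            counts[code3] = counts.get(code3, 0.0) + 1.0
    if n_proteins == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return AminoAcidComposition(counts=counts, chains=float(n_proteins)), n_proteins


def parse_gtdb_taxonomy(taxonomy: str) -> list[tuple[str, str]]:
    """Parse a GTDB taxonomy string into (rank, name) pairs.

    Empty rank fields (e.g. a trailing ``s__``) are skipped, not treated as
    names; an unrecognized prefix is an error.
    """
    prefix_map = dict(GTDB_RANK_PREFIXES)
    pairs: list[tuple[str, str]] = []
    for part in taxonomy.split(";"):
        part = part.strip()
        if not part:
            continue
        prefix = part[:3]
        if prefix not in prefix_map:
            raise ValueError(f"unknown rank prefix in taxonomy string: {part!r}")
        name = part[3:].strip()
        if name:
            pairs.append((prefix_map[prefix], name))
    if not pairs:
        raise ValueError(f"taxonomy string has no named ranks: {taxonomy!r}")
    return pairs


def build_reference_proteomes(
    genomes: Sequence[tuple[str, str, str]],
    weight_by_proteins: bool = False,
    source: str = "",
    version: str = "",
) -> ReferenceProteomeDB:
    """Aggregate (genome id, protein FASTA path, taxonomy string) triples.

    Each genome contributes its mean per-protein composition to every rank
    of its lineage.  With the default unweighted mean, a genus's composition
    is the plain average over its genomes' means regardless of how many
    proteins each genome has.
    """
    if not genomes:
        raise ValueError("at least one genome is required")

    per_genome: list[tuple[np.ndarray, int, list[tuple[str, str]]]] = []
    for genome_id, fasta_path, taxonomy in genomes:
        total, n_proteins = count_fasta_proteins(fasta_path)
        if total.total <= 0:
            raise ValueError(f"genome {genome_id!r} has no residues")
        mean_vec = total.as_vector() / n_proteins
        per_genome.append((mean_vec, n_proteins, parse_gtdb_taxonomy(taxonomy)))

    members: dict[tuple[str, str], list[tuple[np.ndarray, int]]] = {}
    for mean_vec, n_proteins, lineage in per_genome:
        for rank, name in lineage:
            members.setdefault((rank, name), []).append((mean_vec, n_proteins))

    db = ReferenceProteomeDB(source=source, version=version)
    for key in sorted(members):
        vecs = np.array([v for v, _ in members[key]])
        nprot = np.array([n for _, n in members[key]], dtype=float)
        if weight_by_proteins:
            mean = (vecs * nprot[:, None]).sum(axis=0) / nprot.sum()
        else:
            mean = vecs.mean(axis=0)
        comp = AminoAcidComposition(
            counts={code: float(v) for code, v in zip(AA_CODES, mean) if v > 0}, chains=1.0
        )
        db.entries[key] = RefEntry(
            composition=comp, n_genomes=len(members[key]), n_proteins=int(nprot.sum())
        )
    return db


_META_COLUMNS = ["rank", "name", "n_genomes", "n_proteins"]


def write_refdb(db: ReferenceProteomeDB, path) -> None:
    """Write a reference database to its TSV form (columns rank, name,
    n_genomes, n_proteins, Ala..Val)."""
    rows = []
    for (rank, name), entry in db.entries.items():
        row = {"rank": rank, "name": name,
               "n_genomes": entry.n_genomes, "n_proteins": entry.n_proteins}
        vec = entry.composition.as_vector()
        row.update({code: float(v) for code, v in zip(AA_CODES, vec)})
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLUMNS + list(AA_CODES)).to_csv(
        path, sep="\t", index=False
    )


def read_refdb(path, source: str = "", version: str = "") -> ReferenceProteomeDB:
    """Read a reference database TSV; strict about layout.

    Missing amino-acid columns, unknown columns and duplicate (rank, name)
    rows are all errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rank": str, "name": str})
    expected = _META_COLUMNS + list(AA_CODES)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"reference database file is missing columns: {missing}")
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(f"reference database file has unknown columns: {unknown}")

    db = ReferenceProteomeDB(source=source, version=version)
    for _, row in df.iterrows():
        key = (row["rank"], row["name"])
        if key in db.entries:
            raise ValueError(f"duplicate (rank, name) entry: {key}")
        comp = AminoAcidComposition(
            counts={code: float(row[code]) for code in AA_CODES if float(row[code]) > 0},
            chains=1.0,
        )
        db.entries[key] = RefEntry(
            composition=comp,
            n_genomes=int(row["n_genomes"]),
            n_proteins=int(row["n_proteins"]),
        )
    return db
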