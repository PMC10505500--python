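"""Deterministic synthetic fixtures with known ground truth.

Generators for toy reference databases, RDP-style hierarchical count files
and OTU/taxonomy tables, so the full pipeline can be exercised and audited
with no downloads.  Ground truth (expected lowest-level counts, unmapped
percentage, per-sample metrics) is computed *by construction* inside the
generator — the metric values come from :func:`independent_metrics`, a
straight-line array recomputation that shares only the constants tables
with the main chemistry code, never its functions.

Compositions are Dirichlet(1)-random over the 20 amino acids at mean
protein length 300, which spans a realistic Zc range (about -0.3 to 0)
without encoding any real taxon; abundances are log-normal.  No sequencing
or classifier error is simulated: a read's taxon in the fixture is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import AminoAcidComposition
from .constants import AMINO_ACIDS, AA_CODES
from .refdb import RefEntry, ReferenceProteomeDB

__all__ = [
    "FixtureBundle",
    "make_refdb",
    "make_rdp_fixture",
    "independent_metrics",
    "write_bundle",
]

# element matrices straight from the constants table (free formulas; the
# residue is the free amino acid minus one water)
_E_FREE = AMINO_ACIDS[["c", "h", "n", "o", "s"]].to_numpy(dtype=float)  # 20 x CHNOS
_WATER = np.array([0.0, 2.0, 0.0, 1.0, 0.0])
_E_RESIDUE = _E_FREE - _WATER
_ROW = {code: i for i, code in enumerate(AA_CODES)}
# basis columns: glutamine, glutamic acid, cysteine, water, dioxygen
_BASIS = np.column_stack(
    [
        _E_FREE[_ROW["Gln"]],
        _E_FREE[_ROW["Glu"]],
        _E_FREE[_ROW["Cys"]],
        _WATER,
        np.array([0.0, 0.0, 0.0, 2.0, 0.0]),
    ]
)


def independent_metrics(counts_vector: np.ndarray) -> dict[str, float]:
    """Zc, nO2, nH2O for a 20-amino-acid count vector, by direct arithmetic.

    Used for fixture ground truth: residue element totals are a matrix
    product, Zc is the formal-oxidation-state formula, and the basis
    coefficients come from one ``numpy.linalg.solve`` call.
    """
    vec = np.asarray(counts_vector, dtype=float)
    c, h, n, o, s = vec @ _E_RESIDUE
    coeffs = np.linalg.solve(_BASIS, vec @ _E_RESIDUE)
    nres = vec.sum()
    return {
        "Zc": (-h + 3 * n + 2 * o + 2 * s) / c,
        "nO2": coeffs[4] / nres,
        "nH2O": coeffs[3] / nres,
    }


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    ideal = weights / weights.sum() * total
    base = np.floor(ideal).astype(int)
    short = total - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    base[order[:short]] += 1
    return base


def make_refdb(seed: int, n_phyla: int = 3, genera_per_phylum: int = 4) -> ReferenceProteomeDB:
    """Toy reference database: ``n_phyla`` phyla of ``genera_per_phylum`` genera.

    Genus compositions are Dirichlet(1)-random scaled to a mean length of
    300 residues; each phylum entry is the unweighted mean of its genera,
    mirroring the builder's aggregation rule.
    """
    if n_phyla < 1 or genera_per_phylum < 1:
        raise ValueError("n_phyla and genera_per_phylum must be >= 1")
    rng = np.random.default_rng(seed)
    db = ReferenceProteomeDB(source="synthetic", version=f"seed={seed}")
    for p in range(n_phyla):
        genus_vecs = []
        n_prot_sum = 0
        for g in range(genera_per_phylum):
            freqs = rng.dirichlet(np.ones(20))
            length = max(50.0, rng.normal(300.0, 30.0))
            vec = freqs * length
            n_prot = int(rng.integers(500, 3000))
            n_prot_sum += n_prot
            genus_vecs.append(vec)
            db.entries[("genus", f"Genus_{p}_{g}")] = RefEntry(
                composition=AminoAcidComposition(dict(zip(AA_CODES, vec))),
                n_genomes=1,
                n_proteins=n_prot,
            )
        phylum_vec = np.mean(genus_vecs, axis=0)
        db.entries[("phylum", f"Phylum_{p}")] = RefEntry(
            composition=AminoAcidComposition(dict(zip(AA_CODES, phylum_vec))),
            n_genomes=genera_per_phylum,
            n_proteins=n_prot_sum,
        )
    return db


@dataclass
class FixtureBundle:
    """A complete synthetic test scenario with ground truth by construction."""

    refdb: ReferenceProteomeDB
    rdp_text: str
    otu_counts: pd.DataFrame  # ASV x sample
    taxonomy: pd.DataFrame  # ASV x rank
    expected_counts: pd.DataFrame  # columns rank, name, then samples
    expected_unmapped_percent: float
    expected_unmapped_by_sample: pd.Series
    expected_metrics: pd.DataFrame  # sample x (Zc, nO2, nH2O)
    expected_filtered: pd.Series
    expected_unassigned: pd.Series


def make_rdp_fixture(
    refdb: ReferenceProteomeDB,
    n_samples: int = 4,
    seed: int = 0,
    unmapped_fraction: float = 0.0,
    filtered_fraction: float = 0.0,
    total_per_sample: int = 1000,
    phylum_residual_fraction: float = 0.1,
) -> FixtureBundle:
    """Emit an RDP hierarchy file + OTU tables whose truth is known exactly.

    Per sample, ``total_per_sample`` reads are split into: a Chloroplast
    branch (``filtered_fraction``), a genus absent from the reference
    database (``unmapped_fraction`` of the remainder), reads classified
    only to phylum level (``phylum_residual_fraction`` of the mapped part),
    and genus-level reads allocated log-normally across the database's
    genera.  The OTU-table variant carries the same reads, with the
    filtered branch replaced by taxonomically unassigned ASVs.
    """
    if not 0 <= unmapped_fraction < 1 or not 0 <= filtered_fraction < 1:
        raise ValueError("fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genera = sorted(refdb.taxa_at_rank("genus"))
    phyla = sorted(refdb.taxa_at_rank("phylum"))
    if not genera or not phyla:
        raise ValueError("refdb must contain genus- and phylum-rank entries")
    phylum_of = {g: f"Phylum_{g.split('_')[1]}" for g in genera}
    samples = [f"sample{j + 1}" for j in range(n_samples)]

    genus_counts = np.zeros((len(genera), n_samples), dtype=int)
    resid_counts = np.zeros((len(phyla), n_samples), dtype=int)
    unmapped_counts = np.zeros(n_samples, dtype=int)
    filtered_counts = np.zeros(n_samples, dtype=int)
    for j in range(n_samples):
        filtered_counts[j] = int(round(filtered_fraction * total_per_sample))
        rest = total_per_sample - filtered_counts[j]
        unmapped_counts[j] = int(round(unmapped_fraction * rest))
        mapped = rest - unmapped_counts[j]
        resid_total = int(round(phylum_residual_fraction * mapped))
        genus_counts[:, j] = _largest_remainder(
            rng.lognormal(0.0, 1.0, len(genera)), mapped - resid_total
        )
        resid_counts[:, j] = _largest_remainder(
            rng.lognormal(0.0, 1.0, len(phyla)), resid_total
        )

    # --- RDP hierarchical file (cumulative counts) ---
    unmapped_name = "Unmappedium"
    lines = ["taxid\tlineage\tname\trank\t" + "\t".join(samples)]
    taxid = 0

    def add(lineage_pairs, counts_row):
        nonlocal taxid
        taxid += 1
        lineage = ";".join(f"{name};{rank}" for rank, name in lineage_pairs)
        rank, name = lineage_pairs[-1]
        lines.append(
            f"{taxid}\t{lineage}\t{name}\t{rank}\t" + "\t".join(str(int(v)) for v in counts_row)
        )

    root = [("rootrank", "Root")]
    bact = root + [("domain", "Bacteria")]
    total_row = np.full(n_samples, total_per_sample, dtype=int)
    add(root, total_row)
    add(bact, total_row - 0)  # everything sits under Bacteria
    for p, phylum in enumerate(phyla):
        idx = [i for i, g in enumerate(genera) if phylum_of[g] == phylum]
        cum = genus_counts[idx].sum(axis=0) + resid_counts[p]
        if p == 0:
            cum = cum + unmapped_counts
        add(bact + [("phylum", phylum)], cum)
        for i in idx:
            add(bact + [("phylum", phylum), ("genus", genera[i])], genus_counts[i])
        if p == 0 and unmapped_counts.sum() > 0:
            add(bact + [("phylum", phylum), ("genus", unmapped_name)], unmapped_counts)
    if filtered_counts.sum() > 0:
        chloro = bact + [("phylum", "Cyanobacteriota"), ("class", "Chloroplast")]
        add(chloro[:-1], filtered_counts)
        add(chloro, filtered_counts)
    rdp_text = "\n".join(lines) + "\n"

    # --- OTU/taxonomy tables carrying the same reads ---
    otu_rows: dict[str, np.ndarray] = {}
    tax_rows: dict[str, dict[str, str]] = {}
    rank_cols = ["domain", "phylum", "class", "order", "family", "genus", "species"]
    for i, g in enumerate(genera):
        half = genus_counts[i] // 2
        for k, part in enumerate((half, genus_counts[i] - half)):
            asv = f"ASV_{g}_{k}"
            otu_rows[asv] = part
            tax_rows[asv] = {"domain": "Bacteria", "phylum": phylum_of[g], "genus": g}
    for p, phylum in enumerate(phyla):
        asv = f"ASV_{phylum}_resid"
        otu_rows[asv] = resid_counts[p]
        tax_rows[asv] = {"domain": "Bacteria", "phylum": phylum}
    if unmapped_counts.sum() > 0:
        otu_rows["ASV_unmapped"] = unmapped_counts
        tax_rows["ASV_unmapped"] = {"domain": "Bacteria", "phylum": phyla[0], "genus": unmapped_name}
    if filtered_counts.sum() > 0:
        otu_rows["ASV_unassigned"] = filtered_counts
        tax_rows["ASV_unassigned"] = {}
    otu_counts = pd.DataFrame.from_dict(otu_rows, orient="index", columns=samples)
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index").reindex(
        columns=rank_cols, index=otu_counts.index
    ).fillna("")

    # --- ground truth by construction ---
    exp_rows = []
    for i, g in enumerate(genera):
        if genus_counts[i].sum() > 0:
            exp_rows.append({"rank": "genus", "name": g,
                             **dict(zip(samples, genus_counts[i]))})
    for p, phylum in enumerate(phyla):
        if resid_counts[p].sum() > 0:
            exp_rows.append({"rank": "phylum", "name": phylum,
                             **dict(zip(samples, resid_counts[p]))})
    if unmapped_counts.sum() > 0:
        exp_rows.append({"rank": "genus", "name": unmapped_name,
                         **dict(zip(samples, unmapped_counts))})
    expected_counts = pd.DataFrame(exp_rows, columns=["rank", "name"] + samples)

    retained = genus_counts.sum() + resid_counts.sum() + unmapped_counts.sum()
    exp_unmapped = 100.0 * unmapped_counts.sum() / retained if retained else 0.0
    per_sample_tot = genus_counts.sum(axis=0) + resid_counts.sum(axis=0) + unmapped_counts
    exp_unmapped_by_sample = pd.Series(
        np.where(per_sample_tot > 0, 100.0 * unmapped_counts / per_sample_tot, 0.0),
        index=samples,
    )

    genus_vecs = np.array([refdb[("genus", g)].composition.as_vector() for g in genera])
    phylum_vecs = np.array([refdb[("phylum", p)].composition.as_vector() for p in phyla])
    metric_rows = {}
    for j, sample in enumerate(samples):
        w_total = genus_counts[:, j].sum() + resid_counts[:, j].sum()
        community = (
            genus_counts[:, j] @ genus_vecs + resid_counts[:, j] @ phylum_vecs
        ) / w_total
        metric_rows[sample] = independent_metrics(community)
    expected_metrics = pd.DataFrame.from_dict(metric_rows, orient="index")
    expected_metrics.index.name = "sample"

    return FixtureBundle(
        refdb=refdb,
        rdp_text=rdp_text,
        otu_counts=otu_counts,
        taxonomy=taxonomy,
        expected_counts=expected_counts,
        expected_unmapped_percent=float(exp_unmapped),
        expected_unmapped_by_sample=exp_unmapped_by_sample,
        expected_metrics=expected_metrics,
        expected_filtered=pd.Series(filtered_counts, index=samples, dtype=float),
        expected_unassigned=pd.Series(filtered_counts, index=samples, dtype=float),
    )


def write_bundle(bundle: FixtureBundle, outdir) -> dict[str, Path]:
    """Write a fixture bundle to TSV files; returns the paths written."""
    from .refdb import write_refdb

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "refdb": outdir / "refdb.tsv",
        "rdp": outdir / "rdp.tsv",
        "otu": outdir / "otu_counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "expected_counts": outdir / "expected_counts.tsv",
        "expected_metrics": outdir / "expected_metrics.tsv",
    }
    write_refdb(bundle.refdb, paths["refdb"])
    paths["rdp"].write_text(bundle.rdp_text, encoding="utf-8")
    bundle.otu_counts.to_csv(paths["otu"], sep="\t", index_label="otu")
    bundle.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="otu")
    bundle.expected_counts.to_csv(paths["expected_counts"], sep="\t", index=False)
    bundle.expected_metrics.to_csv(paths["expected_metrics"], sep="\t")
    return paths
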