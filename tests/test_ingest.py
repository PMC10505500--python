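"""Tests for RDP hierarchy parsing and OTU/taxonomy pooling."""

import io

import numpy as np
import pandas as pd
import pytest

from commchem.ingest import (
    ClassificationTable,
    MalformedHierarchyError,
    TaxonRecord,
    read_rdp_hierarchy,
    taxa_counts_from_tables,
)


def rdp_file(rows, samples=("s1",)):
    header = "taxid\tlineage\tname\trank\t" + "\t".join(samples)
    lines = [header]
    for i, (lineage, counts) in enumerate(rows):
        pairs = lineage.split(";")
        name, rank = pairs[-2], pairs[-1]
        counts = counts if isinstance(counts, (list, tuple)) else [counts]
        lines.append(f"{i}\t{lineage}\t{name}\t{rank}\t" + "\t".join(map(str, counts)))
    return io.StringIO("\n".join(lines) + "\n")


TOY = [
    ("Root;rootrank", 10),
    ("Root;rootrank;Bacteria;domain", 10),
    ("Root;rootrank;Bacteria;domain;Proteobacteria;phylum", 8),
    ("Root;rootrank;Bacteria;domain;Proteobacteria;phylum;Gammaproteobacteria;class", 6),
    ("Root;rootrank;Bacteria;domain;Proteobacteria;phylum;Gammaproteobacteria;class;Escherichia;genus", 5),
]


class TestReadRdp:
    def test_lowest_level_decomposition(self):
        ct = read_rdp_hierarchy(rdp_file(TOY))
        got = {(r.rank, r.name): ct.counts.iloc[i, 0] for i, r in enumerate(ct.records)}
        assert got == {
            ("genus", "Escherichia"): 5,
            ("class", "Gammaproteobacteria"): 1,
            ("phylum", "Proteobacteria"): 2,
        }
        # Bacteria's residual 2 is dropped as domain-level
        assert ct.dropped.loc["domain-level", "s1"] == 2
        assert ct.dropped.loc["filtered", "s1"] == 0

    def test_chloroplast_lineage_removed(self):
        rows = TOY + [
            ("Root;rootrank;Bacteria;domain;Cyanobacteria;phylum", 3),
            ("Root;rootrank;Bacteria;domain;Cyanobacteria;phylum;Chloroplast;class", 3),
        ]
        rows[0] = ("Root;rootrank", 13)
        rows[1] = ("Root;rootrank;Bacteria;domain", 13)
        ct = read_rdp_hierarchy(rdp_file(rows))
        names = {r.name for r in ct.records}
        assert "Chloroplast" not in names and "Cyanobacteria" not in names
        assert ct.dropped.loc["filtered", "s1"] == 3

    def test_empty_sample_column_retained(self):
        rows = [(lineage, [c, 0]) for lineage, c in TOY]
        ct = read_rdp_hierarchy(rdp_file(rows, samples=("s1", "s2")))
        assert ct.sample_names == ["s1", "s2"]
        assert (ct.counts["s2"] == 0).all()

    def test_child_exceeding_parent_is_an_error(self):
        rows = list(TOY)
        rows[4] = (rows[4][0], 7)  # genus 7 > class 6
        with pytest.raises(MalformedHierarchyError, match="Gammaproteobacteria"):
            read_rdp_hierarchy(rdp_file(rows))

    def test_unknown_rank_label_rejected(self):
        rows = [("Root;rootrank", 1), ("Root;rootrank;Bacteria;kingdom", 1)]
        with pytest.raises(ValueError, match="kingdom"):
            read_rdp_hierarchy(rdp_file(rows))

    def test_missing_parent_rejected(self):
        rows = [
            ("Root;rootrank", 5),
            ("Root;rootrank;Bacteria;domain;Proteobacteria;phylum", 5),
        ]
        with pytest.raises(MalformedHierarchyError, match="no parent"):
            read_rdp_hierarchy(rdp_file(rows))

    def test_species_collapsed_into_genus_by_default(self):
        rows = TOY + [
            (TOY[4][0] + ";Escherichia coli;species", 4),
        ]
        ct = read_rdp_hierarchy(rdp_file(rows))
        got = {(r.rank, r.name): ct.counts.iloc[i, 0] for i, r in enumerate(ct.records)}
        assert got[("genus", "Escherichia")] == 5  # species reads stay in the genus
        ct2 = read_rdp_hierarchy(rdp_file(rows), keep_species=True)
        got2 = {(r.rank, r.name): ct2.counts.iloc[i, 0] for i, r in enumerate(ct2.records)}
        assert got2[("species", "Escherichia coli")] == 4
        assert got2[("genus", "Escherichia")] == 1

    def test_count_conservation_on_fixture(self, bundle):
        ct = read_rdp_hierarchy(io.StringIO(bundle.rdp_text))
        total = ct.counts.sum(axis=0) + ct.dropped.sum(axis=0)
        assert np.allclose(total, 1000)

    def test_expected_lowest_level_counts_on_fixture(self, bundle):
        ct = read_rdp_hierarchy(io.StringIO(bundle.rdp_text))
        got = pd.DataFrame(
            {
                "rank": [r.rank for r in ct.records],
                "name": [r.name for r in ct.records],
                **{s: ct.counts[s].to_numpy() for s in ct.sample_names},
            }
        )
        key = ["rank", "name"]
        merged = got.set_index(key).sort_index()
        expected = bundle.expected_counts.set_index(key).sort_index()
        pd.testing.assert_frame_equal(merged, expected, check_dtype=False)


class TestRoundTrip:
    def test_tsv_round_trip(self, tmp_path, bundle):
        ct = read_rdp_hierarchy(io.StringIO(bundle.rdp_text))
        path = tmp_path / "ct.tsv"
        ct.to_tsv(path)
        back = ClassificationTable.from_tsv(path)
        assert back.records == ct.records
        pd.testing.assert_frame_equal(back.counts, ct.counts, check_dtype=False)

    def test_pooling_is_idempotent(self, classification):
        once = classification.pooled()
        twice = once.pooled()
        assert once.records == twice.records
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestTaxaCountsFromTables:
    def make_tables(self):
        otu = pd.DataFrame({"s1": [5, 3, 2, 4, 1]}, index=[f"asv{i}" for i in range(5)])
        tax = pd.DataFrame(
            {
                "domain": ["Bacteria"] * 4 + [""],
                "phylum": ["Bacteroidota"] * 3 + ["Firmicutes", ""],
                "family": ["Muribaculaceae"] * 3 + ["", ""],
                "genus": ["Muribaculum"] * 3 + ["", ""],
            },
            index=otu.index,
        )
        return otu, tax

    def test_pooling_and_lowest_rank(self):
        otu, tax = self.make_tables()
        ct = taxa_counts_from_tables(otu, tax)
        got = {(r.rank, r.name): ct.counts.iloc[i, 0] for i, r in enumerate(ct.records)}
        assert got == {("genus", "Muribaculum"): 10, ("phylum", "Firmicutes"): 4}
        assert ct.dropped.loc["unassigned", "s1"] == 1

    def test_deepest_filled_rank_wins(self):
        otu = pd.DataFrame({"s1": [2]}, index=["a"])
        tax = pd.DataFrame(
            {"phylum": ["P"], "class": [""], "family": ["F"], "genus": [""]}, index=["a"]
        )
        ct = taxa_counts_from_tables(otu, tax)
        assert ct.records[0].rank == "family"
        assert ct.records[0].lineage == (("phylum", "P"), ("family", "F"))

    def test_disjoint_identifiers_rejected(self):
        otu, tax = self.make_tables()
        tax.index = [f"other{i}" for i in range(5)]
        with pytest.raises(ValueError, match="share no row identifiers"):
            taxa_counts_from_tables(otu, tax)

    def test_negative_counts_rejected(self):
        otu, tax = self.make_tables()
        otu.iloc[0, 0] = -1
        with pytest.raises(ValueError, match="non-negative"):
            taxa_counts_from_tables(otu, tax)

    def test_matches_rdp_route_on_fixture(self, bundle):
        ct = taxa_counts_from_tables(bundle.otu_counts, bundle.taxonomy)
        got = pd.DataFrame(
            {
                "rank": [r.rank for r in ct.records],
                "name": [r.name for r in ct.records],
                **{s: ct.counts[s].to_numpy() for s in ct.sample_names},
            }
        ).set_index(["rank", "name"]).sort_index()
        expected = bundle.expected_counts.set_index(["rank", "name"]).sort_index()
        pd.testing.assert_frame_equal(got, expected, check_dtype=False)
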