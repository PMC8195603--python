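"""Genome model: readers, writers, invariants of the annotation dialect."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextscan.genome_model import (
    AnnotationError,
    Gene,
    Genome,
    Protein,
    TaxonRecord,
    intergenic_gap,
    read_annotation_table,
    read_genbank,
    write_annotation_table,
)
from contextscan.synthetic_data import SyntheticConfig, generate_genomes

from conftest import make_genome


class TestTypes:
    def test_tri_state_flag_is_never_a_plain_boolean_coercion(self):
        t = TaxonRecord("t1", "t1", "Cyanobacteriota", None)
        assert t.multicellular is None
        assert TaxonRecord("t1", "t1", "P", True).multicellular is True

    def test_phylum_must_be_non_empty(self):
        with pytest.raises(ValueError):
            TaxonRecord("t1", "t1", "")

    def test_gene_coordinate_invariants(self):
        with pytest.raises(ValueError):
            Gene("g", "chr", 400, 100, "+")
        with pytest.raises(ValueError):
            Gene("g", "chr", 0, 10, "+")
        with pytest.raises(ValueError):
            Gene("g", "chr", 1, 10, "?")

    def test_intergenic_gap_is_negative_for_overlaps(self):
        a = Gene("a", "chr", 100, 400, "+")
        b = Gene("b", "chr", 390, 600, "+")
        assert intergenic_gap(a, b) == -11
        c = Gene("c", "chr", 451, 600, "+")
        assert intergenic_gap(a, c) == 50

    def test_protein_rejects_bad_alphabet_and_plus_in_domain(self):
        with pytest.raises(ValueError):
            Protein("p", "MAJ")
        with pytest.raises(ValueError):
            Protein("p", "MA", ("Tir+Cas",))

    def test_genome_sorts_genes_and_flags_overlaps(self):
        g = make_genome(
            "t1", "P",
            [("g2", 500, 900, "+", "MA", ()), ("g1", 100, 600, "+", "MK", ())],
        )
        assert [x.gene_id for x in g.genes] == ["g1", "g2"]
        assert g.overlapping_gene_ids() == [("g1", "g2")]

    def test_unresolved_protein_id_is_an_error(self):
        with pytest.raises(AnnotationError):
            Genome(
                taxon=TaxonRecord("t", "t", "P"),
                genes=[Gene("g", "chr", 1, 9, "+", "nope")],
                proteins={},
            )


class TestAnnotationTable:
    def test_round_trip_is_lossless(self, tmp_path):
        g = make_genome(
            "t1", "Cyanobacteriota",
            [
                ("g1", 100, 400, "+", "MAK", ("TIR", "Caspase")),
                ("g2", 450, 800, "-", "MKW", ()),
            ],
            multicellular=True,
        )
        path = tmp_path / "g.tsv"
        write_annotation_table(g, path)
        back = read_annotation_table(path)
        assert back.taxon == g.taxon
        assert back.genes == g.genes
        assert back.proteins == g.proteins

    def test_round_trip_on_generator_output(self, tmp_path):
        genomes, _ = generate_genomes(
            SyntheticConfig(n_taxa=3, carriers_per_cassette=2, phyla_per_cassette=2,
                            n_decoy_anchors=2, seed=7)
        )
        for g in genomes:
            path = tmp_path / f"{g.taxon.taxon_id}.tsv"
            write_annotation_table(g, path)
            back = read_annotation_table(path)
            assert back.taxon == g.taxon
            assert back.genes == g.genes
            assert back.proteins == g.proteins

    def test_architecture_and_tri_state_parsing(self, tmp_path):
        rows = [
            "\t".join(
                "taxon_id phylum multicellular replicon_id gene_id start end "
                "strand protein_id architecture".split()
            ),
            "t1\tCyanobacteriota\ttrue\tchr\tg1\t100\t400\t+\tp1\tTIR+Caspase",
            "t1\tCyanobacteriota\ttrue\tchr\tg2\t500\t700\t-\tp2\t",
        ]
        path = tmp_path / "t1.tsv"
        path.write_text("\n".join(rows) + "\n")
        g = read_annotation_table(path)
        assert g.proteins["p1"].architecture == ("TIR", "Caspase")
        assert g.proteins["p2"].architecture == ()
        assert g.taxon.multicellular is True

    def test_na_flag_round_trips_as_unknown(self, tmp_path):
        g = make_genome("t1", "P", [("g1", 1, 9, "+", "MA", ())], multicellular=None)
        path = tmp_path / "g.tsv"
        write_annotation_table(g, path)
        assert "NA" in path.read_text()
        assert read_annotation_table(path).taxon.multicellular is None

    def test_empty_genome_writes_header_only(self, tmp_path):
        g = Genome(taxon=TaxonRecord("t1", "t1", "P"))
        path = tmp_path / "g.tsv"
        write_annotation_table(g, path)
        assert len(path.read_text().splitlines()) == 1

    @pytest.mark.parametrize(
        "bad_row",
        [
            "t1\tP\ttrue\tchr\tg1\t100\t400\t*\tp1\t",  # strand
            "t1\tP\ttrue\tchr\tg1\t400\t100\t+\tp1\t",  # end < start
        ],
    )
    def test_malformed_rows_error_with_row_number(self, tmp_path, bad_row):
        header = "\t".join(
            "taxon_id phylum multicellular replicon_id gene_id start end "
            "strand protein_id architecture".split()
        )
        path = tmp_path / "bad.tsv"
        path.write_text(header + "\n" + bad_row + "\n")
        with pytest.raises(AnnotationError, match=":2"):
            read_annotation_table(path)

    def test_duplicate_gene_id_errors(self, tmp_path):
        header = "\t".join(
            "taxon_id phylum multicellular replicon_id gene_id start end "
            "strand protein_id architecture".split()
        )
        row = "t1\tP\ttrue\tchr\tg1\t100\t400\t+\tp1\t"
        row2 = "t1\tP\ttrue\tchr\tg1\t500\t600\t+\tp2\t"
        path = tmp_path / "dup.tsv"
        path.write_text(header + "\n" + row + "\n" + row2 + "\n")
        with pytest.raises(AnnotationError, match="duplicate"):
            read_annotation_table(path)


class TestGenBank:
    def test_two_cds_record_maps_fields_directly(self, genbank_two_cds):
        g = read_genbank(genbank_two_cds)
        assert len(g.genes) == 2
        g1, g2 = g.genes
        assert (g1.start, g1.end, g1.strand) == (100, 399, "+")
        assert (g2.start, g2.end, g2.strand) == (500, 799, "-")
        assert g.proteins["p1"].sequence.startswith("MA")
        assert g.taxon.taxon_id == "t900"
        assert g.taxon.phylum == "Cyanobacteriota"
        assert g.taxon.multicellular is None

    def test_zero_cds_gives_empty_gene_list(self, genbank_no_cds):
        g = read_genbank(genbank_no_cds)
        assert g.genes == []

    def test_matches_paired_annotation_table(self, genbank_two_cds, paired_annotation_tsv):
        from_gb = read_genbank(genbank_two_cds)
        from_tsv = read_annotation_table(paired_annotation_tsv)
        assert from_gb.genes == from_tsv.genes
        assert from_gb.proteins == from_tsv.proteins
        for attr in ("taxon_id", "phylum", "multicellular"):
            assert getattr(from_gb.taxon, attr) == getattr(from_tsv.taxon, attr)

    def test_malformed_file_raises_annotation_error(self, tmp_path):
        path = tmp_path / "broken.gbk"
        path.write_text("LOCUS broken\nFEATURES\n")
        with pytest.raises(AnnotationError):
            read_genbank(path)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    starts=st.lists(st.integers(min_value=1, max_value=10_000), min_size=1,
                    max_size=12, unique=True)
)
def test_genes_always_reported_sorted_by_start(starts):
    """Gene order out of Genome is (replicon, start) regardless of input order."""
    genes = [
        (f"g{i}", s, s + 5, "+", None, ()) for i, s in enumerate(starts)
    ]
    g = make_genome("t1", "P", genes)
    out = [x.start for x in g.genes]
    assert out == sorted(out)
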