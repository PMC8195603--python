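"""Shared fixtures: toy genomes, a GenBank text record and its TSV twin."""

from __future__ import annotations

import textwrap

import pytest

from contextscan.genome_model import Gene, Genome, Protein, TaxonRecord


def make_genome(
    taxon_id: str,
    phylum: str,
    genes: list[tuple],
    multicellular=None,
    replicon: str = "chr",
) -> Genome:
    """Build a genome from (gene_id, start, end, strand, sequence, architecture)
    tuples; sequence/architecture may be None/()."""
    gene_objs = []
    proteins = {}
    for gid, start, end, strand, seq, arch in genes:
        pid = f"{gid}_p"
        gene_objs.append(Gene(gid, replicon, start, end, strand, pid))
        proteins[pid] = Protein(pid, seq, tuple(arch))
    taxon = TaxonRecord(taxon_id, taxon_id, phylum, multicellular)
    return Genome(taxon=taxon, genes=gene_objs, proteins=proteins)


GENBANK_TWO_CDS = textwrap.dedent(
    """\
    LOCUS       CHR1                 1200 bp    DNA     linear   BCT 01-JAN-2020
    DEFINITION  Synthetica t900 chromosome.
    ACCESSION   CHR1
    VERSION     CHR1.1
    SOURCE      Synthetica t900
      ORGANISM  Synthetica t900
                Bacteria; Cyanobacteriota; Synthetica.
    FEATURES             Location/Qualifiers
         source          1..1200
                         /organism="Synthetica t900"
                         /db_xref="taxon:t900"
         CDS             100..399
                         /locus_tag="g1"
                         /protein_id="p1"
                         /translation="{p1}"
         CDS             complement(500..799)
                         /locus_tag="g2"
                         /protein_id="p2"
                         /translation="{p2}"
    ORIGIN
    //
    """
).format(p1="M" + "A" * 98, p2="M" + "K" * 98)


GENBANK_NO_CDS = textwrap.dedent(
    """\
    LOCUS       CHR2                  500 bp    DNA     linear   BCT 01-JAN-2020
    DEFINITION  Synthetica t901, no annotated CDS.
    ACCESSION   CHR2
    VERSION     CHR2.1
    SOURCE      Synthetica t901
      ORGANISM  Synthetica t901
                Bacteria; Bacillota.
    FEATURES             Location/Qualifiers
         source          1..500
                         /organism="Synthetica t901"
    ORIGIN
    //
    """
)


@pytest.fixture
def genbank_two_cds(tmp_path):
    path = tmp_path / "two_cds.gbk"
    path.write_text(GENBANK_TWO_CDS, encoding="utf-8")
    return path


@pytest.fixture
def genbank_no_cds(tmp_path):
    path = tmp_path / "no_cds.gbk"
    path.write_text(GENBANK_NO_CDS, encoding="utf-8")
    return path


@pytest.fixture
def paired_annotation_tsv(tmp_path):
    """TSV annotation table equivalent to GENBANK_TWO_CDS."""
    p1 = "M" + "A" * 98
    p2 = "M" + "K" * 98
    rows = [
        "taxon_id\tphylum\tmulticellular\treplicon_id\tgene_id\tstart\tend\t"
        "strand\tprotein_id\tarchitecture\tsequence",
        f"t900\tCyanobacteriota\tNA\tCHR1\tg1\t100\t399\t+\tp1\t\t{p1}",
        f"t900\tCyanobacteriota\tNA\tCHR1\tg2\t500\t799\t-\tp2\t\t{p2}",
    ]
    path = tmp_path / "t900.tsv"
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path
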