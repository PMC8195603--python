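"""Core data types and I/O for annotated genomes, architectures, alignments and hit tables.

The in-memory model is deliberately small: a :class:`Genome` is a taxon record
plus a coordinate-sorted gene list and a protein map.  Coordinates are 1-based
inclusive (GenBank convention); intergenic distance between consecutive genes
is ``next.start - prev.end - 1`` and may be negative for overlapping genes.

Two on-disk dialects are supported for annotations: GenBank flat files (read
only, via Biopython) and a tab-separated annotation table (read/write,
lossless round trip) whose columns are::

    taxon_id  phylum  multicellular  replicon_id  gene_id  start  end  strand
    protein_id  architecture  [sequence]

``architecture`` is a '+'-joined, N-to-C ordered list of domain labels (empty
allowed); ``multicellular`` is the tri-state ``true``/``false``/``NA``.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

ANNOTATION_COLUMNS = [
    "taxon_id",
    "phylum",
    "multicellular",
    "replicon_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "protein_id",
    "architecture",
]


class AnnotationError(ValueError):
    """Malformed annotation input (names the offending row/line where known)."""


@dataclass(frozen=True)
class TaxonRecord:
    """An organism with its phylum label and tri-state multicellularity flag.

    ``multicellular`` is True/False/None; None means "not known" and is never
    silently coerced to a boolean — statistics that need a boolean trait must
    drop unknowns explicitly (see :mod:`contextscan.enrichment`).
    """

    taxon_id: str
    name: str
    phylum: str
    multicellular: Optional[bool] = None

    def __post_init__(self):
        if not self.taxon_id:
            raise ValueError("taxon_id must be non-empty")
        if not self.phylum:
            raise ValueError(f"phylum must be non-empty (taxon {self.taxon_id})")


@dataclass(frozen=True)
class Gene:
    """A gene on a replicon; 1-based inclusive coordinates, strand '+' or '-'."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein_id: Optional[str] = None

    def __post_init__(self):
        if self.start < 1 or self.end < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates must be positive")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


def intergenic_gap(prev: Gene, nxt: Gene) -> int:
    """Nucleotides between two genes on one replicon; negative when they overlap."""
    return nxt.start - prev.end - 1


@dataclass(frozen=True)
class Protein:
    """A protein with optional sequence and an N→C ordered domain architecture."""

    protein_id: str
    sequence: Optional[str] = None
    architecture: tuple[str, ...] = ()

    def __post_init__(self):
        if self.sequence is not None:
            if not self.sequence:
                raise ValueError(f"protein {self.protein_id}: sequence present but empty")
            bad = set(self.sequence) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"protein {self.protein_id}: non amino-acid symbols {sorted(bad)}"
                )
        for dom in self.architecture:
            if not dom or "+" in dom:
                raise ValueError(
                    f"protein {self.protein_id}: invalid domain label {dom!r}"
                )
        object.__setattr__(self, "architecture", tuple(self.architecture))


@dataclass
class Genome:
    """A taxon's genes (sorted by replicon then start) and encoded proteins."""

    taxon: TaxonRecord
    genes: list[Gene] = field(default_factory=list)
    proteins: dict[str, Protein] = field(default_factory=dict)

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.replicon_id, g.start, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r} in genome {self.taxon.taxon_id}")
            seen.add(g.gene_id)
            if g.protein_id is not None and g.protein_id not in self.proteins:
                raise AnnotationError(
                    f"gene {g.gene_id}: protein_id {g.protein_id!r} does not resolve"
                )
        ov = self.overlapping_gene_ids()
        if ov:
            logger.warning(
                "genome %s: %d overlapping gene pairs (kept, flagged)",
                self.taxon.taxon_id, len(ov),
            )

    def overlapping_gene_ids(self) -> list[tuple[str, str]]:
        """Pairs of consecutive genes on the same replicon whose extents overlap."""
        out = []
        for a, b in zip(self.genes, self.genes[1:]):
            if a.replicon_id == b.replicon_id and intergenic_gap(a, b) < 0:
                out.append((a.gene_id, b.gene_id))
        return out

    def genes_on(self, replicon_id: str) -> list[Gene]:
        return [g for g in self.genes if g.replicon_id == replicon_id]

    @property
    def replicon_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.replicon_id, None)
        return list(seen)

    def protein_of(self, gene: Gene) -> Optional[Protein]:
        if gene.protein_id is None:
            return None
        return self.proteins[gene.protein_id]


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: equal-length rows over amino acids plus '-'."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must all have the same length")
        if len(self.rows[0]) < 1:
            raise ValueError("alignment needs at least 1 column")
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)


def _parse_multicellular(text: str, where: str = "") -> Optional[bool]:
    t = text.strip().lower()
    if t == "true":
        return True
    if t == "false":
        return False
    if t in ("na", ""):
        return None
    raise AnnotationError(f"multicellular must be true/false/NA, got {text!r} {where}")


def _format_multicellular(flag: Optional[bool]) -> str:
    if flag is None:
        return "NA"
    return "true" if flag else "false"


def read_annotation_table(path) -> Genome:
    """Read one genome from the TSV annotation-table dialect.

    The file must describe a single taxon; strand symbols, coordinate order and
    gene_id uniqueness are validated with the offending row number in errors.
    """
    path = Path(path)
    genes: list[Gene] = []
    proteins: dict[str, Protein] = {}
    taxon: Optional[TaxonRecord] = None
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise AnnotationError(f"{path}: empty file") from None
        has_seq = header == ANNOTATION_COLUMNS + ["sequence"]
        if not has_seq and header != ANNOTATION_COLUMNS:
            raise AnnotationError(f"{path}: unexpected header {header}")
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            expected = len(ANNOTATION_COLUMNS) + (1 if has_seq else 0)
            if len(row) != expected:
                raise AnnotationError(f"{path}:{rownum}: expected {expected} fields, got {len(row)}")
            (taxon_id, phylum, multi, replicon_id, gene_id,
             start, end, strand, protein_id, architecture) = row[:10]
            where = f"({path}:{rownum})"
            rec = TaxonRecord(taxon_id, taxon_id, phylum, _parse_multicellular(multi, where))
            if taxon is None:
                taxon = rec
            elif rec != taxon:
                raise AnnotationError(f"{path}:{rownum}: multiple taxa in one annotation table")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise AnnotationError(f"{path}:{rownum}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{rownum}: unknown strand symbol {strand!r}")
            if end_i < start_i:
                raise AnnotationError(f"{path}:{rownum}: end < start")
            pid = protein_id or None
            try:
                gene = Gene(gene_id, replicon_id, start_i, end_i, strand, pid)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{rownum}: {exc}") from None
            if any(g.gene_id == gene_id for g in genes):
                raise AnnotationError(f"{path}:{rownum}: duplicate gene_id {gene_id!r}")
            genes.append(gene)
            if pid is not None:
                arch = tuple(architecture.split("+")) if architecture else ()
                seq = (row[10] or None) if has_seq else None
                prot = Protein(pid, seq, arch)
                if pid in proteins and proteins[pid] != prot:
                    raise AnnotationError(f"{path}:{rownum}: conflicting records for protein {pid!r}")
                proteins[pid] = prot
    if taxon is None:
        raise AnnotationError(f"{path}: no data rows")
    return Genome(taxon=taxon, genes=genes, proteins=proteins)


def write_annotation_table(genome: Genome, path) -> None:
    """Write a genome in the TSV dialect; read(write(g)) is field-for-field lossless."""
    path = Path(path)
    has_seq = any(p.sequence is not None for p in genome.proteins.values())
    header = ANNOTATION_COLUMNS + (["sequence"] if has_seq else [])
    t = genome.taxon
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for g in genome.genes:
            prot = genome.protein_of(g)
            row = [
                t.taxon_id, t.phylum, _format_multicellular(t.multicellular),
                g.replicon_id, g.gene_id, str(g.start), str(g.end), g.strand,
                g.protein_id or "",
                "+".join(prot.architecture) if prot else "",
            ]
            if has_seq:
                row.append(prot.sequence or "" if prot else "")
            writer.writerow(row)


def read_annotation_dir(directory) -> list[Genome]:
    """Read every ``*.tsv`` annotation table in a directory, sorted by file name."""
    directory = Path(directory)
    return [read_annotation_table(p) for p in sorted(directory.glob("*.tsv"))]


def read_genbank(path, taxon: Optional[TaxonRecord] = None) -> Genome:
    """Read a GenBank flat file (all records = replicons of one genome).

    CDS locations are flattened to min-start/max-end with strand taken from the
    complement flag; a CDS lacking ``protein_id`` gets ``<locus>_<ordinal>``
    with a warning, and one lacking ``translation`` yields a sequence-less
    :class:`Protein`.  Pass ``taxon`` to override the record-derived metadata
    (GenBank files carry no multicellularity flag, so it defaults to unknown).
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises plain ValueError on bad syntax
        raise AnnotationError(f"{path}: GenBank parse error: {exc}") from exc
    if not records:
        raise AnnotationError(f"{path}: no GenBank records")

    if taxon is None:
        first = records[0]
        organism = first.annotations.get("organism", first.id or path.stem)
        taxonomy = first.annotations.get("taxonomy", [])
        phylum = taxonomy[1] if len(taxonomy) > 1 else "Unknown"
        taxon_id = organism
        for feat in first.features:
            if feat.type == "source":
                for xref in feat.qualifiers.get("db_xref", []):
                    if xref.startswith("taxon:"):
                        taxon_id = xref.split(":", 1)[1]
        taxon = TaxonRecord(taxon_id, organism, phylum, None)

    genes: list[Gene] = []
    proteins: dict[str, Protein] = {}
    n_cds = 0
    for record in records:
        replicon_id = record.name or record.id
        ordinal = 0
        for feat in record.features:
            if feat.type != "CDS":
                continue
            n_cds += 1
            ordinal += 1
            start = int(feat.location.start) + 1  # Biopython is 0-based half-open
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            locus = feat.qualifiers.get("locus_tag", [f"{replicon_id}_{ordinal}"])[0]
            pids = feat.qualifiers.get("protein_id")
            if pids:
                pid = pids[0]
            else:
                pid = f"{locus}_{ordinal}"
                warnings.warn(f"{path}: CDS {locus} lacks protein_id; assigned {pid}")
            translation = feat.qualifiers.get("translation", [None])[0]
            genes.append(Gene(locus, replicon_id, start, end, strand, pid))
            proteins[pid] = Protein(pid, translation, ())
    if n_cds == 0:
        logger.warning("%s: no CDS features; genome has an empty gene list", path)
    return Genome(taxon=taxon, genes=genes, proteins=proteins)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    msa = AlignIO.read(str(path), "fasta")
    return Alignment(
        names=tuple(rec.id for rec in msa),
        rows=tuple(str(rec.seq).upper() for rec in msa),
    )


def write_alignment(alignment: Alignment, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, row in zip(alignment.names, alignment.rows):
            fh.write(f">{name}\n{row}\n")


@dataclass(frozen=True)
class HitRecord:
    query: str
    hit: str
    p_value: float

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0,1], got {self.p_value}")


def read_hit_table(path) -> list[HitRecord]:
    """Read a profile-search hit table: TSV with header query, hit, p_value.

    Duplicate (query, hit) rows are allowed (multiple searches) and resolved
    at network-build time by keeping the best p-value.
    """
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "hit": str})
    if list(df.columns) != ["query", "hit", "p_value"]:
        raise AnnotationError(f"{path}: hit table must have columns query, hit, p_value")
    return [HitRecord(r.query, r.hit, float(r.p_value)) for r in df.itertuples()]


def write_hit_table(records: Iterable[HitRecord], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("query\thit\tp_value\n")
        for r in records:
            fh.write(f"{r.query}\t{r.hit}\t{r.p_value:.6g}\n")


def read_taxon_table(path) -> list[TaxonRecord]:
    """Read a taxon metadata TSV: taxon_id, name, phylum, multicellular."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    required = ["taxon_id", "name", "phylum", "multicellular"]
    if list(df.columns) != required:
        raise AnnotationError(f"{path}: taxon table must have columns {required}")
    return [
        TaxonRecord(r.taxon_id, r.name, r.phylum, _parse_multicellular(r.multicellular))
        for r in df.itertuples()
    ]


def write_taxon_table(taxa: Iterable[TaxonRecord], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("taxon_id\tname\tphylum\tmulticellular\n")
        for t in taxa:
            fh.write(f"{t.taxon_id}\t{t.name}\t{t.phylum}\t{_format_multicellular(t.multicellular)}\n")
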