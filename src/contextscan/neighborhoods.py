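"""Gene-neighborhood extraction and conserved-neighborhood detection.

A neighborhood is the window of genes up- and downstream of an anchor gene on
one replicon.  Candidate neighborhoods are made *valid* by three filters used
in contextual comparative genomics:

1. nucleotide distance: walking outward from the anchor, drop everything past
   the first neighbor whose intergenic gap to the previously retained gene
   exceeds ``max_gap_nt`` (default 50 nt, inclusive; overlapping genes —
   negative gaps — are always retained);
2. directionality: optionally drop neighbors not on the anchor's strand
   (operon semantics);
3. phyletic spread: a group of homologous neighborhoods is only reported when
   its member taxa span more than one phylum.

Homology across taxa is delegated to :mod:`contextscan.clustering`: member
proteins of all neighborhoods are pooled and clustered into families; two
neighborhoods belong to the same conserved group when their anchor proteins
share a family and they share at least one additional flanking family
(transitively closed).  Flank order/synteny is not required by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import networkx as nx

from .clustering import FAMILY_DETECTION, Clustering, cluster
from .genome_model import Gene, Genome, Protein, intergenic_gap


@dataclass(frozen=True)
class Neighborhood:
    """Contiguous genes around an anchor on one replicon, sorted by start."""

    anchor: str
    taxon_id: str
    replicon_id: str
    members: tuple[Gene, ...]
    window: int

    def __post_init__(self):
        if not any(g.gene_id == self.anchor for g in self.members):
            raise ValueError("anchor must be among members")
        starts = [g.start for g in self.members]
        if starts != sorted(starts):
            raise ValueError("members must be sorted by start")

    @property
    def anchor_gene(self) -> Gene:
        return next(g for g in self.members if g.gene_id == self.anchor)


@dataclass(frozen=True)
class FilterFlags:
    """Provenance of the validity filters applied to one neighborhood."""

    distance_trimmed: tuple[str, ...] = ()
    strand_trimmed: tuple[str, ...] = ()
    max_gap_nt: int = 50
    require_codirectional: bool = True


@dataclass
class ConservedNeighborhoodGroup:
    """Homologous neighborhoods from ≥2 phyla sharing anchor + flank families."""

    group_id: str
    member_neighborhoods: list[Neighborhood]
    family_assignment: dict[str, int]  # gene_id -> cluster index
    phyla: frozenset[str]
    filter_flags: dict[str, FilterFlags] = field(default_factory=dict)  # anchor -> flags

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(n.taxon_id for n in self.member_neighborhoods)


AnchorPredicate = Callable[[Gene, Optional[Protein]], bool]


def anchor_by_domain(domain: str) -> AnchorPredicate:
    """Predicate selecting genes whose protein architecture contains ``domain``."""

    def predicate(gene: Gene, protein: Optional[Protein]) -> bool:
        return protein is not None and domain in protein.architecture

    return predicate


def extract_neighborhoods(
    genome: Genome,
    anchor_predicate: AnchorPredicate,
    window: int,
) -> list[Neighborhood]:
    """One neighborhood per matching anchor; truncated at replicon ends."""
    if window < 1:
        raise ValueError("window must be ≥ 1")
    out: list[Neighborhood] = []
    for replicon_id in genome.replicon_ids:
        genes = genome.genes_on(replicon_id)
        for i, gene in enumerate(genes):
            protein = genome.protein_of(gene)
            if not anchor_predicate(gene, protein):
                continue
            lo = max(0, i - window)
            hi = min(len(genes), i + window + 1)
            out.append(
                Neighborhood(
                    anchor=gene.gene_id,
                    taxon_id=genome.taxon.taxon_id,
                    replicon_id=replicon_id,
                    members=tuple(genes[lo:hi]),
                    window=window,
                )
            )
    return out


def apply_validity_filters(
    neigh: Neighborhood,
    max_gap_nt: int = 50,
    require_codirectional: bool = True,
) -> tuple[Neighborhood, FilterFlags]:
    """Trim a neighborhood outward from its anchor by the distance and
    directionality filters; returns the trimmed neighborhood and provenance.

    The gap comparison is inclusive (a gap of exactly ``max_gap_nt`` is kept)
    and negative gaps (overlaps) always pass.  The strand comparison is
    against the anchor's strand.
    """
    if max_gap_nt < 0:
        raise ValueError("max_gap_nt must be ≥ 0")
    members = list(neigh.members)
    idx = next(i for i, g in enumerate(members) if g.gene_id == neigh.anchor)
    anchor = members[idx]

    distance_trimmed: list[str] = []
    strand_trimmed: list[str] = []

    def walk(indices: Sequence[int]) -> list[Gene]:
        kept: list[Gene] = []
        prev = anchor
        for i in indices:
            gene = members[i]
            pair = (prev, gene) if gene.start >= prev.start else (gene, prev)
            gap = intergenic_gap(*pair)
            if gap > max_gap_nt:
                distance_trimmed.extend(members[j].gene_id for j in indices[indices.index(i):])
                break
            if require_codirectional and gene.strand != anchor.strand:
                strand_trimmed.extend(members[j].gene_id for j in indices[indices.index(i):])
                break
            kept.append(gene)
            prev = gene
        return kept

    downstream = walk(list(range(idx + 1, len(members))))
    upstream = walk(list(range(idx - 1, -1, -1)))
    trimmed = sorted(upstream + [anchor] + downstream, key=lambda g: g.start)
    flags = FilterFlags(
        distance_trimmed=tuple(distance_trimmed),
        strand_trimmed=tuple(strand_trimmed),
        max_gap_nt=max_gap_nt,
        require_codirectional=require_codirectional,
    )
    return (
        Neighborhood(neigh.anchor, neigh.taxon_id, neigh.replicon_id,
                     tuple(trimmed), neigh.window),
        flags,
    )


def find_conserved_groups(
    neighborhoods: Sequence[Neighborhood],
    genomes: Mapping[str, Genome],
    clusterer: Optional[Callable[[Mapping[str, str]], Clustering]] = None,
    min_phyla: int = 2,
    filter_flags: Optional[Mapping[str, FilterFlags]] = None,
) -> list[ConservedNeighborhoodGroup]:
    """Pool neighborhood proteins, cluster into families, and group.

    ``genomes`` maps taxon_id → Genome (source of protein sequences and the
    taxon's phylum).  ``clusterer`` defaults to single-linkage clustering at
    the family-detection preset.  Groups whose members span fewer than
    ``min_phyla`` phyla are discarded.  Neighborhood proteins without
    sequences are an error naming the anchor.
    """
    if clusterer is None:
        def clusterer(seqs: Mapping[str, str]) -> Clustering:
            return cluster(seqs, *FAMILY_DETECTION)

    sequences: dict[str, str] = {}
    gene_key: dict[tuple[str, str], str] = {}  # (taxon, gene_id) -> pooled key
    for neigh in neighborhoods:
        genome = genomes[neigh.taxon_id]
        for gene in neigh.members:
            protein = genome.protein_of(gene)
            if protein is None or protein.sequence is None:
                raise ValueError(
                    f"neighborhood {neigh.anchor}: gene {gene.gene_id} lacks a "
                    "protein sequence; cannot cluster"
                )
            key = f"{neigh.taxon_id}:{protein.protein_id}"
            sequences[key] = protein.sequence
            gene_key[(neigh.taxon_id, gene.gene_id)] = key

    clustering = clusterer(sequences)
    family_of = clustering.cluster_of()

    def families(neigh: Neighborhood) -> tuple[int, frozenset[int]]:
        anchor_fam = family_of[gene_key[(neigh.taxon_id, neigh.anchor)]]
        flanks = frozenset(
            family_of[gene_key[(neigh.taxon_id, g.gene_id)]]
            for g in neigh.members
            if g.gene_id != neigh.anchor
        )
        return anchor_fam, flanks

    info = [families(n) for n in neighborhoods]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(neighborhoods)))
    for i in range(len(neighborhoods)):
        for j in range(i + 1, len(neighborhoods)):
            if info[i][0] == info[j][0] and (info[i][1] & info[j][1]):
                graph.add_edge(i, j)

    groups: list[ConservedNeighborhoodGroup] = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (neighborhoods[c[0]].taxon_id, neighborhoods[c[0]].anchor),
    )
    for comp in components:
        members = [neighborhoods[i] for i in comp]
        phyla = frozenset(genomes[n.taxon_id].taxon.phylum for n in members)
        if len(phyla) < min_phyla:
            continue
        assignment = {
            g.gene_id: family_of[gene_key[(n.taxon_id, g.gene_id)]]
            for n in members
            for g in n.members
        }
        flags = {
            n.anchor: filter_flags[n.anchor]
            for n in members
            if filter_flags and n.anchor in filter_flags
        }
        groups.append(
            ConservedNeighborhoodGroup(
                group_id=f"grp{len(groups) + 1}",
                member_neighborhoods=members,
                family_assignment=assignment,
                phyla=phyla,
                filter_flags=flags,
            )
        )
    return groups


def scan_genomes(
    genomes: Sequence[Genome],
    anchor_domain: str,
    window: int = 2,
    max_gap_nt: int = 50,
    require_codirectional: bool = True,
    min_phyla: int = 2,
    clusterer: Optional[Callable[[Mapping[str, str]], Clustering]] = None,
    reject_on_fail: bool = False,
) -> list[ConservedNeighborhoodGroup]:
    """End-to-end conserved-neighborhood scan over a set of genomes.

    With ``reject_on_fail`` a neighborhood that loses any member to the
    distance/directionality filters is dropped entirely instead of trimmed.
    """
    predicate = anchor_by_domain(anchor_domain)
    trimmed: list[Neighborhood] = []
    flags: dict[str, FilterFlags] = {}
    for genome in genomes:
        for neigh in extract_neighborhoods(genome, predicate, window):
            t, f = apply_validity_filters(neigh, max_gap_nt, require_codirectional)
            if reject_on_fail and (f.distance_trimmed or f.strand_trimmed):
                continue
            trimmed.append(t)
            flags[t.anchor] = f
    by_taxon = {g.taxon.taxon_id: g for g in genomes}
    return find_conserved_groups(trimmed, by_taxon, clusterer, min_phyla, flags)


def group_report(groups: Sequence[ConservedNeighborhoodGroup]) -> list[dict]:
    """JSON-serializable provenance report of conserved groups."""
    report = []
    for g in groups:
        report.append(
            {
                "group_id": g.group_id,
                "n_members": len(g.member_neighborhoods),
                "taxa": sorted(g.taxa),
                "phyla": sorted(g.phyla),
                "members": [
                    {
                        "anchor": n.anchor,
                        "taxon_id": n.taxon_id,
                        "replicon_id": n.replicon_id,
                        "genes": [m.gene_id for m in n.members],
                        "families": [g.family_assignment[m.gene_id] for m in n.members],
                    }
                    for n in g.member_neighborhoods
                ],
            }
        )
    return report
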