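"""Synthetic genomes, families, alignments and count tables with planted truth.

Every downstream stage of the pipeline is exercised against data whose ground
truth is known by construction.  The generator emulates the inputs of a
prokaryotic contextual-genomics study:

* multi-replicon genomes with operon-like same-strand runs and realistic
  intergenic gaps (normal, truncated so genes may slightly overlap);
* homologous protein families derived from a random ancestor by i.i.d.
  per-site substitution at a tunable divergence (no indels);
* conserved gene cassettes — co-directional runs of 2+ family members with
  short internal gaps — planted into carrier taxa spanning several phyla;
* decoy anchor genes: unrelated singleton proteins carrying the anchor
  domain, so that specificity of neighborhood recovery is non-trivial;
* domain architectures with a planted terminal-position bias;
* mixed conserved/diversified alignment columns;
* organism × family count tables with planted lineage-specific expansions.

Background genes get unique singleton families so that any false-positive
conserved neighborhood is attributable.  All outputs are fully determined by
the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genome_model import (
    Alignment,
    Gene,
    Genome,
    HitRecord,
    Protein,
    TaxonRecord,
    write_alignment,
    write_annotation_table,
    write_hit_table,
    write_taxon_table,
)

AA = tuple("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_PHYLA = ("Proteobacteria", "Bacillota", "Actinomycetota", "Cyanobacteriota")


@dataclass
class SyntheticConfig:
    """Knobs of the genome generator; the defaults define the study conditions.

    ``family_divergence`` is the per-site substitution probability applied
    independently to each cassette-protein copy relative to the family
    ancestor (uniform over the 19 alternative residues, no indels).
    """

    n_taxa: int = 12
    phyla: tuple[str, ...] = DEFAULT_PHYLA
    phylum_probs: Optional[tuple[float, ...]] = None  # None = uniform
    multicellular_fraction: float = 0.3
    multicellular_unknown_fraction: float = 0.1
    genes_per_replicon: tuple[int, int] = (40, 60)
    intergenic_gap_mean: float = 120.0
    intergenic_gap_sd: float = 80.0
    intergenic_gap_min: int = -30
    operon_mean_run: float = 3.0
    protein_length_range: tuple[int, int] = (150, 400)
    family_divergence: float = 0.1
    n_cassettes: int = 1
    cassette_length: int = 3
    carriers_per_cassette: int = 6
    phyla_per_cassette: int = 3
    cassette_gap_max: int = 40
    n_decoy_anchors: int = 6
    anchor_domain: str = "AnchorDom"
    biased_domain: Optional[str] = "BiasDom"
    biased_domain_occurrences: int = 40
    biased_domain_p_nterm: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.phylum_probs is not None:
            if len(self.phylum_probs) != len(self.phyla):
                raise ValueError("phylum_probs must match phyla")
            if abs(sum(self.phylum_probs) - 1.0) > 1e-9:
                raise ValueError("phylum_probs must sum to 1")
        if not 0.0 <= self.family_divergence <= 0.5:
            raise ValueError("family_divergence must be in [0, 0.5]")
        if self.phyla_per_cassette < 1 or self.carriers_per_cassette < self.phyla_per_cassette:
            raise ValueError("carriers_per_cassette must be ≥ phyla_per_cassette ≥ 1")


@dataclass
class PlantedCassette:
    """One planted conserved neighborhood: family ids in gene order, its
    carrier taxa, the gene_id of the first cassette gene in each carrier,
    and the phyla the carriers span."""

    cassette_id: str
    family_ids: tuple[str, ...]
    carrier_taxa: tuple[str, ...]
    insertion_loci: dict[str, str]
    phyla: tuple[str, ...]


@dataclass
class PlantedTruth:
    """Record of everything the generator planted, keyed by generated ids."""

    cassettes: list[PlantedCassette] = field(default_factory=list)
    biased_domains: dict[str, float] = field(default_factory=dict)
    expansions: dict[tuple[str, str], int] = field(default_factory=dict)
    alignment_entropy_profile: tuple[str, ...] = ()
    decoy_anchor_genes: dict[str, str] = field(default_factory=dict)  # gene_id -> taxon
    cassette_member_proteins: dict[str, list[str]] = field(default_factory=dict)  # family -> taxon:pid

    def to_json(self) -> str:
        payload = {
            "cassettes": [
                {
                    "cassette_id": c.cassette_id,
                    "family_ids": list(c.family_ids),
                    "carrier_taxa": list(c.carrier_taxa),
                    "insertion_loci": c.insertion_loci,
                    "phyla": list(c.phyla),
                }
                for c in self.cassettes
            ],
            "biased_domains": self.biased_domains,
            "expansions": [[o, f, n] for (o, f), n in sorted(self.expansions.items())],
            "alignment_entropy_profile": list(self.alignment_entropy_profile),
            "decoy_anchor_genes": self.decoy_anchor_genes,
            "cassette_member_proteins": self.cassette_member_proteins,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def _mutate(rng: np.random.Generator, sequence: str, divergence: float) -> str:
    """Substitute each site with probability ``divergence``, uniform over the
    19 alternatives; length is preserved (no indels)."""
    if divergence == 0.0:
        return sequence
    chars = np.array(list(sequence))
    hit = rng.random(len(chars)) < divergence
    for i in np.nonzero(hit)[0]:
        alternatives = [a for a in AA if a != chars[i]]
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _truncated_gap(rng: np.random.Generator, cfg: SyntheticConfig) -> int:
    while True:
        g = int(round(rng.normal(cfg.intergenic_gap_mean, cfg.intergenic_gap_sd)))
        if g >= cfg.intergenic_gap_min:
            return g


def _strand_runs(rng: np.random.Generator, n: int, mean_run: float) -> list[str]:
    """Strands assigned operon-style: geometric run lengths, alternating draws."""
    strands: list[str] = []
    while len(strands) < n:
        run = int(rng.geometric(1.0 / mean_run))
        strand = "+" if rng.random() < 0.5 else "-"
        strands.extend([strand] * run)
    return strands[:n]


def generate_genomes(config: SyntheticConfig) -> tuple[list[Genome], PlantedTruth]:
    """Generate annotated genomes with planted cassettes, decoys and biases.

    By construction every planted cassette passes the three neighborhood
    validity filters at default thresholds: its genes are co-directional,
    internal gaps are at most ``cassette_gap_max`` (≤ the 50-nt default), and
    its carriers span ``phyla_per_cassette`` phyla.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth = PlantedTruth()

    if cfg.n_cassettes > 0 and cfg.phyla_per_cassette > len(cfg.phyla):
        raise ValueError("phyla_per_cassette exceeds the number of phyla")

    # Taxa: guarantee every phylum needed by cassettes has at least one taxon.
    phyla_assign: list[str] = []
    probs = cfg.phylum_probs or tuple(1.0 / len(cfg.phyla) for _ in cfg.phyla)
    for i in range(cfg.n_taxa):
        phyla_assign.append(str(rng.choice(cfg.phyla, p=probs)))
    needed = list(cfg.phyla[: cfg.phyla_per_cassette]) if cfg.n_cassettes else []
    for j, ph in enumerate(needed):
        if ph not in phyla_assign:
            phyla_assign[j % cfg.n_taxa] = ph
    if needed:
        # make cassettes feasible: at least carriers_per_cassette taxa in target phyla
        short = cfg.carriers_per_cassette - sum(p in needed for p in phyla_assign)
        for i in range(cfg.n_taxa):
            if short <= 0:
                break
            if phyla_assign[i] not in needed:
                phyla_assign[i] = needed[i % len(needed)]
                short -= 1

    taxa: list[TaxonRecord] = []
    for i in range(cfg.n_taxa):
        u = rng.random()
        if u < cfg.multicellular_unknown_fraction:
            flag = None
        else:
            flag = bool(rng.random() < cfg.multicellular_fraction)
        tid = f"t{i + 1:03d}"
        taxa.append(TaxonRecord(tid, tid, phyla_assign[i], flag))

    # Per-taxon gene plans: list of (protein_seq, architecture, forced_strand|None,
    # forced_gap|None, cassette_tag|None)
    plans: dict[str, list[dict]] = {}
    for t in taxa:
        n_genes = int(rng.integers(cfg.genes_per_replicon[0], cfg.genes_per_replicon[1] + 1))
        lo, hi = cfg.protein_length_range
        plan = []
        for _ in range(n_genes):
            plan.append(
                {
                    "seq": _random_protein(rng, int(rng.integers(lo, hi + 1))),
                    "arch": (),
                    "strand": None,
                    "gap": None,
                    "tag": None,
                }
            )
        plans[t.taxon_id] = plan

    # Plant a terminal-position bias into background architectures.
    if cfg.biased_domain and cfg.biased_domain_occurrences > 0:
        all_slots = [(t.taxon_id, j) for t in taxa for j in range(len(plans[t.taxon_id]))]
        order = rng.permutation(len(all_slots))
        chosen = [all_slots[i] for i in order[: cfg.biased_domain_occurrences]]
        filler = 0
        for tid, j in chosen:
            k = int(rng.integers(2, 5))  # architecture length 2–4
            arch = [f"Flr{filler + m}" for m in range(k)]
            filler += k
            pos = 0 if rng.random() < cfg.biased_domain_p_nterm else int(rng.integers(1, k))
            arch[pos] = cfg.biased_domain
            plans[tid][j]["arch"] = tuple(arch)
        truth.biased_domains[cfg.biased_domain] = cfg.biased_domain_p_nterm

    # Plant cassettes.
    for c in range(cfg.n_cassettes):
        cid = f"cas{c + 1}"
        fam_ids = tuple(f"{cid}_fam{m + 1}" for m in range(cfg.cassette_length))
        lo, hi = cfg.protein_length_range
        ancestors = [_random_protein(rng, int(rng.integers(lo, hi + 1))) for _ in fam_ids]

        target_phyla = list(cfg.phyla[: cfg.phyla_per_cassette])
        by_phylum = {ph: [t for t in taxa if t.phylum == ph] for ph in target_phyla}
        carriers: list[TaxonRecord] = []
        for ph in target_phyla:  # one carrier per required phylum first
            pool = [t for t in by_phylum[ph] if t not in carriers]
            if not pool:
                raise ValueError(f"no taxon available in phylum {ph} for cassette {cid}")
            carriers.append(pool[rng.integers(len(pool))])
        remaining = [t for t in taxa if t.phylum in target_phyla and t not in carriers]
        order = rng.permutation(len(remaining))
        for i in order:
            if len(carriers) >= cfg.carriers_per_cassette:
                break
            carriers.append(remaining[i])
        if len(carriers) < cfg.carriers_per_cassette:
            raise ValueError(f"cassette {cid}: not enough taxa in its phyla for "
                             f"{cfg.carriers_per_cassette} carriers")

        loci: dict[str, str] = {}
        for t in carriers:
            plan = plans[t.taxon_id]
            strand = "+" if rng.random() < 0.5 else "-"
            insert_at = int(rng.integers(0, len(plan) + 1))
            block = []
            for m, fam in enumerate(fam_ids):
                arch: tuple[str, ...]
                if m == 0:
                    arch = (cfg.anchor_domain,)
                else:
                    arch = (f"{cid}_dom{m + 1}",)
                block.append(
                    {
                        "seq": _mutate(rng, ancestors[m], cfg.family_divergence),
                        "arch": arch,
                        "strand": strand,
                        "gap": None if m == 0 else int(rng.integers(0, cfg.cassette_gap_max + 1)),
                        "tag": (cid, fam),
                    }
                )
            plans[t.taxon_id] = plan[:insert_at] + block + plan[insert_at:]
            loci[t.taxon_id] = ""  # gene ids assigned at layout, filled below
        truth.cassettes.append(
            PlantedCassette(cid, fam_ids, tuple(t.taxon_id for t in carriers), loci,
                            tuple(sorted({t.phylum for t in carriers})))
        )

    # Decoy anchors: unrelated singleton proteins flagged with the anchor
    # domain.  Insertion points inside a planted cassette block are forbidden
    # (they would break the cassette's contiguity).
    def allowed_positions(plan: list[dict]) -> list[int]:
        positions = []
        for i in range(len(plan) + 1):
            before = plan[i - 1]["tag"] if i > 0 else None
            after = plan[i]["tag"] if i < len(plan) else None
            inside = (
                before is not None and after is not None
                and before[0] == after[0] and before[0] != "decoy"
            )
            if not inside:
                positions.append(i)
        return positions

    for d in range(cfg.n_decoy_anchors):
        t = taxa[int(rng.integers(len(taxa)))]
        plan = plans[t.taxon_id]
        lo, hi = cfg.protein_length_range
        entry = {
            "seq": _random_protein(rng, int(rng.integers(lo, hi + 1))),
            "arch": (cfg.anchor_domain,),
            "strand": None,
            "gap": None,
            "tag": ("decoy", f"decoy{d + 1}"),
        }
        positions = allowed_positions(plan)
        plan.insert(positions[int(rng.integers(len(positions)))], entry)

    # Lay out coordinates and build Genome objects.
    genomes: list[Genome] = []
    for t in taxa:
        plan = plans[t.taxon_id]
        strands = _strand_runs(rng, len(plan), cfg.operon_mean_run)
        genes: list[Gene] = []
        proteins: dict[str, Protein] = {}
        pos = 1
        for j, entry in enumerate(plan):
            gap = entry["gap"] if entry["gap"] is not None else _truncated_gap(rng, cfg)
            if j == 0:
                gap = max(gap, 0)
            start = pos + gap
            if start < 1:
                start = 1
            length_nt = 3 * len(entry["seq"]) + 3
            end = start + length_nt - 1
            strand = entry["strand"] if entry["strand"] is not None else strands[j]
            gid = f"{t.taxon_id}_g{j + 1:04d}"
            pid = f"{t.taxon_id}_p{j + 1:04d}"
            genes.append(Gene(gid, "chr", start, end, strand, pid))
            proteins[pid] = Protein(pid, entry["seq"], entry["arch"])
            tag = entry["tag"]
            if tag is not None:
                kind, name = tag[0], tag[1]
                if kind == "decoy":
                    truth.decoy_anchor_genes[gid] = t.taxon_id
                else:
                    truth.cassette_member_proteins.setdefault(name, []).append(
                        f"{t.taxon_id}:{pid}"
                    )
                    cas = next(c for c in truth.cassettes if c.cassette_id == kind)
                    if name == cas.family_ids[0]:
                        cas.insertion_loci[t.taxon_id] = gid
            pos = end + 1
        genomes.append(Genome(taxon=t, genes=genes, proteins=proteins))
    return genomes, truth


def cassette_family_members(truth: PlantedTruth) -> dict[str, list[str]]:
    """Map planted family id → 'taxon:protein_id' member keys."""
    return {fam: list(members) for fam, members in truth.cassette_member_proteins.items()}


def generate_family(
    n_members: int,
    length: int,
    divergence: float,
    rng: np.random.Generator,
) -> list[str]:
    """A homologous family: ``n_members`` independent mutants of one ancestor."""
    ancestor = _random_protein(rng, length)
    return [_mutate(rng, ancestor, divergence) for _ in range(n_members)]


def generate_alignment(
    n_rows: int,
    profile: Sequence[str],
    seed: int = 0,
    k_diversified: int = 8,
) -> Alignment:
    """Alignment with per-column classes ``conserved`` (single residue, H=0)
    or ``diversified`` (uniform over ``k_diversified`` residues, H → log2 k)."""
    if n_rows < 2:
        raise ValueError("n_rows must be ≥ 2")
    rng = np.random.default_rng(seed)
    columns = []
    for cls in profile:
        if cls == "conserved":
            res = rng.choice(AA)
            columns.append([res] * n_rows)
        elif cls == "diversified":
            pool = rng.choice(AA, size=k_diversified, replace=False)
            columns.append(list(rng.choice(pool, size=n_rows)))
        else:
            raise ValueError(f"unknown column class {cls!r}")
    rows = ["".join(col[i] for col in columns) for i in range(n_rows)]
    return Alignment(names=tuple(f"s{i + 1}" for i in range(n_rows)), rows=tuple(rows))


def generate_count_table(
    n_org: int,
    n_fam: int,
    expansion_spec: Optional[dict[str, dict[str, int]]] = None,
    seed: int = 0,
    background_lambda: float = 1.0,
):
    """Organism × family count table: Poisson background plus planted expansions.

    ``expansion_spec`` maps organism id → {family id: planted count}; family
    ids not among the background columns are appended.  Returns
    ``(CountTable, PlantedTruth)`` with the expansions recorded.
    """
    from .pds import CountTable

    rng = np.random.default_rng(seed)
    organisms = [f"o{i + 1:03d}" for i in range(n_org)]
    families = [f"fam{j + 1:03d}" for j in range(n_fam)]
    counts = rng.poisson(background_lambda, size=(n_org, n_fam)).astype(np.int64)

    truth = PlantedTruth()
    spec = expansion_spec or {}
    extra = sorted({f for fams in spec.values() for f in fams if f not in families})
    all_fams = families + extra
    if extra:
        counts = np.concatenate([counts, np.zeros((n_org, len(extra)), dtype=np.int64)], axis=1)
    col = {f: j for j, f in enumerate(all_fams)}
    for org, fams in spec.items():
        if org not in organisms:
            raise ValueError(f"expansion organism {org!r} outside table")
        i = organisms.index(org)
        for fam, n in fams.items():
            counts[i, col[fam]] += int(n)
            truth.expansions[(org, fam)] = int(n)
    return CountTable(organisms=organisms, families=all_fams, counts=counts), truth


def generate_hit_table(labels: Sequence[str], seed: int = 0,
                       edge_prob: float = 0.25) -> list[HitRecord]:
    """Synthetic profile-search hits: random pairs with log-uniform p-values."""
    rng = np.random.default_rng(seed)
    records = []
    for q in labels:
        for h in labels:
            if q == h or rng.random() >= edge_prob:
                continue
            p = float(10.0 ** rng.uniform(-12, 0))
            records.append(HitRecord(q, h, p))
    return records


def generate_zmatrix(labels: Sequence[str], seed: int = 0,
                     n_groups: int = 2) -> tuple[list[str], np.ndarray]:
    """Symmetric structure-similarity Z-scores with block (group) structure."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    group = rng.integers(n_groups, size=n)
    z = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                z[i, j] = rng.uniform(40, 60)
            else:
                base = 20.0 if group[i] == group[j] else 5.0
                z[i, j] = z[j, i] = base + rng.uniform(-2, 2)
    return list(labels), z


def write_dataset(genomes: Sequence[Genome], truth: PlantedTruth, outdir) -> None:
    """Write annotation tables (one per taxon, under ``annotations/``), the
    taxon table and truth JSON."""
    outdir = Path(outdir)
    (outdir / "annotations").mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_annotation_table(g, outdir / "annotations" / f"{g.taxon.taxon_id}.tsv")
    write_taxon_table([g.taxon for g in genomes], outdir / "taxa.tsv")
    (outdir / "planted_truth.json").write_text(truth.to_json(), encoding="utf-8")
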