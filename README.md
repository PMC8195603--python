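# contextscan

Contextual comparative genomics for prokaryotic conflict systems: conserved
gene-neighborhood detection, domain-architecture network analysis, and the
statistics used to characterize rapidly evolving protein families —
polydomain scores, entropy-based diversification contrasts, positional-bias
χ², hypergeometric trait enrichment, and Z-score structure trees.

## The problem

Bacterial defense and conflict systems (effector-associated domains,
Death-like-domain adaptors and their relatives) are found by *context*: the
genes that flank an anchor gene, the domains that co-occur in the same
polypeptide, and the lineages in which a family has expanded. `contextscan`
implements that analytical toolkit as a tested, reusable library and CLI:

- **Gene neighborhoods.** Around each anchor gene, the up/downstream window
  is trimmed by a nucleotide distance constraint (default ≤ 50 nt between
  consecutive genes, inclusive; overlaps always kept) and by conservation of
  gene directionality relative to the anchor. Neighborhoods from different
  taxa are grouped when their anchor proteins fall in one sequence cluster
  and share at least one flanking family; a group is only reported when its
  taxa span more than one phylum.
- **Clustering.** Single-linkage clustering after the BLASTCLUST contract:
  sequences are linked when coverage ≥ L of the longer sequence and score
  density ≥ S bits per aligned column (global BLOSUM62 alignment, affine
  gaps 11/1). Presets: near-identical (L=0.9, S=1.89) and family detection
  (L=0.6, S=0.8).
- **Architecture networks.** Directed domain-adjacency graphs over unique
  architectures (arrowhead toward the C terminus), and retrieval networks
  from profile-search hit tables (edge iff p < 1e-4, weight −log₁₀ p).
- **Positional bias.** For a domain in multi-domain architectures, Pearson
  χ² (df = 2) of N-terminal/internal/C-terminal occurrence counts against a
  slot-availability null (each occurrence uniform over its architecture's
  k slots: 1/k, (k−2)/k, 1/k).
- **Diversification.** Column-wise Shannon entropy H = −Σᵢ Pᵢ log₂ Pᵢ over
  non-gap residues, and a two-sided Welch t-test contrasting mean column
  entropy of two alignments.
- **Enrichment.** Upper-tail hypergeometric test P(X ≥ q) for association
  of a system with a binary taxon trait (e.g. multicellularity), with
  q = trait-positive carriers, m/n = trait-positive/negative background,
  k = carriers; tri-state unknowns are excluded from all counts.
- **Polydomain score.** PD(o) = Σₚ c(o,p)·(f(p) − f̄) with
  f(p) = log₂(Σₒ c(o,p) / ΣₚΣₒ c(o,p)); large |PD| flags lineage-specific
  expansions.
- **Structure trees.** Pairwise structure-similarity Z-scores converted to
  distances (d = Z_max − z) and clustered by average linkage (UPGMA) with
  deterministic tie-breaking; Newick output.

A synthetic-data module generates multi-replicon genomes with operon-like
strand runs, planted conserved cassettes spanning multiple phyla, decoy
anchors, planted terminal-position biases, divergence-controlled protein
families, mixed-entropy alignments and count tables with planted expansions
— so every stage is validated against known ground truth.

## Worked example

Generate a synthetic dataset with one planted cassette and run every stage:

```bash
contextscan demo --out demo_out --seed 1
# demo complete: 20 artifact(s) in demo_out
```

The conserved-neighborhood scan (`demo_out/groups.json`) recovers exactly
the planted cassette — one group whose four member taxa are the planted
carriers, spanning two phyla (`['t003', 't005', 't006', 't008']`,
`['Bacillota', 'Proteobacteria']`); the decoy anchors attract no group.

Contrasting the diversified against the conserved synthetic family:

```bash
contextscan divtest --fasta-a demo_out/data/family_diversified.afa \
                    --fasta-b demo_out/data/family_conserved.afa
{
 "t": 6.853211763268321,
 "p": 3.0785723346193077e-09,
 "mean_a": 1.224078494806367,
 "mean_b": 0.09515737858607957
}
```

The diversified family averages 1.22 bits per column against 0.10 for the
conserved one — a highly significant elevation, the signature of a rapidly
diversifying family.

The planted N-terminal bias is detected (`demo_out/positional_bias.tsv`):

```
domain   n_N  n_int  n_C  chi2       p
BiasDom  22   1      2    27.910603  8.6954e-07
```

and the polydomain score isolates the planted expansion outlier: `o001`,
seeded with 300 extra copies spread over ten globally rare families, scores
PD = −83.06 while every background organism stays within ±7
(`demo_out/pds.tsv`). The Z-score tree (`demo_out/tree.nwk`) splits the two
planted structural groups at the root.

Each stage is also available on its own (`contextscan neighborhoods`,
`cluster`, `archnet`, `retnet`, `posbias`, `entropy`, `divtest`, `enrich`,
`pds`, `tree`) and through a YAML-configured `contextscan pipeline` runner
that writes a full manifest and is byte-reproducible for a fixed seed.

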