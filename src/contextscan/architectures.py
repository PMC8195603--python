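"""Domain-architecture networks, search-retrieval networks and positional bias.

An *architecture network* summarizes how domains combine in polypeptides: a
directed edge d1 → d2 (arrowhead toward the C terminus) with weight equal to
the number of distinct architectures in which d2 immediately follows d1.
A *retrieval network* summarizes profile-profile search results: an edge
query → hit for every hit with p-value below a strict threshold (default
1e-4), weighted by −log10 of the best p-value.

Positional bias asks whether a domain preferentially sits at the N terminus,
C terminus, or inside multi-domain architectures.  Observed counts are taken
over unique architectures only; the null expectation is *slot availability*:
each occurrence is equally likely at any of the k slots of its architecture,
giving per-occurrence probabilities (1/k, (k−2)/k, 1/k).  A Pearson χ² test
(df = 2) compares observed counts to that expectation.  The naive
uniform-thirds null is available via ``null="uniform"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
from scipy import stats

from .genome_model import HitRecord, Protein

Architecture = tuple[str, ...]


def _unique_architectures(
    items: Iterable[Protein | Sequence[str]], dedupe: bool = True
) -> list[Architecture]:
    archs = []
    for item in items:
        arch = tuple(item.architecture) if isinstance(item, Protein) else tuple(item)
        archs.append(arch)
    if not dedupe:
        return archs
    seen: dict[Architecture, None] = {}
    for a in archs:
        seen.setdefault(a, None)
    return list(seen)


def build_architecture_network(
    proteins: Iterable[Protein | Sequence[str]], dedupe: bool = True
) -> nx.DiGraph:
    """Directed domain-adjacency graph over (optionally deduplicated)
    architectures; single-domain architectures contribute nodes only and
    tandem repeats yield self-loops."""
    graph = nx.DiGraph()
    for arch in _unique_architectures(proteins, dedupe):
        for dom in arch:
            graph.add_node(dom)
        for d1, d2 in zip(arch, arch[1:]):
            if graph.has_edge(d1, d2):
                graph[d1][d2]["weight"] += 1
            else:
                graph.add_edge(d1, d2, weight=1)
    return graph


def build_retrieval_network(
    hit_table: Iterable[HitRecord], p_threshold: float = 1e-4
) -> nx.DiGraph:
    """Query → hit graph for hits with p strictly below ``p_threshold``;
    duplicate (query, hit) pairs keep the minimum p; weight = −log10(p)."""
    best: dict[tuple[str, str], float] = {}
    for rec in hit_table:
        if rec.p_value <= 0:
            raise ValueError(f"non-positive p-value for ({rec.query}, {rec.hit})")
        key = (rec.query, rec.hit)
        if key not in best or rec.p_value < best[key]:
            best[key] = rec.p_value
    graph = nx.DiGraph()
    for (q, h), p in best.items():
        if p < p_threshold:
            graph.add_edge(q, h, weight=-math.log10(p), p_value=p)
    return graph


@dataclass(frozen=True)
class PositionalCounts:
    """Occurrence counts of one domain over unique multi-domain architectures
    and the slot-availability expectation (proportions summing to 1)."""

    domain: str
    n_nterm: int
    n_internal: int
    n_cterm: int
    slot_expectation: tuple[float, float, float]

    @property
    def total(self) -> int:
        return self.n_nterm + self.n_internal + self.n_cterm

    @property
    def observed(self) -> tuple[int, int, int]:
        return (self.n_nterm, self.n_internal, self.n_cterm)


def positional_counts(
    domain: str,
    proteins: Iterable[Protein | Sequence[str]],
    null: str = "slots",
) -> PositionalCounts:
    """Classify each occurrence of ``domain`` in unique architectures with ≥2
    domains as N-terminal / internal / C-terminal and compute the null
    expectation (``"slots"`` = slot availability, ``"uniform"`` = thirds)."""
    archs = [a for a in _unique_architectures(proteins, dedupe=True)
             if len(a) >= 2 and domain in a]
    if not archs:
        raise ValueError(f"domain {domain!r} absent from all multi-domain architectures")
    n_n = n_i = n_c = 0
    exp = [0.0, 0.0, 0.0]
    for arch in archs:
        k = len(arch)
        for pos, dom in enumerate(arch):
            if dom != domain:
                continue
            if pos == 0:
                n_n += 1
            elif pos == k - 1:
                n_c += 1
            else:
                n_i += 1
            if null == "slots":
                exp[0] += 1.0 / k
                exp[1] += (k - 2) / k
                exp[2] += 1.0 / k
            elif null == "uniform":
                exp[0] += 1.0 / 3
                exp[1] += 1.0 / 3
                exp[2] += 1.0 / 3
            else:
                raise ValueError(f"unknown null {null!r}")
    total = n_n + n_i + n_c
    expectation = tuple(e / total for e in exp)
    return PositionalCounts(domain, n_n, n_i, n_c, expectation)


def positional_bias_test(counts: PositionalCounts) -> tuple[float, int, float]:
    """Pearson χ² of observed terminal/internal counts against the null
    expectation; returns (χ², df=2, p).  An expected count of zero with a
    nonzero observed count is an error (merge categories first)."""
    if counts.total < 1:
        raise ValueError("need at least one occurrence")
    observed = counts.observed
    expected = [counts.total * e for e in counts.slot_expectation]
    chi2 = 0.0
    for o, e in zip(observed, expected):
        if e == 0.0:
            if o:
                raise ValueError(
                    "expected count of 0 with nonzero observed count; "
                    "merge categories before testing"
                )
            continue
        chi2 += (o - e) ** 2 / e
    p = float(stats.chi2.sf(chi2, df=2))
    return chi2, 2, p


def positional_report(
    domains: Sequence[str], proteins: Sequence[Protein | Sequence[str]],
    null: str = "slots",
) -> list[dict]:
    """Per-domain TSV-ready rows: counts, χ² and p."""
    rows = []
    for dom in domains:
        counts = positional_counts(dom, proteins, null=null)
        chi2, df, p = positional_bias_test(counts)
        rows.append(
            {
                "domain": dom,
                "n_N": counts.n_nterm,
                "n_int": counts.n_internal,
                "n_C": counts.n_cterm,
                "chi2": chi2,
                "p": p,
            }
        )
    return rows


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def write_dot(graph: nx.DiGraph, path) -> None:
    """Minimal deterministic DOT export (weights as edge labels)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("digraph architectures {\n")
        for node in sorted(graph.nodes):
            fh.write(f'  "{node}";\n')
        for u, v in sorted(graph.edges):
            w = graph[u][v]["weight"]
            fh.write(f'  "{u}" -> "{v}" [label="{w:g}"];\n')
        fh.write("}\n")
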