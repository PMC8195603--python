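"""Hypergeometric enrichment of a system among trait-positive organisms.

The question: given that k organisms carry a system, and the background
contains m trait-positive (e.g. multicellular) and n trait-negative
organisms, is the number q of trait-positive carriers larger than chance?
The answer is the upper tail of the hypergeometric distribution,

    p = P(X ≥ q),   X ~ Hypergeometric(m, n, k),

the convention of R's ``phyper(q - 1, m, n, k, lower.tail = FALSE)`` — the
observed value is included, which is the conservative choice for an
enrichment test.  Only over-representation is tested.

Organisms whose trait is unknown (tri-state NA) are dropped from all four
counts before testing.  The tail is computed by exact summation in log space
(log-gamma binomials accumulated with logaddexp), which is stable out to
backgrounds of tens of thousands of organisms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .genome_model import TaxonRecord


@dataclass(frozen=True)
class EnrichmentInput:
    """The four counts of the test; unknown-trait organisms already excluded.

    q: trait-positive carriers; m: trait-positive background; n:
    trait-negative background; k: carriers.
    """

    q: int
    m: int
    n: int
    k: int

    def __post_init__(self):
        if min(self.q, self.m, self.n, self.k) < 0:
            raise ValueError("counts must be non-negative")
        if self.q > min(self.m, self.k):
            raise ValueError("q cannot exceed min(m, k)")
        if self.k > self.m + self.n:
            raise ValueError("k cannot exceed m + n")


def trait_counts(
    carrier_ids: Iterable[str],
    taxa: Sequence[TaxonRecord],
) -> tuple[EnrichmentInput, dict]:
    """Count q/m/n/k from carrier taxon ids and a taxon table.

    Unknown-trait taxa are excluded consistently from all counts; carriers
    absent from the table are an error listing the offending ids.  Returns
    the counts plus an audit record of what was excluded.
    """
    carriers = set(carrier_ids)
    if not carriers:
        raise ValueError("zero carriers: nothing to test")
    known = {t.taxon_id: t for t in taxa}
    missing = sorted(carriers - known.keys())
    if missing:
        raise ValueError(f"carrier taxa absent from taxon table: {missing}")

    m = sum(1 for t in taxa if t.multicellular is True)
    n = sum(1 for t in taxa if t.multicellular is False)
    unknown_background = sum(1 for t in taxa if t.multicellular is None)
    scored_carriers = [tid for tid in sorted(carriers) if known[tid].multicellular is not None]
    q = sum(1 for tid in scored_carriers if known[tid].multicellular is True)
    k = len(scored_carriers)
    audit = {
        "n_carriers_input": len(carriers),
        "n_carriers_unknown_trait_excluded": len(carriers) - k,
        "n_background_unknown_trait_excluded": unknown_background,
    }
    return EnrichmentInput(q=q, m=m, n=n, k=k), audit


def _log_pmf(m: int, n: int, k: int, j: np.ndarray) -> np.ndarray:
    """log P(X = j) for X ~ Hypergeometric(m, n, k), via log-gamma binomials."""
    j = np.asarray(j, dtype=np.float64)
    log_binom_m = gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)
    log_binom_n = gammaln(n + 1) - gammaln(k - j + 1) - gammaln(n - k + j + 1)
    log_binom_mn = gammaln(m + n + 1) - gammaln(k + 1) - gammaln(m + n - k + 1)
    return log_binom_m + log_binom_n - log_binom_mn


def hypergeom_upper_tail_all(m: int, n: int, k: int) -> np.ndarray:
    """P(X ≥ q) for every q in the support [max(0, k−n), min(m, k)].

    Computed as a reverse cumulative logaddexp over the log pmf, so the
    smallest tails never underflow before the sum.
    """
    EnrichmentInput(q=max(0, k - n), m=m, n=n, k=k)  # validate
    lo, hi = max(0, k - n), min(m, k)
    support = np.arange(lo, hi + 1)
    log_pmf = _log_pmf(m, n, k, support)
    log_tail = np.logaddexp.accumulate(log_pmf[::-1])[::-1]
    return np.exp(np.minimum(log_tail, 0.0))


def hypergeom_upper_tail(inp: EnrichmentInput) -> float:
    """p = P(X ≥ q); returns exactly 1.0 when q is at or below the support
    minimum (the whole support is included)."""
    lo = max(0, inp.k - inp.n)
    if inp.q <= lo:
        return 1.0
    tails = hypergeom_upper_tail_all(inp.m, inp.n, inp.k)
    return float(tails[inp.q - lo])


def enrichment_report(carrier_ids: Iterable[str], taxa: Sequence[TaxonRecord]) -> dict:
    """JSON-ready report: the four counts, the p-value and the audit record."""
    inp, audit = trait_counts(carrier_ids, taxa)
    return {
        "q": inp.q,
        "m": inp.m,
        "n": inp.n,
        "k": inp.k,
        "p_value": hypergeom_upper_tail(inp),
        **audit,
    }
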