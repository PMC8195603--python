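"""Polydomain score (PDS): flagging lineage-specific expansions per organism.

Given a count table c(o, p) of protein-family copy numbers over organisms O
and families P, each family gets a global log2 frequency

    f(p) = log2( Σ_o c(o, p) / Σ_q Σ_o c(o, q) )

and, with f̄ the unweighted mean of f(p) over families, each organism scores

    PD(o) = Σ_p c(o, p) · (f(p) − f̄).

An organism with many copies of families that are globally common (f > f̄)
scores high positive; concentration in globally rare families scores
negative.  Large |PD| marks organisms with expanded, architecturally diverse
repertoires.  Families with an all-zero column have no defined f(p) and are
dropped before scoring (their removal provably leaves every score unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class CountTable:
    """Organism × protein-family copy-number matrix (non-negative integers)."""

    organisms: list[str]
    families: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.organisms), len(self.families)):
            raise ValueError("counts shape must be (n_organisms, n_families)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.organisms, columns=self.families)

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        """Wide matrix TSV (first column = organism id) or long-format TSV
        with columns organism, family, count."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.columns) == ["family", "count"] or set(df.columns) == {"family", "count"}:
            df = df.reset_index()
            df.columns = ["organism", "family", "count"]
            wide = df.pivot_table(index="organism", columns="family", values="count",
                                  fill_value=0, aggfunc="sum")
            return cls.from_dataframe(wide.astype(np.int64))
        return cls.from_dataframe(df)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "organism"
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class PdsResult:
    """Per-organism scores with the family frequencies that produced them."""

    pd_scores: pd.Series  # organism -> PD(o)
    f: pd.Series  # family -> log2 frequency (≤ 0)
    f_bar: float


def family_frequencies(table: CountTable) -> tuple[pd.Series, float]:
    """f(p) = log2(column total / grand total) over families with nonzero
    totals, and the unweighted mean f̄; errors on an all-zero table."""
    counts = table.counts.astype(np.float64)
    col_totals = counts.sum(axis=0)
    keep = col_totals > 0
    if not keep.any():
        raise ValueError("count table has a zero grand total; PDS undefined")
    grand = col_totals[keep].sum()
    f = np.log2(col_totals[keep] / grand)
    families = [fam for fam, k in zip(table.families, keep) if k]
    series = pd.Series(f, index=families)
    return series, float(series.mean())


def compute_pds(table: CountTable) -> PdsResult:
    """PD(o) = Σ_p c(o, p)·(f(p) − f̄) after dropping all-zero family columns."""
    f, f_bar = family_frequencies(table)
    keep_idx = [j for j, fam in enumerate(table.families) if fam in f.index]
    counts = table.counts[:, keep_idx].astype(np.float64)
    scores = counts @ (f.to_numpy() - f_bar)
    return PdsResult(
        pd_scores=pd.Series(scores, index=table.organisms),
        f=f,
        f_bar=f_bar,
    )


def compute_pds_with_frequencies(
    counts: np.ndarray, organisms: Sequence[str], f: pd.Series, f_bar: float
) -> pd.Series:
    """PD(o) from externally supplied f(p)/f̄ (columns must match f's index
    order).  Useful for scoring new organisms against fixed background
    frequencies; with f held fixed, PD is linear in the count row."""
    counts = np.asarray(counts, dtype=np.float64)
    return pd.Series(counts @ (f.to_numpy() - f_bar), index=list(organisms))


def write_pds_tsv(result: PdsResult, path) -> None:
    """PD(o) sorted descending; ties broken by organism id for determinism."""
    df = result.pd_scores.rename("PD").rename_axis("organism").reset_index()
    df = df.sort_values(["PD", "organism"], ascending=[False, True])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_frequencies_tsv(result: PdsResult, path) -> None:
    df = result.f.rename("f").rename_axis("family").reset_index()
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
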