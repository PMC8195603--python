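"""Column-wise Shannon entropy of alignments and the mean-entropy contrast.

For one alignment column the entropy is H = −Σᵢ Pᵢ log₂ Pᵢ, where Pᵢ is the
fraction of (non-gap) residues of amino-acid type i and the sum runs over the
observed types; 0·log 0 ≡ 0, so a fully conserved column has H = 0 and a
uniform column over all 20 types has H = log₂ 20 ≈ 4.32 bits.

Rapidly diversifying protein families — a hallmark of biological conflict
systems — show elevated mean column entropy.  Two families are contrasted by
a two-sided Welch t-test on their per-column entropies, treating columns as
independent observations (a deliberate simplification; no phylogenetic
correction is applied).  Columns with more than ``max_gap_fraction`` gaps are
excluded before either computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .genome_model import Alignment

GAP_CHARS = frozenset("-.")

MAX_COLUMN_ENTROPY = math.log2(20.0)


def column_entropy(column: Iterable[str]) -> float:
    """Shannon entropy (bits) of one column; gaps are excluded from the
    denominator.  A column that is entirely gaps is undefined → ValueError."""
    residues = [c for c in column if c not in GAP_CHARS]
    if not residues:
        raise ValueError("column is entirely gaps; entropy undefined")
    n = len(residues)
    h = 0.0
    for count in _type_counts(residues).values():
        p = count / n
        h -= p * math.log2(p)
    return h


def _type_counts(residues: Sequence[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    return counts


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column entropies of one alignment after gap filtering."""

    alignment_id: str
    columns_used: tuple[int, ...]
    entropies: tuple[float, ...]

    def __post_init__(self):
        if len(self.columns_used) != len(self.entropies):
            raise ValueError("columns_used and entropies must align")
        for h in self.entropies:
            if not (0.0 <= h <= MAX_COLUMN_ENTROPY + 1e-12):
                raise ValueError(f"entropy {h} outside [0, log2 20]")

    def __len__(self) -> int:
        return len(self.entropies)

    @property
    def mean(self) -> float:
        return float(np.mean(self.entropies))


def entropy_profile(
    alignment: Alignment,
    max_gap_fraction: float = 0.5,
    alignment_id: str = "",
    column_mask: Optional[Sequence[int]] = None,
) -> EntropyProfile:
    """Entropy of every retained column (gap fraction ≤ ``max_gap_fraction``).

    ``column_mask`` optionally restricts the computation to the given column
    indices before gap filtering.  Raises if no column survives.
    """
    n_rows = len(alignment.rows)
    indices = range(alignment.n_columns) if column_mask is None else column_mask
    used: list[int] = []
    values: list[float] = []
    for i in indices:
        col = alignment.column(i)
        gap_fraction = sum(c in GAP_CHARS for c in col) / n_rows
        if gap_fraction > max_gap_fraction:
            continue
        used.append(i)
        values.append(column_entropy(col))
    if not used:
        raise ValueError("no columns retained after gap filtering")
    return EntropyProfile(alignment_id, tuple(used), tuple(values))


class MeanEntropyTest(NamedTuple):
    t: float
    p: float
    mean_a: float
    mean_b: float


def mean_entropy_test(profile_a: EntropyProfile, profile_b: EntropyProfile) -> MeanEntropyTest:
    """Two-sided Welch t-test on per-column entropies of two profiles.

    When both profiles have zero variance the statistic degenerates: equal
    means give (t=0, p=1), different means (t=±inf, p=0).
    """
    if len(profile_a) < 2 or len(profile_b) < 2:
        raise ValueError("both profiles need at least 2 columns")
    a = np.asarray(profile_a.entropies)
    b = np.asarray(profile_b.entropies)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if mean_a == mean_b:
            return MeanEntropyTest(0.0, 1.0, mean_a, mean_b)
        t = math.inf if mean_a > mean_b else -math.inf
        return MeanEntropyTest(t, 0.0, mean_a, mean_b)
    res = stats.ttest_ind(a, b, equal_var=False)
    return MeanEntropyTest(float(res.statistic), float(res.pvalue), mean_a, mean_b)


def write_entropy_tsv(profile: EntropyProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("column_index\tentropy\n")
        for i, h in zip(profile.columns_used, profile.entropies):
            fh.write(f"{i}\t{h:.6f}\n")
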