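"""Z-score matrices, Z→distance conversion, and UPGMA trees.

Structure-similarity searches report pairwise Z-scores; a hierarchical
picture of structural relationships is obtained by converting those to a
distance matrix and applying average-linkage (UPGMA) clustering.  The
conversion used here is d(i, j) = Z_max − z(i, j) with Z_max the largest
off-diagonal Z-score (so the most similar pair sits at distance 0); the
reciprocal transform d = 1/z is available because the two can disagree on
tree topology.  Z-scores may optionally be normalized by the self-Z values
first (z / sqrt(z_ii · z_jj)).

UPGMA merges the closest pair of clusters at height d/2, replacing distances
by leaf-count-weighted arithmetic means; ties are broken by the
lexicographically smallest (smallest-member, smallest-member) label pair, so
the tree is deterministic and independent of input order.  The result is
ultrametric by construction and serializes to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ZMatrix:
    """Symmetric pairwise Z-scores with self-Z on the diagonal."""

    labels: tuple[str, ...]
    z: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z, dtype=np.float64)
        n = len(self.labels)
        if z.shape != (n, n):
            raise ValueError("z must be square and match labels")
        if not np.allclose(z, z.T, atol=1e-9):
            raise ValueError("z must be symmetric (tolerance 1e-9)")
        diag = np.diag(z)
        off = z - np.diag(diag)
        for i in range(n):
            for j in range(n):
                if i != j and z[i, j] > min(diag[i], diag[j]) + 1e-9:
                    raise ValueError(
                        f"off-diagonal Z({self.labels[i]},{self.labels[j]}) exceeds self-Z"
                    )
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def read_tsv(cls, path) -> "ZMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("Z-matrix TSV must have identical row/column labels")
        return cls(tuple(df.index.astype(str)), df.to_numpy(dtype=np.float64))

    def normalized(self) -> "ZMatrix":
        """Scale by self-Z: z'_ij = z_ij / sqrt(z_ii z_jj); diagonal becomes 1."""
        d = np.sqrt(np.diag(self.z))
        if (d <= 0).any():
            raise ValueError("self-Z must be positive to normalize")
        return ZMatrix(self.labels, self.z / np.outer(d, d))


def zscores_to_distance(zmatrix: ZMatrix, transform: str = "zmax") -> np.ndarray:
    """Distance matrix from Z-scores: ``"zmax"`` → d = Z_max − z (the pair
    with the largest Z lands at 0), ``"reciprocal"`` → d = 1/z."""
    n = len(zmatrix.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    z = zmatrix.z
    off_mask = ~np.eye(n, dtype=bool)
    if transform == "zmax":
        d = z[off_mask].max() - z
    elif transform == "reciprocal":
        if (z[off_mask] <= 0).any():
            raise ValueError("reciprocal transform requires positive Z-scores")
        d = 1.0 / z
    else:
        raise ValueError(f"unknown transform {transform!r}")
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return (d + d.T) / 2.0


@dataclass
class TreeNode:
    """A rooted ultrametric tree node; ``height`` is the merge height (leaves
    sit at height 0) and edges to children carry ``height − child.height``."""

    name: Optional[str] = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        return [leaf for child in self.children for leaf in child.leaves()]

    def leaf_depths(self, depth: float = 0.0) -> dict[str, float]:
        """Root-to-leaf path lengths (equal for an ultrametric tree)."""
        if self.is_leaf:
            return {self.name or "": depth}
        out: dict[str, float] = {}
        for child in self.children:
            out.update(child.leaf_depths(depth + (self.height - child.height)))
        return out

    def cophenetic(self) -> dict[frozenset[str], float]:
        """Pairwise cophenetic distances (2 × merge height of the LCA)."""
        out: dict[frozenset[str], float] = {}

        def visit(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.name or ""]
            groups = [visit(c) for c in node.children]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a in groups[i]:
                        for b in groups[j]:
                            out[frozenset((a, b))] = 2.0 * node.height
            return [leaf for g in groups for leaf in g]

        visit(self)
        return out

    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: TreeNode, parent_height: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                parts = [fmt(c, node.height) for c in node.children]
                body = "(" + ",".join(parts) + ")"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - node.height:.{precision}g}"

        return fmt(self, None) + ";"


def upgma(distance_matrix: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Average-linkage agglomeration of a symmetric non-negative distance
    matrix with zero diagonal; merge heights are d/2, ties broken by the
    lexicographically smallest pair of smallest member labels."""
    d = np.asarray(distance_matrix, dtype=np.float64)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix must match labels")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if (d < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(d, d.T, atol=1e-9) or not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 2:
        raise ValueError("need at least 2 labels")

    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    sizes: dict[str, int] = {lab: 1 for lab in labels}
    dist: dict[frozenset[str], float] = {}
    active = sorted(str(lab) for lab in labels)
    if len(set(active)) != n:
        raise ValueError("labels must be unique")
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((str(labels[i]), str(labels[j])))] = float(d[i, j])

    while len(active) > 1:
        best: Optional[tuple[float, str, str]] = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                dij = dist[frozenset((a, b))]
                cand = (dij, a, b)  # active is sorted, so (a, b) is the lexicographic key
                if best is None or cand < best:
                    best = cand
        dij, a, b = best
        height = dij / 2.0
        merged = TreeNode(height=height, children=[nodes[a], nodes[b]])
        key = min(a, b)  # cluster inherits its smallest member's label as key
        size = sizes[a] + sizes[b]
        for other in active:
            if other in (a, b):
                continue
            new_d = (
                sizes[a] * dist[frozenset((a, other))]
                + sizes[b] * dist[frozenset((b, other))]
            ) / size
            dist[frozenset((key, other))] = new_d
        active = sorted(x for x in active if x not in (a, b)) + [key]
        active.sort()
        nodes[key] = merged
        sizes[key] = size
    root = nodes[active[0]]
    return root


def zscore_tree(zmatrix: ZMatrix, transform: str = "zmax",
                normalize: bool = False) -> TreeNode:
    """Convenience: normalize (optionally), convert to distances, run UPGMA."""
    zm = zmatrix.normalized() if normalize else zmatrix
    d = zscores_to_distance(zm, transform=transform)
    return upgma(d, zm.labels)
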