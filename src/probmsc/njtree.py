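"""Neighbor-Joining phylogeny from the normalized divergence matrix.

Standard Saitou-Nei agglomeration with the Studier-Keppler Q-matrix.  Ties in
the Q minimization are broken deterministically by the lowest (row, col)
index pair so that repeated runs and bootstrap replicates are reproducible.
Negative branch lengths (a known NJ artifact on noisy matrices) are clamped
to zero with the deficit moved to the adjacent branch.

Support values come from a site bootstrap: divergent sites are resampled
with replacement, the divergence matrix and NJ tree are rebuilt, and each
internal edge of the full-data tree is annotated with the percentage of
replicates in which its bipartition reappears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .sites import DivergentSiteTable

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    """Node of an (unrooted, represented rooted-at-trifurcation) phylogeny."""

    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, include_support: bool = True) -> str:
        return self._newick(include_support) + ";"

    def _newick(self, include_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick(include_support) for c in self.children)
        label = ""
        if include_support and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class PhyloTree:
    """Unrooted tree over the study taxa with lengths and bootstrap support."""

    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def newick(self, include_support: bool = True) -> str:
        return self.root.newick(include_support)

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each canonicalized as the side *not*
        containing the alphabetically first leaf."""
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = all_leaves - below if anchor in below else below
                out.add(side)
            return below

        walk(self.root)
        return out

    def path_lengths(self) -> dict[frozenset[str], float]:
        """Leaf-to-leaf path lengths (for additivity checks)."""
        dists: dict[frozenset[str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: node.length}
            sub = [walk(c) for c in node.children]
            for d1, d2 in combinations(sub, 2):
                for a, da in d1.items():
                    for b, db in d2.items():
                        dists[frozenset((a, b))] = da + db
            merged: dict[str, float] = {}
            for d in sub:
                for a, da in d.items():
                    merged[a] = da + node.length
            return merged

        walk(self.root)
        return dists

    def annotate_support(self, support: dict[frozenset[str], float]) -> None:
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = all_leaves - below if anchor in below else below
                if side in support:
                    node.support = support[side]
            return below

        walk(self.root)


def _validate_matrix(matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    labels = list(matrix.index)
    if list(matrix.columns) != labels:
        raise ValueError("distance matrix rows and columns must match")
    d = matrix.to_numpy(dtype=float)
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    return labels, d.copy()


def _clamp(length: float, sibling: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to the sibling."""
    if length < 0:
        logger.debug("clamping negative NJ branch %.3g", length)
        return 0.0, sibling + length
    return length, sibling


def nj(matrix: pd.DataFrame) -> PhyloTree:
    """Saitou-Nei Neighbor Joining with deterministic lowest-index tie-break."""
    labels, d = _validate_matrix(matrix)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best: tuple[int, int] | None = None
        best_q = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best  # type: ignore[misc]
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li, lj)
        lj, li = _clamp(lj, li)
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = np.zeros((n - 1, n - 1))
        keep = [k for k in range(n) if k not in (i, j)]
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                new_d[a, b] = d[ka, kb]
            new_d[a, n - 2] = new_d[n - 2, a] = (d[i, ka] + d[j, ka] - d[i, j]) / 2.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = new_d
    # terminal three-point join
    (a, b, c), dd = nodes, d
    la = (dd[0, 1] + dd[0, 2] - dd[1, 2]) / 2.0
    lb = dd[0, 1] - la
    lc = dd[0, 2] - la
    for node, l in zip((a, b, c), (max(la, 0.0), max(lb, 0.0), max(lc, 0.0))):
        node.length = l
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root=root)


def bootstrap_support(
    table: DivergentSiteTable,
    replicates: int = 10000,
    seed: int | None = None,
    include_outgroup: bool = True,
) -> PhyloTree:
    """Site bootstrap around the NJ tree of the full divergence matrix.

    Sites are resampled with replacement; per-edge support is the percentage
    of replicates whose NJ tree contains the same bipartition.
    """
    from .divergence import divergence_matrix  # local import to avoid a cycle

    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    full = nj(divergence_matrix(table, with_uncertainty=False)
              .distance_frame(include_outgroup))
    counts: dict[frozenset[str], int] = {s: 0 for s in full.splits()}
    rng = np.random.default_rng(seed)
    n = len(table.df)
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        sub = DivergentSiteTable(table.df.iloc[idx].reset_index(drop=True),
                                 polarized=table.polarized)
        try:
            rep = nj(divergence_matrix(sub, with_uncertainty=False)
                     .distance_frame(include_outgroup))
        except ValueError:
            continue  # degenerate resample (e.g. zero normalizer)
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    support = {s: 100.0 * c / replicates for s, c in counts.items()}
    full.annotate_support(support)
    return full
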