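"""Subtype phylogeny: average-linkage (UPGMA) agglomeration of 1 - rho.

The between-subtype similarity (median Spearman correlation) is turned
into a dissimilarity ``D = 1 - rho`` (range [0, 2], diagonal forced to 0)
and agglomerated by unweighted average linkage: at every step the pair of
clusters with the smallest mean leaf-pair distance merges at exactly that
mean. Ties on the minimum distance are broken by the lexicographically
smallest pair of cluster labels, a cluster's label being the smallest leaf
label it contains — this makes the topology reproducible where generic
implementations depend on input order. Merge heights never decrease, so
the dendrogram is ultrametric and exports cleanly to rooted Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import PipelineError
from .correlation import SubtypeSimilarity


@dataclass
class SubtypeTree:
    """Rooted binary merge tree in scipy node numbering.

    ``leaves[i]`` is leaf node ``i``; merge step ``s`` creates internal
    node ``len(leaves) + s`` from nodes ``merges[s][0]`` and
    ``merges[s][1]`` at height ``merges[s][2]``.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Leaf labels under every node id."""
        n = len(self.leaves)
        out: dict[int, frozenset[str]] = {
            i: frozenset([lbl]) for i, lbl in enumerate(self.leaves)
        }
        for s, (a, b, _h) in enumerate(self.merges):
            out[n + s] = out[a] | out[b]
        return out


def to_dissimilarity(similarity: SubtypeSimilarity | np.ndarray) -> np.ndarray:
    """D = 1 - median_rho, diagonal forced to zero for clustering."""
    rho = (
        similarity.median_rho
        if isinstance(similarity, SubtypeSimilarity)
        else np.asarray(similarity, dtype=float)
    )
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    return D


def average_linkage(D: np.ndarray, labels: Sequence[str]) -> SubtypeTree:
    """UPGMA agglomeration with deterministic label tie-breaking.

    ``D`` must be symmetric with a zero diagonal and finite entries.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise PipelineError("dissimilarity shape does not match labels")
    if not np.isfinite(D).all():
        raise PipelineError("non-finite dissimilarity entries")
    if not np.allclose(D, D.T):
        raise PipelineError("dissimilarity matrix is not symmetric")
    if n == 1:
        return SubtypeTree([str(labels[0])], [])

    total = 2 * n - 1
    dist = np.full((total, total), np.inf)
    dist[:n, :n] = D
    np.fill_diagonal(dist, np.inf)
    size = np.zeros(total, dtype=int)
    size[:n] = 1
    minlab = [str(l) for l in labels] + [""] * (n - 1)
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        # minimum over active pairs, ties broken by smallest (label, label)
        act = np.asarray(active)
        sub = dist[np.ix_(act, act)]
        iu = np.triu_indices(len(act), k=1)
        vals = sub[iu]
        dmin = vals.min()
        cand = np.nonzero(vals == dmin)[0]
        best_key = None
        best = None
        for c in cand:
            a, b = int(act[iu[0][c]]), int(act[iu[1][c]])
            la, lb = sorted((minlab[a], minlab[b]))
            key = (la, lb)
            if best_key is None or key < best_key:
                best_key = key
                best = (a, b)
        a, b = best  # type: ignore[misc]
        h = float(dist[a, b])
        left, right = (a, b) if minlab[a] <= minlab[b] else (b, a)
        new = n + step
        # unweighted average linkage (Lance-Williams)
        for c in active:
            if c in (a, b):
                continue
            dist[new, c] = dist[c, new] = (
                size[a] * dist[a, c] + size[b] * dist[b, c]
            ) / (size[a] + size[b])
        size[new] = size[a] + size[b]
        minlab[new] = min(minlab[a], minlab[b])
        active = [c for c in active if c not in (a, b)] + [new]
        merges.append((left, right, h))
    return SubtypeTree([str(l) for l in labels], merges)


def merge_table(tree: SubtypeTree) -> list[dict]:
    """Flat merge records for TSV export."""
    sets = tree.leaf_sets()
    n = len(tree.leaves)
    rows = []
    for s, (a, b, h) in enumerate(tree.merges):
        rows.append(
            {
                "step": s,
                "node": n + s,
                "left": a,
                "right": b,
                "height": h,
                "left_leaves": ",".join(sorted(sets[a])),
                "right_leaves": ",".join(sorted(sets[b])),
            }
        )
    return rows
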