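"""Clustering of sequences by modular profile.

Each sequence is described by a vector of module occurrence counters.
Without the reverse option the matrix has one attribute per module; with
it, three: direct count ``Mi``, reverse count ``rMi`` and total
``Mi|rMi``.  A truncated occurrence contributes its conserved fraction
instead of 1 (to its orientation counter and to the total).

Sequences are then agglomerated under the Ward criterion.  The pairwise
loss of inertia is

    delta(x, y) = (1 / 2n) * sum_i (x_i - y_i)^2

with n the number of sequences, clusters start at weight 1/n, weights are
additive, and merged distances follow the Lance-Williams recurrence

    delta(xUy, z) = ((nx+nz) d(x,z) + (ny+nz) d(y,z) - nz d(x,y)) / (nx+ny+nz).

The 1/(2n) scaling is a global constant: it scales heights, not topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from temodules.detection import ModuleCatalog


@dataclass
class IncidenceMatrix:
    """Sequences x module-attributes matrix of fractional counts."""

    sequence_ids: tuple[str, ...]
    columns: tuple[str, ...]
    values: np.ndarray  # shape (n_sequences, n_columns)

    def row(self, i: int) -> np.ndarray:
        return self.values[i]

    def to_tsv(self) -> str:
        lines = ["sequence_id\t" + "\t".join(self.columns)]
        for rid, row in zip(self.sequence_ids, self.values):
            lines.append(rid + "\t" + "\t".join(f"{v:.4f}" for v in row))
        return "\n".join(lines) + "\n"


def build_incidence_matrix(
    catalog: ModuleCatalog,
    reverse_option: bool = False,
    truncated_option: bool = False,
) -> IncidenceMatrix:
    """Counters per sequence and module attribute.

    Full occurrences count 1, truncated occurrences their conserved
    fraction.  With ``reverse_option`` each module gets three attributes
    (direct, reverse, total); otherwise one counter of all occurrences.
    """
    n = catalog.family.n
    ids = catalog.family.ids
    cols: list[str] = []
    for mod in catalog.modules:
        if reverse_option:
            cols += [f"M{mod.id}", f"rM{mod.id}", f"M{mod.id}|rM{mod.id}"]
        else:
            cols.append(f"M{mod.id}")
    values = np.zeros((n, len(cols)), dtype=float)
    for mi, mod in enumerate(catalog.modules):
        for occ in mod.occurrences:
            if not truncated_option and occ.kind.startswith("truncated"):
                continue
            w = occ.conserved_fraction
            if reverse_option:
                base = 3 * mi
                if occ.kind in ("direct", "truncated_direct"):
                    values[occ.seq_index, base] += w
                else:
                    values[occ.seq_index, base + 1] += w
                values[occ.seq_index, base + 2] += w
            else:
                values[occ.seq_index, mi] += w
    return IncidenceMatrix(ids, tuple(cols), values)


def ward_delta(x: Sequence[float], y: Sequence[float], n: int) -> float:
    """Loss of inertia for aggregating two sequences: (1/2n) sum (xi-yi)^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("attribute vectors must have equal length")
    return float(np.sum((x - y) ** 2) / (2.0 * n))


@dataclass
class ClusterNode:
    """Node of the binary merge tree; leaves carry the sequence index."""

    height: float
    weight: float
    leaf: Optional[int] = None
    children: Optional[tuple["ClusterNode", "ClusterNode"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.leaf]
        out = []
        for c in self.children:
            out += c.leaves()
        return out


@dataclass
class ClusterTree:
    """Binary merge tree over the family's sequences with Ward heights."""

    root: ClusterNode
    sequence_ids: tuple[str, ...]
    merges: list[tuple[frozenset, frozenset, float]] = field(default_factory=list)

    def leaf_order(self) -> list[int]:
        return self.root.leaves()


def hac_ward(matrix: IncidenceMatrix) -> ClusterTree:
    """Hierarchical agglomerative clustering under the Ward criterion.

    Iteratively merges the minimum-delta pair, breaking ties toward the
    pair with the lowest smallest leaf index (then lowest second index),
    updating merged distances with the Lance-Williams recurrence until a
    single cluster remains.
    """
    n = len(matrix.sequence_ids)
    if n == 0:
        raise ValueError("empty matrix")
    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(0.0, 1.0 / n, leaf=i) for i in range(n)
    }
    min_leaf = {i: i for i in range(n)}
    merges: list[tuple[frozenset, frozenset, float]] = []
    if n == 1:
        return ClusterTree(nodes[0], matrix.sequence_ids, merges)

    delta: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            delta[(i, j)] = ward_delta(matrix.values[i], matrix.values[j], n)

    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            (
                (delta[(min(a, b), max(a, b))],
                 min(min_leaf[a], min_leaf[b]),
                 max(min_leaf[a], min_leaf[b]),
                 min(a, b), max(a, b))
                for a in active
                for b in active
                if a < b
            ),
        )
        d, _, _, a, b = best
        na, nb = nodes[a], nodes[b]
        merged = ClusterNode(d, na.weight + nb.weight, children=(na, nb))
        merges.append(
            (frozenset(na.leaves()), frozenset(nb.leaves()), d)
        )
        nodes[next_id] = merged
        min_leaf[next_id] = min(min_leaf[a], min_leaf[b])
        active.discard(a)
        active.discard(b)
        wa, wb = na.weight, nb.weight
        for z in active:
            wz = nodes[z].weight
            daz = delta[(min(a, z), max(a, z))]
            dbz = delta[(min(b, z), max(b, z))]
            dab = d
            dnew = ((wa + wz) * daz + (wb + wz) * dbz - wz * dab) / (wa + wb + wz)
            delta[(min(next_id, z), max(next_id, z))] = dnew
        active.add(next_id)
        next_id += 1

    return ClusterTree(nodes[next_id - 1], matrix.sequence_ids, merges)


def _newick_label(label: str) -> str:
    if any(ch in label for ch in " ():;,[]'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: ClusterNode, ids: tuple[str, ...]) -> str:
    if node.is_leaf:
        return _newick_label(ids[node.leaf])
    parts = []
    for child in node.children:
        bl = max(node.height - child.height, 0.0)
        parts.append(f"{_newick_node(child, ids)}:{bl:.6g}")
    return "(" + ",".join(parts) + ")"


def newick_string(tree: ClusterTree) -> str:
    """Serialize the tree: leaf labels are sequence ids, branch lengths
    are differences of Ward merge heights."""
    return _newick_node(tree.root, tree.sequence_ids) + ";"


def write_newick(tree: ClusterTree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")
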