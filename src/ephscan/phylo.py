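"""Distance-based lineage-expansion phylogenetics.

Kimura-corrected protein distances on profile-anchored domain alignments,
canonical neighbor-joining (Saitou–Nei) tree construction, and detection of
lineage-specific expansions — maximal clades whose leaves all belong to one
lineage, the topological signature of post-divergence gene duplications.
Trees serialize as Newick via scikit-bio and round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import io
import warnings

import numpy as np
import pandas as pd
from skbio import TreeNode

from ephscan.profilehmm import Alignment

#: distance cap: the Kimura correction diverges as p -> ~0.854
P_CAP = 0.85
D_MAX = -float(np.log(1.0 - P_CAP - 0.2 * P_CAP * P_CAP))


class UndefinedDistanceError(ValueError):
    """No co-ungapped column between two aligned rows."""


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self):
        d = self.data
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


def protein_distance(row_a: str, row_b: str) -> float:
    """Kimura-corrected distance between two aligned rows:
    d = -ln(1 - p - 0.2 p^2) with p the mismatch fraction over co-ungapped
    columns; p >= 0.85 is capped at d_max."""
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    pairs = [
        (a, b) for a, b in zip(row_a.upper(), row_b.upper()) if a != "-" and b != "-"
    ]
    if not pairs:
        raise UndefinedDistanceError("no co-ungapped column")
    p = sum(a != b for a, b in pairs) / len(pairs)
    if p >= P_CAP:
        return D_MAX
    return -float(np.log(1.0 - p - 0.2 * p * p))


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    ids = tuple(rid for rid, _ in alignment.rows)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = protein_distance(
                alignment.rows[i][1], alignment.rows[j][1]
            )
    return DistanceMatrix(ids=ids, data=d)


def _pair_key(ids: list[str], i: int, j: int) -> tuple[str, str]:
    a, b = ids[i], ids[j]
    return (a, b) if a <= b else (b, a)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining (Saitou–Nei Q-criterion).

    Ties in Q are broken by the lexicographically smallest id pair; negative
    branch lengths are clamped to zero with the deficit moved to the sibling
    branch. Returns an unrooted tree represented with a trifurcating root.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    ids = list(matrix.ids)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    # tie-break key per working node: the smallest leaf label in its clade
    keys = list(ids)
    D = matrix.data.astype(float).copy()

    while len(ids) > 3:
        m = len(ids)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                kk = tuple(sorted((keys[i], keys[j])))
                cand = (q, kk, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _q, _kk, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        newd = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newd[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        ids = [ids[k] for k in keep] + [f"__internal_{len(ids)}"]

    # final trifurcation: three-point formulas
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, 0.5 * (d01 + d02 - d12))
    l1 = max(0.0, 0.5 * (d01 + d12 - d02))
    l2 = max(0.0, 0.5 * (d02 + d12 - d01))
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = float(ln)
    return TreeNode(children=nodes)


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def from_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")


def _bipartition_sides(tree: TreeNode) -> set[frozenset[str]]:
    all_leaves = frozenset(t.name for t in tree.tips())
    sides: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        s = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        if s and s != all_leaves:
            sides.add(s)
            sides.add(all_leaves - s)
    return sides


def detect_expansions(
    tree: TreeNode,
    lineage_map: dict[str, str],
    min_clade_size: int = 3,
) -> list[tuple[str, tuple[str, ...]]]:
    """Maximal single-lineage clades (bipartition sides) with at least
    min_clade_size leaves. min_clade_size=1 degenerately reports every leaf
    that is not inside a larger pure clade."""
    leaves = [t.name for t in tree.tips()]
    for name in leaves:
        if name not in lineage_map:
            raise KeyError(f"leaf {name!r} has no lineage label")
    pure = []
    for side in _bipartition_sides(tree):
        lins = {lineage_map[x] for x in side}
        if len(lins) == 1 and len(side) >= min_clade_size:
            pure.append((next(iter(lins)), side))
    maximal = [
        (lin, side)
        for lin, side in pure
        if not any(side < other for _l, other in pure)
    ]
    return sorted((lin, tuple(sorted(side))) for lin, side in maximal)


def compare_domain_trees(
    tree_lbd: TreeNode,
    tree_kinase: TreeNode,
    lineage_map: dict[str, str],
    min_clade_size: int = 3,
) -> pd.DataFrame:
    """Per-lineage expansion counts for two domain trees side by side
    (the receptor LBD tree versus the kinase tree). Leaf sets are
    intersected (with a warning) when they differ; an empty intersection
    is an error."""
    leaves_a = {t.name for t in tree_lbd.tips()}
    leaves_b = {t.name for t in tree_kinase.tips()}
    shared = leaves_a & leaves_b
    if not shared:
        raise ValueError("the two trees share no leaves")
    ta, tb = tree_lbd, tree_kinase
    if shared != leaves_a or shared != leaves_b:
        warnings.warn("leaf sets differ; intersecting on shared ids")
        ta = tree_lbd.shear(sorted(shared))
        tb = tree_kinase.shear(sorted(shared))
    exp_a = detect_expansions(ta, lineage_map, min_clade_size)
    exp_b = detect_expansions(tb, lineage_map, min_clade_size)
    lineages = sorted({lineage_map[x] for x in shared})
    out = pd.DataFrame(
        {
            "lbd": [sum(1 for lin, _ in exp_a if lin == L) for L in lineages],
            "kinase": [sum(1 for lin, _ in exp_b if lin == L) for L in lineages],
        },
        index=lineages,
    )
    out.index.name = "lineage"
    return out
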