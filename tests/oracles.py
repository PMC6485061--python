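"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration (paths,
alignments, subsets) and is deliberately independent of the implementation
paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from ephscan.seqs import AA_INDEX


def enumerate_path_scores(prof, seq: str) -> np.ndarray:
    """Log2-odds scores of every legal glocal path of a profile against a
    sequence (model traversed begin-to-end, flanks free, >=1 match emission).

    Feasible only for tiny models (M <= 3) and sequences (len <= 5).
    """
    M, L = prof.M, len(seq)
    lg = np.log2
    me = lg(prof.match_emissions) - lg(prof.background)
    scores: list[float] = []

    def ext(j: int, i: int, sc: float, last: str) -> None:
        if last in ("M", "D") and j == M - 1:
            scores.append(sc)
        if last == "M" and j < M - 1:
            if i < L:
                ext(j + 1, i + 1, sc + lg(prof.t_mm[j]) + me[j + 1, AA_INDEX[seq[i]]], "M")
                ext(j, i + 1, sc + lg(prof.t_mi[j]), "I")
            ext(j + 1, i, sc + lg(prof.t_md[j]), "D")
        elif last == "I" and j < M - 1:
            if i < L:
                ext(j + 1, i + 1, sc + lg(prof.t_im[j]) + me[j + 1, AA_INDEX[seq[i]]], "M")
                ext(j, i + 1, sc + lg(prof.t_ii[j]), "I")
        elif last == "D" and j < M - 1:
            if i < L:
                ext(j + 1, i + 1, sc + lg(prof.t_dm[j]) + me[j + 1, AA_INDEX[seq[i]]], "M")
            ext(j + 1, i, sc + lg(prof.t_dd[j]), "D")

    for start in range(L):
        ext(0, start + 1, lg(prof.begin[0]) + me[0, AA_INDEX[seq[start]]], "M")
        for j in range(1, M):
            e = lg(prof.begin[1])
            for k in range(j - 1):
                e += lg(prof.t_dd[k])
            e += lg(prof.t_dm[j - 1])
            ext(j, start + 1, e + me[j, AA_INDEX[seq[start]]], "M")
    return np.array(scores)


def enumerate_global_alignments(a: str, b: str):
    """All global alignments of two short strings as (aligned_a, aligned_b)."""
    out = []

    def ext(i, j, ra, rb):
        if i == len(a) and j == len(b):
            out.append((ra, rb))
            return
        if i < len(a) and j < len(b):
            ext(i + 1, j + 1, ra + a[i], rb + b[j])
        if i < len(a):
            ext(i + 1, j, ra + a[i], rb + "-")
        if j < len(b):
            ext(i, j + 1, ra + "-", rb + b[j])

    ext(0, 0, "", "")
    return out


def best_alignment_identities(a: str, b: str) -> set[float]:
    """Identity fractions of every score-optimal global alignment
    (match 1, mismatch 0, linear gap -1)."""
    best_score = None
    idents: set[float] = set()
    for ra, rb in enumerate_global_alignments(a, b):
        score = matches = 0
        for x, y in zip(ra, rb):
            if x == "-" or y == "-":
                score -= 1
            elif x == y:
                score += 1
                matches += 1
        if best_score is None or score > best_score:
            best_score = score
            idents = {matches / len(ra)}
        elif score == best_score:
            idents.add(matches / len(ra))
    return idents


def greedy_cluster_oracle(ids, seqs, identity_matrix, threshold):
    """Greedy incremental clustering computed from a precomputed identity
    matrix: longest first (ties by id), join first representative above
    threshold."""
    order = sorted(range(len(ids)), key=lambda k: (-len(seqs[k]), ids[k]))
    reps: list[int] = []
    clusters: dict[int, list[int]] = {}
    for k in order:
        for r in reps:
            if identity_matrix[k][r] >= threshold:
                clusters[r].append(k)
                break
        else:
            reps.append(k)
            clusters[k] = []
    return [(ids[r], tuple(ids[m] for m in clusters[r])) for r in reps]


def resolve_overlaps_oracle(hits, tolerance=0.10):
    """Independent re-statement of greedy overlap resolution: process hits in
    priority order (E, -bits, start, profile) and keep each iff compatible
    with everything already kept."""
    order = sorted(hits, key=lambda h: (h.evalue, -h.bits, h.start, h.profile))
    kept = []
    for h in order:
        compatible = True
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start) + 1
            if ov > tolerance * min(h.end - h.start + 1, k.end - k.start + 1):
                compatible = False
        if compatible:
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def unrooted_bipartitions(tree) -> set:
    """Non-trivial unrooted bipartitions of a tree as frozensets of both sides."""
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset((side, leaves - side)))
    return out


def random_additive_tree(n: int, rng: np.random.Generator):
    """A random binary tree with branch lengths in [0.1, 1) and its exact
    leaf-to-leaf distance matrix."""
    import skbio

    ids = [f"t{i}" for i in range(n)]
    nodes = [skbio.TreeNode(name=i) for i in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        nodes[i].length = float(rng.uniform(0.1, 1.0))
        nodes[j].length = float(rng.uniform(0.1, 1.0))
        parent = skbio.TreeNode(children=[nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    tree = nodes[0]
    D = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        D[a, b] = D[b, a] = tree.find(ids[a]).distance(tree.find(ids[b]))
    return tree, tuple(ids), D
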