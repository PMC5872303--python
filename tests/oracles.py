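"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: alignment scoring is a
plain-Python Gotoh recurrence, p-distance is a column-counting loop, and
additive trees are built/measured with explicit path enumeration.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Score-only affine-gap global alignment (three-state DP)."""
    la, lb = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def count_p_distance(row_a: str, row_b: str) -> float:
    """p-distance by explicit column counting."""
    assert len(row_a) == len(row_b)
    diff = 0
    for x, y in zip(row_a, row_b):
        if x != y:
            diff += 1
    return diff / len(row_a)


# ---------------------------------------------------------------------------
# random additive trees

class _Node:
    def __init__(self, name=None):
        self.name = name
        self.edges = []  # (neighbor, length)


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree with strictly positive branch lengths.

    Returns (leaf names, distance matrix, set of non-trivial bipartitions).
    Distances are exact path sums, so the matrix is additive by
    construction.
    """
    names = [f"T{i}" for i in range(n_leaves)]
    nodes = [_Node(nm) for nm in names]

    def link(u, v, length):
        u.edges.append((v, length))
        v.edges.append((u, length))

    # random sequential joining of subtrees until one remains
    subtrees = list(nodes)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        parent = _Node()
        link(parent, subtrees[i], float(rng.uniform(0.05, 1.0)))
        link(parent, subtrees[j], float(rng.uniform(0.05, 1.0)))
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(parent)

    # path lengths by BFS from every leaf
    d = np.zeros((n_leaves, n_leaves))
    index = {nm: k for k, nm in enumerate(names)}
    for leaf in nodes:
        dist = {id(leaf): 0.0}
        stack = [leaf]
        while stack:
            cur = stack.pop()
            for nb, ln in cur.edges:
                if id(nb) not in dist:
                    dist[id(nb)] = dist[id(cur)] + ln
                    stack.append(nb)
        for other in nodes:
            d[index[leaf.name], index[other.name]] = dist[id(other)]
    d = (d + d.T) / 2.0  # exact symmetry despite float summation order

    # bipartitions: for every internal edge, leaves on one side
    all_names = frozenset(names)
    anchor = min(all_names)
    biparts = set()
    seen_edges = set()
    every_node = _collect(subtrees[0])
    for u in every_node:
        for v, _ln in u.edges:
            key = frozenset((id(u), id(v)))
            if key in seen_edges:
                continue
            seen_edges.add(key)
            side = frozenset(_leaves_beyond(v, u))
            if anchor in side:
                side = all_names - side
            if 2 <= len(side) <= n_leaves - 2:
                biparts.add(side)
    return names, d, biparts


def _collect(start):
    out, stack, seen = [], [start], set()
    while stack:
        cur = stack.pop()
        if id(cur) in seen:
            continue
        seen.add(id(cur))
        out.append(cur)
        stack.extend(nb for nb, _ in cur.edges)
    return out


def _leaves_beyond(node, parent):
    out, stack, seen = [], [(node, parent)], set()
    while stack:
        cur, par = stack.pop()
        seen.add(id(cur))
        if cur.name is not None:
            out.append(cur.name)
        for nb, _ in cur.edges:
            if nb is not par and id(nb) not in seen:
                stack.append((nb, cur))
    return out
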