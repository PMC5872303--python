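"""Distance phylogenetics of LuxR homolog proteins.

The tree-building path mirrors the classic MEGA-style workflow: multiple
alignment, complete deletion of every column containing a gap or missing
residue, p-distance (fraction of differing positions), neighbor joining
with non-negative branch lengths, Felsenstein bootstrap over alignment
columns, and rooting on an outgroup that carries the LuxR DNA-binding
domain but not the signal-binding domain (GerE-like).

The built-in progressive aligner (k-mer UPGMA guide tree + profile-profile
global alignment) is a deliberately simple default so the pipeline has no
external aligner dependency; externally computed alignments in aligned
FASTA are accepted everywhere an MSA is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy

from .dereplication import AlignmentScoring, global_align
from .records import PROTEIN_ALPHABET

_GAPPY = ("-", ".", "X")  # column killers for complete deletion


# ---------------------------------------------------------------------------
# alignment containers

@dataclass
class MSA:
    """A multiple sequence alignment: equal-length gapped rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_positions(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "MSA":
        return cls(list(seqs), list(seqs.values()))

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.names, self.rows))


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with named taxa."""

    names: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.names)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match names")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")


# ---------------------------------------------------------------------------
# trees

class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None):
        self.name: Optional[str] = name
        self.length: Optional[float] = length
        self.support: Optional[float] = None
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add(self, child: "TreeNode", length: Optional[float] = None) -> "TreeNode":
        if length is not None:
            child.length = length
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def __repr__(self):
        return f"TreeNode({self.name!r})"


class PhyloTree:
    """Rooted or unrooted tree (unrooted = multifurcation at a nominal root)."""

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def iter_branches(self):
        """Yield (node, length) for every non-root node."""
        for node in self.root.walk():
            if node is not self.root:
                yield node, node.length

    def total_length(self) -> float:
        return sum(l or 0.0 for _, l in self.iter_branches())

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = "" if node.support is None else str(int(round(node.support)))
                label = f"({inner}){sup}"
            if node.length is None:
                return label
            return f"{label}:{node.length:.6f}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side NOT
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: set[frozenset] = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            side = frozenset(l.name for l in node.leaves())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def find_leaf(self, name: str) -> TreeNode:
        for node in self.root.walk():
            if node.is_leaf and node.name == name:
                return node
        raise KeyError(f"leaf {name!r} not in tree")

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.name, node.length)
            c.support = node.support
            for child in node.children:
                c.add(clone(child))
            return c

        return PhyloTree(clone(self.root), self.rooted)


# ---------------------------------------------------------------------------
# progressive alignment

_K = 3  # k-mer size for the guide-tree distance


def _kmer_distance(a: str, b: str) -> float:
    ka = {a[i : i + _K] for i in range(max(0, len(a) - _K + 1))}
    kb = {b[i : i + _K] for i in range(max(0, len(b) - _K + 1))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_matrix(rows: Sequence[str], alphabet: str) -> np.ndarray:
    """Column residue-frequency matrix (positions x alphabet), gaps excluded
    from counts but kept in the normalization (gap pairs score zero)."""
    index = {aa: i for i, aa in enumerate(alphabet)}
    out = np.zeros((len(rows[0]), len(alphabet)))
    for row in rows:
        for pos, aa in enumerate(row):
            if aa in index:
                out[pos, index[aa]] += 1
    return out / len(rows)


def _align_profiles(
    rows_a: list[str], rows_b: list[str], scoring: AlignmentScoring
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment (Gotoh affine DP, sum-of-pairs
    average scoring).  Tie order: diagonal, then gap in profile B (up),
    then gap in profile A (left)."""
    matrix = substitution_matrices.load(scoring.matrix_name)
    alphabet = "".join(sorted(PROTEIN_ALPHABET))
    sub = np.array(
        [[matrix[x, y] for y in alphabet] for x in alphabet], dtype=float
    )
    fa = _profile_matrix(rows_a, alphabet)
    fb = _profile_matrix(rows_b, alphabet)
    score = fa @ sub @ fb.T  # (la, lb) expected pair score
    la, lb = score.shape
    go, ge = scoring.gap_open, scoring.gap_extend
    neg = -np.inf

    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -go - ge * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -go - ge * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best + score[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, Y[i, j - 1] - ge, X[i, j - 1] - go)

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    finals = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax(finals))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state_next = int(np.argmax(prev))
            out_a.append("col")
            out_b.append("col")
            i, j = i - 1, j - 1
            state = state_next
        elif state == 1 or (j == 0 and i > 0):
            prev = (M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            state_next = int(np.argmax(prev)) if i > 1 or j > 0 else 0
            out_a.append("col")
            out_b.append("gap")
            i -= 1
            state = state_next if i > 0 else (2 if j > 0 else 0)
        else:
            prev = (M[i, j - 1] - go, Y[i, j - 1] - ge, X[i, j - 1] - go)
            idx = int(np.argmax(prev))
            state_next = (0, 2, 1)[idx]
            out_a.append("gap")
            out_b.append("col")
            j -= 1
            state = state_next if j > 0 else (1 if i > 0 else 0)

    out_a.reverse()
    out_b.reverse()

    def expand(rows: list[str], ops: list[str]) -> list[str]:
        result = []
        for row in rows:
            chars = []
            pos = 0
            for op in ops:
                if op == "col":
                    chars.append(row[pos])
                    pos += 1
                else:
                    chars.append("-")
            result.append("".join(chars))
        return result

    return expand(rows_a, out_a), expand(rows_b, out_b)


def progressive_align(
    seqs: dict[str, str], scoring: AlignmentScoring | None = None
) -> MSA:
    """Progressive multiple alignment.

    Guide tree: UPGMA on fractional common k-mer distances; profiles are
    merged bottom-up by global profile alignment.  Two sequences reduce to
    the exact pairwise global alignment.  Deterministic.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    scoring = scoring or AlignmentScoring()
    names = list(seqs)
    if len(seqs) == 2:
        a, b, _ = global_align(seqs[names[0]], seqs[names[1]], scoring)
        return MSA(names, [a, b])

    n = len(names)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(_kmer_distance(seqs[names[i]], seqs[names[j]]))
    Z = hierarchy.linkage(np.array(condensed), method="average")

    # cluster id -> (names, aligned rows)
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [seqs[names[i]]]) for i in range(n)
    }
    for step, (a_id, b_id, _dist, _cnt) in enumerate(Z):
        na, ra = profiles.pop(int(a_id))
        nb, rb = profiles.pop(int(b_id))
        ra2, rb2 = _align_profiles(ra, rb, scoring)
        profiles[n + step] = (na + nb, ra2 + rb2)
    (_, (out_names, out_rows)), = profiles.items()
    order = {name: k for k, name in enumerate(names)}
    paired = sorted(zip(out_names, out_rows), key=lambda t: order[t[0]])
    return MSA([p[0] for p in paired], [p[1] for p in paired])


# ---------------------------------------------------------------------------
# distances

def complete_deletion(msa: MSA) -> MSA:
    """Remove every column containing a gap or missing residue in ANY row."""
    keep = [
        i
        for i in range(msa.n_positions)
        if all(row[i] not in _GAPPY for row in msa.rows)
    ]
    if not keep:
        raise ValueError("no positions remain after complete deletion")
    rows = ["".join(row[i] for i in keep) for row in msa.rows]
    return MSA(list(msa.names), rows)


def p_distance(msa: MSA) -> DistanceMatrix:
    """Pairwise fraction of differing positions (requires a gap-free MSA)."""
    if msa.n_positions < 1:
        raise ValueError("alignment has zero positions")
    for name, row in zip(msa.names, msa.rows):
        if any(ch in _GAPPY for ch in row):
            raise ValueError(
                f"{name}: alignment contains gaps/missing data; "
                "apply complete_deletion first"
            )
    arr = np.frombuffer(
        "".join(msa.rows).encode(), dtype="S1"
    ).reshape(len(msa.rows), msa.n_positions)
    n = len(msa.names)
    d = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i] != arr[i + 1 :]).mean(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return DistanceMatrix(list(msa.names), d)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Q(i,j) = (n-2) d(i,j) - r_i - r_j; the minimal pair joins first, ties
    broken by the smallest index pair.  Limb lengths use the standard
    formulas; a negative limb is clamped to zero with the deficit moved to
    its sister.  The result is unrooted (trifurcation at the nominal root).
    """
    n = len(dm.names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.names]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] < best[0] - 1e-12:
                    best = (q[ai, aj], ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li  # move the deficit to the sister limb
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        parent.add(nodes[i], li)
        parent.add(nodes[j], lj)

        new_idx = d.shape[0]
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_idx, : new_idx] = new_row
        d[: new_idx, new_idx] = new_row
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [new_idx]

    i, j, k = active
    root = TreeNode()
    root.add(nodes[i], max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k])))
    root.add(nodes[j], max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k])))
    root.add(nodes[k], max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j])))
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(
    msa: MSA, n_reps: int, seed: int
) -> dict[frozenset, float]:
    """Felsenstein bootstrap: column resampling, NJ per replicate.

    Returns support (percent of replicates) for every non-trivial
    bipartition of the tree built from the original alignment.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    base_tree = neighbor_joining(p_distance(msa))
    targets = base_tree.bipartitions()
    counts = {bp: 0 for bp in targets}
    L = msa.n_positions
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep_tree = neighbor_joining(p_distance(MSA(list(msa.names), rows)))
        found = rep_tree.bipartitions()
        for bp in targets:
            if bp in found:
                counts[bp] += 1
    return {bp: 100.0 * c / n_reps for bp, c in counts.items()}


def annotate_supports(tree: PhyloTree, supports: dict[frozenset, float]) -> None:
    """Attach bootstrap percentages to the internal nodes they belong to."""
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(l.name for l in node.leaves())
        if anchor in side:
            side = all_leaves - side
        if side in supports:
            node.support = supports[side]


# ---------------------------------------------------------------------------
# rooting

def root_with_outgroup(tree: PhyloTree, outgroup_name: str) -> PhyloTree:
    """Root on the outgroup's pendant edge, split at its midpoint.

    Ingroup topology (bipartitions) and all path lengths are preserved.
    """
    work = tree.copy()
    leaf = work.find_leaf(outgroup_name)
    pendant = leaf.length if leaf.length is not None else 0.0
    old_parent = leaf.parent
    if old_parent is None:
        raise ValueError("cannot root a single-leaf tree")
    old_parent.children.remove(leaf)

    # reverse parent links from old_parent up to the old root
    path = []
    node = old_parent
    while node is not None:
        path.append(node)
        node = node.parent
    for idx in range(len(path) - 1):
        child, parent = path[idx], path[idx + 1]
        parent.children.remove(child)
        child.add(parent, child.length)
    path[0].length = None
    for n_ in path:
        n_.parent = None

    ingroup = path[0]
    # collapse a degree-2 pass-through left behind at the old root
    _suppress_unary(ingroup)

    new_root = TreeNode()
    leaf.parent = None
    new_root.add(leaf, pendant / 2.0)
    new_root.add(ingroup, pendant / 2.0)
    return PhyloTree(new_root, rooted=True)


def _suppress_unary(node: TreeNode) -> None:
    for child in list(node.children):
        _suppress_unary(child)
    for child in list(node.children):
        if len(child.children) == 1 and not child.is_leaf:
            (grand,) = child.children
            grand.length = (grand.length or 0.0) + (child.length or 0.0)
            grand.support = grand.support or child.support
            pos = node.children.index(child)
            node.children[pos] = grand
            grand.parent = node


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a bifurcating root into the adjacent multifurcation."""
    work = tree.copy()
    root = work.root
    if len(root.children) != 2:
        return PhyloTree(root, rooted=False)
    a, b = root.children
    internal = b if not b.is_leaf else a
    other = a if internal is b else b
    merged = (a.length or 0.0) + (b.length or 0.0)
    internal.parent = None
    internal.length = None
    internal.add(other, merged)
    return PhyloTree(internal, rooted=False)
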