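"""CD-HIT-style greedy identity clustering of LuxR protein sequences.

Redundant screen hits are collapsed by clustering their LuxR homolog
protein sequences at a mutual-identity cutoff (default 0.9) and keeping
one representative sequence — and hence one representative BGC — per
cluster.  Identity follows CD-HIT's convention: identical aligned residue
pairs divided by the length of the shorter sequence.  Unlike CD-HIT no
k-mer pre-filter is used; every comparison is an exact global alignment
(BLOSUM62, affine gaps), which is fine at the scales this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .records import PROTEIN_ALPHABET


@dataclass
class AlignmentScoring:
    """Substitution matrix + affine gap parameters for global alignment."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


_DEFAULT_SCORING = AlignmentScoring()
_aligner_cache: dict[tuple, PairwiseAligner] = {}


def _get_aligner(scoring: AlignmentScoring) -> PairwiseAligner:
    key = (scoring.matrix_name, scoring.gap_open, scoring.gap_extend)
    if key not in _aligner_cache:
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix_name)
        aligner.open_gap_score = -scoring.gap_open
        aligner.extend_gap_score = -scoring.gap_extend
        aligner.mode = "global"
        _aligner_cache[key] = aligner
    return _aligner_cache[key]


def _check_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{label}: illegal character(s) {sorted(bad)!r}")


def global_align(a: str, b: str, scoring: AlignmentScoring | None = None):
    """Optimal global alignment of two protein sequences.

    Returns ``(aligned_a, aligned_b, score)`` where the aligned strings are
    equal length with ``-`` for gaps.  Deterministic: the first optimal
    traceback reported by the aligner is always the same for the same input.
    """
    _check_protein(a, "sequence a")
    _check_protein(b, "sequence b")
    aligner = _get_aligner(scoring or _DEFAULT_SCORING)
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    return aligned_a, aligned_b, alignment.score


def percent_identity(a: str, b: str, scoring: AlignmentScoring | None = None) -> float:
    """Mutual identity of two proteins in [0, 1].

    Identical aligned residue pairs divided by the length of the shorter
    sequence (CD-HIT's denominator), so a perfect local match embedded in a
    longer sequence still counts as identity 1.
    """
    aligned_a, aligned_b, _ = global_align(a, b, scoring)
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    return matches / min(len(a), len(b))


@dataclass
class IdentityCluster:
    """One dereplication cluster: representative + members.

    Every non-representative member aligns to the representative at
    identity >= the clustering cutoff.
    """

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    pairwise_identity_to_rep: dict[str, float] = field(default_factory=dict)


def greedy_cluster(
    seqs: dict[str, str],
    cutoff: float = 0.9,
    scoring: AlignmentScoring | None = None,
) -> list[IdentityCluster]:
    """Greedy incremental clustering at an identity cutoff.

    Sequences are processed by decreasing length (ties broken by id); each
    sequence joins the first existing cluster whose *representative* it
    matches at >= ``cutoff``, otherwise it founds a new cluster and becomes
    its representative.  Output clusters are in founding order, so the
    representative is always the longest member.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must lie in (0, 1]")
    ids = list(seqs)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")

    order = sorted(ids, key=lambda i: (-len(seqs[i]), i))
    clusters: list[IdentityCluster] = []
    for sid in order:
        placed = False
        for cluster in clusters:
            pid = percent_identity(seqs[sid], seqs[cluster.representative_id], scoring)
            if pid >= cutoff:
                cluster.member_ids.append(sid)
                cluster.pairwise_identity_to_rep[sid] = pid
                placed = True
                break
        if not placed:
            clusters.append(
                IdentityCluster(
                    representative_id=sid,
                    member_ids=[sid],
                    pairwise_identity_to_rep={sid: 1.0},
                )
            )
    return clusters


def cluster_table(clusters: list[IdentityCluster]) -> list[dict]:
    """Flatten clusters into TSV-ready rows."""
    rows = []
    for idx, c in enumerate(clusters):
        rows.append(
            {
                "cluster_index": idx,
                "representative_id": c.representative_id,
                "n_members": len(c.member_ids),
                "member_ids": ",".join(c.member_ids),
                "identities": ",".join(
                    f"{c.pairwise_identity_to_rep[m]:.4f}" for m in c.member_ids
                ),
            }
        )
    return rows
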