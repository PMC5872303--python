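"""Alignment, p-distance, neighbor joining, bootstrap, rooting."""

import numpy as np
import pytest

from luxrbgc import phylogeny as P
from luxrbgc.dereplication import global_align
from luxrbgc.synthetic import SynthSpec, generate_dataset, mutate_protein, random_protein

from .oracles import count_p_distance, random_additive_tree


def _pairwise_path_lengths(tree: P.PhyloTree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths via root paths (independent of topology shape)."""
    paths = {}

    def walk(node, acc):
        acc = acc + [(node, node.length or 0.0)]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    names = sorted(paths)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa = {id(n): (n, l) for n, l in paths[a]}
            shared = 0.0
            for n, l in paths[b]:
                if id(n) in pa:
                    shared += 2 * l
            total = sum(l for _, l in paths[a]) + sum(l for _, l in paths[b]) - shared
            out[frozenset((a, b))] = total
    return out


class TestProgressiveAlign:
    def test_identical_sequences_align_gapless(self):
        msa = P.progressive_align({"a": "MKTAYI" * 10, "b": "MKTAYI" * 10,
                                   "c": "MKTAYI" * 10})
        assert all("-" not in row for row in msa.rows)

    def test_two_sequences_reduce_to_pairwise_global_alignment(self):
        rng = np.random.default_rng(1)
        a = random_protein(60, rng)
        b = mutate_protein(a, 0.7, rng)[:50]
        msa = P.progressive_align({"x": a, "y": b})
        ga, gb, _ = global_align(a, b)
        assert msa.to_dict() == {"x": ga, "y": gb}

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            P.progressive_align({"a": "MKT" * 20})

    def test_planted_families_give_conserved_columns(self, luxr_sequences,
                                                     default_dataset):
        """Within one family (>0.9 identity, substitution-only) at least 90%
        of alignment columns are fully conserved."""
        _, _, truth = default_dataset
        fam0 = {k: v for k, v in luxr_sequences.items() if truth.family_of[k] == 0}
        msa = P.progressive_align(fam0)
        conserved = sum(
            1 for i in range(msa.n_positions)
            if len({row[i] for row in msa.rows}) == 1
        )
        assert conserved / msa.n_positions >= 0.9


class TestCompleteDeletion:
    def test_gapless_msa_unchanged(self):
        msa = P.MSA(["a", "b"], ["MKT", "MKA"])
        out = P.complete_deletion(msa)
        assert out.rows == msa.rows

    def test_column_with_any_gap_removed_for_all_rows(self):
        msa = P.MSA(["a", "b", "c"], ["MK-TA", "MKTTA", "MKTTA"])
        out = P.complete_deletion(msa)
        assert out.rows == ["MKTA", "MKTA", "MKTA"]
        assert out.n_positions == 4

    def test_missing_data_column_removed(self):
        msa = P.MSA(["a", "b"], ["MXT", "MKT"])
        assert P.complete_deletion(msa).rows == ["MT", "MT"]

    def test_error_when_no_positions_remain(self):
        with pytest.raises(ValueError, match="no positions remain"):
            P.complete_deletion(P.MSA(["a", "b"], ["M-", "-K"]))


class TestPDistance:
    def test_identical_rows_give_zero(self):
        dm = P.p_distance(P.MSA(["a", "b"], ["MKTA", "MKTA"]))
        assert dm.d[0, 1] == 0.0

    def test_quarter_mismatch(self):
        dm = P.p_distance(P.MSA(["a", "b"], ["AAAA", "AAAT"]))
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gappy_alignment_rejected(self):
        with pytest.raises(ValueError, match="complete_deletion"):
            P.p_distance(P.MSA(["a", "b"], ["M-TA", "MKTA"]))

    def test_matches_bruteforce_counting_on_random_rows(self):
        rng = np.random.default_rng(2)
        names = [f"s{i}" for i in range(6)]
        rows = [random_protein(40, rng) for _ in names]
        dm = P.p_distance(P.MSA(names, rows))
        for i in range(6):
            for j in range(6):
                assert dm.d[i, j] == pytest.approx(
                    count_p_distance(rows[i], rows[j])
                )


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # distances generated from the tree ((A:1,B:2):1,(C:3,D:4))
        names = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6],
             [3, 0, 6, 7],
             [5, 6, 0, 7],
             [6, 7, 7, 0]], dtype=float,
        )
        tree = P.neighbor_joining(P.DistanceMatrix(names, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        paths = _pairwise_path_lengths(tree)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                assert paths[frozenset((a, b))] == pytest.approx(
                    d[names.index(a), names.index(b)], abs=1e-9
                )

    def test_three_taxa_closed_form_limbs(self):
        names = ["A", "B", "C"]
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = P.neighbor_joining(P.DistanceMatrix(names, d))
        limbs = {c.name: c.length for c in tree.root.children}
        assert limbs["A"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert limbs["B"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert limbs["C"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            P.neighbor_joining(P.DistanceMatrix(["a", "b", "c"], d))

    def test_random_additive_trees_recovered(self):
        """NJ is consistent on additive matrices: topology and all path
        lengths are recovered (fuzz over random 4-12 leaf trees)."""
        rng = np.random.default_rng(3)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            names, d, biparts = random_additive_tree(n, rng)
            tree = P.neighbor_joining(P.DistanceMatrix(names, d))
            assert tree.bipartitions() == biparts, f"trial {trial}"
            paths = _pairwise_path_lengths(tree)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    assert paths[frozenset((a, b))] == pytest.approx(
                        d[names.index(a), names.index(b)], abs=1e-9
                    )

    def test_ultrametric_matrix_matches_upgma_topology(self):
        """On ultrametric distances NJ and UPGMA (scipy, independent route)
        produce the same rooted clusters, hence the same bipartitions."""
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            # random ultrametric: cophenetic distances of a random dendrogram
            pts = rng.uniform(size=(n, 5))
            Z = hierarchy.average(squareform(
                np.abs(pts[:, None, :] - pts[None, :, :]).sum(-1), checks=False
            ))
            d = squareform(hierarchy.cophenet(Z))
            names = [f"t{i}" for i in range(n)]
            tree = P.neighbor_joining(P.DistanceMatrix(names, d))

            anchor = min(names)
            upgma_biparts = set()
            link = {i: frozenset([names[i]]) for i in range(n)}
            for k, (a, b, _, _) in enumerate(Z):
                merged = link[int(a)] | link[int(b)]
                link[n + k] = merged
                side = frozenset(set(names) - merged) if anchor in merged else merged
                if 2 <= len(side) <= n - 2:
                    upgma_biparts.add(side)
            assert tree.bipartitions() == upgma_biparts


@pytest.fixture(scope="module")
def family_msa():
    """Two clearly separated planted families in one alignment."""
    spec = SynthSpec(n_families=2, members_per_family=(4, 4),
                     within_identity=0.95, between_identity=0.5,
                     negatives=0, luxi_only_decoys=0, seed=21)
    records, _, truth = generate_dataset(spec)
    seqs = {}
    for rec in records:
        for g in rec.genes:
            if g.gene_id in truth.family_of:
                seqs[g.gene_id] = g.translation
    msa = P.progressive_align(seqs)
    return P.complete_deletion(msa), truth


class TestBootstrap:
    def test_separated_families_get_high_support(self, family_msa):
        msa, truth = family_msa
        supports = P.bootstrap_support(msa, n_reps=100, seed=0)
        fam0 = frozenset(k for k, f in truth.family_of.items() if f == 0)
        anchor = min(msa.names)
        key = fam0 if anchor not in fam0 else frozenset(msa.names) - fam0
        assert supports[key] >= 95.0

    def test_single_replicate_supports_are_zero_or_hundred(self, family_msa):
        msa, _ = family_msa
        supports = P.bootstrap_support(msa, n_reps=1, seed=5)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self, family_msa):
        msa, _ = family_msa
        s1 = P.bootstrap_support(msa, n_reps=25, seed=7)
        s2 = P.bootstrap_support(msa, n_reps=25, seed=7)
        assert s1 == s2

    def test_row_permutation_invariance_of_strong_splits(self, family_msa):
        """Bipartition keys are row-order independent, and strongly supported
        splits keep their support under row permutation.  (Weak splits may
        shift: exactly tied distances are broken by input index, as in any
        NJ implementation.)"""
        msa, truth = family_msa
        perm = P.MSA(list(reversed(msa.names)), list(reversed(msa.rows)))
        s1 = P.bootstrap_support(msa, n_reps=25, seed=3)
        s2 = P.bootstrap_support(perm, n_reps=25, seed=3)
        fam0 = frozenset(k for k, f in truth.family_of.items() if f == 0)
        anchor = min(msa.names)
        key = fam0 if anchor not in fam0 else frozenset(msa.names) - fam0
        assert s1[key] == s2[key] == 100.0


class TestRooting:
    def test_three_taxon_star_rooted_on_outgroup(self):
        d = np.array([[0, 0.2, 0.9], [0.2, 0, 0.9], [0.9, 0.9, 0]])
        tree = P.neighbor_joining(P.DistanceMatrix(["A", "B", "C"], d))
        rooted = P.root_with_outgroup(tree, "C")
        assert rooted.rooted
        kids = rooted.root.children
        assert {k.name for k in kids if k.is_leaf} == {"C"}
        ingroup = next(k for k in kids if not k.is_leaf)
        assert {l.name for l in ingroup.leaves()} == {"A", "B"}

    def test_total_branch_length_conserved(self):
        rng = np.random.default_rng(11)
        names, d, _ = random_additive_tree(7, rng)
        tree = P.neighbor_joining(P.DistanceMatrix(names, d))
        rooted = P.root_with_outgroup(tree, names[0])
        assert rooted.total_length() == pytest.approx(tree.total_length(), abs=1e-9)

    def test_root_then_unroot_restores_bipartitions(self):
        rng = np.random.default_rng(12)
        names, d, _ = random_additive_tree(8, rng)
        tree = P.neighbor_joining(P.DistanceMatrix(names, d))
        rooted = P.root_with_outgroup(tree, names[3])
        assert P.unroot(rooted).bipartitions() == tree.bipartitions()

    def test_pairwise_path_lengths_preserved_by_rooting(self):
        rng = np.random.default_rng(13)
        names, d, _ = random_additive_tree(6, rng)
        tree = P.neighbor_joining(P.DistanceMatrix(names, d))
        rooted = P.root_with_outgroup(tree, names[2])
        assert _pairwise_path_lengths(rooted) == pytest.approx(
            _pairwise_path_lengths(tree)
        )

    def test_missing_outgroup_name_rejected(self):
        d = np.array([[0, 0.2, 0.9], [0.2, 0, 0.9], [0.9, 0.9, 0]])
        tree = P.neighbor_joining(P.DistanceMatrix(["A", "B", "C"], d))
        with pytest.raises(KeyError):
            P.root_with_outgroup(tree, "Z")

    def test_nj_matches_scikit_bio_tree(self):
        """Cross-check the NJ implementation against scikit-bio's on a
        random additive matrix (same bipartitions)."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(14)
        names, d, biparts = random_additive_tree(7, rng)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=names))
        anchor = min(names)
        sk_biparts = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = frozenset(names) - side
            if 2 <= len(side) <= len(names) - 2:
                sk_biparts.add(side)
        ours = P.neighbor_joining(P.DistanceMatrix(names, d)).bipartitions()
        assert ours == biparts == sk_biparts
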