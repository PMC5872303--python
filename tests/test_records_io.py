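"""Domain types and format round trips."""

import dendropy
import pytest

from luxrbgc import io as _io
from luxrbgc.phylogeny import PhyloTree, TreeNode
from luxrbgc.records import BGCRecord, DomainHit, GeneFeature, GeneRole, Habitat
from luxrbgc.synthetic import MODEL_LENGTHS, SynthSpec, generate_dataset


class TestGeneFeature:
    def test_rejects_inverted_coordinates(self):
        with pytest.raises(ValueError):
            GeneFeature("g", 250, 100, 1, "MKT")

    def test_rejects_empty_translation(self):
        with pytest.raises(ValueError):
            GeneFeature("g", 0, 9, 1, "")

    def test_rejects_illegal_residue(self):
        with pytest.raises(ValueError, match="illegal"):
            GeneFeature("g", 0, 9, 1, "MK*")

    def test_role_defaults_to_unknown_when_qualifier_absent(self):
        assert GeneRole.from_qualifier(None) is GeneRole.UNKNOWN
        assert GeneRole.from_qualifier("biosynthetic-additional") is GeneRole.BIOSYNTHETIC


class TestGenBank:
    def test_genbank_coordinate_convention(self, tmp_path):
        """GenBank location 101..250 becomes 0-based half-open [100, 250)."""
        gbk = tmp_path / "one.gbk"
        rec = BGCRecord(
            record_id="R1",
            organism="Test sp.",
            bgc_type="NRPS",
            genes=[GeneFeature("g1", 100, 250, 1, "M" * 50, GeneRole.BIOSYNTHETIC)],
            region_seq="A" * 300,
        )
        _io.write_genbank([rec], gbk)
        text = gbk.read_text()
        assert "101..250" in text
        back = _io.read_genbank(gbk)[0]
        assert (back.genes[0].start, back.genes[0].end) == (100, 250)

    def test_record_and_gene_counts_preserved(self, tmp_path):
        recs = [
            BGCRecord(
                record_id=f"R{k}",
                genes=[
                    GeneFeature(f"R{k}_g{i}", 10 + 100 * i, 100 + 100 * i, 1, "M" * 30)
                    for i in range(n)
                ],
                region_seq="ACGT" * 300,
            )
            for k, n in enumerate((5, 3))
        ]
        path = tmp_path / "two.gbk"
        _io.write_genbank(recs, path)
        back = _io.read_genbank(path)
        assert [len(r.genes) for r in back] == [5, 3]

    def test_synthetic_round_trip_is_field_identical(self, tmp_path):
        records, _, _ = generate_dataset(SynthSpec(seed=5))
        path = tmp_path / "rt.gbk"
        _io.write_genbank(records, path)
        back = _io.read_genbank(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.record_id == b.record_id
            assert a.organism == b.organism
            assert tuple(a.taxonomy) == tuple(b.taxonomy)
            assert a.habitat is b.habitat
            assert a.bgc_type == b.bgc_type
            assert a.region_seq == b.region_seq
            assert a.genome_gc == pytest.approx(b.genome_gc, abs=1e-9)
            assert [
                (g.gene_id, g.start, g.end, g.strand, g.translation, g.role)
                for g in a.genes
            ] == [
                (g.gene_id, g.start, g.end, g.strand, g.translation, g.role)
                for g in b.genes
            ]

    def test_cds_without_translation_skipped_with_warning(self, tmp_path, caplog):
        gbk = tmp_path / "broken.gbk"
        rec = BGCRecord(
            record_id="R1",
            genes=[GeneFeature("ok", 0, 90, 1, "M" * 30)],
            region_seq="ACGT" * 100,
        )
        _io.write_genbank([rec], gbk)
        # strip the translation qualifier of a second, hand-added CDS
        text = gbk.read_text().replace(
            "ORIGIN",
            '     CDS             200..280\n'
            '                     /locus_tag="no_translation"\n'
            "ORIGIN",
        )
        gbk.write_text(text)
        with caplog.at_level("WARNING"):
            back = _io.read_genbank(gbk)
        assert [g.gene_id for g in back[0].genes] == ["ok"]
        assert any("no translation" in m for m in caplog.messages)

    def test_habitat_qualifier_maps_to_enum(self):
        assert Habitat.from_qualifier("plant_associated") is Habitat.PLANT_ASSOCIATED
        assert Habitat.from_qualifier(None) is Habitat.UNKNOWN
        assert Habitat.from_qualifier("weird") is Habitat.UNKNOWN


class TestDomtblout:
    def test_comment_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.dom"
        p.write_text("# nothing here\n# at all\n")
        assert _io.read_domtblout(p) == []

    def test_model_coverage_arithmetic(self, tmp_path):
        hit = DomainHit("prot1", "PF00196", 1e-10, 100.0, 5, 100, (100 - 5 + 1) / 100)
        p = tmp_path / "one.dom"
        _io.write_domtblout([hit], p, model_lengths={"PF00196": 100})
        (back,) = _io.read_domtblout(p)
        assert back.model_coverage == pytest.approx(0.96)

    def test_short_row_raises_with_row_number(self, tmp_path):
        p = tmp_path / "bad.dom"
        p.write_text("# header\nonly three fields\n")
        with pytest.raises(ValueError, match="row 2"):
            _io.read_domtblout(p)

    def test_synthetic_hits_round_trip(self, tmp_path):
        _, hits, _ = generate_dataset(SynthSpec(seed=5))
        p = tmp_path / "rt.dom"
        _io.write_domtblout(hits, p, MODEL_LENGTHS)
        assert _io.read_domtblout(p) == hits


class TestNewick:
    @staticmethod
    def _two_leaf_tree():
        root = TreeNode()
        root.add(TreeNode("A"), 0.1)
        root.add(TreeNode("B"), 0.2)
        return PhyloTree(root)

    def test_two_leaf_serialization(self, tmp_path):
        p = tmp_path / "t.nwk"
        _io.write_newick(self._two_leaf_tree(), p)
        assert p.read_text().strip() == "(A:0.100000,B:0.200000);"

    def test_negative_branch_length_rejected_before_writing(self, tmp_path):
        tree = self._two_leaf_tree()
        tree.root.children[0].length = -0.5
        p = tmp_path / "t.nwk"
        with pytest.raises(ValueError, match="negative"):
            _io.write_newick(tree, p)
        assert not p.exists()

    def test_duplicate_leaf_names_rejected(self, tmp_path):
        root = TreeNode()
        root.add(TreeNode("A"), 0.1)
        root.add(TreeNode("A"), 0.2)
        with pytest.raises(ValueError, match="duplicate"):
            _io.write_newick(PhyloTree(root), tmp_path / "t.nwk")

    def test_round_trip_topology_and_lengths_via_dendropy(self, tmp_path):
        root = TreeNode()
        a = root.add(TreeNode(), 0.05)
        a.support = 87.0
        a.add(TreeNode("A"), 0.1)
        a.add(TreeNode("B"), 0.2)
        b = root.add(TreeNode(), 0.07)
        b.support = 100.0
        b.add(TreeNode("C"), 0.3)
        b.add(TreeNode("D"), 0.4)
        p = tmp_path / "t.nwk"
        _io.write_newick(PhyloTree(root), p)
        t = dendropy.Tree.get(path=str(p), schema="newick")
        leaves = {l.taxon.label for l in t.leaf_node_iter()}
        assert leaves == {"A", "B", "C", "D"}
        lengths = sorted(
            e.length for e in t.preorder_edge_iter() if e.length is not None
        )
        assert lengths == pytest.approx([0.05, 0.07, 0.1, 0.2, 0.3, 0.4], abs=1e-6)
        supports = sorted(
            int(n.label) for n in t.preorder_node_iter()
            if n.label and not n.is_leaf()
        )
        assert supports == [87, 100]
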