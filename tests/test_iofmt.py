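import numpy as np
import pandas as pd
import pytest

from lncarray import iofmt
from lncarray.iofmt import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    Locus,
    MiRNATargetTable,
    SchemaError,
)


def write_matrix_tsv(path, probe_rows, samples):
    lines = ["probe_id\t" + "\t".join(samples)]
    for pid, vals in probe_rows:
        lines.append(pid + "\t" + "\t".join(str(v) for v in vals))
    path.write_text("\n".join(lines) + "\n")


class TestExpressionMatrix:
    def test_read_shape(self, tmp_path):
        samples = [f"s{i}" for i in range(8)]
        write_matrix_tsv(
            tmp_path / "m.tsv",
            [(f"P{i}", [float(i + j + 1) for j in range(8)]) for i in range(3)],
            samples,
        )
        gmap = {s: ("case" if i < 5 else "control") for i, s in enumerate(samples)}
        m = iofmt.read_expression_matrix(tmp_path / "m.tsv", gmap)
        assert m.shape == (3, 8)
        assert m.group_labels == ["case"] * 5 + ["control"] * 3

    def test_duplicate_probe_named_in_error(self, tmp_path):
        samples = ["a", "b", "c", "d"]
        write_matrix_tsv(
            tmp_path / "m.tsv",
            [("P1", [1, 2, 3, 4]), ("P1", [5, 6, 7, 8])],
            samples,
        )
        gmap = {"a": "case", "b": "case", "c": "control", "d": "control"}
        with pytest.raises(SchemaError, match="P1"):
            iofmt.read_expression_matrix(tmp_path / "m.tsv", gmap)

    def test_roundtrip_identity(self, tmp_path, tiny_matrix):
        iofmt.write_expression_matrix(tiny_matrix, tmp_path / "m.tsv", tmp_path / "g.tsv")
        gmap = iofmt.read_group_map(tmp_path / "g.tsv")
        back = iofmt.read_expression_matrix(tmp_path / "m.tsv", gmap)
        assert back.probe_ids == tiny_matrix.probe_ids
        assert back.sample_ids == tiny_matrix.sample_ids
        assert back.group_labels == tiny_matrix.group_labels
        np.testing.assert_allclose(back.values, tiny_matrix.values, rtol=1e-9)

    def test_sample_missing_from_group_map(self, tmp_path):
        write_matrix_tsv(tmp_path / "m.tsv", [("P1", [1, 2, 3, 4])], ["a", "b", "c", "d"])
        with pytest.raises(SchemaError, match="group map"):
            iofmt.read_expression_matrix(
                tmp_path / "m.tsv", {"a": "case", "b": "case", "c": "control"}
            )

    def test_nonpositive_intensity_rejected(self, tmp_path):
        write_matrix_tsv(tmp_path / "m.tsv", [("P1", [1, -2, 3, 4])], ["a", "b", "c", "d"])
        gmap = dict.fromkeys("ab", "case") | dict.fromkeys("cd", "control")
        with pytest.raises(ValueError):
            iofmt.read_expression_matrix(tmp_path / "m.tsv", gmap)

    def test_single_group_rejected(self):
        with pytest.raises(SchemaError):
            ExpressionMatrix(["P1"], ["a", "b"], ["case", "case"], np.ones((1, 2)))

    def test_log_transform_is_explicit(self, tiny_matrix):
        np.testing.assert_allclose(tiny_matrix.log2(), np.log2(tiny_matrix.values))


class TestGMT:
    def test_parse_members(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("GO:X\tdesc\tA\tB\n")
        coll = iofmt.read_gmt(p)
        assert len(coll) == 1
        assert set(coll.sets[0].members) == {"A", "B"}

    def test_short_line_is_error_with_line_number(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("GO:X\tdesc\tA\nGO:Y\tdesc\n")
        with pytest.raises(SchemaError, match=":2"):
            iofmt.read_gmt(p)

    def test_two_sets(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("GO:X\tdesc\tA\tB\nGO:Y\tdesc2\tC\n")
        assert len(iofmt.read_gmt(p)) == 2

    def test_roundtrip_preserves_category(self, tmp_path):
        coll = GeneSetCollection(
            [GeneSet("GO:1", "BP", "proc", ["A", "B"]), GeneSet("KP:1", "pathway", "pw", ["C"])]
        )
        iofmt.write_gmt(coll, tmp_path / "s.gmt")
        back = iofmt.read_gmt(tmp_path / "s.gmt")
        assert [(s.set_id, s.category, s.members) for s in back] == [
            (s.set_id, s.category, s.members) for s in coll
        ]

    def test_duplicate_set_id_rejected(self):
        with pytest.raises(SchemaError):
            GeneSetCollection([GeneSet("X", "BP", "", ["A"]), GeneSet("X", "BP", "", ["B"])])


class TestLoci:
    def test_single_exon(self, tmp_path):
        p = tmp_path / "l.bed"
        p.write_text("chr1\t100\t200\tL1\t0\t+\n")
        (locus,) = iofmt.read_loci(p)
        assert locus.blocks == [(100, 200)]
        assert locus.tss == 100

    def test_minus_strand_tss(self):
        locus = Locus("L", "chr1", 100, 200, "-")
        assert locus.tss == 199

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(SchemaError, match="overlap"):
            Locus("L", "chr1", 0, 100, "+", [(0, 60), (50, 100)])

    def test_block_outside_span_rejected(self):
        with pytest.raises(SchemaError, match="outside"):
            Locus("L", "chr1", 10, 100, "+", [(0, 50)])

    def test_end_not_after_start_rejected(self):
        with pytest.raises(SchemaError):
            Locus("L", "chr1", 100, 100, "+")

    def test_roundtrip(self, tmp_path):
        loci = [
            Locus("L1", "chr1", 100, 1000, "+", [(100, 200), (800, 1000)]),
            Locus("L2", "chr2", 5, 50, "-"),
        ]
        iofmt.write_loci(loci, tmp_path / "l.bed")
        back = iofmt.read_loci(tmp_path / "l.bed")
        assert back == loci

    def test_introns(self):
        locus = Locus("L", "chr1", 0, 100, "+", [(0, 20), (50, 100)])
        assert locus.introns == [(20, 50)]


class TestNetworkTables:
    def test_sif_line(self, tmp_path):
        iofmt.write_network_tables(
            [("A", "lncRNA"), ("B", "mRNA")], [("A", "B", 0.99, "positive")], tmp_path / "net"
        )
        assert (tmp_path / "net.sif").read_text() == "A\tpp\tB\n"

    def test_negative_edge_relation(self, tmp_path):
        iofmt.write_network_tables(
            [("A", "lncRNA"), ("B", "mRNA")], [("A", "B", -0.99, "negative")], tmp_path / "net"
        )
        assert (tmp_path / "net.sif").read_text() == "A\tpn\tB\n"

    def test_dangling_edge_rejected(self, tmp_path):
        with pytest.raises(SchemaError, match="unknown node"):
            iofmt.write_network_tables(
                [("A", "lncRNA")], [("A", "B", 0.5, "positive")], tmp_path / "net"
            )

    def test_empty_edge_list(self, tmp_path):
        node_path, edge_path, sif_path = iofmt.write_network_tables(
            [("A", "lncRNA")], [], tmp_path / "net"
        )
        assert edge_path.read_text() == "source\ttarget\tweight\tsign\n"
        assert sif_path.read_text() == ""


class TestMiRNATargets:
    def test_roundtrip(self, tmp_path):
        t = MiRNATargetTable(
            pd.DataFrame(
                {"mirna_id": ["m1", "m2"], "target_gene_id": ["g1", "g1"], "mre_count": [1, 3]}
            )
        )
        iofmt.write_mirna_targets(t, tmp_path / "t.tsv")
        back = iofmt.read_mirna_targets(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back.table, t.table)

    def test_duplicate_pair_rejected(self):
        with pytest.raises(SchemaError):
            MiRNATargetTable(
                pd.DataFrame(
                    {"mirna_id": ["m1", "m1"], "target_gene_id": ["g1", "g1"], "mre_count": [1, 2]}
                )
            )

    def test_zero_mre_rejected(self):
        with pytest.raises(SchemaError):
            MiRNATargetTable(
                pd.DataFrame({"mirna_id": ["m1"], "target_gene_id": ["g1"], "mre_count": [0]})
            )

    def test_lookups(self):
        t = MiRNATargetTable(
            pd.DataFrame(
                {
                    "mirna_id": ["m1", "m2", "m1"],
                    "target_gene_id": ["g1", "g1", "g2"],
                    "mre_count": [2, 1, 4],
                }
            )
        )
        assert t.mirnas_for("g1") == {"m1", "m2"}
        assert t.mre_weights_for("g2") == {"m1": 4}


class TestProbeAnnotation:
    def _frame(self):
        return pd.DataFrame(
            {
                "seqname": ["T1", "T2"],
                "probe_name": ["P1", "P2"],
                "chrom": ["chr1", "chr2"],
                "strand": ["+", "-"],
                "biotype": ["lncRNA", "mRNA"],
                "gene_symbol": ["A", "."],
            }
        )

    def test_roundtrip(self, tmp_path):
        ann = iofmt.ProbeAnnotation(self._frame())
        iofmt.write_probe_annotation(ann, tmp_path / "a.tsv")
        back = iofmt.read_probe_annotation(tmp_path / "a.tsv")
        pd.testing.assert_frame_equal(back.table, ann.table)

    def test_bad_strand_rejected(self):
        frame = self._frame()
        frame.loc[0, "strand"] = "*"
        with pytest.raises(SchemaError, match="strand"):
            iofmt.ProbeAnnotation(frame)

    def test_duplicate_key_rejected(self):
        frame = pd.concat([self._frame(), self._frame()])
        with pytest.raises(SchemaError):
            iofmt.ProbeAnnotation(frame)
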