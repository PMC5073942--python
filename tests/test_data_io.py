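import numpy as np
import pytest

from netmark.data import (ExpressionDataset, GeneProteinMap, Marker,
                          MarkerSet, PPINetwork, overlay, read_expression,
                          read_gene_protein_map, read_markers, read_network,
                          write_markers)


def _write_expr(tmp_path, text, labels_text):
    expr_path = tmp_path / "expr.tsv"
    lab_path = tmp_path / "labels.tsv"
    expr_path.write_text(text)
    lab_path.write_text(labels_text)
    return expr_path, lab_path


LABELS_4 = "s1\t1\ns2\t1\ns3\t2\ns4\t2\n"


class TestReadExpression:
    def test_round_trip_shape_and_values(self, tmp_path):
        text = ("gene_id\ts1\ts2\ts3\ts4\n"
                "g1\t1\t2\t3\t4\n"
                "g2\t0.5\t0.5\t0.5\t0.5\n"
                "g3\t-1\t0\t1\t2\n")
        expr_path, lab_path = _write_expr(tmp_path, text, LABELS_4)
        ds = read_expression(expr_path, lab_path)
        assert ds.values.shape == (3, 4)
        assert ds.gene_ids == ("g1", "g2", "g3")
        np.testing.assert_allclose(ds.values[2], [-1, 0, 1, 2])
        np.testing.assert_array_equal(ds.labels, [1, 1, 2, 2])

    def test_duplicate_gene_rows_are_averaged(self, tmp_path):
        text = ("gene_id\ts1\ts2\ts3\ts4\n"
                "g1\t1\t2\t3\t4\n"
                "g1\t3\t4\t5\t6\n")
        expr_path, lab_path = _write_expr(tmp_path, text, LABELS_4)
        ds = read_expression(expr_path, lab_path)
        assert ds.values.shape == (1, 4)
        np.testing.assert_allclose(ds.values[0], [2, 3, 4, 5])

    def test_single_phenotype_rejected(self, tmp_path):
        text = "gene_id\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\n"
        labels = "s1\t1\ns2\t1\ns3\t1\ns4\t1\n"
        expr_path, lab_path = _write_expr(tmp_path, text, labels)
        with pytest.raises(ValueError):
            read_expression(expr_path, lab_path)

    def test_missing_label_rejected(self, tmp_path):
        text = "gene_id\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\n"
        labels = "s1\t1\ns2\t1\ns3\t2\n"
        expr_path, lab_path = _write_expr(tmp_path, text, labels)
        with pytest.raises(ValueError, match="missing phenotype"):
            read_expression(expr_path, lab_path)

    def test_sparse_missing_values_imputed_heavy_rows_dropped(self, tmp_path):
        # g1: 1 of 12 missing -> imputed with row mean; g2: 6 of 12 -> dropped
        cols = [f"s{i}" for i in range(1, 13)]
        labels = "".join(f"s{i}\t{1 if i <= 6 else 2}\n" for i in range(1, 13))
        g1 = ["1"] * 11 + ["NA"]
        g2 = ["2"] * 6 + ["NA"] * 6
        text = ("gene_id\t" + "\t".join(cols) + "\n"
                "g1\t" + "\t".join(g1) + "\n"
                "g2\t" + "\t".join(g2) + "\n")
        expr_path, lab_path = _write_expr(tmp_path, text, labels)
        ds = read_expression(expr_path, lab_path)
        assert ds.gene_ids == ("g1",)
        np.testing.assert_allclose(ds.values[0], np.ones(12))


class TestReadNetwork:
    def test_dedup_and_self_loop_removal(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tA\nA\tA\n")
        net = read_network(p)
        assert net.n_proteins == 2
        assert net.edges() == [("A", "B")]

    def test_sif_multi_target(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\tpp\tB\tC\n")
        net = read_network(p, dialect="sif")
        assert sorted(net.edges()) == [("A", "B"), ("A", "C")]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            read_network(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nlonely\n")
        with pytest.raises(ValueError, match=":2"):
            read_network(p)


def _expr_for(genes, rng=None, n=4):
    rng = rng or np.random.default_rng(0)
    values = rng.normal(size=(len(genes), n))
    labels = np.array([1] * (n // 2) + [2] * (n - n // 2))
    return ExpressionDataset(gene_ids=tuple(genes), values=values, labels=labels)


class TestOverlay:
    def test_manual_intersection(self):
        net = PPINetwork.from_edges([("A", "B"), ("B", "C")])
        expr = _expr_for(["A", "B"])
        ind = overlay(expr, net, GeneProteinMap.identity(["A", "B", "C"]))
        assert set(ind.nodes) == {"A", "B"}
        assert ind.network.n_interactions == 1

    def test_identity_overlay(self):
        net = PPINetwork.from_edges([("A", "B")])
        expr = _expr_for(["A", "B"])
        ind = overlay(expr, net, GeneProteinMap.identity(["A", "B"]))
        assert set(ind.nodes) == {"A", "B"}
        np.testing.assert_allclose(
            ind.expression.values,
            expr.values[[expr.gene_ids.index(g) for g in ind.nodes]])

    def test_disjoint_universes_rejected(self):
        net = PPINetwork.from_edges([("X", "Y")])
        expr = _expr_for(["A", "B"])
        with pytest.raises(ValueError):
            overlay(expr, net, GeneProteinMap((("A", "A"), ("B", "B"))))

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(7)
        net = PPINetwork.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "F")])
        expr = _expr_for(["A", "B", "C", "D", "Z"], rng)
        mapping = GeneProteinMap.identity(["A", "B", "C", "D", "E", "Z"])
        ind1 = overlay(expr, net, mapping)
        assert ind1.network.n_proteins <= net.n_proteins
        assert ind1.network.n_interactions <= net.n_interactions
        ind2 = overlay(ind1.expression, ind1.network,
                       GeneProteinMap.identity(ind1.nodes))
        assert set(ind2.nodes) == set(ind1.nodes)
        assert sorted(ind2.network.edges()) == sorted(ind1.network.edges())
        np.testing.assert_array_equal(ind2.expression.values,
                                      ind1.expression.values)

    def test_protein_keeps_highest_variance_gene(self):
        net = PPINetwork.from_edges([("P1", "P2")])
        values = np.array([[0.0, 0.0, 0.0, 0.1],     # gLow: tiny variance
                           [-3.0, 3.0, -3.0, 3.0],   # gHigh: large variance
                           [1.0, 2.0, 1.0, 2.0]])
        expr = ExpressionDataset(gene_ids=("gLow", "gHigh", "gP2"),
                                 values=values,
                                 labels=np.array([1, 1, 2, 2]))
        mapping = GeneProteinMap(
            (("gLow", "P1"), ("gHigh", "P1"), ("gP2", "P2")))
        ind = overlay(expr, net, mapping)
        assert ind.node_gene["P1"] == "gHigh"
        np.testing.assert_allclose(
            ind.expression.values[ind.nodes.index("P1")], values[1])


class TestMarkerIO:
    @pytest.fixture
    def markers(self):
        return MarkerSet(
            markers=(
                Marker(genes=("g1", "g2"), exemplar="g1", t_score=4.0),
                Marker(genes=("g3",), exemplar="g3", t_score=-2.5),
            ),
            provenance={"topo_index": "tversky", "alpha": 0.5},
        )

    def test_json_round_trip_lossless(self, tmp_path, markers):
        p = tmp_path / "m.json"
        write_markers(markers, p, format="json")
        back = read_markers(p)
        assert back.markers == markers.markers
        assert back.provenance == dict(markers.provenance)

    def test_gmt_one_line_per_marker(self, tmp_path, markers):
        p = tmp_path / "m.gmt"
        write_markers(markers, p, format="gmt")
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 2
        fields = lines[0].split("\t")
        assert fields[2:] == ["g1", "g2"]
        # single-member marker still yields a valid 3-field line
        assert lines[1].split("\t")[2:] == ["g3"]

    def test_empty_marker_set_rejected_on_write(self, tmp_path):
        empty = MarkerSet(markers=())  # construction is fine...
        assert empty.gene_union() == frozenset()
        with pytest.raises(ValueError):  # ...but writing must fail
            write_markers(empty, tmp_path / "m.json")

    def test_overlapping_members_rejected(self):
        with pytest.raises(ValueError):
            MarkerSet(markers=(
                Marker(genes=("g1",), exemplar="g1", t_score=3.0),
                Marker(genes=("g1", "g2"), exemplar="g2", t_score=1.0),
            ))

    def test_misordered_scores_rejected(self):
        with pytest.raises(ValueError):
            MarkerSet(markers=(
                Marker(genes=("g1",), exemplar="g1", t_score=1.0),
                Marker(genes=("g2",), exemplar="g2", t_score=5.0),
            ))
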