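import numpy as np
import pandas as pd
import pytest

from decidiff.deg import DEGSet
from decidiff.clustering import Dendrogram
from decidiff.errors import FormatError
from decidiff.formats import (CellMatrix, ExpressionMatrix, StudyDesign,
                              read_cell_matrix, read_deg_table,
                              read_expression_tsv, read_obo_subset,
                              write_cell_matrix, write_deg_table,
                              write_expression_tsv, write_obo_subset,
                              read_annotation_tsv, write_annotation_tsv,
                              write_outputs)
from decidiff.errors import DesignError


class TestExpressionTSV:
    def test_round_trip_identity(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_expression_tsv(tiny_matrix, path)
        again = read_expression_tsv(path)
        pd.testing.assert_frame_equal(again.data, tiny_matrix.data,
                                      check_exact=False, rtol=1e-5,
                                      check_dtype=False)
        assert again.gene_ids == tiny_matrix.gene_ids  # order preserved

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\ts1\nACTB\t1.0\nACTB\t2.0\n")
        with pytest.raises(FormatError, match="ACTB"):
            read_expression_tsv(path)

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\ts1\ts1\nACTB\t1.0\t2.0\n")
        with pytest.raises(FormatError, match="s1"):
            read_expression_tsv(path)

    def test_negative_value_names_cell(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\ts1\ts2\nACTB\t1.0\t-1.0\n")
        with pytest.raises(FormatError) as err:
            read_expression_tsv(path)
        assert "ACTB" in str(err.value) and "s2" in str(err.value)

    def test_non_numeric_value_names_cell(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\ts1\nACTB\tlow\n")
        with pytest.raises(FormatError, match="ACTB"):
            read_expression_tsv(path)


class TestCellMatrixIO:
    def test_unlisted_coordinates_are_zero(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            "5 4 3\n1 1 2.0\n3 2 4.0\n5 4 1.5\n")
        (tmp_path / "genes.txt").write_text("\n".join(
            f"g{i}" for i in range(1, 6)) + "\n")
        (tmp_path / "cells.tsv").write_text(
            "cell_id\tphase\n" + "\n".join(
                f"c{i}\tlate_secretory" for i in range(1, 5)) + "\n")
        cm = read_cell_matrix(tmp_path / "m.mtx", tmp_path / "genes.txt",
                              tmp_path / "cells.tsv")
        assert cm.data.loc["g1", "c1"] == 2.0
        assert cm.data.loc["g3", "c2"] == 4.0
        assert cm.data.loc["g2", "c3"] == 0.0
        assert cm.data.to_numpy().sum() == pytest.approx(7.5)

    def test_unknown_phase_lists_allowed_labels(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            "1 1 1\n1 1 1.0\n")
        (tmp_path / "genes.txt").write_text("g1\n")
        (tmp_path / "cells.tsv").write_text("cell_id\tphase\nc1\tmid_secretory\n")
        with pytest.raises(FormatError, match="late_proliferative"):
            read_cell_matrix(tmp_path / "m.mtx", tmp_path / "genes.txt",
                             tmp_path / "cells.tsv")

    def test_missing_cell_metadata_rejected(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            "1 2 1\n1 1 1.0\n")
        (tmp_path / "genes.txt").write_text("g1\n")
        (tmp_path / "cells.tsv").write_text("cell_id\tphase\nc1\tlate_secretory\n")
        with pytest.raises(FormatError, match="absent from metadata"):
            read_cell_matrix(tmp_path / "m.mtx", tmp_path / "genes.txt",
                             tmp_path / "cells.tsv")

    def test_round_trip_random_matrix(self, tmp_path):
        rng = np.random.default_rng(0)
        dense = rng.random((6, 5)) * (rng.random((6, 5)) > 0.4)
        genes = [f"g{i}" for i in range(6)]
        cells = [f"c{i}" for i in range(5)]
        phases = {c: ("late_secretory" if i % 2 else "late_proliferative")
                  for i, c in enumerate(cells)}
        cm = CellMatrix(pd.DataFrame(dense, index=genes, columns=cells), phases)
        write_cell_matrix(cm, tmp_path / "m.mtx", tmp_path / "g.txt",
                          tmp_path / "c.tsv")
        again = read_cell_matrix(tmp_path / "m.mtx", tmp_path / "g.txt",
                                 tmp_path / "c.tsv")
        np.testing.assert_allclose(again.data.to_numpy(), dense, rtol=1e-8)
        assert dict(again.phase_of) == phases


class TestOBO:
    def test_linear_chain(self, tmp_path):
        path = tmp_path / "o.obo"
        stanzas = ["format-version: 1.2", ""]
        parents = [None, "T:1", "T:2", "T:3"]
        for i, parent in enumerate(parents, 1):
            stanzas += [f"[Term]", f"id: T:{i}", f"name: term {i}",
                        "namespace: biological_process"]
            if parent:
                stanzas.append(f"is_a: {parent} ! term")
            stanzas.append("")
        path.write_text("\n".join(stanzas))
        onto = read_obo_subset(path)
        assert onto.roots == {"T:1"}
        assert onto.ancestors("T:4") == {"T:1", "T:2", "T:3"}

    def test_undeclared_is_a_target(self, tmp_path):
        path = tmp_path / "o.obo"
        path.write_text("format-version: 1.2\n\n[Term]\nid: T:1\n"
                        "name: one\nis_a: T:99 ! ghost\n")
        with pytest.raises(FormatError, match="T:99"):
            read_obo_subset(path)

    def test_cycle_rejected(self, tmp_path):
        path = tmp_path / "o.obo"
        path.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: T:1\nname: one\nis_a: T:2 ! two\n\n"
            "[Term]\nid: T:2\nname: two\nis_a: T:1 ! one\n")
        with pytest.raises(FormatError, match="cycle"):
            read_obo_subset(path)

    def test_diamond_retains_both_parents(self, diamond_ontology, tmp_path):
        path = tmp_path / "o.obo"
        write_obo_subset(diamond_ontology, path)
        again = read_obo_subset(path)
        # hand enumeration of the expected edge set
        assert set(again.graph.edges) == {
            ("A", "R"), ("B", "R"), ("C", "A"), ("C", "B"),
            ("D", "C"), ("E", "B")}
        assert again.parents("C") == {"A", "B"}


class TestAnnotationTSV:
    def test_read_and_dedup(self, diamond_ontology, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text("g1\tD\ng1\tD\ng2\tE\ng1\tA\n")
        ann = read_annotation_tsv(path, diamond_ontology)
        assert len(ann.direct) == 2
        assert ann.direct["g1"] == frozenset({"D", "A"})
        assert ann.population == frozenset({"g1", "g2"})

    def test_unknown_term_rejected(self, diamond_ontology, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text("g1\tZZ\n")
        with pytest.raises(FormatError, match="ZZ"):
            read_annotation_tsv(path, diamond_ontology)

    def test_round_trip(self, diamond_ontology, diamond_annotation, tmp_path):
        path = tmp_path / "a.tsv"
        write_annotation_tsv(diamond_annotation, path)
        again = read_annotation_tsv(path, diamond_ontology)
        assert again.direct == diamond_annotation.direct


class TestProductWriters:
    def test_two_leaf_newick_shape(self, tmp_path):
        dend = Dendrogram(("A", "B"), [(("A",), ("B",), 2.5)])
        assert dend.to_newick() == "(A:2.5,B:2.5);"

    def test_empty_degset_header_only(self, tmp_path):
        path = tmp_path / "deg.tsv"
        write_deg_table(DEGSet("x"), path)
        assert path.read_text() == "contrast\tgene\tdirection\tfold_change\n"
        assert read_deg_table(path) == {}

    def test_deg_table_round_trip(self, tmp_path):
        ds = DEGSet("cAMP", {"g1": 2.345678, "g2": 7.0},
                    {"g3": 0.1234567})
        path = tmp_path / "deg.tsv"
        write_deg_table(ds, path)
        again = read_deg_table(path)["cAMP"]
        assert again.up_genes == {"g1", "g2"}
        assert again.down_genes == {"g3"}
        assert again.up["g1"] == pytest.approx(2.345678, rel=1e-5)
        assert again.down["g3"] == pytest.approx(0.1234567, rel=1e-5)

    def test_write_outputs_dispatch(self, tmp_path):
        write_outputs({"n": 3}, tmp_path / "s.json")
        assert '"n": 3' in (tmp_path / "s.json").read_text()
        with pytest.raises(TypeError):
            write_outputs(object(), tmp_path / "x")


class TestStudyDesign:
    def test_control_protocol_consistency(self):
        with pytest.raises(DesignError, match="different protocol"):
            StudyDesign(("a", "b"), {"a": "ctrl", "b": "ctrl"},
                        {"a": 4, "b": 14})

    def test_missing_control_rejected(self):
        with pytest.raises(DesignError, match="without a control"):
            StudyDesign(("a",), {}, {"a": 4})
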