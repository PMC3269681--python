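"""Matrix container, TSV dialect, merging, gene-set subsetting, log transform."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_matrix
from gpinet import datamodel
from gpinet.datamodel import (
    AlignmentError,
    GeneSet,
    MatrixFormatError,
    NodeDescriptor,
    SampleMatrix,
    SelectionError,
    aggregate_condition_means,
    combine,
    make_phenotype_nodes,
    read_gmt,
    read_sample_matrix,
    subset_by_gene_set,
    table2_gene_sets,
    to_log_space,
    write_sample_matrix,
)


def write_tsv(path, rows):
    path.write_text("\n".join("\t".join(str(c) for c in row) for row in rows) + "\n")


KIND3 = {"Fmr1": "gene", "Mecp2": "gene", "Neurite_length": "phenotype"}


class TestReadSampleMatrix:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_tsv(path, [
            ["node", "s1", "s2", "s3", "s4"],
            ["#condition", "DMSO", "DMSO", "T3", "T3"],
            ["Fmr1", 1.0, 2.0, 3.0, 4.0],
            ["Mecp2", 0.5, 0.25, 1.5, 2.5],
            ["Neurite_length", 10, 11, 12, 13],
        ])
        m = read_sample_matrix(path, KIND3)
        assert (m.n_nodes, m.n_samples) == (3, 4)
        assert m.space == "raw"
        assert m.node_names == ["Fmr1", "Mecp2", "Neurite_length"]
        assert m.condition == ["DMSO", "DMSO", "T3", "T3"]
        assert m.nodes[2].kind == "phenotype"
        np.testing.assert_allclose(m.values[0], [1, 2, 3, 4])

    def test_zero_value_names_offender(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_tsv(path, [
            ["node", "s1", "s2", "s3"],
            ["#condition", "a", "a", "a"],
            ["Fmr1", 1.0, 0.0, 3.0],
            ["Mecp2", 1.0, 1.0, 1.0],
        ])
        with pytest.raises(MatrixFormatError, match="Fmr1.*s2"):
            read_sample_matrix(path, KIND3)

    def test_duplicate_node_row(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_tsv(path, [
            ["node", "s1", "s2", "s3"],
            ["#condition", "a", "a", "a"],
            ["Fmr1", 1, 2, 3],
            ["Fmr1", 4, 5, 6],
        ])
        with pytest.raises(MatrixFormatError, match="duplicate node"):
            read_sample_matrix(path, KIND3)

    @pytest.mark.parametrize("bad_cell", ["abc", ""])
    def test_non_numeric_cell(self, tmp_path, bad_cell):
        path = tmp_path / "m.tsv"
        write_tsv(path, [
            ["node", "s1", "s2", "s3"],
            ["#condition", "a", "a", "a"],
            ["Fmr1", 1, bad_cell, 3],
            ["Mecp2", 1, 1, 1],
        ])
        with pytest.raises(MatrixFormatError):
            read_sample_matrix(path, KIND3)

    def test_missing_kind(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_tsv(path, [
            ["node", "s1", "s2", "s3"],
            ["#condition", "a", "a", "a"],
            ["Fmr1", 1, 2, 3],
            ["Unknown9", 1, 1, 1],
        ])
        with pytest.raises(MatrixFormatError, match="Unknown9"):
            read_sample_matrix(path, KIND3)

    def test_round_trip_bit_exact(self, tmp_path, rng):
        m = make_matrix(np.exp(rng.normal(size=(4, 6))))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_sample_matrix(m, p1)
        kinds = {n.name: n.kind for n in m.nodes}
        m2 = read_sample_matrix(p1, kinds)
        write_sample_matrix(m2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(m.values, m2.values)


class TestCombine:
    def test_gene_plus_phenotype(self, rng):
        expr = make_matrix(np.exp(rng.normal(size=(16, 30))))
        pheno = make_matrix(np.exp(rng.normal(size=(10, 30))))
        pheno.nodes = [NodeDescriptor(f"p{i}", "phenotype") for i in range(10)]
        out = combine(expr, pheno)
        assert (out.n_nodes, out.n_samples) == (26, 30)
        assert [n.kind for n in out.nodes] == ["gene"] * 16 + ["phenotype"] * 10
        np.testing.assert_array_equal(out.values[:16], expr.values)

    def test_sample_order_mismatch(self, rng):
        a = make_matrix(np.exp(rng.normal(size=(3, 4))))
        b = make_matrix(np.exp(rng.normal(size=(3, 4))))
        b.nodes = [NodeDescriptor(f"p{i}", "phenotype") for i in range(3)]
        b.sample_ids = list(reversed(b.sample_ids))
        with pytest.raises(AlignmentError, match="sample IDs"):
            combine(a, b)

    def test_dose_absent_is_identity_on_kinds(self, rng):
        a = make_matrix(np.exp(rng.normal(size=(3, 4))))
        b = make_matrix(np.exp(rng.normal(size=(2, 4))))
        b.nodes = [NodeDescriptor(f"p{i}", "phenotype") for i in range(2)]
        out = combine(a, b, dose=None)
        assert {n.kind for n in out.nodes} == {"gene", "phenotype"}

    def test_dose_matrix_appended_last(self, rng):
        expr = make_matrix(np.exp(rng.normal(size=(3, 4))))
        pheno = make_matrix(np.exp(rng.normal(size=(2, 4))))
        pheno.nodes = [NodeDescriptor(f"p{i}", "phenotype") for i in range(2)]
        dose = make_matrix(np.full((2, 4), 10.0))
        dose.nodes = [NodeDescriptor("dose_uM", "dose"), NodeDescriptor("t", "dose")]
        out = combine(expr, pheno, dose)
        assert out.n_nodes == 7
        assert [n.kind for n in out.nodes][-2:] == ["dose", "dose"]

    def test_duplicate_names_rejected(self, rng):
        a = make_matrix(np.exp(rng.normal(size=(3, 4))))
        b = make_matrix(np.exp(rng.normal(size=(3, 4))))
        with pytest.raises(AlignmentError, match="duplicate"):
            combine(a, b)


class TestSubsetByGeneSet:
    def test_autism_set_against_full_matrix(self, rng):
        gs = table2_gene_sets()["Autism"]
        assert len(gs.symbols) == 18
        nodes = [NodeDescriptor(s, "gene") for s in gs.symbols]
        nodes += make_phenotype_nodes()
        m = SampleMatrix(
            nodes, np.exp(rng.normal(size=(28, 5))),
            [f"s{i}" for i in range(5)], ["c"] * 5,
        )
        sub, unmatched = subset_by_gene_set(m, gs, keep_kinds={"phenotype"})
        assert sub.n_nodes == 28
        assert unmatched == []

    def test_case_insensitive_match_and_unmatched_report(self, rng):
        m = make_matrix(np.exp(rng.normal(size=(3, 4))))
        m.nodes = [NodeDescriptor(n, "gene") for n in ["FMR1", "Mecp2", "Reln"]]
        gs = GeneSet("toy", ("fmr1", "MECP2", "Ube3a"))
        sub, unmatched = subset_by_gene_set(m, gs, keep_kinds=set())
        assert sub.node_names == ["FMR1", "Mecp2"]
        assert unmatched == ["Ube3a"]

    def test_empty_selection_error(self, rng):
        m = make_matrix(np.exp(rng.normal(size=(3, 4))))
        gs = GeneSet("toy", ("NotPresent",))
        with pytest.raises(SelectionError):
            subset_by_gene_set(m, gs, keep_kinds=set())

    def test_subset_commutes_with_combine(self, rng):
        gs = table2_gene_sets()["Parkinson"]
        expr_nodes = [NodeDescriptor(s, "gene") for s in gs.symbols[:6]]
        expr = SampleMatrix(expr_nodes, np.exp(rng.normal(size=(6, 4))),
                            [f"s{i}" for i in range(4)], ["c"] * 4)
        pheno_nodes = make_phenotype_nodes()[:3]
        pheno = SampleMatrix(pheno_nodes, np.exp(rng.normal(size=(3, 4))),
                             [f"s{i}" for i in range(4)], ["c"] * 4)
        sub_then_combine = combine(
            subset_by_gene_set(expr, gs, keep_kinds=set())[0], pheno
        )
        combine_then_sub, _ = subset_by_gene_set(
            combine(expr, pheno), gs, keep_kinds={"phenotype"}
        )
        assert sub_then_combine.node_names == combine_then_sub.node_names
        np.testing.assert_array_equal(
            sub_then_combine.values, combine_then_sub.values
        )


class TestToLogSpace:
    def test_known_values(self):
        m = make_matrix([[np.e, 1.0, 0.5e-6], [1.0, 1.0, 1.0]])
        out = to_log_space(m, floor=1e-6)
        assert out.space == "log"
        assert out.values[0, 0] == pytest.approx(1.0)
        assert out.values[0, 1] == 0.0
        assert out.values[0, 2] == pytest.approx(np.log(1e-6))
        assert out.n_floored == 1

    def test_double_transform_rejected(self, small_raw_matrix):
        once = to_log_space(small_raw_matrix)
        with pytest.raises(MatrixFormatError, match="already"):
            to_log_space(once)

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3),
                    min_size=6, max_size=6))
    def test_log_exp_round_trip(self, flat):
        m = make_matrix(np.asarray(flat).reshape(2, 3))
        out = to_log_space(m, floor=1e-6)
        np.testing.assert_allclose(np.exp(out.values), m.values, rtol=1e-12)
        assert out.n_floored == 0


class TestGeneSets:
    def test_table2_roster(self):
        sets = table2_gene_sets()
        sizes = {name: len(gs.symbols) for name, gs in sets.items()}
        assert sizes == {
            "Alzheimer": 16, "Autism": 18, "Parkinson": 15,
            "Axon_guidance": 21, "Pluripotent": 22,
            "Neural_development": 21, "Oxidative_stress": 26,
        }

    def test_gmt_rejects_short_lines(self, tmp_path):
        bad = tmp_path / "bad.gmt"
        bad.write_text("OnlyName\tdesc\n")
        with pytest.raises(MatrixFormatError):
            read_gmt(bad)


def test_aggregate_condition_means(rng):
    m = make_matrix(
        np.exp(rng.normal(size=(2, 6))),
        condition=["a", "a", "b", "b", "c", "c"],
    )
    out = aggregate_condition_means(m)
    assert out.sample_ids == ["a", "b", "c"]
    np.testing.assert_allclose(out.values[:, 0], m.values[:, :2].mean(axis=1))
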