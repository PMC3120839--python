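import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ctfingerprint as cf
from ctfingerprint.errors import ParseError, ValidationError

from conftest import expr


def write_table(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCtTable:
    def test_echoes_values_and_floors_nondetects(self, tmp_path):
        p = write_table(tmp_path, "cell,gA,gB\nc1,12.1,40\nc2,18.5,39.2\n")
        ct = cf.read_ct_table(p)
        assert ct.cell_ids == ["c1", "c2"]
        assert ct.gene_ids == ["gA", "gB"]
        np.testing.assert_array_equal(ct.values, [[12.1, 40.0], [18.5, 39.2]])
        assert ct.nondetect_mask.sum() == 1

    def test_values_above_lod_floored(self, tmp_path):
        p = write_table(tmp_path, "cell,gA\nc1,41.3\n")
        ct = cf.read_ct_table(p, lod_ct=40)
        assert ct.values[0, 0] == 40.0

    def test_missing_entries_become_nondetects(self, tmp_path):
        p = write_table(tmp_path, "cell,gA,gB\nc1,,20\nc2,NA,21\n")
        ct = cf.read_ct_table(p)
        assert (ct.values[:, 0] == 40.0).all()

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = write_table(tmp_path, "cell,gA,gA\nc1,12,13\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            cf.read_ct_table(p)

    def test_non_numeric_payload_names_row_and_column(self, tmp_path):
        p = write_table(tmp_path, "cell,gA,gB\nc1,12,oops\n")
        with pytest.raises(ParseError, match=r"c1.*gB|gB.*c1"):
            cf.read_ct_table(p)

    def test_tsv_dialect_from_extension(self, tmp_path):
        p = write_table(tmp_path, "cell\tgA\nc1\t22.5\n", name="t.tsv")
        assert cf.read_ct_table(p).values[0, 0] == 22.5

    def test_chip_export_shim_transposes(self, tmp_path):
        p = write_table(tmp_path, "assay,s1,s2\ngA,12,13\ngB,20,41\n")
        ct = cf.read_chip_export(p)
        assert ct.cell_ids == ["s1", "s2"]
        assert ct.gene_ids == ["gA", "gB"]
        np.testing.assert_array_equal(ct.values, [[12, 20], [13, 40]])


class TestCtMatrixInvariants:
    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValidationError):
            cf.CtMatrix(np.array([[45.0]]), ["c1"], ["g1"])
        with pytest.raises(ValidationError):
            cf.CtMatrix(np.array([[-1.0]]), ["c1"], ["g1"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cf.CtMatrix(np.ones((2, 2)) * 20, ["c1"], ["g1", "g2"])


class TestNormalize:
    def test_median_centering_definition(self):
        ct = cf.CtMatrix(np.array([[20.0], [22.0], [24.0]]), list("abc"), ["g"])
        e = cf.normalize(ct)
        np.testing.assert_allclose(e.values[:, 0], [2.0, 0.0, -2.0])

    def test_nondetect_hits_clamp_floor(self):
        # median 20; 20 - 40 = -20 clamps to -5
        ct = cf.CtMatrix(np.array([[20.0], [20.0], [40.0]]), list("abc"), ["g"])
        e = cf.normalize(ct, clamp_bound=5)
        np.testing.assert_allclose(e.values[:, 0], [0.0, 0.0, -5.0])

    def test_constant_gene_maps_to_zero(self):
        ct = cf.CtMatrix(np.full((4, 2), 25.0), list("abcd"), ["g1", "g2"])
        assert np.all(cf.normalize(ct).values == 0.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            cf.normalize(cf.CtMatrix(np.empty((0, 1)), [], ["g"]))

    def test_pooled_vs_per_population_medians(self):
        a = cf.CtMatrix(np.full((3, 1), 20.0), list("abc"), ["g"])
        b = cf.CtMatrix(np.full((3, 1), 24.0), list("def"), ["g"])
        ea, eb = cf.normalize_populations([a, b], pooled=True)
        # pooled median is 22 -> populations sit either side of zero
        assert np.all(ea.values == 2.0) and np.all(eb.values == -2.0)
        ea2, eb2 = cf.normalize_populations([a, b], pooled=False)
        assert np.all(ea2.values == 0.0) and np.all(eb2.values == 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.5, 40.0), min_size=2, max_size=20),
           st.floats(0.5, 8.0))
    def test_output_bounded_by_clamp(self, col, clamp):
        vals = np.array(col)[:, None]
        ct = cf.CtMatrix(vals, [f"c{i}" for i in range(len(col))], ["g"])
        e = cf.normalize(ct, clamp_bound=clamp)
        assert np.abs(e.values).max() <= clamp + 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(5.0, 30.0), min_size=3, max_size=15),
           st.floats(-4.0, 4.0))
    def test_shift_equivariance_before_clamp(self, col, c):
        vals = np.array(col)[:, None]
        ids = [f"c{i}" for i in range(len(col))]
        e1 = cf.normalize(cf.CtMatrix(vals, ids, ["g"]), clamp_bound=50)
        e2 = cf.normalize(cf.CtMatrix(vals + c, ids, ["g"]), clamp_bound=50)
        # adding a constant to the gene's Ct column shifts the median identically
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-9)


class TestChipLayout:
    @pytest.mark.parametrize("assays,samples,expected",
                             [(48, 48, 2304), (1, 1, 1), (48, 96, 4608)])
    def test_reaction_count(self, assays, samples, expected):
        assert cf.chip_reaction_count(cf.ChipLayout(assays, samples)) == expected

    def test_count_matches_grid_enumeration(self):
        layout = cf.ChipLayout(7, 11)
        brute = sum(1 for _ in range(7) for _ in range(11))
        assert cf.chip_reaction_count(layout) == brute

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValidationError):
            cf.ChipLayout(0, 48)


class TestRoundTrip:
    def test_expression_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        e = expr(rng.uniform(-5, 5, (20, 7)))
        p = tmp_path / "e.tsv"
        cf.write_expression_table(e, p)
        back = cf.read_expression_table(p)
        assert back.cell_ids == e.cell_ids and back.gene_ids == e.gene_ids
        np.testing.assert_array_equal(back.values, e.values)

    def test_rewrite_is_bitwise_identical(self, tmp_path, normalized_trio):
        e = normalized_trio["cd34lo"]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        cf.write_expression_table(e, p1)
        cf.write_expression_table(cf.read_expression_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_ct_roundtrip(self, tmp_path, fixture_trio):
        ct = fixture_trio.cd34lo
        p = tmp_path / "ct.csv"
        cf.write_ct_table(ct, p)
        back = cf.read_ct_table(p)
        np.testing.assert_array_equal(back.values, ct.values)
        assert back.gene_ids == ct.gene_ids

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            cf.ExpressionMatrix(np.empty((2, 0)), ["a", "b"], [])


def test_nondetect_gene_filter():
    vals = np.full((10, 2), 20.0)
    vals[:8, 1] = 40.0  # 80% nondetect in gene 2
    ct = cf.CtMatrix(vals, [f"c{i}" for i in range(10)], ["g1", "g2"])
    kept = cf.filter_genes_by_nondetect(ct, max_fraction=0.5)
    assert kept.gene_ids == ["g1"]
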