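import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualgcn.preprocess import (GeneInterval, ResponseRecord, SegmentCNV,
                                ZScoreNormalizer, filter_cell_lines,
                                filter_drugs, read_gene_intervals,
                                segment_to_gene_cnv, transform_cnv,
                                transform_expression)


def sample_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "cancer_type",
                                       "expr_available", "cnv_available"])


class TestFilterCellLines:
    def test_small_cancer_type_entirely_removed(self):
        rows = [(f"s{i}", "rare", True, True) for i in range(9)]
        rows += [(f"t{i}", "common", True, True) for i in range(12)]
        kept, log = filter_cell_lines(sample_table(rows))
        assert set(kept["cancer_type"]) == {"common"} and len(kept) == 12
        assert sum(1 for _, r in log if r == "cancer-type-too-small") == 9

    def test_missing_omics_and_annotation_reasons(self):
        rows = [("a", "lung", True, False), ("b", "lung", False, True),
                ("c", None, True, True)]
        rows += [(f"s{i}", "lung", True, True) for i in range(10)]
        kept, log = filter_cell_lines(sample_table(rows))
        reasons = dict(log)
        assert reasons["a"] == "cnv-missing"
        assert reasons["b"] == "expr-missing"
        assert reasons["c"] == "cancer-type-missing"
        assert len(kept) == 10

    def test_idempotent(self):
        rows = [(f"s{i}", "lung", True, True) for i in range(11)]
        rows += [(f"r{i}", "rare", True, True) for i in range(3)]
        once, _ = filter_cell_lines(sample_table(rows))
        twice, log2 = filter_cell_lines(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2 == []


class TestFilterDrugs:
    def test_shared_pubchem_id_drops_all_members(self):
        df = pd.DataFrame({"gdsc_id": ["d1", "d2", "d3"],
                           "pubchem_id": ["p1", "p1", "p2"]})
        kept = filter_drugs(df)
        assert list(kept["gdsc_id"]) == ["d3"]

    def test_missing_pubchem_dropped_unique_kept(self):
        df = pd.DataFrame({"gdsc_id": ["d1", "d2", "d3"],
                           "pubchem_id": ["", None, "p9"]})
        assert list(filter_drugs(df)["gdsc_id"]) == ["d3"]

    def test_duplicate_gdsc_rows_same_pubchem_survive(self):
        # one GDSC id listed twice is not an ambiguous mapping
        df = pd.DataFrame({"gdsc_id": ["d1", "d1"], "pubchem_id": ["p1", "p1"]})
        assert len(filter_drugs(df)) == 2


class TestTransforms:
    @pytest.mark.parametrize("fn,x,expected", [
        (transform_expression, 0, 0.0), (transform_expression, 1, 1.0),
        (transform_expression, 7, 3.0),
        (transform_cnv, 0, 0.0), (transform_cnv, 1, 1.0), (transform_cnv, 3, 2.0),
    ])
    def test_closed_form(self, fn, x, expected):
        assert fn(x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fn", [transform_expression, transform_cnv])
    def test_negative_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-0.1)

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=20, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_strictly_monotone(self, xs):
        # separate inputs by >= 1e-6 so strict ordering is representable
        xs = sorted({round(x, 6) for x in xs})
        if len(xs) < 2:
            return
        ys = transform_expression(np.array(xs))
        assert np.all(np.diff(ys) > 0)


class TestZScore:
    def test_training_matrix_standardized(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 2, size=(4, 10)))
        z = ZScoreNormalizer().fit_transform(df)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_hand_computed_values_population_sd(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        z = ZScoreNormalizer().fit_transform(df)
        np.testing.assert_allclose(z.values[0], [-1.224744871391589, 0.0,
                                                 1.224744871391589], atol=1e-12)

    def test_constant_row_maps_to_zero(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], index=["c", "g"])
        z = ZScoreNormalizer().fit_transform(df)
        assert np.all(z.loc["c"] == 0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 training samples"):
            ZScoreNormalizer().fit(pd.DataFrame([[1.0]]))

    def test_fit_on_train_apply_to_heldout_preserves_order(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame(rng.normal(size=(3, 8)))
        test = pd.DataFrame(rng.normal(size=(3, 5)))
        z = ZScoreNormalizer().fit(train).transform(test)
        for g in range(3):
            assert np.array_equal(np.argsort(test.iloc[g]), np.argsort(z.iloc[g]))


class TestSegmentToGene:
    GENE = GeneInterval("TP53", "chr17", 1001, 2000)  # L = 1000

    def test_uncovered_gene_is_neutral(self):
        assert segment_to_gene_cnv([], self.GENE) == pytest.approx(1.0, abs=1e-12)

    def test_full_cover_neutral_ratio(self):
        seg = SegmentCNV("s", "chr17", 500, 3000, 1.0)
        assert segment_to_gene_cnv([seg], self.GENE) == pytest.approx(1.0, abs=1e-12)

    def test_half_cover_ratio_three(self):
        seg = SegmentCNV("s", "chr17", 1001, 1500, 3.0)  # 500/1000 of the gene
        got = segment_to_gene_cnv([seg], self.GENE)
        assert got == pytest.approx(np.log2(3.0), abs=1e-12)

    def test_other_chromosome_ignored(self):
        seg = SegmentCNV("s", "chr1", 1001, 1500, 5.0)
        assert segment_to_gene_cnv([seg], self.GENE) == pytest.approx(1.0)

    def test_split_invariance(self):
        whole = [SegmentCNV("s", "chr17", 1001, 1800, 2.5)]
        split = [SegmentCNV("s", "chr17", 1001, 1399, 2.5),
                 SegmentCNV("s", "chr17", 1400, 1800, 2.5)]
        assert segment_to_gene_cnv(whole, self.GENE) == pytest.approx(
            segment_to_gene_cnv(split, self.GENE), abs=1e-12)

    def test_overlapping_segments_rejected(self):
        segs = [SegmentCNV("s", "chr17", 1001, 1500, 2.0),
                SegmentCNV("s", "chr17", 1400, 1900, 3.0)]
        with pytest.raises(ValueError, match="overlap"):
            segment_to_gene_cnv(segs, self.GENE)


def test_response_record_rejects_nonfinite():
    with pytest.raises(ValueError):
        ResponseRecord("d", "s", float("nan"))


def test_bed_coordinates_converted_to_one_based(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t999\t2000\tGENE1\t0\t+\n")
    (gi,) = read_gene_intervals(bed)
    assert (gi.start, gi.end, gi.length) == (1000, 2000, 1001)
    tsv = tmp_path / "genes.tsv"
    tsv.write_text("gene\tchrom\tstart\tend\nGENE1\tchr1\t1000\t2000\n")
    (gi2,) = read_gene_intervals(tsv)
    assert (gi2.start, gi2.end) == (1000, 2000)
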