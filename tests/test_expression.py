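import io

import numpy as np
import pandas as pd
import pytest

from stemwall import expression
from stemwall.expression import (
    ExpressionMatrix,
    NormalizedMatrix,
    ValidationError,
    detection_filter,
    housekeeping_qc,
    normalize_per20m,
    read_counts,
    scale_genes,
)

META = pd.DataFrame(
    {"internode": [9, 4], "replicate": [1, 1], "genotype": ["B73", "B73"]},
    index=["s1", "s2"],
)


class TestReadCounts:
    def test_parses_toy_tsv(self):
        tsv = io.StringIO("gene\ts1\ts2\ng1\t5\t10\ng2\t0\t3\ng3\t7\t7\n")
        m = read_counts(tsv, META)
        assert m.gene_ids == ["g1", "g2", "g3"]
        assert m.counts.shape == (3, 2)
        # library sizes default to column sums
        assert m.library_sizes["s1"] == 12

    def test_duplicate_gene_id_is_named(self):
        tsv = io.StringIO("gene\ts1\ts2\ng1\t5\t10\ng1\t1\t2\n")
        with pytest.raises(ValidationError, match="g1"):
            read_counts(tsv, META)

    def test_empty_file_errors(self):
        with pytest.raises(ValidationError, match="no data rows"):
            read_counts(io.StringIO("gene\ts1\ts2\n"), META)

    def test_sample_without_metadata_errors(self):
        tsv = io.StringIO("gene\ts1\ts9\ng1\t5\t10\n")
        with pytest.raises(ValidationError, match="s9"):
            read_counts(tsv, META)

    def test_explicit_library_size_wins_over_column_sum(self):
        tsv = io.StringIO("gene\ts1\ts2\ng1\t5\t10\n")
        m = read_counts(tsv, META, library_sizes={"s1": 1e6, "s2": 2e6})
        assert m.library_sizes["s1"] == 1e6

    def test_zero_library_size_rejected(self):
        tsv = io.StringIO("gene\ts1\ts2\ng1\t5\t10\n")
        with pytest.raises(ValidationError, match="library"):
            read_counts(tsv, META, library_sizes={"s1": 0, "s2": 1e6})


class TestNormalizePer20M:
    def test_linear_scaling_to_20m(self, toy_matrix):
        norm = normalize_per20m(toy_matrix)
        # count 50 at library 10M -> 100 per 20M; replicate s2 gives 120;
        # the collapsed value is the mean
        assert norm.values.loc["g1", 9] == pytest.approx((100 + 120) / 2)

    def test_replicates_scaling_to_80_and_120_average_to_100(self):
        counts = pd.DataFrame({"a": [40], "b": [120]}, index=["g"])
        meta = pd.DataFrame(
            {"internode": [5, 5], "replicate": [1, 2], "genotype": ["X", "X"]},
            index=["a", "b"],
        )
        libs = pd.Series({"a": 10e6, "b": 20e6})
        norm = normalize_per20m(ExpressionMatrix(counts, meta, libs))
        assert norm.values.loc["g", 5] == pytest.approx(100.0)

    def test_all_zero_counts_stay_zero(self):
        counts = pd.DataFrame({"a": [0], "b": [0]}, index=["g"])
        meta = pd.DataFrame(
            {"internode": [5, 5], "replicate": [1, 2], "genotype": ["X", "X"]},
            index=["a", "b"],
        )
        libs = pd.Series({"a": 1e6, "b": 1e6})
        norm = normalize_per20m(ExpressionMatrix(counts, meta, libs))
        assert (norm.values.to_numpy() == 0).all()

    def test_idempotent_on_already_scaled_single_replicate(self):
        counts = pd.DataFrame({"a": [100, 7], "b": [3, 40]}, index=["g1", "g2"])
        meta = pd.DataFrame(
            {"internode": [9, 4], "replicate": [1, 1], "genotype": ["X", "X"]},
            index=["a", "b"],
        )
        libs = pd.Series(20e6, index=["a", "b"])
        m = ExpressionMatrix(counts, meta, libs)
        once = normalize_per20m(m)
        assert np.allclose(once.values.to_numpy(), counts[["a", "b"]].to_numpy())

    def test_column_sums_reach_20m_when_libraries_are_column_sums(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(50, 3)), columns=["a", "b", "c"]
        )
        meta = pd.DataFrame(
            {"internode": [9, 8, 7], "replicate": [1, 1, 1], "genotype": ["X"] * 3},
            index=["a", "b", "c"],
        )
        norm = normalize_per20m(ExpressionMatrix(counts, meta))
        sums = norm.values.sum(axis=0).to_numpy()
        assert np.allclose(sums, 20e6, rtol=1e-3)

    def test_internode_order_is_youngest_first(self, toy_matrix):
        norm = normalize_per20m(toy_matrix)
        assert norm.internodes == [9, 4]

    def test_dispersion_variance_for_two_replicates(self, toy_matrix):
        norm = normalize_per20m(toy_matrix)
        # two replicates -> variance across the scaled values 100 and 120
        assert norm.dispersion.loc["g1", 9] == pytest.approx(np.var([100, 120], ddof=1))


class TestDetectionFilter:
    def _nm(self, rows):
        df = pd.DataFrame(rows, columns=[9, 4])
        return NormalizedMatrix(values=df, dispersion=df * 0)

    def test_threshold_arithmetic(self):
        nm = self._nm({"kept": [25.0, 0.0], "dropped": [10.0, 5.0]}).values
        nm = NormalizedMatrix(values=pd.DataFrame(
            {9: [25.0, 10.0], 4: [0.0, 5.0]}, index=["kept", "dropped"]),
            dispersion=pd.DataFrame(0.0, index=["kept", "dropped"], columns=[9, 4]))
        kept, report = detection_filter(nm, 1.0)
        assert kept == ["kept"]  # 25 per 20M = 1.25 CPM; 10 per 20M = 0.5 CPM
        assert report["n_dropped"] == 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.gamma(1, 40, size=(200, 4)), columns=[9, 8, 5, 4])
        nm = NormalizedMatrix(values=vals, dispersion=vals * 0)
        kept_low, _ = detection_filter(nm, 0.5)
        kept_high, _ = detection_filter(nm, 2.0)
        assert set(kept_high) <= set(kept_low)

    def test_planted_detectable_fraction_recovered(self):
        # 40,000 genes, 80% planted safely above 1 CPM, 20% safely below
        rng = np.random.default_rng(7)
        n = 40_000
        n_up = int(n * 0.8)
        peaks = np.concatenate(
            [rng.uniform(30, 3000, n_up), rng.uniform(0.1, 10, n - n_up)]
        )
        vals = pd.DataFrame({9: peaks, 4: peaks * rng.uniform(0, 1, n)})
        nm = NormalizedMatrix(values=vals, dispersion=vals * 0)
        kept, _ = detection_filter(nm, 1.0)
        assert abs(len(kept) - n_up) <= 0.01 * n


class TestScaleGenes:
    def test_zscore_definition(self):
        vals = pd.DataFrame({9: [1.0], 8: [2.0], 7: [3.0]}, index=["g"])
        nm = NormalizedMatrix(values=vals, dispersion=vals * 0)
        row = scale_genes(nm).values.loc["g"].to_numpy()
        expect = (np.array([1, 2, 3]) - 2) / np.std([1, 2, 3])
        assert np.allclose(row, expect)
        assert abs(row.mean()) < 1e-9

    def test_constant_row_becomes_zeros_with_warning(self):
        vals = pd.DataFrame({9: [5.0, 1.0], 8: [5.0, 2.0], 7: [5.0, 3.0]},
                            index=["flat", "g"])
        nm = NormalizedMatrix(values=vals, dispersion=vals * 0)
        scaled = scale_genes(nm)
        assert (scaled.values.loc["flat"] == 0).all()
        assert scaled.constant_genes == ["flat"]

    def test_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(2)
        base = pd.DataFrame(rng.gamma(2, 30, size=(20, 5)), columns=[9, 8, 7, 6, 5])
        nm1 = NormalizedMatrix(values=base, dispersion=base * 0)
        nm2 = NormalizedMatrix(values=base * 37.5, dispersion=base * 0)
        assert np.allclose(
            scale_genes(nm1).values.to_numpy(), scale_genes(nm2).values.to_numpy()
        )


class TestHousekeepingQC:
    def _matrix(self, factor_s3=1.0):
        rng = np.random.default_rng(3)
        panel = [f"hk{i}" for i in range(8)]
        base = rng.uniform(100, 1000, size=8)
        counts = pd.DataFrame(
            {s: base for s in ["s1", "s2", "s3"]}, index=panel
        ).round().astype(int)
        counts["s3"] = (counts["s3"] * factor_s3).round().astype(int)
        meta = pd.DataFrame(
            {"internode": [9, 8, 7], "replicate": [1, 1, 1], "genotype": ["X"] * 3},
            index=["s1", "s2", "s3"],
        )
        libs = pd.Series(20e6, index=counts.columns)
        return ExpressionMatrix(counts, meta, libs), panel

    def test_consistent_samples_pass(self):
        m, panel = self._matrix()
        qc = housekeeping_qc(m, panel)
        assert not qc["exclude"].any()
        assert np.allclose(qc["deviation"], 0.0)

    def test_collapsed_panel_sample_is_flagged(self):
        # panel counts multiplied by 0.05 -> deviation near log2(0.05) ~ -4.3
        m, panel = self._matrix(factor_s3=0.05)
        qc = housekeeping_qc(m, panel)
        assert qc.loc["s3", "exclude"]
        assert qc.loc["s3", "deviation"] < -2

    def test_too_few_panel_genes_errors(self):
        m, panel = self._matrix()
        with pytest.raises(ValidationError, match=">= 5"):
            housekeeping_qc(m, panel[:3])


def test_normalized_matrix_roundtrip(tmp_path, toy_matrix):
    norm = normalize_per20m(toy_matrix)
    path = tmp_path / "norm.tsv"
    expression.write_normalized(norm, path)
    back = expression.read_normalized(path)
    assert back.internodes == norm.internodes
    assert np.allclose(back.values.to_numpy(), norm.values.to_numpy(), rtol=1e-5)
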