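"""Filtering and normalization: hand oracles, boundaries, and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ptaging as pt
from ptaging.types import Layer

from conftest import make_matrix


class TestValidValues:
    def test_boundary_half_valid_retained(self):
        # 2/4 valid at every age with min_frac 0.5: boundary inclusive
        vals = np.ones((2, 12))
        vals[0, [0, 1, 4, 5, 8, 9]] = np.nan      # gene 0: 2/4 valid per age
        vals[1, [0, 1, 2, 4, 5, 6, 8, 9, 10]] = np.nan  # gene 1: 1/4 valid per age
        m = make_matrix(vals, reps=4)
        out, rep = pt.filter_valid_values(m, 0.5)
        assert out.genes == ["g0"]
        assert rep.steps[0].removed == ["g1"]

    def test_all_valid_identity(self):
        m = make_matrix(np.arange(12.0).reshape(2, 6))
        out, rep = pt.filter_valid_values(m)
        assert out.genes == m.genes
        assert rep.steps[0].genes_in == rep.steps[0].genes_out == 2


class TestContaminants:
    def test_listed_gene_removed(self):
        m = make_matrix(np.ones((2, 6)), genes=["Alb", "Snap25"])
        out, _ = pt.remove_contaminants(m, pt.default_contaminants())
        assert out.genes == ["Snap25"]

    def test_disjoint_set_identity(self):
        m = make_matrix(np.ones((2, 6)), genes=["a", "b"])
        out, rep = pt.remove_contaminants(m, pt.GeneSet("x", frozenset({"zzz"})))
        assert out.genes == ["a", "b"]
        assert rep.steps[0].removed == []

    def test_flagged_row_removed(self):
        m = make_matrix(np.ones((2, 6)), genes=["a", "b"])
        m.flags = pd.DataFrame({"Reverse": ["+", ""]}, index=["a", "b"], dtype="string")
        out, _ = pt.remove_contaminants(m, None)
        assert out.genes == ["b"]


class TestLowCounts:
    @pytest.mark.parametrize(
        "total, kept",
        [(5, False), (6, True), (0, False)],
        ids=["sum5-removed", "sum6-retained", "allzero-removed"],
    )
    def test_total_count_boundary(self, total, kept):
        vals = np.zeros((1, 6))
        vals[0, :total] = 1.0 if total <= 6 else None
        m = make_matrix(vals, layer=Layer.MRNA_TOTAL)
        out, _ = pt.filter_low_counts(m, 5)
        assert ("g0" in out.genes) == kept


class TestQuantileNormalize:
    def test_two_by_two_hand_oracle(self):
        # columns (1,3) and (4,2): sorted means (1.5, 3.5)
        m = make_matrix([[1, 4], [3, 2]], ages=(6,), reps=2)
        out = pt.quantile_normalize(m)
        expect = np.array([[1.5, 3.5], [3.5, 1.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expect)

    def test_identical_columns_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        m = make_matrix(np.column_stack([col] * 4), ages=(6, 12), reps=2)
        out = pt.quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_sorted_columns_identical_postcondition(self, rng):
        m = make_matrix(rng.lognormal(2, 1, (40, 6)))
        out = pt.quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, rtol=1e-12)

    def test_missing_cells_stay_missing(self, rng):
        vals = rng.lognormal(2, 1, (30, 6))
        vals[3, 2] = np.nan
        out = pt.quantile_normalize(make_matrix(vals))
        assert np.isnan(out.values.iloc[3, 2])
        assert out.values.notna().sum().sum() == 30 * 6 - 1


class TestMedianCenter:
    def test_divisive_hand_case(self):
        m = make_matrix([[2, 4, 6]], ages=(6,), reps=3)
        out = pt.median_center_rows(m, "divisive")
        np.testing.assert_allclose(out.values.to_numpy(), [[0.5, 1.0, 1.5]])

    def test_fixed_point(self):
        m = make_matrix([[0.5, 1.0, 1.5]], ages=(6,), reps=3)
        out = pt.median_center_rows(m, "divisive")
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_every_row_median_one(self, rng):
        m = make_matrix(rng.lognormal(3, 1, (25, 6)))
        out = pt.median_center_rows(m, "divisive")
        np.testing.assert_allclose(out.values.median(axis=1), 1.0, atol=1e-12)

    def test_subtractive_log_scale(self, rng):
        m = make_matrix(rng.normal(0, 1, (10, 6)))
        out = pt.median_center_rows(m, "subtractive")
        np.testing.assert_allclose(out.values.median(axis=1), 0.0, atol=1e-12)


class TestPercentileRank:
    def test_three_values_hand_oracle(self):
        m = make_matrix([[10], [20], [30]], ages=(6,), reps=1)
        out = pt.percentile_rank(m)
        np.testing.assert_allclose(out.values.iloc[:, 0], [1 / 3, 2 / 3, 1.0])

    def test_tie_at_top_average_rank(self):
        # n=4 with the top pair tied: ranks (3, 4) average 3.5 -> 0.875
        m = make_matrix([[1], [2], [9], [9]], ages=(6,), reps=1)
        out = pt.percentile_rank(m)
        np.testing.assert_allclose(out.values.iloc[2:, 0], [0.875, 0.875])

    def test_monotone_transform_invariance(self, rng):
        vals = rng.lognormal(0, 1, (30, 4))
        a = pt.percentile_rank(make_matrix(vals)).values.to_numpy()
        b = pt.percentile_rank(make_matrix(np.log(vals))).values.to_numpy()
        np.testing.assert_allclose(a, b)

    def test_output_in_unit_interval(self, rng):
        out = pt.percentile_rank(make_matrix(rng.normal(0, 1, (20, 6)))).values.to_numpy()
        assert (out > 0).all() and (out <= 1).all()

    def test_quantile_then_rank_equals_rank_alone(self, rng):
        m = make_matrix(rng.lognormal(2, 1, (50, 6)))
        direct = pt.percentile_rank(m).values.to_numpy()
        via_qn = pt.percentile_rank(pt.quantile_normalize(m)).values.to_numpy()
        np.testing.assert_allclose(direct, via_qn, atol=1e-12)


class TestStderrFilter:
    def test_zero_se_retained(self):
        m = make_matrix(np.full((1, 6), 7.0))
        out, _ = pt.filter_stderr(m, 1e-6)
        assert out.genes == ["g0"]

    def test_exact_threshold_removed(self):
        # log2 values per age (x, x + d): SE = d/2; choose d so SE == 0.12
        d = 0.24
        row = 2 ** np.array([[1.0, 1.0 + d, 2.0, 2.0 + d, 3.0, 3.0 + d]])
        m = make_matrix(row)
        out, _ = pt.filter_stderr(m, 0.12)
        assert out.genes == []
        out2, _ = pt.filter_stderr(m, 0.12 + 1e-9)
        assert out2.genes == ["g0"]

    def test_removal_rate_matches_sampling_distribution(self, rng):
        # Normal log2 noise, n=4 per age: per-age SE^2 ~ (sigma^2/4) * chi2_3 / 3.
        # Keep iff all three ages pass, so P(keep) = P(SE < t)^3.
        sigma, t, n_genes = 0.1, 0.06, 4000
        vals = 2 ** rng.normal(5, sigma, (n_genes, 12))
        m = make_matrix(vals, reps=4)
        out, _ = pt.filter_stderr(m, t)
        from scipy.stats import chi2

        p_age = chi2.cdf(3 * (t**2) * 4 / sigma**2, df=3)
        expected = p_age**3
        observed = len(out.genes) / n_genes
        se = np.sqrt(expected * (1 - expected) / n_genes)
        assert abs(observed - expected) < 4 * se + 1e-3


def test_cascade_report_bookkeeping(small_cohort):
    from ptaging.preprocess import preprocess_layer

    m = small_cohort.matrices[Layer.PROTEIN_TOTAL]
    out, rep = preprocess_layer(
        m, contaminants=pt.default_contaminants(), stderr_threshold=0.4
    )
    df = rep.to_frame()
    assert (df["genes_in"] - df["genes_out"] == df["n_removed"]).all()
    # consecutive stages chain: genes_out of one step = genes_in of the next
    assert (df["genes_in"].iloc[1:].to_numpy() == df["genes_out"].iloc[:-1].to_numpy()).all()
    assert out.values.shape[0] == df["genes_out"].iloc[-1]
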