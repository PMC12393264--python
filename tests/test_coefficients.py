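"""Coefficient tables, cross-age Z-scores, distribution shape, correlations."""

import numpy as np
import pandas as pd
import pytest

import ptaging as pt
from ptaging.coefficients import fwhm_of_values, zscore_frame
from ptaging.types import Layer

from conftest import make_matrix


def ranked(vals, layer, **kw):
    return pt.percentile_rank(make_matrix(vals, layer=layer, **kw))


class TestRatio:
    def test_rank_ratio_arithmetic(self):
        # protein rank 0.8 vs mRNA rank 0.4 in the same animal -> raw ratio 2
        pcol = np.array([0.8, 0.4, 0.2, 0.6, 1.0])
        mcol = np.array([0.4, 0.8, 0.2, 0.6, 1.0])
        prot = make_matrix(np.column_stack([pcol, pcol]), ages=(6,), reps=2)
        mrna = make_matrix(
            np.column_stack([mcol, mcol]), layer=Layer.MRNA_TOTAL, ages=(6,), reps=2
        )
        t = pt.compute_ratio_coefficient(prot, mrna, "pm", renormalize=False)
        assert t.ratio.iloc[0, 0] == pytest.approx(2.0)

    def test_identical_layers_give_unit_ratio_zero_z(self, rng):
        vals = rng.lognormal(0, 1, (30, 6))
        a = ranked(vals, Layer.PROTEIN_TOTAL)
        b = ranked(vals, Layer.MRNA_TOTAL)
        t = pt.compute_ratio_coefficient(a, b, "pm", renormalize=False)
        np.testing.assert_allclose(t.ratio.to_numpy(), 1.0)
        np.testing.assert_allclose(t.z.to_numpy(), 0.0)
        assert set(t.constant_genes) == set(t.ratio.index)

    def test_unmatched_animal_dropped(self, rng):
        vals = rng.lognormal(0, 1, (10, 6))
        a = ranked(vals, Layer.PROTEIN_TOTAL)
        b = ranked(vals[:, :5], Layer.MRNA_TOTAL)  # one animal missing
        with pytest.warns(UserWarning, match="unmatched"):
            t = pt.compute_ratio_coefficient(a, b, "pm")
        assert t.ratio.shape[1] == 5

    def test_planted_offset_sign_recovered(self, small_cohort, small_stack):
        # mito-like set: planted p/m drop at 24m -> its median Z at 24m is
        # below the complement's
        pm = small_stack["coeffs"]["pm"]
        mito = {s.name: s for s in small_cohort.gene_sets}["mito_like"]
        per_age = pm.per_age_mean("z")
        old = per_age.columns[-1]
        members = sorted(mito.intersect(per_age.index))
        rest = per_age.index.difference(members)
        assert per_age.loc[members, old].median() < per_age.loc[rest, old].median()


class TestZscore:
    def test_three_values_hand_case(self):
        z, const = zscore_frame(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])
        assert const == []

    def test_constant_gene_flagged_zero(self):
        z, const = zscore_frame(pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"]))
        np.testing.assert_allclose(z.to_numpy(), 0.0)
        assert const == ["g"]

    def test_mean_zero_sd_one_property(self, rng):
        x = pd.DataFrame(rng.normal(0, 2, (50, 12)))
        z, const = zscore_frame(x)
        assert const == []
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)


class TestDistributionStats:
    def test_gaussian_fwhm_closed_form(self, rng):
        sigma = 0.7
        x = rng.normal(0.0, sigma, 50_000)
        res = fwhm_of_values(x)
        assert res.fwhm == pytest.approx(2.3548 * sigma, rel=0.03)

    def test_gaussian_median_abs(self, rng):
        x = np.abs(rng.normal(0.0, 1.0, 50_000))
        assert np.median(x) == pytest.approx(0.6745, abs=0.01)

    def test_scale_equivariance(self, rng):
        x = rng.normal(0, 1, 5_000)
        f1 = fwhm_of_values(x).fwhm
        f3 = fwhm_of_values(3.0 * x).fwhm
        assert f3 == pytest.approx(3.0 * f1, rel=1e-9)

    def test_bimodal_flagged(self, rng):
        x = np.concatenate([rng.normal(-3, 0.3, 2000), rng.normal(3, 0.3, 2000)])
        assert fwhm_of_values(x).n_crossings > 2


class TestInterlayerCorrelation:
    def test_self_correlation_is_one(self, rng):
        vals = rng.lognormal(0, 1, (50, 6))
        a = make_matrix(vals, layer=Layer.PROTEIN_TOTAL)
        b = make_matrix(vals, layer=Layer.MRNA_TOTAL)
        corr = pt.interlayer_correlation(a, b)
        np.testing.assert_allclose(corr["rho"], 1.0)

    def test_rank_reversal_is_minus_one(self, rng):
        vals = rng.lognormal(0, 1, (50, 6))
        a = make_matrix(vals, layer=Layer.PROTEIN_TOTAL)
        b = make_matrix(-vals, layer=Layer.MRNA_TOTAL)
        corr = pt.interlayer_correlation(a, b)
        np.testing.assert_allclose(corr["rho"], -1.0)

    def test_matches_rank_pearson_oracle(self, rng):
        from scipy.stats import rankdata

        vals_a = rng.normal(0, 1, (50, 6))
        vals_b = rng.normal(0, 1, (50, 6))
        a = make_matrix(vals_a, layer=Layer.PROTEIN_TOTAL)
        b = make_matrix(vals_b, layer=Layer.MRNA_TOTAL)
        corr = pt.interlayer_correlation(a, b).set_index("animal_id")
        for j, s in enumerate(a.samples):
            rx, ry = rankdata(vals_a[:, j]), rankdata(vals_b[:, j])
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert corr.loc[s.animal_id, "rho"] == pytest.approx(oracle, abs=1e-12)

    def test_age_medians(self, small_cohort, small_stack):
        # correlation over abundances (raw layers, filtered genes): the
        # generator couples protein baselines to mRNA baselines, so the
        # median per-animal Spearman is clearly positive at every age
        norm = small_stack["normalized"]
        raw = small_cohort.matrices
        corr = pt.interlayer_correlation(
            raw[Layer.PROTEIN_TOTAL].subset_genes(norm[Layer.PROTEIN_TOTAL].genes),
            raw[Layer.MRNA_TOTAL].subset_genes(norm[Layer.MRNA_TOTAL].genes),
        )
        med = pt.correlation_age_medians(corr)
        assert list(med.index) == [6, 12, 24]
        assert (med > 0.2).all()


class TestLogFC:
    @pytest.fixture()
    def table(self, rng):
        vals = rng.lognormal(0, 1, (20, 6))
        a = ranked(vals * [1, 1, 2, 2, 4, 4], Layer.PROTEIN_TOTAL)
        b = ranked(vals, Layer.MRNA_TOTAL)
        return pt.compute_ratio_coefficient(a, b, "pm", renormalize=False)

    def test_equal_means_zero(self, rng):
        vals = rng.lognormal(0, 1, (20, 6))
        t = pt.compute_ratio_coefficient(
            ranked(vals, Layer.PROTEIN_TOTAL), ranked(vals, Layer.MRNA_TOTAL),
            "pm", renormalize=False,
        )
        lfc = pt.coefficient_logfc(t, 24, 12)
        np.testing.assert_allclose(lfc["log2fc"], 0.0, atol=1e-12)

    def test_doubled_ratio_gives_one(self):
        ratio = pd.DataFrame(
            [[1.0, 1.0, 2.0, 2.0]], index=["g"], columns=["a1", "a2", "b1", "b2"]
        )
        meta = pd.DataFrame({"age_months": [12, 12, 24, 24]},
                            index=pd.Index(["a1", "a2", "b1", "b2"], name="animal_id"))
        t = pt.CoefficientTable("pm", ratio, ratio * 0, meta)
        lfc = pt.coefficient_logfc(t, 24, 12)
        assert lfc.loc["g", "log2fc"] == pytest.approx(1.0)

    def test_antisymmetry(self, table):
        fwd = pt.coefficient_logfc(table, 24, 12)["log2fc"]
        rev = pt.coefficient_logfc(table, 12, 24)["log2fc"]
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)


def test_z_invariants_hold_for_all_pipeline_tables(small_stack):
    for kind, t in small_stack["coeffs"].items():
        ok = ~t.ratio.index.isin(t.constant_genes)
        z = t.z.loc[ok]
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)
        assert (t.ratio.to_numpy() > 0).all() or kind == "aggregation"
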