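"""Sequence features, pI/GRAVY, biosynthetic cost and the turnover model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ptaging as pt
from ptaging.biochem import compute_avecpa
from ptaging.types import STANDARD_AA

AA = st.sampled_from(STANDARD_AA)
SEQ = st.text(alphabet=STANDARD_AA, min_size=5, max_size=60)


@pytest.fixture(scope="module")
def costs():
    from pathlib import Path

    import ptaging.io as pio

    return pio.read_cost_table(Path(pt.__file__).parent / "data" / "demo_costs.tsv")


class TestComposition:
    def test_polylysine(self):
        c = pt.compute_composition("KKKK")
        assert c.frac_lysine == 1.0 and c.frac_positive == 1.0

    def test_charge_classes(self):
        c = pt.compute_composition("KRDE")
        assert c.frac_positive == 0.5
        assert c.frac_negative == 0.5

    def test_histidine_optional(self):
        assert pt.compute_composition("KH").frac_positive == 0.5
        assert pt.compute_composition("KH", include_histidine=True).frac_positive == 1.0

    def test_nonstandard_excluded_from_denominator(self):
        c = pt.compute_composition("KKXX")
        assert c.length_aa == 2 and c.n_nonstandard == 2
        assert c.frac_lysine == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(seq=SEQ)
    def test_fractions_sum_to_one(self, seq):
        c = pt.compute_composition(seq)
        assert sum(c.frac.values()) == pytest.approx(1.0, abs=1e-9)


class TestPhyschem:
    def test_gravy_polyalanine(self):
        assert pt.gravy("AAAA") == pytest.approx(1.8)

    @settings(derandomize=True, max_examples=30)
    @given(seq=SEQ)
    def test_gravy_matches_biopython(self, seq):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        assert pt.gravy(seq) == pytest.approx(ProteinAnalysis(seq).gravy(), abs=1e-9)

    def test_pi_sign_of_charge(self):
        assert pt.isoelectric_point("K" * 10) > 7
        assert pt.isoelectric_point("D" * 10) < 7

    @settings(derandomize=True, max_examples=30)
    @given(seq=SEQ)
    def test_net_charge_vanishes_at_pi(self, seq):
        pi = pt.isoelectric_point(seq)
        assert abs(pt.net_charge(seq, pi)) < 1e-4


class TestAvecpa:
    def test_homopolymer_equals_residue_cost(self, costs):
        for aa in "AWKG":
            assert compute_avecpa(aa * 17, costs) == pytest.approx(costs.cost_per_aa[aa])

    def test_two_residue_mean(self):
        table = pt.CostTable({aa: 1.0 for aa in STANDARD_AA} | {"A": 2.0, "G": 4.0})
        assert compute_avecpa("AG", table) == pytest.approx(3.0)

    @settings(derandomize=True, max_examples=30)
    @given(seq=SEQ, perm_seed=st.integers(0, 2**31 - 1))
    def test_permutation_invariance_and_bounds(self, costs, seq, perm_seed):
        rng = np.random.default_rng(perm_seed)
        shuffled = "".join(rng.permutation(list(seq)))
        v = compute_avecpa(seq, costs)
        assert compute_avecpa(shuffled, costs) == pytest.approx(v)
        assert min(costs.cost_per_aa.values()) <= v <= max(costs.cost_per_aa.values())


class TestCostModel:
    def test_direct_formula(self):
        c_prot, c_total = pt.compute_cost_model(100, 10.0)
        assert c_prot == pytest.approx(100 * math.log(2) / 10)
        assert c_total == pytest.approx(c_prot)

    def test_halving_under_half_life_doubling(self):
        a, _ = pt.compute_cost_model(123, 7.0)
        b, _ = pt.compute_cost_model(123, 14.0)
        assert b == a / 2

    def test_atp_factor_exact(self):
        c1, t1 = pt.compute_cost_model(50, 3.0, 7.0, atp_factor=1)
        c5, t5 = pt.compute_cost_model(50, 3.0, 7.0, atp_factor=5)
        assert c5 == 5 * c1 and t5 == 5 * t1

    @settings(derandomize=True, max_examples=30)
    @given(
        length=st.integers(30, 3000),
        hl=st.floats(0.5, 500.0),
        copies=st.floats(1.0, 1e6),
        k=st.floats(0.1, 10.0),
    )
    def test_linearity_in_length_and_copies(self, length, hl, copies, k):
        c, t = pt.compute_cost_model(length, hl, copies)
        c2, _ = pt.compute_cost_model(k * length, hl, copies)
        _, t2 = pt.compute_cost_model(length, hl, k * copies)
        assert c2 == pytest.approx(k * c, rel=1e-12)
        assert t2 == pytest.approx(k * t, rel=1e-12)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError, match="half-life"):
            pt.compute_cost_model(10, 0.0)


class TestFeatureTable:
    def test_columns_and_invariants(self, costs, rng):
        seqs = pt.generate_sequences(30, (50, 120), seed=5)
        tt = pt.TurnoverTable(
            pd.DataFrame(
                {"half_life_h": rng.lognormal(4, 1, 30), "copy_number": rng.lognormal(8, 2, 30)},
                index=pd.Index(sorted(seqs), name="gene"),
            )
        )
        df = pt.build_feature_table(seqs, costs=costs, turnover=tt)
        frac_cols = [c for c in df.columns if c.startswith("frac_") and len(c) == 6]
        np.testing.assert_allclose(df[frac_cols].sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            df["C_prot"], df["length_aa"] * math.log(2) / df["half_life_h"]
        )
        np.testing.assert_allclose(df["C_total"], df["C_prot"] * df["copy_number"])


class TestCorrelateFeatures:
    def test_self_and_reversal(self, costs):
        seqs = pt.generate_sequences(40, (50, 100), seed=3)
        df = pt.build_feature_table(seqs, costs=costs)
        hit = pt.correlate_features(df, df["gravy"])
        assert hit.loc["gravy", "rho"] == pytest.approx(1.0)
        rev = pt.correlate_features(df, -df["gravy"])
        assert rev.loc["gravy", "rho"] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self, rng):
        from scipy.stats import rankdata

        feats = pd.DataFrame(
            rng.normal(0, 1, (100, 3)), columns=["f1", "f2", "f3"],
            index=[f"g{i}" for i in range(100)],
        )
        target = pd.Series(rng.normal(0, 1, 100), index=feats.index)
        out = pt.correlate_features(feats, target)
        for col in feats.columns:
            oracle = np.corrcoef(rankdata(feats[col]), rankdata(target))[0, 1]
            assert out.loc[col, "rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_feature_reported_missing(self, rng):
        feats = pd.DataFrame(
            {"const": np.ones(50), "ok": rng.normal(0, 1, 50)},
            index=[f"g{i}" for i in range(50)],
        )
        target = pd.Series(rng.normal(0, 1, 50), index=feats.index)
        out = pt.correlate_features(feats, target)
        assert np.isnan(out.loc["const", "rho"])


def test_planted_charge_effect_recovered():
    """A generator that couples the late-age translation offset negatively to
    the positive-residue fraction must surface as rho < 0 with p < 0.01."""
    import warnings

    from ptaging.preprocess import percentile_rank, preprocess_layer
    from ptaging.types import Layer

    cfg = pt.SyntheticConfig(
        n_genes=1000, positive_charge_coupling=-0.6, pm_dispersion=(0.3, 0.3, 0.3),
        effect_size=0.1, seed=9,
    )
    cohort = pt.generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = {}
        for lay in (Layer.MRNA_TOTAL, Layer.PROTEIN_TOTAL):
            norm[lay], _ = preprocess_layer(
                cohort.matrices[lay], stderr_threshold=0.12 if lay.is_count else 0.4
            )
        pm = pt.compute_ratio_coefficient(
            percentile_rank(norm[Layer.PROTEIN_TOTAL]),
            percentile_rank(norm[Layer.MRNA_TOTAL]),
            "pm",
        )
    ages = pm.ages
    lfc = pt.coefficient_logfc(pm, ages[-1], ages[-2])["log2fc"]
    feats = pt.build_feature_table(cohort.sequences)
    res = pt.correlate_features(feats[["frac_positive"]], lfc)
    assert res.loc["frac_positive", "rho"] < 0
    assert res.loc["frac_positive", "p_value"] < 0.01
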