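import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evotol import expression


class TestLayout:
    def test_spot_arithmetic(self):
        layout = expression.ArrayLayout(12078, 6, 4280,
                                        passes=((8000, 4253), (4078, 27)))
        info = expression.layout_spot_count(layout)
        assert info["spots"] == 72_468
        assert info["cds_targeted"] == 4280

    def test_trivial_layout(self):
        assert expression.layout_spot_count(expression.ArrayLayout(1, 1, 1))["spots"] == 1

    def test_pass_sums_validated(self):
        with pytest.raises(ValueError):
            expression.ArrayLayout(100, 2, 50, passes=((90, 50),))


def test_background_adjust():
    spots = pd.DataFrame({"fg": [10.0, 5.0], "bg": [2.0, 6.0]})
    out = expression.background_adjust(spots)
    assert out["adjusted"].tolist() == [8.0, -1.0]


class TestGlog:
    def test_approximates_log2_for_large_values(self):
        x = np.array([1e6])
        assert expression.glog(x, lam=1.0)[0] == pytest.approx(np.log2(2e6), abs=1e-6)

    def test_finite_through_zero_and_negative(self):
        out = expression.glog(np.array([-5.0, 0.0, 5.0]), lam=2.0)
        assert np.all(np.isfinite(out))
        assert out[1] == 0.0
        assert out[0] == -out[2]  # odd function

    def test_invalid_lam(self):
        with pytest.raises(ValueError):
            expression.glog(np.array([1.0]), lam=-1.0)


class TestQuantileNormalize:
    def test_postcondition_identical_sorted_columns(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mat = pd.DataFrame(rng.normal(size=(50, 4)))
            out = expression.quantile_normalize(mat)
            sorted_cols = np.sort(out.to_numpy(), axis=0)
            for j in range(1, 4):
                assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j])

    def test_ties_within_a_column_stay_tied(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 5.0, 9.0],
                            "b": [0.0, 2.0, 4.0, 6.0]})
        out = expression.quantile_normalize(mat)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_preserves_within_column_order(self):
        mat = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [10.0, 30.0, 20.0]})
        out = expression.quantile_normalize(mat)
        assert np.array_equal(np.argsort(out["a"]), np.argsort(mat["a"]))
        assert np.array_equal(np.argsort(out["b"]), np.argsort(mat["b"]))

    def test_single_column_identity_with_warning(self):
        mat = pd.DataFrame({"a": [3.0, 1.0]})
        with pytest.warns(UserWarning):
            out = expression.quantile_normalize(mat)
        assert out.equals(mat)


class TestCollapseReplicates:
    design = pd.DataFrame({
        "sample": ["s1", "s2", "s3"],
        "condition": ["c", "c", "c"]})

    def spots(self, values_by_sample):
        rows = []
        for sample, vals in values_by_sample.items():
            for i, v in enumerate(vals):
                rows.append({"spot": f"{sample}_{i}", "probe": "p1",
                             "sample": sample, "adjusted": v})
        return pd.DataFrame(rows)

    def test_median_of_technical_spots(self):
        spots = self.spots({"s1": [1.0, 2.0, 100.0], "s2": [5.0], "s3": [7.0]})
        out = expression.collapse_replicates(spots, self.design)
        assert out.loc["p1", "s1"] == 2.0

    def test_probe_acceptable_in_one_replicate_dropped(self):
        spots = self.spots({"s1": [5.0], "s2": [-1.0], "s3": [-2.0]})
        out = expression.collapse_replicates(spots, self.design,
                                             acceptance_min=0.0)
        assert "p1" not in out.index

    def test_two_acceptable_replicates_kept(self):
        spots = self.spots({"s1": [5.0], "s2": [4.0], "s3": [-2.0]})
        out = expression.collapse_replicates(spots, self.design,
                                             acceptance_min=0.0)
        assert "p1" in out.index


def test_select_probe_per_gene_min_sd():
    design = pd.DataFrame({"sample": ["s1", "s2", "s3", "s4"],
                           "condition": ["c1", "c1", "c2", "c2"]})
    mat = pd.DataFrame({
        "s1": [1.0, 1.0], "s2": [1.1, 3.0], "s3": [2.0, 2.0], "s4": [2.1, 5.0]},
        index=["pA", "pB"])
    probe_to_gene = pd.Series({"pA": "g1", "pB": "g1"})
    out = expression.select_probe_per_gene(mat, probe_to_gene, design)
    assert out.index.tolist() == ["g1"]
    assert np.allclose(out.loc["g1"], mat.loc["pA"])  # pA has smaller spread


def test_filter_genes():
    mat = pd.DataFrame({
        "s1": [500.0, 500.0, 10.0],
        "s2": [600.0, 500.2, 12.0],
        "s3": [800.0, 500.4, 14.0],
        "s4": [900.0, 500.6, 16.0]},
        index=["keeps", "flat", "dim"])
    out = expression.filter_genes(mat, intensity_min=100.0, iqr_min=0.5)
    assert out.index.tolist() == ["keeps"]


def test_adjust_bh_hand_toy():
    adj, sig = expression.adjust_bh([0.01, 0.02, 0.03, 0.5], cutoff=0.05)
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])
    assert sig.tolist() == [True, True, True, False]
    with pytest.raises(ValueError):
        expression.adjust_bh([0.5, 1.5])


class TestModeratedT:
    def make_data(self, seed=0, n_genes=40):
        rng = np.random.default_rng(seed)
        design = pd.DataFrame(
            [{"sample": f"{st}_{tr}_{r}", "strain": st, "treated": tr}
             for st in ("mut", "ref") for tr in (True, False) for r in (1, 2, 3)])
        mat = pd.DataFrame(rng.normal(size=(n_genes, 12)),
                           index=[f"g{i}" for i in range(n_genes)],
                           columns=design["sample"])
        return mat, design

    def test_student_t_reduction(self):
        mat, design = self.make_data(seed=1)
        res = expression.moderated_t_test(mat, design, "ref_treatment", prior_df=0)
        # prior weight zero: ordinary two-sample pooled t with 4 df
        expected_p = 2.0 * stats.t.sf(np.abs(res["t"]), 4)
        assert np.allclose(res["p"], expected_p, atol=1e-10)

    def test_interaction_effect_sign(self):
        mat, design = self.make_data(seed=2)
        # the alphabetically first strain ("mut" here) is the reference, so a
        # shift in its treated cell enters the interaction with a + ref sign,
        # i.e. as -10 in the (non-reference minus reference) difference
        cols = design[(design["strain"] == "mut") & design["treated"]]["sample"]
        mat.loc["g0", cols] += 10.0
        res = expression.moderated_t_test(mat, design, "interaction").set_index("gene")
        assert res.loc["g0", "effect"] == pytest.approx(-10.0, abs=2.0)
        assert res.loc["g0", "p"] < 1e-4

    def test_unknown_contrast_and_small_groups(self):
        mat, design = self.make_data()
        with pytest.raises(ValueError):
            expression.moderated_t_test(mat, design, "main_effect")
        # leave a single sample in the reference strain's treated cell
        one = design[~((design["strain"] == "mut") & design["treated"])
                     | (design["sample"] == "mut_True_1")]
        with pytest.raises(ValueError):
            expression.moderated_t_test(mat[one["sample"]], one, "ref_treatment")


class TestVariancePrior:
    def test_recovers_planted_prior_df(self):
        rng = np.random.default_rng(8)
        d0, s0_2, df = 4.0, 1.0, 6.0
        # s2 | s_g^2 ~ s_g^2 chi2_df / df, with s_g^2 ~ d0 s0^2 / chi2_d0
        true_var = d0 * s0_2 / rng.chisquare(d0, size=5000)
        s2 = true_var * rng.chisquare(df, size=5000) / df
        est_d0, est_s0 = expression.estimate_variance_prior(s2, df)
        assert 2.5 < est_d0 < 6.0
        assert est_s0 == pytest.approx(s0_2, rel=0.2)

    def test_constant_variances_give_infinite_df(self):
        from scipy import special

        d0, s0 = expression.estimate_variance_prior(np.full(100, 2.0), 6.0)
        assert math.isinf(d0)
        # the moment match inverts the expected log of a chi-square draw
        expected = 2.0 * math.exp(-special.digamma(3.0) + math.log(3.0))
        assert s0 == pytest.approx(expected, rel=1e-12)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            expression.estimate_variance_prior(np.zeros(10), 6.0)


def test_normalize_cascade_postcondition():
    rng = np.random.default_rng(4)
    adjusted = pd.DataFrame(rng.gamma(2.0, 200.0, size=(60, 3)) - 5.0,
                            columns=["s1", "s2", "s3"])
    out = expression.normalize(adjusted)
    sorted_cols = np.sort(out.to_numpy(), axis=0)
    assert np.allclose(sorted_cols[:, 0], sorted_cols[:, 1])
    assert np.allclose(sorted_cols[:, 0], sorted_cols[:, 2])
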