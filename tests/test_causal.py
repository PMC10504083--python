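"""Heritability, weight training, PWAS, colocalization, causal calls."""

import numpy as np
import pandas as pd
import pytest

from sexqtl.causal import (
    ColocPriors,
    ColocResult,
    PwasRecord,
    WeightModel,
    assign_pwas_fdr,
    cis_heritability,
    classify_sex_specific,
    coloc_abf,
    harmonize_gwas,
    intersect_causal_sets,
    pwas_assoc,
    train_weights,
)


def _dosages(rng, n=700, m=50, maf=0.3):
    return rng.binomial(2, maf, size=(n, m)).astype(float)


class TestHeritability:
    def test_null_expression_rarely_flagged(self, rng):
        X = _dosages(rng, n=300, m=30)
        flags = 0
        for _ in range(40):
            h = cis_heritability(X, rng.standard_normal(300))
            flags += h.heritable
        assert flags <= 2  # nominal 1% rate

    @pytest.mark.parametrize("h2_true", [0.25, 0.5])
    def test_planted_h2_recovered(self, rng, h2_true):
        n, m = 700, 50
        X = _dosages(rng, n=n, m=m)
        Xs = (X - X.mean(0)) / X.std(0)
        b = rng.normal(0, np.sqrt(h2_true / m), m)
        y = Xs @ b + rng.normal(0, np.sqrt(1 - h2_true), n)
        h = cis_heritability(X, y)
        assert h.h2 == pytest.approx(h2_true, abs=0.15)
        assert h.heritable

    def test_zero_h2_recovered_near_zero(self, rng):
        X = _dosages(rng, n=700, m=50)
        h = cis_heritability(X, rng.standard_normal(700))
        assert h.h2 <= 0.15

    def test_input_guards(self, rng):
        with pytest.raises(ValueError):
            cis_heritability(_dosages(rng, n=10, m=5), np.ones(10) + np.arange(10))
        with pytest.raises(ValueError, match="constant"):
            cis_heritability(_dosages(rng, n=60, m=5), np.ones(60))


class TestTrainWeights:
    def test_single_causal_snp_gets_largest_weight(self, rng):
        X = _dosages(rng, n=400, m=20)
        y = X[:, 7] * 1.0 + rng.normal(0, 0.3, 400)
        w = train_weights(X, y, [f"v{j}" for j in range(20)], seed=0)
        assert int(np.argmax(np.abs(w.weights))) == 7
        assert w.cv_r2 > 0.5
        assert w.model in w.all_cv_r2 and w.all_cv_r2[w.model] == max(w.all_cv_r2.values())

    def test_null_gene_has_no_predictive_power(self, rng):
        X = _dosages(rng, n=400, m=20)
        w = train_weights(X, rng.standard_normal(400), [f"v{j}" for j in range(20)], seed=0)
        assert w.cv_r2 <= 0.05

    def test_duplicated_causal_snps_ridge_splits_lasso_concentrates(self, rng):
        X = _dosages(rng, n=500, m=10)
        X[:, 1] = X[:, 0]
        y = X[:, 0] * 1.0 + rng.normal(0, 0.3, 500)
        from sklearn.linear_model import Lasso, Ridge

        Xs = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        yc = y - y.mean()
        ridge_w = Ridge(alpha=1.0).fit(Xs, yc).coef_
        lasso_w = Lasso(alpha=0.05).fit(Xs, yc).coef_
        assert abs(ridge_w[0] - ridge_w[1]) < 0.1 * abs(ridge_w[0] + ridge_w[1])
        assert min(abs(lasso_w[0]), abs(lasso_w[1])) < 0.2 * max(abs(lasso_w[0]), abs(lasso_w[1]))
        pred_r = Xs @ ridge_w
        pred_l = Xs @ lasso_w
        assert np.corrcoef(pred_r, pred_l)[0, 1] > 0.99


class TestPwas:
    def test_single_variant_identity(self):
        w = WeightModel("g", "joint", ["a"], np.array([1.0]), "ridge_blup", 0.5)
        rec = pwas_assoc(w, np.array([5.0]), np.array([[1.0]]), ridge=0.0)
        assert rec.z == pytest.approx(5.0)

    def test_two_correlated_variants_hand_computed(self):
        w = WeightModel("g", "joint", ["a", "b"], np.array([0.5, 0.5]), "ridge_blup", 0.5)
        rec0 = pwas_assoc(w, np.array([4.0, 4.0]), np.ones((2, 2)), ridge=0.0)
        assert rec0.z == pytest.approx(4.0)
        rec = pwas_assoc(w, np.array([4.0, 4.0]), np.ones((2, 2)))  # default stabilizer
        assert rec.z == pytest.approx(4.0, abs=0.03)

    def test_null_gwas_type_one_error(self, rng):
        hits = 0
        n_genes = 400
        for _ in range(n_genes):
            m = 10
            R = np.eye(m)
            wts = rng.normal(0, 1, m)
            z = rng.standard_normal(m)
            rec = pwas_assoc(
                WeightModel("g", "joint", [f"v{j}" for j in range(m)], wts, "lasso", 0.3),
                z, R, ridge=0.0,
            )
            hits += rec.p < 0.05
        rate = hits / n_genes
        assert rate == pytest.approx(0.05, abs=2 * np.sqrt(0.05 * 0.95 / n_genes) + 0.01)

    def test_zero_weights_raise(self):
        w = WeightModel("g", "joint", ["a"], np.array([0.0]), "lasso", 0.0)
        with pytest.raises(ValueError):
            pwas_assoc(w, np.array([1.0]), np.eye(1))

    def test_allele_harmonization_flips_and_drops(self):
        w = WeightModel("g", "joint", ["v1", "v2", "v3", "v4"],
                        np.array([0.5, 0.5, 0.5, 0.5]), "lasso", 0.3)
        gwas = pd.DataFrame(
            {"SNP": ["v1", "v2", "v3"], "A1": ["G", "A", "A"], "A2": ["A", "C", "T"],
             "Z": [3.0, 2.0, 1.0]}
        )
        alleles = pd.DataFrame(
            {"id": ["v1", "v2", "v3", "v4"], "ref_allele": ["G", "C", "T", "A"],
             "alt_allele": ["A", "A", "A", "G"]}
        )
        keep, z, dropped = harmonize_gwas(w, gwas, weight_alleles=alleles)
        # v1: flipped orientation -> -3; v2: matches -> +2; v3: A/T ambiguous
        # -> dropped; v4: absent -> dropped
        assert list(keep) == [0, 1]
        np.testing.assert_allclose(z, [-3.0, 2.0])
        assert dropped == 2


class TestColoc:
    def _profile(self, betas, se=0.1):
        b = np.asarray(betas, dtype=float)
        return pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(len(b))], "beta": b, "se": se}
        )

    def test_shared_strong_signal_gives_pp4(self):
        b = np.zeros(30)
        b[11] = 0.8  # z = 8 at se 0.1
        r = coloc_abf(self._profile(b), self._profile(b))
        assert r.pp4 > 0.95

    def test_no_signal_gives_pp0(self):
        z = np.zeros(30)
        r = coloc_abf(self._profile(z), self._profile(z))
        assert np.argmax(r.posteriors) == 0

    def test_distinct_variants_give_pp3(self):
        b1, b2 = np.zeros(30), np.zeros(30)
        b1[4], b2[22] = 0.8, 0.8
        r = coloc_abf(self._profile(b1), self._profile(b2))
        assert np.argmax(r.posteriors) == 3

    def test_posteriors_sum_to_one(self, rng):
        for _ in range(20):
            b1 = rng.normal(0, 0.2, 25)
            b2 = rng.normal(0, 0.2, 25)
            r = coloc_abf(self._profile(b1), self._profile(b2))
            assert np.sum(r.posteriors) == pytest.approx(1.0, abs=1e-10)

    def test_guards(self):
        with pytest.raises(ValueError, match="variant lists"):
            coloc_abf(self._profile([0.1, 0.2]), self._profile([0.1, 0.2, 0.3]))
        bad = self._profile([0.1, 0.2])
        bad.loc[0, "se"] = 0.0
        with pytest.raises(ValueError, match="standard errors"):
            coloc_abf(bad, self._profile([0.1, 0.2]))
        with pytest.raises(ValueError):
            ColocPriors(p1=1e-4, p2=1e-4, p12=1e-3)


class TestClassifySexSpecific:
    def _pwas(self, stratum, p, q):
        return PwasRecord("g", stratum, 3.0, p, q)

    def _coloc(self, stratum, pp4):
        rest = (1 - pp4) / 4
        return ColocResult("g", stratum, rest, rest, rest, rest, pp4)

    def test_female_only_rule(self):
        call = classify_sex_specific(
            self._pwas("female", 0.001, 0.01), self._pwas("male", 0.4, 0.6),
            self._coloc("female", 0.9), self._coloc("male", 0.2), "g", "trait",
        )
        assert call.classification == "female_only"

    def test_nominal_male_signal_blocks_call(self):
        call = classify_sex_specific(
            self._pwas("female", 0.001, 0.01), self._pwas("male", 0.03, 0.2),
            self._coloc("female", 0.9), None, "g", "trait",
        )
        assert call.classification == "neither"

    def test_absent_male_record_counts_as_silent(self):
        call = classify_sex_specific(
            self._pwas("female", 0.001, 0.01), None,
            self._coloc("female", 0.9), None, "g", "trait",
        )
        assert call.classification == "female_only"
        assert call.detail["male_record_absent"]

    def test_both_and_label_symmetry(self):
        f, m = self._pwas("female", 1e-4, 0.01), self._pwas("male", 1e-4, 0.01)
        cf, cm = self._coloc("female", 0.9), self._coloc("male", 0.9)
        assert classify_sex_specific(f, m, cf, cm, "g", "t").classification == "both"
        a = classify_sex_specific(f, self._pwas("male", 0.5, 0.8), cf, cm, "g", "t")
        b = classify_sex_specific(self._pwas("female", 0.5, 0.8), m, cm, cf, "g", "t")
        assert a.classification == "female_only"
        assert b.classification == "male_only"

    def test_pp4_below_threshold_blocks(self):
        call = classify_sex_specific(
            self._pwas("female", 0.001, 0.01), None,
            self._coloc("female", 0.6), None, "g", "trait",
        )
        assert call.classification == "neither"


class TestFdrAndIntersection:
    def test_pwas_fdr_within_stratum(self):
        recs = [PwasRecord("g1", "female", 3, 0.001), PwasRecord("g2", "female", 1, 0.5),
                PwasRecord("g1", "male", 2, 0.04)]
        assign_pwas_fdr(recs)
        assert recs[0].q == pytest.approx(0.002)
        assert recs[2].q == pytest.approx(0.04)

    def test_intersection_hand_counts(self):
        causal = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(20)], "trait": ["t1"] * 10 + ["t2"] * 10}
        )
        sexde = {f"g{i}" for i in range(8)}
        sbq = {"g5", "g15"}
        df = intersect_causal_sets(causal, sexde, sbq).set_index("trait")
        assert df.loc["t1", "n_sex_biased_expression"] == 8
        assert df.loc["t1", "pct_sex_biased_expression"] == 80.0
        assert df.loc["t2", "n_sbqtl"] == 1
        assert df.loc["all_traits", "n_causal"] == 20
        assert df.loc["all_traits", "pct_sex_biased_expression"] == 40.0

    def test_disjoint_and_empty_cases(self):
        causal = pd.DataFrame({"gene_id": ["a", "b"], "trait": ["t", "t"]})
        df = intersect_causal_sets(causal, {"x"}, set()).set_index("trait")
        assert df.loc["t", "n_sex_biased_expression"] == 0
        with pytest.raises(ValueError):
            intersect_causal_sets(causal.iloc[:0], set(), set())
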