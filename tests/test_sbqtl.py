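"""Two-stage sex-biased QTL procedure, clumping, classification, replication."""

import numpy as np
import pandas as pd
import pytest

from sexqtl.expression import ExpressionMatrix
from sexqtl.genotype import GenotypeMatrix
from sexqtl.sbqtl import (
    AnalysisConfig,
    cis_scan,
    classify_sbqtl,
    environment_check,
    interaction_scan,
    ld_clump,
    map_cis_pairs,
    pi1_replication,
    stage1_union,
)
from sexqtl.stats import ols_fit


def _geno(dosages, positions=None, chrom="1"):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chromosome": [chrom] * m,
            "position": positions if positions is not None else np.arange(1, m + 1) * 100,
            "ref_allele": ["A"] * m,
            "alt_allele": ["G"] * m,
        }
    )
    return GenotypeMatrix(d, variants, [f"s{i}" for i in range(n)])


def _expr(values):
    v = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(
        v, [f"g{i}" for i in range(v.shape[0])], [f"s{j}" for j in range(v.shape[1])],
        "protein", "zscored",
    )


class TestMapCisPairs:
    def test_window_boundaries_inclusive(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chromosome": "1", "start": 1000, "end": 2000}]
        )
        variants = pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "chromosome": ["1"] * 4,
                "position": [499, 500, 2500, 2501],
            }
        )
        pairs = map_cis_pairs(genes, variants, window=500)
        assert set(pairs["variant_id"]) == {"b", "c"}

    def test_other_chromosome_excluded_and_zero_window(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chromosome": "1", "start": 100, "end": 200}]
        )
        variants = pd.DataFrame(
            {"id": ["in", "out", "chr2"], "chromosome": ["1", "1", "2"],
             "position": [150, 250, 150]}
        )
        pairs = map_cis_pairs(genes, variants, window=0)
        assert list(pairs["variant_id"]) == ["in"]

    def test_inverted_gene_raises(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chromosome": "1", "start": 500, "end": 100}]
        )
        with pytest.raises(ValueError, match="end < start"):
            map_cis_pairs(genes, pd.DataFrame({"id": [], "chromosome": [], "position": []}))


class TestCisScan:
    def _planted(self, rng, n=700, beta=0.5):
        x = rng.binomial(2, 0.3, n).astype(float)
        other = rng.binomial(2, 0.3, (n, 3)).astype(float)
        y = beta * x + rng.normal(0, 1, n)
        g = _geno(np.column_stack([x, other]))
        sex = rng.integers(0, 2, n)
        pairs = pd.DataFrame({"gene_id": ["g0"] * 4, "variant_id": [f"v{j}" for j in range(4)]})
        return pairs, g, _expr(y), sex

    def test_planted_cis_effect_detected_joint(self, rng):
        pairs, g, e, sex = self._planted(rng)
        df = cis_scan(pairs, g, e, None, sex, mode="joint")
        hit = df[df["variant_id"] == "v0"].iloc[0]
        assert hit["q"] < 0.05
        assert hit["beta"] == pytest.approx(0.5, abs=0.12)

    def test_matches_full_ols_exactly(self, rng):
        pairs, g, e, sex = self._planted(rng, n=150)
        covs = rng.normal(size=(150, 3))
        df = cis_scan(pairs, g, e, covs, sex, mode="joint")
        for r in df.itertuples(index=False):
            j = int(r.variant_id[1:])
            X = np.column_stack([np.ones(150), sex, covs, g.dosages[:, j]])
            fit = ols_fit(X, e.values[0])
            assert r.beta == pytest.approx(fit.coefficients[-1], rel=1e-9)
            assert r.p == pytest.approx(fit.p_values[-1], rel=1e-7)

    def test_null_scan_calibrated(self, rng):
        n, m = 400, 60
        g = _geno(rng.binomial(2, 0.3, (n, m)).astype(float),
                  positions=np.arange(1, m + 1) * 10)
        e = _expr(rng.normal(size=(5, n)))
        pairs = pd.DataFrame(
            [(f"g{i}", f"v{j}") for i in range(5) for j in range(m)],
            columns=["gene_id", "variant_id"],
        )
        sex = rng.integers(0, 2, n)
        df = cis_scan(pairs, g, e, None, sex, mode="joint")
        assert (df["q"] < 0.05).mean() <= 0.02
        from sexqtl.stats import qq_lambda

        lam, _, _ = qq_lambda(df["p"].to_numpy())
        assert 0.9 <= lam <= 1.1

    def test_male_stratum_excludes_females_and_small_stratum_raises(self, rng):
        pairs, g, e, sex = self._planted(rng, n=200)
        male = cis_scan(pairs, g, e, None, sex, mode="male")
        assert (male["n"] == (sex == 0).sum()).all()
        tiny_sex = np.ones(200, dtype=int)
        tiny_sex[:10] = 0
        with pytest.raises(ValueError, match="stratum"):
            cis_scan(pairs, g, e, None, tiny_sex, mode="male")

    def test_x_males_keep_hemizygous_coding(self, small_cohort):
        g, sex = small_cohort["g"], small_cohort["sex"]
        xcols = np.where(g.is_x().to_numpy())[0]
        male_x = g.dosages[np.ix_(sex == 0, xcols)]
        assert set(np.unique(male_x[~np.isnan(male_x)])) <= {0.0, 2.0}


class TestStage1Union:
    def _df(self, mode, qs):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(qs))],
             "variant_id": [f"v{i}" for i in range(len(qs))],
             "mode": mode, "beta": 0.1, "se": 0.05, "p": np.array(qs) / 2,
             "n": 100, "q": qs}
        )

    def test_hand_fixture_union_of_six_pairs(self):
        joint = self._df("joint", [0.01, 0.2, 0.9, 0.8, 0.5, 0.04])
        male = self._df("male", [0.5, 0.01, 0.9, 0.9, 0.9, 0.9])
        female = self._df("female", [0.5, 0.5, 0.02, 0.9, 0.9, 0.01])
        s1 = stage1_union(joint, male, female)
        assert len(s1) == 4
        got = dict(zip(s1["gene_id"], s1["source_modes"]))
        assert got["g0"] == "joint"
        assert got["g1"] == "male"
        assert got["g2"] == "female"
        assert set(got["g5"].split(",")) == {"joint", "female"}

    def test_nowhere_significant_excluded(self):
        dfs = [self._df(m, [0.5, 0.9]) for m in ("joint", "male", "female")]
        assert len(stage1_union(*dfs)) == 0


class TestInteractionScan:
    def test_planted_interaction_recovered(self, rng):
        n = 700
        sex = rng.integers(0, 2, n)
        x = rng.binomial(2, 0.3, n).astype(float)
        y = 0.2 * x + 0.4 * x * sex + rng.normal(0, 1, n)
        g = _geno(x[:, None])
        pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]})
        df = interaction_scan(pairs, g, _expr(y), None, sex)
        assert df["significant"].iloc[0]
        assert df["beta_interaction"].iloc[0] == pytest.approx(0.4, abs=0.1)

    def test_identical_sexes_give_no_detection(self, rng):
        n, m = 500, 100
        x = rng.binomial(2, 0.3, (n, m)).astype(float)
        sex = rng.integers(0, 2, n)
        e = _expr((x[:, :5] @ rng.normal(0.3, 0.1, 5) + rng.normal(0, 1, n)))
        g = _geno(x, positions=np.arange(1, m + 1) * 10)
        pairs = pd.DataFrame({"gene_id": ["g0"] * m, "variant_id": [f"v{j}" for j in range(m)]})
        df = interaction_scan(pairs, g, _expr(e.values), None, sex)
        assert not df["significant"].any()

    def test_sex_swap_negates_interaction_betas(self, rng):
        n = 300
        sex = rng.integers(0, 2, n)
        x = rng.binomial(2, 0.4, n).astype(float)
        y = 0.3 * x * sex + rng.normal(0, 1, n)
        g = _geno(x[:, None])
        pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]})
        a = interaction_scan(pairs, g, _expr(y), None, sex)
        b = interaction_scan(pairs, g, _expr(y), None, 1 - sex)
        assert a["beta_interaction"].iloc[0] == pytest.approx(
            -b["beta_interaction"].iloc[0], rel=1e-9
        )
        assert a["p_interaction"].iloc[0] == pytest.approx(
            b["p_interaction"].iloc[0], rel=1e-9
        )

    def test_constant_dosage_within_sex_skipped(self, rng):
        n = 200
        sex = np.array([0, 1] * (n // 2))
        x = np.where(sex == 0, 0.0, rng.binomial(2, 0.5, n).astype(float))
        g = _geno(x[:, None])
        pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]})
        df = interaction_scan(pairs, g, _expr(rng.normal(size=n)), None, sex)
        # still estimable (dosage varies overall) or skipped with reason;
        # a fully monomorphic variant must be skipped
        g2 = _geno(np.zeros((n, 1)))
        df2 = interaction_scan(pairs, g2, _expr(rng.normal(size=n)), None, sex)
        assert len(df2) == 0
        assert df2.attrs["skipped"][0][2] == "monomorphic"

    def test_stage_p_is_max_significant_raw_p(self, small_cohort):
        from sexqtl.experiments import run_two_stage

        c = small_cohort
        _, _, _, inter = run_two_stage(c["g"], c["e"], c["sex"], c["genes"])
        if inter is not None and inter["significant"].any():
            sig = inter[inter["significant"]]
            assert inter.attrs["stage_p"] == sig["p_interaction"].max()
            assert (inter.loc[~inter["significant"], "p_interaction"]
                    > inter.attrs["stage_p"]).all()


def _brute_force_clump(records, r2_mat, positions, r2, window):
    """Independent oracle: literal greedy clumping over explicit matrices."""
    order = sorted(
        range(len(records)),
        key=lambda i: (records[i][2], positions[records[i][1]], records[i][1]),
    )
    assigned, index_of = set(), {}
    for i in order:
        if i in assigned:
            continue
        assigned.add(i)
        index_of[i] = i
        for j in order:
            if j in assigned:
                continue
            vi, vj = records[i][1], records[j][1]
            if abs(positions[vi] - positions[vj]) <= window and r2_mat[vi][vj] >= r2:
                assigned.add(j)
                index_of[j] = i
    return index_of


class TestLdClump:
    def test_three_perfectly_linked_snps(self, rng):
        n = 200
        x = rng.binomial(2, 0.4, n).astype(float)
        g = _geno(np.column_stack([x, x, x]), positions=[100, 200, 300])
        recs = pd.DataFrame(
            {"gene_id": ["g0"] * 3, "variant_id": ["v0", "v1", "v2"],
             "p_interaction": [1e-8, 1e-6, 1e-5]}
        )
        out, summary = ld_clump(recs, g)
        assert summary["n_index_primary"] == 1
        assert out.loc[out["is_index"], "variant_id"].iloc[0] == "v0"
        assert (out["clump_index"] == "v0").all()

    def test_uncorrelated_snps_all_index(self, rng):
        n = 300
        g = _geno(rng.binomial(2, 0.4, (n, 5)).astype(float),
                  positions=[100, 200, 300, 400, 500])
        recs = pd.DataFrame(
            {"gene_id": ["g0"] * 5, "variant_id": [f"v{j}" for j in range(5)],
             "p_interaction": [1e-8, 1e-7, 1e-6, 1e-5, 1e-4]}
        )
        _, summary = ld_clump(recs, g)
        assert summary["n_index_primary"] == 5

    def test_matches_brute_force_oracle_on_random_fixture(self, rng):
        n, m = 250, 20
        # blocks of correlated dosages
        base = rng.binomial(2, 0.4, (n, 5)).astype(float)
        cols = []
        for j in range(m):
            src = base[:, j % 5]
            noise_mask = rng.random(n) < 0.3
            col = np.where(noise_mask, rng.binomial(2, 0.4, n), src).astype(float)
            cols.append(col)
        d = np.column_stack(cols)
        positions = np.sort(rng.choice(np.arange(1, 500_000), m, replace=False))
        g = _geno(d, positions=positions)
        recs = pd.DataFrame(
            {"gene_id": ["g0"] * m, "variant_id": [f"v{j}" for j in range(m)],
             "p_interaction": rng.random(m)}
        )
        out, _ = ld_clump(recs, g, r2=0.5, window=250_000)

        Z = g.imputed_standardized()
        r2_mat = {
            f"v{a}": {f"v{b}": (float(Z[:, a] @ Z[:, b]) / n) ** 2 for b in range(m)}
            for a in range(m)
        }
        pos = dict(zip(g.variants["id"], g.variants["position"]))
        oracle = _brute_force_clump(
            [(r.gene_id, r.variant_id, r.p_interaction) for r in recs.itertuples(index=False)],
            r2_mat, pos, 0.5, 250_000,
        )
        for i, r in out.iterrows():
            assert r["clump_index"] == recs.loc[oracle[i], "variant_id"]


class TestClassify:
    def _scan(self, qs, betas, mode):
        return pd.DataFrame(
            {"gene_id": ["g0"] * len(qs), "variant_id": [f"v{i}" for i in range(len(qs))],
             "mode": mode, "beta": betas, "se": 0.05, "p": np.array(qs) / 2,
             "n": 100, "q": qs}
        )

    @pytest.mark.parametrize(
        "mq,fq,mb,fb,expected",
        [
            (1e-4, 0.4, 0.3, 0.3, "male_only"),
            (0.4, 1e-4, 0.3, 0.3, "female_only"),
            (0.01, 0.01, 0.3, 0.3, "both_concordant"),
            (0.01, 0.01, 0.3, -0.3, "both_discordant"),
        ],
    )
    def test_definitional_categories(self, mq, fq, mb, fb, expected):
        sb = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]})
        male = self._scan([mq], [mb], "male")
        female = self._scan([fq], [fb], "female")
        out = classify_sbqtl(sb, male, female)
        assert out["category"].iloc[0] == expected
        assert not out["joint_only"].iloc[0]

    def test_joint_only_annotated(self):
        sb = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]})
        male = self._scan([0.4], [0.5], "male")
        female = self._scan([0.5], [0.1], "female")
        out = classify_sbqtl(sb, male, female)
        assert out["joint_only"].iloc[0]
        assert out["category"].iloc[0] == "male_only"  # larger |Z| in males

    def test_simulation_plants_all_categories(self, rng):
        n = 2000
        sex = np.array([0, 1] * (n // 2))
        specs = {  # gene -> (male beta, female beta)
            "male_only": (0.8, 0.0),
            "female_only": (0.0, 0.8),
            "both_concordant": (0.8, 0.8),
            "both_discordant": (0.8, -0.8),
        }
        for label, (bm, bf) in specs.items():
            x = rng.binomial(2, 0.4, n).astype(float)
            y = np.where(sex == 0, bm * x, bf * x) + rng.normal(0, 1, n)
            g = _geno(x[:, None])
            male = cis_scan(pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]}),
                            g, _expr(y), None, sex, mode="male")
            female = cis_scan(pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]}),
                              g, _expr(y), None, sex, mode="female")
            out = classify_sbqtl(pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]}),
                                 male, female)
            assert out["category"].iloc[0] == label


class TestEnvironmentCheck:
    def _setup(self, rng, env_effect=False, n=500):
        sex = rng.integers(0, 2, n)
        x = rng.binomial(2, 0.4, n).astype(float)
        env = sex * 0.8 + rng.normal(0, 0.6, n)  # env correlated with sex
        if env_effect:
            y = 0.2 * x + 0.5 * x * env + rng.normal(0, 1, n)
        else:
            y = 0.2 * x + 0.5 * x * sex + rng.normal(0, 1, n)
        g = _geno(x[:, None])
        s = pd.DataFrame({"sample_id": range(n), "sex": sex, "alcohol": env,
                          "education": rng.normal(16, 3, n)})
        recs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]})
        return recs, g, _expr(y), s

    def test_independent_environment_not_flagged(self, rng):
        recs, g, e, s = self._setup(rng, env_effect=False)
        out = environment_check(recs, g, e, s, ["education"], stage_p=1e-4)
        assert (out["flag"] == "not_flagged").all()

    def test_environment_driven_interaction_attenuated(self, rng):
        recs, g, e, s = self._setup(rng, env_effect=True, n=900)
        out = environment_check(recs, g, e, s, ["alcohol"], stage_p=1e-3)
        row = out.iloc[0]
        assert row["snp_by_env_p"] < 1e-3
        assert row["flag"] == "attenuated"

    def test_true_sex_interaction_robust(self, rng):
        recs, g, e, s = self._setup(rng, env_effect=False, n=900)
        out = environment_check(recs, g, e, s, ["alcohol"], stage_p=1e-3)
        row = out.iloc[0]
        if row["flag"] != "not_flagged":
            assert row["flag"] == "robust"

    def test_constant_environment_surfaces_model_error(self, rng):
        recs, g, e, s = self._setup(rng)
        s["constant_env"] = 1.0
        out = environment_check(recs, g, e, s, ["constant_env", "education"], stage_p=1e-4)
        flags = dict(zip(out["environment"], out["flag"]))
        assert flags["constant_env"].startswith("model_error")
        assert flags["education"] == "not_flagged"

    def test_missing_environment_raises(self, rng):
        recs, g, e, s = self._setup(rng)
        with pytest.raises(KeyError):
            environment_check(recs, g, e, s, ["unknown_env"], stage_p=1e-4)


class TestPi1Replication:
    def test_empty_discovery_raises(self):
        with pytest.raises(ValueError):
            pi1_replication(pd.DataFrame(), pd.DataFrame())

    def test_trivial_match_and_unmatched_bookkeeping(self, rng):
        disc = pd.DataFrame({"gene_id": ["g0", "g1"], "variant_id": ["v0", "v9"]})
        rep = pd.DataFrame(
            {"gene_id": ["g0"], "variant_id": ["v0"], "p_interaction": [1e-9]}
        )
        with pytest.warns(UserWarning):
            res = pi1_replication(disc, rep)
        assert res.n_matched == 1
        assert res.unmatched == [("g1", "v9")]
        assert res.pi1 == 1.0


class TestAnalysisConfig:
    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            AnalysisConfig(fdr=1.5)
        with pytest.raises(ValueError):
            AnalysisConfig(cis_window=-1)
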