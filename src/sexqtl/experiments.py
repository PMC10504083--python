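"""Calibration, power and recovery experiments on synthetic cohorts.

Each function sets up a synthetic study with known truth, runs the
relevant pipeline stages, and returns summary numbers: false-discovery
calibration of the two-stage sb-QTL procedure on a global interaction
null, bias and power for planted interaction effects, Storey pi1 recovery
across discovery/replication pairs, colocalization behavior under shared
vs distinct causal variants, and end-to-end recovery of a planted
sex-specific protein-mediated trait effect.

Seeds are combined with replicate indices through ``numpy``'s SeedSequence
spawning, so every experiment is a pure function of its arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .causal import (
    ColocPriors,
    assign_pwas_fdr,
    cis_heritability,
    classify_sex_specific,
    coloc_abf,
    pwas_assoc,
    train_weights,
)
from .sbqtl import (
    cis_scan,
    interaction_scan,
    ld_clump,
    map_cis_pairs,
    pi1_replication,
    stage1_union,
)
from .simulate import SimConfig, simulate_expression, simulate_genotypes, simulate_gwas
from .stats import qq_lambda

__all__ = [
    "run_two_stage",
    "null_calibration",
    "interaction_recovery",
    "pi1_recovery",
    "coloc_behavior",
    "sex_specific_recovery",
]


def run_two_stage(g, e, sex, genes, covariates=None, fdr=0.05, interaction_fdr=0.05,
                  cis_window=500_000):
    """Convenience wrapper: cis scans, stage-1 union, interaction scan."""
    pairs = map_cis_pairs(genes, g.variants, cis_window)
    scans = {m: cis_scan(pairs, g, e, covariates, sex, mode=m)
             for m in ("joint", "male", "female")}
    stage1 = stage1_union(scans["joint"], scans["male"], scans["female"], fdr)
    inter = (interaction_scan(stage1, g, e, covariates, sex, interaction_fdr)
             if len(stage1) else None)
    return pairs, scans, stage1, inter


def _null_config(n_samples, n_genes, snps_per_gene, seed):
    return SimConfig(
        n_samples=n_samples, n_genes=n_genes, snps_per_gene=snps_per_gene,
        fraction_x_genes=0.0, n_x_background=0,
        sex_effect_fraction=0.15, cis_fraction=0.5,
        interaction_fraction=0.0,  # the global interaction null
        n_hidden_factors=0, seed=seed,
    )


def null_calibration(n_reps=50, n_samples=700, n_genes=100, snps_per_gene=50, seed=0) -> dict:
    """Two-stage sb-QTL discovery on the global interaction null.

    Expression carries real sex and cis main effects but zero
    genotype-by-sex interaction everywhere, so every sb-QTL gene call is a
    false discovery and the per-replicate false-discovery proportion is 1
    when anything is called, 0 otherwise. The genomic-inflation lambda is
    pooled over the interaction term of every cis pair: a QQ diagnostic of
    only the stage-1-selected subset would be inflated by construction,
    because pairs entering stage 1 through a noisy single-sex scan are
    enriched for extreme interaction statistics.
    """
    fdp, lams, all_ps = [], [], []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        cfg = _null_config(n_samples, n_genes, snps_per_gene, seed)
        g, sex, genes = simulate_genotypes(cfg, rng=rng)
        e, _ = simulate_expression(g, cfg, sex, genes, rng)
        pairs, scans, stage1, inter = run_two_stage(g, e, sex, genes)
        if inter is None or len(inter) == 0:
            fdp.append(0.0)
        else:
            n_sig_genes = inter.loc[inter["significant"], "gene_id"].nunique()
            fdp.append(1.0 if n_sig_genes > 0 else 0.0)
        inter_all = interaction_scan(pairs, g, e, None, sex)
        ps = inter_all["p_interaction"].to_numpy()
        all_ps.append(ps)
        if len(ps) >= 100:
            lams.append(qq_lambda(ps)[0])
    pooled = np.concatenate(all_ps) if all_ps else np.array([0.5])
    return {
        "n_reps": n_reps,
        "empirical_fdr": float(np.mean(fdp)),
        "mc_se": float(np.sqrt(0.05 * 0.95 / n_reps)),
        "lambda_pooled": float(qq_lambda(pooled)[0]),
        "lambda_mean": float(np.mean(lams)) if lams else np.nan,
        "n_interaction_tests": int(pooled.size),
    }


def interaction_recovery(
    n_effects=200, n_samples=700, snps_per_gene=10, beta=0.4,
    beta_grid=(0.2, 0.4, 0.6), n_grid=(300, 500, 700), grid_effects=60, seed=0,
) -> dict:
    """Bias of interaction-beta estimates and power across effect/size grids.

    Bias is measured at the planted pairs themselves (one planted
    interaction per gene, fixed magnitude ``beta`` with random sign), not
    conditioned on discovery, so selection effects cannot inflate it.
    Power on the grids is the fraction of planted pairs that survive the
    full two-stage call.
    """

    def _cohort(n_genes, n, b, rng):
        cfg = SimConfig(
            n_samples=n, n_genes=n_genes, snps_per_gene=snps_per_gene,
            fraction_x_genes=0.0, n_x_background=0, sex_effect_fraction=0.0,
            cis_fraction=0.3, interaction_fraction=0.0, n_hidden_factors=0,
            seed=seed,
        )
        g, sex, genes = simulate_genotypes(cfg, rng=rng)
        e, truth = simulate_expression(g, cfg, sex, genes, rng)
        # plant exactly one interaction per gene, magnitude b, random sign
        var_gene = g.variants["id"].str.rsplit("_", n=1).str[0].to_numpy()
        planted = {}
        for gid in truth.gene_ids:
            j = int(rng.integers(snps_per_gene))
            sgn = 1.0 if rng.random() < 0.5 else -1.0
            truth.interaction_betas[gid][:] = 0.0
            truth.interaction_betas[gid][j] = sgn * b
            planted[gid] = (j, sgn * b)
        for i, gid in enumerate(truth.gene_ids):
            cols = np.where(var_gene == gid)[0]
            X = g.dosages[:, cols]
            e.values[i] += (X * sex[:, None]) @ truth.interaction_betas[gid]
        return g, e, sex, genes, planted

    rng = np.random.default_rng([seed, 101])
    g, e, sex, genes, planted = _cohort(n_effects, n_samples, beta, rng)
    pairs = pd.DataFrame(
        [(gid, f"{gid}_snp{j:03d}") for gid, (j, _) in planted.items()],
        columns=["gene_id", "variant_id"],
    )
    est = interaction_scan(pairs, g, e, None, sex)
    truth_b = np.array([planted[gid][1] for gid in est["gene_id"]])
    bias = float(np.mean(est["beta_interaction"].to_numpy() - truth_b))

    def _power(n_genes, n, b, tag):
        r = np.random.default_rng([seed, 200 + tag])
        gg, ee, sx, gn, pl = _cohort(n_genes, n, b, r)
        _, _, _, inter = run_two_stage(gg, ee, sx, gn)
        if inter is None or len(inter) == 0:
            return 0.0
        sig = set(zip(inter.loc[inter["significant"], "gene_id"],
                      inter.loc[inter["significant"], "variant_id"]))
        hits = sum((gid, f"{gid}_snp{j:03d}") in sig for gid, (j, _) in pl.items())
        return hits / len(pl)

    power_beta = [_power(grid_effects, n_samples, b, i) for i, b in enumerate(beta_grid)]
    power_n = [_power(grid_effects, n, beta, 10 + i) for i, n in enumerate(n_grid)]
    return {
        "mean_bias": bias,
        "n_effects": int(len(est)),
        "beta_grid": list(beta_grid),
        "power_beta": power_beta,
        "n_grid": list(n_grid),
        "power_n": power_n,
    }


def pi1_recovery(fractions=(0.0, 0.5, 1.0), n_samples=700, n_genes=1600,
                 snps_per_gene=12, seed=0) -> dict:
    """Storey pi1 across replication fractions with known truth.

    Discovery and replication cohorts are equal-size independent draws;
    the replication retains each discovery interaction effect with the
    given probability. SNPs are drawn without LD here so the retained
    fraction is exactly the expected share of true signals among index
    records (LD leakage from retained neighbors would otherwise blur the
    truth value), and the experiment is sized to give Storey's smoother a
    few thousand matched records, where its sampling noise is well below
    the planted-fraction spacing. Interaction magnitudes are drawn
    uniformly in [0.5, 0.9] SD per allele (random sign) so that every
    retained signal replicates essentially surely and pi1 measures the
    plumbing (matching, clumping, estimation), not marginal power.
    """
    out = {}
    for k, frac in enumerate(fractions):
        rng = np.random.default_rng([seed, 300 + k])
        cfg = SimConfig(
            n_samples=n_samples, n_genes=n_genes, snps_per_gene=snps_per_gene,
            fraction_x_genes=0.0, n_x_background=0, ld_block_size=1, ld_rho=0.0,
            sex_effect_fraction=0.15, cis_fraction=0.5,
            interaction_fraction=0.0, n_hidden_factors=0, seed=seed,
        )
        g_d, sex_d, genes = simulate_genotypes(cfg, rng=rng)
        e_d, truth = simulate_expression(g_d, cfg, sex_d, genes, rng)
        var_gene = g_d.variants["id"].str.rsplit("_", n=1).str[0].to_numpy()
        for i, gid in enumerate(truth.gene_ids):
            m = truth.interaction_betas[gid].shape[0]
            planted = rng.random(m) < 0.3
            mags = rng.uniform(0.5, 0.9, m) * np.where(rng.random(m) < 0.5, 1.0, -1.0)
            truth.interaction_betas[gid] = np.where(planted, mags, 0.0)
            cols = np.where(var_gene == gid)[0]
            X = g_d.dosages[:, cols]
            e_d.values[i] += (X * sex_d[:, None]) @ truth.interaction_betas[gid]
        rep_inter = {gid: np.where(rng.random(ib.shape) < frac, ib, 0.0)
                     for gid, ib in truth.interaction_betas.items()}
        rep_effects = {"sex_effects": truth.sex_effects, "cis_betas": truth.cis_betas,
                       "interaction_betas": rep_inter,
                       "hidden_loadings": truth.hidden_loadings}
        g_r, sex_r, _ = simulate_genotypes(cfg, rng=rng, template=(g_d.variants, genes))
        e_r, _ = simulate_expression(g_r, cfg, sex_r, genes, rng,
                                     truth_effects=rep_effects)

        _, _, _, inter_d = run_two_stage(g_d, e_d, sex_d, genes)
        if inter_d is None or not inter_d["significant"].any():
            out[frac] = {"pi1": np.nan, "n_index": 0}
            continue
        sig = inter_d[inter_d["significant"]]
        clumped, _ = ld_clump(sig, g_d)
        index = clumped[clumped["is_index"]]
        rep_scan = interaction_scan(index[["gene_id", "variant_id"]], g_r, e_r, None, sex_r)
        res = pi1_replication(index, rep_scan)
        out[frac] = {"pi1": res.pi1, "n_index": res.n_discovery_hits,
                     "n_matched": res.n_matched}
    return out


def coloc_behavior(n_runs=50, n_variants=50, peak_z=8.0, se=0.05, seed=0) -> dict:
    """Colocalization posteriors under shared vs distinct causal variants.

    Each run draws two single-signal association profiles over the same
    variant list (peak |z| = ``peak_z`` at the causal variant, standard
    normal noise z elsewhere, constant SE). Shared runs place the causal
    variant at the same position for both traits; distinct runs at
    different positions.
    """
    pp4_shared, pp3_wins, sums = [], [], []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, 400 + run])
        vids = [f"v{i:03d}" for i in range(n_variants)]

        def _profile(causal_idx):
            z = rng.standard_normal(n_variants)
            z[causal_idx] = peak_z
            return pd.DataFrame({"variant_id": vids, "beta": z * se, "se": se})

        i_shared = int(rng.integers(n_variants))
        r = coloc_abf(_profile(i_shared), _profile(i_shared))
        pp4_shared.append(r.pp4)
        sums.append(float(np.sum(r.posteriors)))
        i1 = int(rng.integers(n_variants))
        i2 = (i1 + 1 + int(rng.integers(n_variants - 1))) % n_variants
        r2 = coloc_abf(_profile(i1), _profile(i2))
        pp3_wins.append(int(np.argmax(r2.posteriors)) == 3)
        sums.append(float(np.sum(r2.posteriors)))
    return {
        "n_runs": n_runs,
        "pp4_pass_rate": float(np.mean([p > 0.75 for p in pp4_shared])),
        "mean_pp4_shared": float(np.mean(pp4_shared)),
        "pp3_argmax_rate": float(np.mean(pp3_wins)),
        "max_posterior_sum_error": float(np.max(np.abs(np.array(sums) - 1.0))),
    }


def sex_specific_recovery(
    n_runs=50, n_samples=600, n_genes=6, snps_per_gene=12, gwas_n=20_000,
    protein_trait_effect=0.3, cis_beta=0.8, seed=0, swap_sexes=False,
) -> dict:
    """End-to-end recovery of a planted female-only causal protein.

    Each run simulates a cohort in which every gene has exactly one causal
    cis variant (so the single-causal-variant assumption of the
    colocalization holds), gives one target gene a female-only
    protein-to-trait effect, simulates a sex-stratified GWAS through the
    mediation model, and runs heritability filtering, weight training,
    PWAS and colocalization per sex before applying the sex-specific
    classification rule. Reports the fraction of runs classified
    female_only. ``swap_sexes`` relabels the strata to check label
    symmetry (the same runs must then come out male_only).
    """
    calls = []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, 500 + run])
        cfg = SimConfig(
            n_samples=n_samples, n_genes=n_genes, snps_per_gene=snps_per_gene,
            fraction_x_genes=0.0, n_x_background=0,
            sex_effect_fraction=0.0, cis_fraction=0.0, interaction_fraction=0.0,
            n_hidden_factors=0, gwas_n=gwas_n, seed=seed,
        )
        g, sex, genes = simulate_genotypes(cfg, rng=rng)
        e, truth = simulate_expression(g, cfg, sex, genes, rng)
        var_gene = g.variants["id"].str.rsplit("_", n=1).str[0].to_numpy()
        for i, gid in enumerate(truth.gene_ids):
            j = int(rng.integers(snps_per_gene))
            truth.cis_betas[gid][:] = 0.0
            truth.cis_betas[gid][j] = cis_beta
            cols = np.where(var_gene == gid)[0]
            e.values[i] += g.dosages[:, cols] @ truth.cis_betas[gid]
        target = truth.gene_ids[0]
        eff = {target: {"female": protein_trait_effect, "male": 0.0}}
        gwas = simulate_gwas(cfg, truth, eff, rng=rng)

        if swap_sexes:
            sex = 1 - sex
            gwas = {**gwas, "male": gwas["female"], "female": gwas["male"]}

        pwas, coloc = {}, {}
        records = []
        for stratum, scode in (("male", 0), ("female", 1)):
            mask = sex == scode
            gsum = gwas[stratum].set_index("SNP")
            for gi, gid in enumerate(truth.gene_ids):
                cols = np.where(var_gene == gid)[0]
                X = g.dosages[np.ix_(mask, cols)]
                y = e.values[gi, mask]
                h = cis_heritability(X, y, gid, stratum)
                if not h.heritable:
                    continue
                vids = list(g.variants["id"].iloc[cols])
                w = train_weights(X, y, vids, gid, stratum, seed=seed)
                z = gsum.loc[vids, "Z"].to_numpy(dtype=float)
                sub = gwas["ld_cohort"].subset(variants=cols)
                R = np.corrcoef(sub.imputed_standardized(), rowvar=False)
                rec = pwas_assoc(w, z, R)
                records.append(rec)
                pwas[(gid, stratum)] = rec
                from .pipeline import _marginal_stats

                pb, pse = _marginal_stats(X, y)
                t2 = gsum.loc[vids]
                coloc[(gid, stratum)] = coloc_abf(
                    pd.DataFrame({"variant_id": vids, "beta": pb, "se": pse}),
                    pd.DataFrame({"variant_id": vids, "beta": t2["BETA"].to_numpy(),
                                  "se": t2["SE"].to_numpy()}),
                    ColocPriors(), gene_id=gid, stratum=stratum,
                )
        assign_pwas_fdr(records)
        call = classify_sex_specific(
            pwas.get((target, "female")), pwas.get((target, "male")),
            coloc.get((target, "female")), coloc.get((target, "male")),
            target, "sim_trait",
        )
        calls.append(call.classification)
    want = "male_only" if swap_sexes else "female_only"
    return {
        "n_runs": n_runs,
        "recovery_rate": float(np.mean([c == want for c in calls])),
        "classifications": {c: calls.count(c) for c in set(calls)},
        "expected_label": want,
    }
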