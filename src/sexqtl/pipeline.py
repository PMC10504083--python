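"""End-to-end orchestration with a reproducible run manifest.

Stages run in dependency order into a fresh output directory; every
output TSV has a header and deterministic row order (chromosome,
position, gene id), and the manifest — config snapshot, seeds, per-stage
record counts, version, timestamps — is written last. No stage mutates
its inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .causal import (
    ColocPriors,
    assign_pwas_fdr,
    cis_heritability,
    classify_sex_specific,
    coloc_abf,
    pwas_assoc,
    train_weights,
)
from .expression import ExpressionMatrix, estimate_svs, read_expression_tsv, zscore
from .genotype import genetic_pcs, infer_sex, qc_filter, read_genotypes
from .sbqtl import (
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
from .sexde import records_to_frame, sexdiff_scan
from .simulate import (
    SimConfig,
    SimTruth,
    simulate_gwas,
    simulate_metadata,
    simulate_replication_pair,
    write_cohort,
)
from .stats import qq_lambda

STAGES = ["simulate", "qc", "prep", "sexde", "sbqtl", "replicate", "causal"]

DEFAULT_CONFIG: dict = {
    # simulation
    "n_samples": 716,
    "n_genes": 60,
    "snps_per_gene": 12,
    "maf_min": 0.05,
    "maf_max": 0.5,
    "ld_block_size": 6,
    "ld_rho": 0.8,
    "fraction_x_genes": 0.05,
    "sex_effect_sd": 0.5,
    "sex_effect_fraction": 0.15,
    "cis_beta_sd": 0.4,
    "cis_fraction": 0.5,
    "interaction_beta_sd": 0.4,
    "interaction_fraction": 0.1,
    "n_hidden_factors": 3,
    "hidden_loading_sd": 0.3,
    "noise_sd": 1.0,
    "replication_overlap": 1.0,
    "replication_n": 300,
    "gwas_n": 20000,
    "n_causal_female": 2,
    "n_causal_male": 1,
    "protein_trait_effect": 0.3,
    # analysis thresholds
    "fdr": 0.05,
    "interaction_fdr": 0.05,
    "cis_window": 500000,
    "clump_r2": 0.50,
    "clump_r2_independent": 0.10,
    "clump_window": 250000,
    "n_pcs": 10,
    "n_svs": None,
    "coloc_p1": 1e-4,
    "coloc_p2": 1e-4,
    "coloc_p12": 1e-5,
    "pp4_min": 0.75,
    "heritability_p": 0.01,
    "stage2_universe": "stage1_pairs",  # or "all_pairs"
    "seed": 0,
}

_RANGE_CHECKS = {
    "fdr": (0.0, 1.0),
    "interaction_fdr": (0.0, 1.0),
    "pp4_min": (0.0, 1.0),
    "heritability_p": (0.0, 1.0),
    "clump_r2": (0.0, 1.0),
    "clump_r2_independent": (0.0, 1.0),
    "replication_overlap": (0.0, 1.0),
}


class ConfigError(ValueError):
    pass


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides onto the defaults."""
    cfg = dict(DEFAULT_CONFIG)
    user: dict = {}
    if path is not None:
        import yaml

        user.update(yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        user.update(overrides)
    bad = [k for k in user if k not in DEFAULT_CONFIG]
    if bad:
        raise ConfigError(
            f"invalid config keys {bad}; valid keys: {sorted(DEFAULT_CONFIG)}"
        )
    cfg.update(user)
    for key, (lo, hi) in _RANGE_CHECKS.items():
        v = cfg[key]
        if not (lo < v <= hi):
            raise ConfigError(f"config key {key}={v} outside ({lo}, {hi}]")
    if cfg["stage2_universe"] not in ("stage1_pairs", "all_pairs"):
        raise ConfigError("stage2_universe must be 'stage1_pairs' or 'all_pairs'")
    return cfg


def _sim_config(cfg: dict, **kw) -> SimConfig:
    fields = {f for f in SimConfig.__dataclass_fields__}
    base = {k: v for k, v in cfg.items() if k in fields}
    base.update(kw)
    return SimConfig(**base)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _chrom_rank(s: pd.Series) -> pd.Series:
    """Natural chromosome order: 1..22 numerically, then X/Y/other."""
    def rank(c):
        c = str(c)
        return f"{int(c):02d}" if c.isdigit() else f"90{c}"

    return s.map(rank)


def _sorted_out(df: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("chromosome", "position", "gene_id", "variant_id") if c in df.columns]
    if not cols:
        return df
    key = lambda s: _chrom_rank(s) if s.name == "chromosome" else s
    return df.sort_values(cols, kind="mergesort", key=key).reset_index(drop=True)


class Pipeline:
    """Stateful runner; each stage reads prior outputs from the run dir."""

    def __init__(self, config: dict, outdir, seed: int | None = None):
        self.cfg = dict(config)
        if seed is not None:
            self.cfg["seed"] = int(seed)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "version": __version__,
            "config": {k: v for k, v in self.cfg.items()},
            "seed": self.cfg["seed"],
            "stages": {},
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    # -- helpers -----------------------------------------------------------

    def _require(self, path: str, producer: str) -> Path:
        p = self.outdir / path
        if not p.exists():
            raise FileNotFoundError(
                f"missing {p.name}; run the '{producer}' stage first"
            )
        return p

    def _record(self, stage: str, **counts) -> None:
        self.manifest["stages"][stage] = counts

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.cfg
        scfg = _sim_config(cfg)
        disc, repl_full, truth = simulate_replication_pair(scfg, cfg["replication_overlap"])
        # replication cohort is smaller, like a typical confirmation set
        n_rep = min(cfg["replication_n"], repl_full["genotypes"].n_samples)
        keep = np.arange(n_rep)
        repl = {
            "genotypes": repl_full["genotypes"].subset(samples=keep),
            "expression": ExpressionMatrix(
                repl_full["expression"].values[:, keep],
                repl_full["expression"].gene_ids,
                [repl_full["expression"].sample_ids[i] for i in keep],
                repl_full["expression"].level,
                repl_full["expression"].stage,
            ),
            "sex": repl_full["sex"][keep],
            "genes": repl_full["genes"],
        }
        rng = np.random.default_rng(cfg["seed"] + 1)
        disc_meta = simulate_metadata(scfg, disc["sex"], disc["genotypes"].sample_ids, rng)
        repl_meta = simulate_metadata(scfg, repl["sex"], repl["genotypes"].sample_ids, rng)

        # assign protein->trait effects for the causal stage
        rng_eff = np.random.default_rng(cfg["seed"] + 2)
        eligible = [g for g in truth.gene_ids if np.any(truth.cis_betas[g] != 0)]
        n_f, n_m = cfg["n_causal_female"], cfg["n_causal_male"]
        chosen = list(rng_eff.choice(eligible, size=min(n_f + n_m, len(eligible)), replace=False))
        eff = {}
        for i, gid in enumerate(chosen):
            e0 = float(cfg["protein_trait_effect"])
            eff[gid] = {"female": e0, "male": 0.0} if i < n_f else {"female": 0.0, "male": e0}
        truth.protein_trait_effects["causal"] = eff

        write_cohort(self.outdir / "data" / "discovery", disc["genotypes"], disc["expression"],
                     disc_meta, disc["genes"], truth)
        write_cohort(self.outdir / "data" / "replication", repl["genotypes"], repl["expression"],
                     repl_meta, repl["genes"])
        self._record("simulate", n_discovery=disc["genotypes"].n_samples,
                     n_replication=repl["genotypes"].n_samples,
                     n_genes=len(disc["genes"]), n_variants=disc["genotypes"].n_variants,
                     n_causal_genes=len(eff))

    def _load_cohort(self, name: str):
        d = self.outdir / "data" / name
        self._require(f"data/{name}/genotypes.bed", "simulate")
        g = read_genotypes(d / "genotypes")
        e = read_expression_tsv(d / "expression.tsv", stage="residualized")
        samples = pd.read_csv(d / "samples.tsv", sep="\t", dtype={"batch": str})
        genes = pd.read_csv(
            d / "genes.bed", sep="\t", header=None,
            names=["chromosome", "start0", "end", "gene_id"], dtype={"chromosome": str},
        )
        genes["start"] = genes["start0"] + 1  # back to 1-based inclusive
        return g, e, samples, genes

    def qc(self) -> None:
        g, e, samples, genes = self._load_cohort("discovery")
        sex = samples["sex"].to_numpy()
        gq, report = qc_filter(g, sex=sex)
        calls = infer_sex(gq)
        concord = float(np.mean([
            (c.call == "male") == (s == 0) and c.call != "ambiguous"
            for c, s in zip(calls, sex)
        ]))
        # autosomes only: X hemizygosity would imprint sex on the PCs
        auto = gq.subset(variants=np.where(~gq.is_x().to_numpy())[0])
        pcs = genetic_pcs(auto, k=min(self.cfg["n_pcs"], auto.n_samples - 1, auto.n_variants - 1))
        np.savetxt(self.outdir / "qc_pcs.tsv", pcs, delimiter="\t",
                   header="\t".join(f"PC{i+1}" for i in range(pcs.shape[1])), comments="")
        report.to_json(self.outdir / "qc_report.json")
        pd.DataFrame([c.__dict__ for c in calls]).to_csv(
            self.outdir / "qc_sex_calls.tsv", sep="\t", index=False
        )
        self._record("qc", n_variants_kept=gq.n_variants, n_samples=gq.n_samples,
                     sex_concordance=concord)

    def prep(self) -> None:
        g, e, samples, genes = self._load_cohort("discovery")
        svs = estimate_svs(e, samples, seed=self.cfg["seed"], n_sv=self.cfg["n_svs"])
        ez = zscore(e)
        np.savetxt(self.outdir / "svs.tsv", svs.matrix, delimiter="\t",
                   header="\t".join(f"SV{i+1}" for i in range(svs.k)) or "empty", comments="")
        ez.write_tsv(self.outdir / "expression_zscored.tsv")
        self._record("prep", n_svs=svs.k, n_genes=ez.n_genes)

    def _covariates(self, g) -> np.ndarray:
        svs = _load_matrix(self._require("svs.tsv", "prep"), g.n_samples)
        pcs = _load_matrix(self._require("qc_pcs.tsv", "qc"), g.n_samples)
        return np.column_stack([svs, pcs])

    def sexde(self) -> None:
        _, _, samples, genes = self._load_cohort("discovery")
        ez = read_expression_tsv(self._require("expression_zscored.tsv", "prep"), stage="zscored")
        sv_arr = _load_matrix(self._require("svs.tsv", "prep"), ez.n_samples)
        from .expression import SurrogateVariables

        svs = SurrogateVariables(sv_arr, sv_arr.shape[1])
        records = sexdiff_scan(ez, samples, svs, fdr=self.cfg["fdr"])
        chrom_map = dict(zip(genes["gene_id"], genes["chromosome"].astype(str)))
        for r in records:
            r.chromosome = chrom_map.get(r.gene_id)
        df = _sorted_out(records_to_frame(records))
        df.to_csv(self.outdir / "sexde.tsv", sep="\t", index=False)
        self._record("sexde", n_tested=len(df),
                     n_significant=int((df["q"] < self.cfg["fdr"]).sum()))

    def _run_sbqtl(self, g, e, samples, genes, covs):
        acfg = AnalysisConfig(
            cis_window=self.cfg["cis_window"], fdr=self.cfg["fdr"],
            interaction_fdr=self.cfg["interaction_fdr"], clump_r2=self.cfg["clump_r2"],
            clump_r2_independent=self.cfg["clump_r2_independent"],
            clump_window=self.cfg["clump_window"],
            stage2_universe=self.cfg["stage2_universe"],
        )
        sex = samples["sex"].to_numpy()
        pairs = map_cis_pairs(genes, g.variants, acfg.cis_window)
        scans = {
            mode: cis_scan(pairs, g, e, covs, sex, mode=mode)
            for mode in ("joint", "male", "female")
        }
        stage1 = stage1_union(scans["joint"], scans["male"], scans["female"], acfg.fdr)
        if len(stage1) == 0:
            return acfg, pairs, scans, stage1, None
        if acfg.stage2_universe == "all_pairs":
            # BH over the interaction p-values of every scanned pair; the
            # sb-QTL definition still requires stage-1 membership
            inter = interaction_scan(
                pairs[["gene_id", "variant_id"]].drop_duplicates(),
                g, e, covs, sex, acfg.interaction_fdr,
            )
            s1 = set(zip(stage1["gene_id"], stage1["variant_id"]))
            in_s1 = [
                (r.gene_id, r.variant_id) in s1 for r in inter.itertuples(index=False)
            ]
            inter["significant"] = inter["significant"] & np.asarray(in_s1)
            sig_p = inter.loc[inter["significant"], "p_interaction"]
            inter.attrs["stage_p"] = float(sig_p.max()) if len(sig_p) else float("nan")
        else:
            inter = interaction_scan(stage1, g, e, covs, sex, acfg.interaction_fdr)
        return acfg, pairs, scans, stage1, inter

    def sbqtl(self) -> None:
        g, e, samples, genes = self._load_cohort("discovery")
        covs = self._covariates(g)
        acfg, pairs, scans, stage1, inter = self._run_sbqtl(g, e, samples, genes, covs)
        for mode, df in scans.items():
            _sorted_out(df).to_csv(self.outdir / f"assoc_{mode}.tsv", sep="\t", index=False)
        stage1.to_csv(self.outdir / "stage1_pairs.tsv", sep="\t", index=False)
        summary = {"n_pairs": len(pairs), "n_stage1": len(stage1)}
        if inter is not None and len(inter):
            sig = inter[inter["significant"]].copy()
            if len(sig):
                clumped, clump_summary = ld_clump(
                    sig, g, acfg.clump_r2, acfg.clump_window, acfg.clump_r2_independent
                )
                clumped = classify_sbqtl(clumped, scans["male"], scans["female"], acfg.fdr)
                _sorted_out(clumped).to_csv(self.outdir / "sbqtl.tsv", sep="\t", index=False)
                summary.update(clump_summary)
                index_recs = clumped[clumped["is_index"]]
                stage_p = inter.attrs["stage_p"]
                env = environment_check(
                    index_recs, g, e, samples, ["education", "alcohol", "smoking"],
                    stage_p, covs,
                )
                env.to_csv(self.outdir / "environment_check.tsv", sep="\t", index=False)
                summary["stage_p"] = stage_p
                summary["n_env_attenuated"] = int((env["flag"] == "attenuated").sum())
            _sorted_out(inter).to_csv(self.outdir / "interaction.tsv", sep="\t", index=False)
            lam, exp_q, obs_q = qq_lambda(inter["p_interaction"].to_numpy())
            pd.DataFrame({"expected": exp_q, "observed": obs_q}).to_csv(
                self.outdir / "qq_interaction.tsv", sep="\t", index=False
            )
            summary["lambda_interaction"] = lam
            summary["n_sbqtl_records"] = int(inter["significant"].sum())
            summary["n_sbqtl_genes"] = int(
                inter.loc[inter["significant"], "gene_id"].nunique()
            )
        (self.outdir / "sbqtl_summary.json").write_text(json.dumps(summary, indent=2))
        self._record("sbqtl", **{k: v for k, v in summary.items() if isinstance(v, (int, float))})

    def replicate(self) -> None:
        self._require("sbqtl_summary.json", "sbqtl")
        g, e, samples, genes = self._load_cohort("replication")
        svs = estimate_svs(e, samples, seed=self.cfg["seed"] + 3, n_sv=self.cfg["n_svs"])
        pcs = genetic_pcs(g, k=min(self.cfg["n_pcs"], g.n_samples - 1, g.n_variants - 1))
        covs = np.column_stack([svs.matrix, pcs])
        sbq_path = self.outdir / "sbqtl.tsv"
        if not sbq_path.exists():
            self._record("replicate", n_matched=0, pi1=float("nan"))
            return
        discovery = pd.read_csv(sbq_path, sep="\t")
        index_recs = discovery[discovery["is_index"]]
        sex = samples["sex"].to_numpy()
        pairs = index_recs[["gene_id", "variant_id"]]
        inter = interaction_scan(pairs, g, e, covs, sex)
        res = pi1_replication(index_recs, inter)
        payload = {"n_discovery_hits": res.n_discovery_hits, "n_matched": res.n_matched,
                   "pi1": res.pi1}
        (self.outdir / "replication.json").write_text(json.dumps(payload, indent=2))
        self._record("replicate", **payload)

    def causal(self) -> None:
        g, e, samples, genes = self._load_cohort("discovery")
        truth = SimTruth.from_json(self.outdir / "data" / "discovery" / "truth.json", genes)
        eff = truth.protein_trait_effects.get("causal", {})
        if not eff:
            self._record("causal", n_tested=0)
            return
        cfg = self.cfg
        scfg = _sim_config(cfg)
        gwas = simulate_gwas(scfg, truth, eff, rng=np.random.default_rng(cfg["seed"] + 7))
        priors = ColocPriors(cfg["coloc_p1"], cfg["coloc_p2"], cfg["coloc_p12"])
        sex = samples["sex"].to_numpy()
        var_gene = g.variants["id"].str.rsplit("_", n=1).str[0].to_numpy()
        ld_cohort = gwas["ld_cohort"]

        pwas_records = {"male": [], "female": []}
        coloc_results = {}
        herit_rows = []
        genes_to_test = sorted(eff)
        for stratum, scode in (("male", 0), ("female", 1)):
            mask = sex == scode
            gsum = gwas[stratum].set_index("SNP")
            for gid in genes_to_test:
                cols = np.where(var_gene == gid)[0]
                X = g.dosages[np.ix_(mask, cols)]
                gi = e.gene_ids.index(gid)
                y = e.values[gi, mask]
                h = cis_heritability(X, y, gid, stratum, cfg["heritability_p"])
                herit_rows.append(h.__dict__)
                if not h.heritable:
                    continue
                vids = list(g.variants["id"].iloc[cols])
                w = train_weights(X, y, vids, gid, stratum, seed=cfg["seed"])
                zvec = gsum.loc[vids, "Z"].to_numpy(dtype=float)
                sub = ld_cohort.subset(variants=cols)
                Zs = sub.imputed_standardized()
                R = np.corrcoef(Zs, rowvar=False)
                rec = pwas_assoc(w, zvec, R)
                pwas_records[stratum].append(rec)
                # coloc: protein marginal stats in this stratum vs GWAS
                prot = _marginal_stats(X, y)
                t2 = gsum.loc[vids]
                coloc_results[(gid, stratum)] = coloc_abf(
                    pd.DataFrame({"variant_id": vids, "beta": prot[0], "se": prot[1]}),
                    pd.DataFrame({"variant_id": vids, "beta": t2["BETA"].to_numpy(),
                                  "se": t2["SE"].to_numpy()}),
                    priors, gene_id=gid, stratum=stratum,
                )
        assign_pwas_fdr(pwas_records["male"] + pwas_records["female"])
        calls = []
        by_key = {(r.gene_id, r.stratum): r for s in pwas_records.values() for r in s}
        for gid in genes_to_test:
            call = classify_sex_specific(
                by_key.get((gid, "female")), by_key.get((gid, "male")),
                coloc_results.get((gid, "female")), coloc_results.get((gid, "male")),
                gid, trait="sim_trait", fdr=cfg["fdr"], pp4_min=cfg["pp4_min"],
            )
            calls.append({"gene_id": gid, "trait": call.trait,
                          "classification": call.classification,
                          "truth_female": eff[gid]["female"], "truth_male": eff[gid]["male"],
                          **{k: v for k, v in call.detail.items()}})
        pd.DataFrame(herit_rows).to_csv(self.outdir / "heritability.tsv", sep="\t", index=False)
        pd.DataFrame(calls).to_csv(self.outdir / "causal_calls.tsv", sep="\t", index=False)
        n_correct = sum(
            1 for c in calls
            if c["classification"] == (
                "female_only" if c["truth_female"] and not c["truth_male"]
                else "male_only" if c["truth_male"] and not c["truth_female"]
                else "both" if c["truth_male"] and c["truth_female"] else "neither")
        )
        self._record("causal", n_tested=len(calls), n_correct=n_correct)

    # -- driver ------------------------------------------------------------

    def run(self, subcommand: str = "all") -> dict:
        stages = STAGES if subcommand == "all" else [subcommand]
        if any(s not in STAGES for s in stages):
            raise ConfigError(f"unknown subcommand {subcommand!r}; one of {STAGES + ['all']}")
        for stage in stages:
            getattr(self, stage)()
        self.manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.manifest["input_checksums"] = {
            p.name: _sha256(p)
            for p in sorted((self.outdir / "data").rglob("*"))
            if p.is_file()
        } if (self.outdir / "data").exists() else {}
        (self.outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))
        return self.manifest


def _load_matrix(path, n_rows: int) -> np.ndarray:
    """Read a headered TSV of floats; an empty body yields an (n, 0) array."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return arr if arr.size else np.empty((n_rows, 0))


def _marginal_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant marginal beta/se of y on each dosage column."""
    Xc = np.nan_to_num(X)
    Xc = Xc - Xc.mean(axis=0)
    yc = y - y.mean()
    n = len(y)
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    xtx[xtx == 0] = np.nan
    beta = (Xc.T @ yc) / xtx
    ss = yc @ yc - beta**2 * xtx
    se = np.sqrt(ss / (n - 2) / xtx)
    return beta, se


def run_pipeline(config_path=None, subcommand: str = "all", outdir="runs/run1",
                 seed: int | None = None, overrides: dict | None = None) -> dict:
    """Load config, run the requested stage(s), return the manifest."""
    cfg = load_config(config_path, overrides)
    return Pipeline(cfg, outdir, seed=seed).run(subcommand)
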