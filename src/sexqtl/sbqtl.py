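"""Sex-biased cis-QTL mapping.

The two-stage procedure at the heart of the package:

stage 1
    cis-QTL scans run jointly in both sexes (sex as covariate) and in each
    sex separately; a (gene, variant) pair enters stage 2 if it is
    significant at BH FDR < 0.05 in any of the three scans.
stage 2
    the stage-1 pairs are tested for a genotype-by-sex interaction
    (expression ~ dosage + sex + dosage*sex + covariates); pairs whose
    interaction term survives BH FDR < 0.05 over all stage-1 pairs are
    sex-biased QTLs (sb-QTLs).

Downstream: greedy LD clumping of sb-QTL records to index variants
(r2 >= 0.50 within 250 kb, with the r2 >= 0.10 count also reported),
sex-category classification of index records, an environment-interaction
confounding check, and Storey pi1 discovery/replication estimation.

Scans use the Frisch-Waugh-Lovell decomposition: expression and dosages
are residualized on the covariate design once per gene, after which every
variant's effect, SE and p-value come from closed-form projections. This
matches full per-pair OLS exactly (same estimates and t-tests) while
scanning thousands of pairs per second.

Sex is coded male = 0 / female = 1; the interaction beta is the
female-minus-male difference in per-allele effect. Male X dosages are
{0, 2} in every mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genotype import GenotypeMatrix
from .stats import bh_fdr, storey_pi1

__all__ = [
    "AnalysisConfig",
    "map_cis_pairs",
    "cis_scan",
    "stage1_union",
    "interaction_scan",
    "ld_clump",
    "classify_sbqtl",
    "environment_check",
    "pi1_replication",
]


@dataclass
class AnalysisConfig:
    """Thresholds of the sb-QTL procedure (defaults follow the standard
    two-stage design: FDR 0.05 at both stages, +/-500 kb cis window,
    clumping at r2 0.50 / 250 kb with a 0.10 secondary threshold)."""

    cis_window: int = 500_000
    fdr: float = 0.05
    interaction_fdr: float = 0.05
    clump_r2: float = 0.50
    clump_r2_independent: float = 0.10
    clump_window: int = 250_000
    min_stratum_n: int = 30
    stage2_universe: str = "stage1_pairs"  # or "all_pairs"

    def __post_init__(self) -> None:
        for name in ("fdr", "interaction_fdr", "clump_r2", "clump_r2_independent"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.cis_window < 0 or self.clump_window < 0:
            raise ValueError("windows must be nonnegative")


# ---------------------------------------------------------------------------
# cis pair mapping
# ---------------------------------------------------------------------------


def map_cis_pairs(
    genes: pd.DataFrame, variants: pd.DataFrame, window: int = 500_000
) -> pd.DataFrame:
    """Enumerate gene-variant cis pairs within ``window`` bp of gene bodies.

    ``genes`` needs columns gene_id/chromosome/start/end (1-based
    inclusive); ``variants`` needs id/chromosome/position. A variant pairs
    with a gene iff it lies in [start - window, end + window] on the same
    chromosome. Returns a frame (gene_id, variant_id, distance) where
    distance is 0 inside the gene body.
    """
    if (genes["end"] < genes["start"]).any():
        bad = genes.loc[genes["end"] < genes["start"], "gene_id"].tolist()
        raise ValueError(f"gene end < start for {bad}")
    out = []
    vsorted = variants.sort_values("position")
    by_chrom = {c: df for c, df in vsorted.groupby(variants["chromosome"].astype(str))}
    for g in genes.itertuples(index=False):
        vdf = by_chrom.get(str(g.chromosome))
        if vdf is None:
            continue
        lo, hi = g.start - window, g.end + window
        pos = vdf["position"].to_numpy()
        sel = vdf[(pos >= lo) & (pos <= hi)]
        for v in sel.itertuples(index=False):
            if v.position < g.start:
                dist = g.start - v.position
            elif v.position > g.end:
                dist = v.position - g.end
            else:
                dist = 0
            out.append((g.gene_id, v.id, int(dist)))
    return pd.DataFrame(out, columns=["gene_id", "variant_id", "distance"])


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M on the column space of Z."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def _t_pvals(t: np.ndarray, dof: int) -> np.ndarray:
    from scipy import stats as sps

    return np.clip(2.0 * sps.t.sf(np.abs(t), dof), 0.0, 1.0)


def _check_alignment(g: GenotypeMatrix, e: ExpressionMatrix) -> None:
    if list(g.sample_ids) != list(e.sample_ids):
        raise ValueError("genotype and expression sample ids are not aligned")


def cis_scan(
    pairs: pd.DataFrame,
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    covariates: np.ndarray | None,
    sex: np.ndarray,
    mode: str = "joint",
    min_stratum_n: int = 30,
) -> pd.DataFrame:
    """Per-pair OLS association scan in one mode.

    mode "joint" uses all samples and adds sex to the covariates; "male" /
    "female" restrict to one stratum. Missing dosages are mean-imputed;
    variants monomorphic in the analysis stratum are skipped (their count
    is attached as ``frame.attrs['n_skipped_monomorphic']``). BH q-values
    are computed across every tested pair within the mode.
    """
    _check_alignment(g, e)
    sex = np.asarray(sex, dtype=float)
    n_all = g.n_samples
    if mode == "joint":
        mask = np.ones(n_all, dtype=bool)
    elif mode == "male":
        mask = sex == 0
    elif mode == "female":
        mask = sex == 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = int(mask.sum())
    if mode != "joint" and n < min_stratum_n:
        raise ValueError(f"{mode} stratum has n={n} < {min_stratum_n}")

    cov = covariates[mask] if covariates is not None else np.empty((n, 0))
    Zcols = [np.ones(n)]
    if mode == "joint":
        Zcols.append(sex[mask])
    Z = np.column_stack(Zcols + [cov]) if cov.size else np.column_stack(Zcols)
    p_base = Z.shape[1]
    dof = n - p_base - 1
    if dof <= 0:
        raise ValueError("not enough samples for the covariate design")

    gene_index = {gid: i for i, gid in enumerate(e.gene_ids)}
    var_index = {vid: j for j, vid in enumerate(g.variants["id"])}
    D = _imputed(g.dosages[mask])
    E = e.values[:, mask]

    rows = []
    n_skipped = 0
    for gene_id, sub in pairs.groupby("gene_id", sort=False):
        gi = gene_index.get(gene_id)
        if gi is None:
            continue
        y = E[gi]
        ok = ~np.isnan(y)
        vidx = np.array([var_index[v] for v in sub["variant_id"] if v in var_index])
        if vidx.size == 0:
            continue
        X = D[:, vidx]
        if not ok.all():
            yv, Xv, Zv = y[ok], X[ok], Z[ok]
            dof_g = int(ok.sum()) - p_base - 1
        else:
            yv, Xv, Zv = y, X, Z
            dof_g = dof
        if dof_g <= 0:
            continue
        mono = Xv.std(axis=0) == 0
        n_skipped += int(mono.sum())
        yr = _residualize(yv[:, None], Zv).ravel()
        Xr = _residualize(Xv, Zv)
        xtx = np.einsum("ij,ij->j", Xr, Xr)
        xty = Xr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = xty / xtx
            ss_res = yr @ yr - beta * xty
            sigma2 = ss_res / dof_g
            se = np.sqrt(sigma2 / xtx)
            tstat = beta / se
        pvals = _t_pvals(tstat, dof_g)
        vids = [v for v in sub["variant_id"] if v in var_index]
        for j, vid in enumerate(vids):
            if mono[j] or not np.isfinite(pvals[j]):
                continue
            rows.append((gene_id, vid, mode, beta[j], se[j], pvals[j], len(yv)))
    df = pd.DataFrame(rows, columns=["gene_id", "variant_id", "mode", "beta", "se", "p", "n"])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else np.nan
    df.attrs["n_skipped_monomorphic"] = n_skipped
    return df


def _imputed(d: np.ndarray) -> np.ndarray:
    d = d.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(d, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.where(np.isnan(d))
    d[idx] = mu[idx[1]]
    return d


def stage1_union(
    joint: pd.DataFrame, male: pd.DataFrame, female: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Pairs significant at BH FDR < ``fdr`` in any of the three scans.

    Returns a frame (gene_id, variant_id, source_modes) where source_modes
    is a comma-joined list of the scans in which the pair was significant.
    """
    sources: dict[tuple[str, str], list[str]] = {}
    for df in (joint, male, female):
        if len(df) == 0:
            continue
        sig = df[df["q"] < fdr]
        for r in sig.itertuples(index=False):
            sources.setdefault((r.gene_id, r.variant_id), []).append(r.mode)
    rows = [(g, v, ",".join(modes)) for (g, v), modes in sorted(sources.items())]
    return pd.DataFrame(rows, columns=["gene_id", "variant_id", "source_modes"])


def interaction_scan(
    stage1: pd.DataFrame,
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    covariates: np.ndarray | None,
    sex: np.ndarray,
    interaction_fdr: float = 0.05,
) -> pd.DataFrame:
    """Genotype-by-sex interaction test on the stage-1 pairs.

    Fits expression ~ dosage + sex + dosage*sex + covariates per pair via
    FWL (dosage and the product term residualized jointly on the base
    design). BH correction runs over the interaction p-values of every
    stage-1 pair carried into this scan. The returned frame has one row
    per tested pair with ``significant`` flags at ``interaction_fdr``;
    ``frame.attrs['stage_p']`` holds the largest raw p among significant
    pairs (the FDR-equivalent p threshold), and
    ``frame.attrs['skipped']`` lists pairs dropped for collinearity.
    """
    if len(stage1) == 0:
        raise ValueError("stage-1 set is empty")
    _check_alignment(g, e)
    sex = np.asarray(sex, dtype=float)
    n = g.n_samples
    cov = covariates if covariates is not None else np.empty((n, 0))
    Z = np.column_stack([np.ones(n), sex] + ([cov] if cov.size else []))
    p_base = Z.shape[1]

    gene_index = {gid: i for i, gid in enumerate(e.gene_ids)}
    var_index = {vid: j for j, vid in enumerate(g.variants["id"])}
    D = _imputed(g.dosages)

    rows, skipped = [], []
    for gene_id, sub in stage1.groupby("gene_id", sort=False):
        gi = gene_index.get(gene_id)
        if gi is None:
            skipped.extend((gene_id, v, "gene not in expression") for v in sub["variant_id"])
            continue
        y = e.values[gi]
        ok = ~np.isnan(y)
        yv, Zv, sexv = y[ok], Z[ok], sex[ok]
        dof = int(ok.sum()) - p_base - 2
        if dof <= 0:
            skipped.extend((gene_id, v, "insufficient samples") for v in sub["variant_id"])
            continue
        yr = _residualize(yv[:, None], Zv).ravel()
        yy = yr @ yr
        for vid in sub["variant_id"]:
            vj = var_index.get(vid)
            if vj is None:
                skipped.append((gene_id, vid, "variant not in genotypes"))
                continue
            x = D[ok, vj]
            if x.std() == 0:
                skipped.append((gene_id, vid, "monomorphic"))
                continue
            GX = np.column_stack([x, x * sexv])
            R = _residualize(GX, Zv)
            gg = R[:, 0] @ R[:, 0]
            ii = R[:, 1] @ R[:, 1]
            gi_ = R[:, 0] @ R[:, 1]
            det = gg * ii - gi_ * gi_
            if det <= 1e-10 * max(gg * ii, 1e-300):
                skipped.append((gene_id, vid, "collinear design (dosage constant in a sex?)"))
                continue
            gy = R[:, 0] @ yr
            iy = R[:, 1] @ yr
            b_g = (ii * gy - gi_ * iy) / det
            b_i = (gg * iy - gi_ * gy) / det
            ss_res = yy - b_g * gy - b_i * iy
            sigma2 = max(ss_res, 0.0) / dof
            se_i = np.sqrt(sigma2 * gg / det)
            if se_i == 0:
                skipped.append((gene_id, vid, "zero residual variance"))
                continue
            t = b_i / se_i
            rows.append((gene_id, vid, b_g, b_i, se_i, _t_pvals(np.array([t]), dof)[0]))
    df = pd.DataFrame(
        rows, columns=["gene_id", "variant_id", "beta_main", "beta_interaction",
                       "se_interaction", "p_interaction"]
    )
    if len(df):
        df["q_interaction"] = bh_fdr(df["p_interaction"].to_numpy())
        df["significant"] = df["q_interaction"] < interaction_fdr
        sig_p = df.loc[df["significant"], "p_interaction"]
        df.attrs["stage_p"] = float(sig_p.max()) if len(sig_p) else np.nan
    else:
        df["q_interaction"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        df.attrs["stage_p"] = np.nan
    df.attrs["skipped"] = skipped
    return df


# ---------------------------------------------------------------------------
# clumping and classification
# ---------------------------------------------------------------------------


def ld_clump(
    records: pd.DataFrame,
    g: GenotypeMatrix,
    r2: float = 0.50,
    window: int = 250_000,
    alt_r2: float = 0.10,
    p_col: str = "p_interaction",
) -> tuple[pd.DataFrame, dict]:
    """Greedy LD clumping of significant records to index variants.

    Clumping runs within gene (each gene's records form one phenotype's
    clump set, as PLINK does per phenotype). Repeatedly the unassigned
    record with the smallest p becomes an index (ties broken by position
    then variant id); every unassigned record of the same gene within
    ``window`` bp of the index and with genotype r2 >= ``r2`` joins its
    clump. r2 is the squared correlation of mean-imputed standardized
    dosages in the full sample.

    Returns the records with ``is_index`` and ``clump_index`` columns set,
    plus a summary dict with index counts at both r2 thresholds.
    """
    Zstd = g.imputed_standardized()
    n = Zstd.shape[0]
    var_col = {vid: j for j, vid in enumerate(g.variants["id"])}
    positions = g.variants["position"].to_numpy()
    chroms = g.variants["chromosome"].astype(str).to_numpy()

    def _clump(threshold: float) -> pd.DataFrame:
        out = records.copy().reset_index(drop=True)
        is_index = np.zeros(len(out), dtype=bool)
        clump_index = np.empty(len(out), dtype=object)
        rec_col = np.array([var_col[v] for v in out["variant_id"]])
        rec_pos = positions[rec_col]
        rec_chrom = chroms[rec_col]
        pvals = out[p_col].to_numpy()
        vids = out["variant_id"].to_numpy()
        for _, idxs in out.groupby("gene_id", sort=False).indices.items():
            order = idxs[np.lexsort((vids[idxs], rec_pos[idxs], pvals[idxs]))]
            pos_of = {rec: a for a, rec in enumerate(order)}
            assigned = np.zeros(len(order), dtype=bool)
            for a, i in enumerate(order):
                if assigned[a]:
                    continue
                is_index[i] = True
                clump_index[i] = vids[i]
                assigned[a] = True
                rest = order[~assigned]
                if rest.size == 0:
                    continue
                near = (
                    (np.abs(rec_pos[rest] - rec_pos[i]) <= window)
                    & (rec_chrom[rest] == rec_chrom[i])
                )
                cand = rest[near]
                if cand.size:
                    r = (Zstd[:, rec_col[cand]].T @ Zstd[:, rec_col[i]]) / n
                    members = cand[r * r >= threshold]
                    clump_index[members] = vids[i]
                    for rec in members:
                        assigned[pos_of[rec]] = True
        out["is_index"] = is_index
        out["clump_index"] = clump_index
        return out

    main = _clump(r2)
    alt = _clump(alt_r2)
    summary = {
        "n_records": int(len(records)),
        "n_index_primary": int(main["is_index"].sum()),
        "r2_primary": r2,
        "n_index_independent": int(alt["is_index"].sum()),
        "r2_independent": alt_r2,
        "n_genes": int(records["gene_id"].nunique()),
    }
    return main, summary


def classify_sbqtl(
    sbqtl: pd.DataFrame, male: pd.DataFrame, female: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Attach the sex-category label to each sb-QTL record.

    both_concordant / both_discordant when the pair is significant in both
    per-sex scans (same / opposite beta sign), male_only / female_only when
    significant in exactly one. Pairs significant in neither per-sex scan
    (stage-1 entry came from the joint scan alone) are labeled by the
    larger |per-sex Z| and annotated ``joint_only=True``.
    """
    msub = male.set_index(["gene_id", "variant_id"])
    fsub = female.set_index(["gene_id", "variant_id"])
    cats, joint_only = [], []
    for r in sbqtl.itertuples(index=False):
        key = (r.gene_id, r.variant_id)
        mrec = msub.loc[key] if key in msub.index else None
        frec = fsub.loc[key] if key in fsub.index else None
        m_sig = mrec is not None and mrec["q"] < fdr
        f_sig = frec is not None and frec["q"] < fdr
        jo = False
        if m_sig and f_sig:
            cat = "both_concordant" if np.sign(mrec["beta"]) == np.sign(frec["beta"]) else "both_discordant"
        elif m_sig:
            cat = "male_only"
        elif f_sig:
            cat = "female_only"
        else:
            jo = True
            zm = abs(mrec["beta"] / mrec["se"]) if mrec is not None and mrec["se"] > 0 else 0.0
            zf = abs(frec["beta"] / frec["se"]) if frec is not None and frec["se"] > 0 else 0.0
            cat = "male_only" if zm >= zf else "female_only"
        cats.append(cat)
        joint_only.append(jo)
    out = sbqtl.copy()
    out["category"] = cats
    out["joint_only"] = joint_only
    return out


# ---------------------------------------------------------------------------
# environment check
# ---------------------------------------------------------------------------


def environment_check(
    index_records: pd.DataFrame,
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    s: pd.DataFrame,
    env_names: list[str],
    stage_p: float,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Test whether environment interactions could masquerade as sex bias.

    Step 1: test each environment for a sex difference (two-sample t-test
    for numeric, chi-square for categorical). Step 2: for every index
    record x environment, fit expression ~ SNP + env + SNP*env +
    covariates and flag SNP-by-env p < ``stage_p``. Step 3: for flagged
    records refit with both SNP*sex and SNP*env terms; the record is
    ``robust`` if the SNP*sex p-value stays below ``stage_p``, else
    ``attenuated``.
    """
    from .stats import ols_fit

    _check_alignment(g, e)
    for env in env_names:
        if env not in s.columns:
            raise KeyError(f"environment column {env!r} missing from sample table")
    sex = s["sex"].to_numpy(dtype=float)
    n = g.n_samples
    cov = covariates if covariates is not None else np.empty((n, 0))
    gene_index = {gid: i for i, gid in enumerate(e.gene_ids)}
    var_index = {vid: j for j, vid in enumerate(g.variants["id"])}
    D = _imputed(g.dosages)

    sex_env_diff = {}
    from scipy import stats as sps

    for env in env_names:
        col = s[env]
        if col.dtype.kind in "OUSb":
            tab = pd.crosstab(col, sex)
            sex_env_diff[env] = float(sps.chi2_contingency(tab.to_numpy())[1])
        else:
            a = col[sex == 0].astype(float)
            b = col[sex == 1].astype(float)
            sex_env_diff[env] = float(sps.ttest_ind(a, b, equal_var=False).pvalue)

    rows = []
    for r in index_records.itertuples(index=False):
        gi = gene_index.get(r.gene_id)
        vj = var_index.get(r.variant_id)
        if gi is None or vj is None:
            continue
        y = e.values[gi]
        x = D[:, vj]
        ok = ~np.isnan(y)
        for env in env_names:
            envv = pd.to_numeric(s[env], errors="coerce").to_numpy(dtype=float)
            okk = ok & ~np.isnan(envv)
            try:
                X2 = np.column_stack(
                    [np.ones(okk.sum()), x[okk], envv[okk], x[okk] * envv[okk]]
                    + ([cov[okk]] if cov.size else [])
                )
                fit2 = ols_fit(X2, y[okk])
                p_sxe = float(fit2.p_values[3])
            except Exception as err:
                rows.append(
                    {"gene_id": r.gene_id, "variant_id": r.variant_id, "environment": env,
                     "sex_env_diff_p": sex_env_diff[env], "snp_by_env_p": np.nan,
                     "snp_by_sex_p": np.nan, "flag": f"model_error: {err}"}
                )
                continue
            flag = "not_flagged"
            p_sxs = np.nan
            if p_sxe < stage_p:
                X3 = np.column_stack(
                    [np.ones(okk.sum()), x[okk], sex[okk], envv[okk],
                     x[okk] * sex[okk], x[okk] * envv[okk]]
                    + ([cov[okk]] if cov.size else [])
                )
                fit3 = ols_fit(X3, y[okk])
                p_sxs = float(fit3.p_values[4])
                flag = "robust" if p_sxs < stage_p else "attenuated"
            rows.append(
                {"gene_id": r.gene_id, "variant_id": r.variant_id, "environment": env,
                 "sex_env_diff_p": sex_env_diff[env], "snp_by_env_p": p_sxe,
                 "snp_by_sex_p": p_sxs, "flag": flag}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------


@dataclass
class ReplicationResult:
    n_discovery_hits: int
    n_matched: int
    pi1: float
    discovery_label: str = "discovery"
    replication_label: str = "replication"
    unmatched: list = field(default_factory=list)


def pi1_replication(
    discovery_index: pd.DataFrame,
    replication_scan: pd.DataFrame,
    p_col: str = "p_interaction",
) -> ReplicationResult:
    """Storey pi1 of replication interaction p-values at discovery hits.

    ``discovery_index`` is the clumped index sb-QTL set of the discovery
    cohort; each record is matched to the replication interaction scan by
    (gene_id, variant_id). pi1 estimates the fraction of discovery sb-QTLs
    that are true signals in the replication cohort.
    """
    if len(discovery_index) == 0:
        raise ValueError("discovery set is empty")
    rep = replication_scan.set_index(["gene_id", "variant_id"])
    ps, unmatched = [], []
    for r in discovery_index.itertuples(index=False):
        key = (r.gene_id, r.variant_id)
        if key in rep.index:
            ps.append(float(rep.loc[key, p_col]))
        else:
            unmatched.append(key)
    if not ps:
        raise ValueError("no discovery records matched the replication scan")
    pi1 = storey_pi1(ps)
    return ReplicationResult(len(discovery_index), len(ps), float(pi1), unmatched=unmatched)
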