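"""Sex-differential expression scanning and downstream summaries.

Per-gene OLS of expression on sex plus surrogate variables, BH correction
across genes, per-chromosome composition of the hits, cross-level
(protein vs transcript) concordance with a Storey pi1 replication estimate,
and Fisher enrichment of hit sets against arbitrary category maps.

Sex is coded male = 0, female = 1 throughout, so a positive sex
coefficient means higher expression in females.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SurrogateVariables
from .stats import bh_fdr, fisher_exact_or, ols_fit, storey_pi1

__all__ = [
    "SexDiffRecord",
    "ConcordanceSummary",
    "sexdiff_scan",
    "chromosome_composition",
    "cross_level_concordance",
    "enrichment_fisher",
]


@dataclass
class SexDiffRecord:
    gene_id: str
    beta_sex: float  # female-minus-male difference, SD units on zscored input
    se: float
    p: float
    q: float
    direction: str  # higher_in_females | higher_in_males
    chromosome: str | None = None


@dataclass
class ConcordanceSummary:
    n_overlap_genes: int
    n_both_significant: int
    percent_concordant_direction: float
    pi1_protein_to_mrna: float
    mean_mrna_protein_correlation: float | None = None


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def sexdiff_scan(
    e: ExpressionMatrix,
    s: pd.DataFrame,
    svs: SurrogateVariables | None = None,
    fdr: float = 0.05,
) -> list[SexDiffRecord]:
    """Per-gene regression of expression on sex with SV covariates.

    Missing expression values are excluded pairwise per gene. BH q-values
    are computed across all scanned genes; ``fdr`` is recorded implicitly
    by callers filtering on ``q``.
    """
    if e.stage not in ("zscored", "residualized"):
        raise ValueError("sexdiff_scan expects zscored or residualized expression")
    sex = s["sex"].to_numpy(dtype=float)
    if np.isnan(sex).any():
        raise ValueError("sex must be non-missing for all analysis samples")
    if len(np.unique(sex)) < 2:
        raise ValueError("both sexes must be present")
    sv = svs.matrix if svs is not None and svs.k > 0 else np.empty((e.n_samples, 0))
    X = np.column_stack([np.ones(e.n_samples), sex, sv])

    betas = np.full(e.n_genes, np.nan)
    ses = np.full(e.n_genes, np.nan)
    ps = np.full(e.n_genes, np.nan)
    for i in range(e.n_genes):
        y = e.values[i]
        ok = ~np.isnan(y)
        if ok.sum() <= X.shape[1]:
            continue
        fit = ols_fit(X[ok], y[ok])
        betas[i], ses[i], ps[i] = fit.coefficients[1], fit.standard_errors[1], fit.p_values[1]
    qs = bh_fdr(ps)
    return [
        SexDiffRecord(
            g,
            float(betas[i]),
            float(ses[i]),
            float(ps[i]),
            float(qs[i]),
            "higher_in_females" if betas[i] > 0 else "higher_in_males",
        )
        for i, g in enumerate(e.gene_ids)
        if np.isfinite(ps[i])
    ]


def chromosome_composition(
    records: list[SexDiffRecord], gene_chromosomes: dict[str, str], fdr: float = 0.05
) -> pd.DataFrame:
    """Per-chromosome counts and proportions of significant genes."""
    rows = []
    unmapped = 0
    by_chrom: dict[str, list[SexDiffRecord]] = {}
    for r in records:
        chrom = gene_chromosomes.get(r.gene_id)
        if chrom is None:
            unmapped += 1
            continue
        r.chromosome = str(chrom)
        by_chrom.setdefault(str(chrom), []).append(r)
    if unmapped:
        import warnings

        warnings.warn(f"{unmapped} genes had no chromosome mapping and were excluded",
                      UserWarning, stacklevel=2)
    total_sig = sum(1 for rs in by_chrom.values() for r in rs if r.q < fdr)
    for chrom in sorted(by_chrom, key=_chrom_key):
        rs = by_chrom[chrom]
        n_sig = sum(1 for r in rs if r.q < fdr)
        rows.append(
            {
                "chromosome": chrom,
                "n_tested": len(rs),
                "n_significant": n_sig,
                "proportion": n_sig / len(rs),
                "share_of_hits": n_sig / total_sig if total_sig else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _chrom_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def cross_level_concordance(
    protein_records: list[SexDiffRecord],
    mrna_records: list[SexDiffRecord],
    fdr: float = 0.05,
    paired_protein: ExpressionMatrix | None = None,
    paired_mrna: ExpressionMatrix | None = None,
) -> ConcordanceSummary:
    """Compare sex-differential hits between protein and transcript levels.

    Direction concordance is computed among genes significant at both
    levels; pi1 is Storey's estimate on the mRNA p-values of the protein
    hits (how much protein-level signal replicates in mRNA). When paired
    matrices are supplied, the mean per-gene Pearson correlation over the
    overlap is also reported.
    """
    prot = {r.gene_id: r for r in protein_records}
    mrna = {r.gene_id: r for r in mrna_records}
    shared = sorted(set(prot) & set(mrna))
    if not shared:
        raise ValueError("no shared genes between the two record sets")
    both_sig = [g for g in shared if prot[g].q < fdr and mrna[g].q < fdr]
    if both_sig:
        conc = np.mean(
            [np.sign(prot[g].beta_sex) == np.sign(mrna[g].beta_sex) for g in both_sig]
        )
    else:
        conc = np.nan
    prot_hits = [g for g in shared if prot[g].q < fdr]
    pi1 = storey_pi1([mrna[g].p for g in prot_hits]) if prot_hits else np.nan

    mean_corr = None
    if paired_protein is not None and paired_mrna is not None:
        pp = paired_protein.to_frame()
        pm = paired_mrna.to_frame()
        genes = [g for g in shared if g in pp.index and g in pm.index]
        samples = [c for c in pp.columns if c in set(pm.columns)]
        corrs = []
        for g in genes:
            a = pp.loc[g, samples].to_numpy(dtype=float)
            b = pm.loc[g, samples].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() > 3 and a[ok].std() > 0 and b[ok].std() > 0:
                corrs.append(np.corrcoef(a[ok], b[ok])[0, 1])
        mean_corr = float(np.mean(corrs)) if corrs else None

    return ConcordanceSummary(
        n_overlap_genes=len(shared),
        n_both_significant=len(both_sig),
        percent_concordant_direction=float(conc * 100) if np.isfinite(conc) else np.nan,
        pi1_protein_to_mrna=float(pi1),
        mean_mrna_protein_correlation=mean_corr,
    )


def enrichment_fisher(
    hit_ids, background_ids, categories: dict[str, str]
) -> pd.DataFrame:
    """Per-category Fisher enrichment of a hit set within a background.

    ``categories`` maps id -> category label; background ids without a
    label form their own "uncategorized" class. Returns a frame with OR,
    95% CI, p, and BH q per category. Degenerate cells yield an infinite
    OR with an upper-unbounded CI.
    """
    hits = set(hit_ids)
    background = set(background_ids)
    if not hits <= background:
        raise ValueError("hit ids must be a subset of the background")
    label = {i: categories.get(i, "uncategorized") for i in background}
    cats = sorted(set(label.values()))
    rows = []
    for cat in cats:
        in_cat = {i for i in background if label[i] == cat}
        a = len(hits & in_cat)
        b = len(hits - in_cat)
        c = len(in_cat - hits)
        d = len(background - hits - in_cat)
        odds, p, ci = fisher_exact_or([[a, b], [c, d]])
        rows.append({"category": cat, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "ci_low": ci[0], "ci_high": ci[1], "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df
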