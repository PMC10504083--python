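"""Expression-matrix QC and normalization.

Mirrors a standard proteomic/transcriptomic preprocessing cascade:
missingness filtering, total-abundance (protein) or log2-CPM (transcript)
normalization, iterative-PCA sample-outlier removal, covariate regression,
surrogate-variable estimation that protects the sex effect, and per-gene
Z-scoring. Stages are tagged and only move forward:
raw -> normalized -> residualized -> zscored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ols_fit

__all__ = [
    "ExpressionMatrix",
    "SurrogateVariables",
    "read_expression_tsv",
    "filter_missing",
    "normalize_protein",
    "remove_outlier_samples",
    "regress_out",
    "estimate_svs",
    "zscore",
    "prepare_transcripts",
    "select_isoform",
]

_STAGES = ["raw", "normalized", "residualized", "zscored"]


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with a processing-stage tag."""

    values: np.ndarray  # genes x samples, NaN = missing
    gene_ids: list[str]
    sample_ids: list[str]
    level: str = "protein"  # protein | transcript
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with gene/sample ids")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def advance(self, values: np.ndarray, stage: str, gene_ids=None, sample_ids=None) -> "ExpressionMatrix":
        if _STAGES.index(stage) < _STAGES.index(self.stage):
            raise ValueError(f"stage may only move forward ({self.stage} -> {stage})")
        return ExpressionMatrix(
            values,
            list(gene_ids if gene_ids is not None else self.gene_ids),
            list(sample_ids if sample_ids is not None else self.sample_ids),
            self.level,
            stage,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", na_rep="NA")


def read_expression_tsv(path, level: str = "protein", stage: str = "raw") -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene id, 'NA' for missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns], level, stage
    )


@dataclass
class SurrogateVariables:
    """Inferred hidden factors, sample space, orthogonal to protected sex."""

    matrix: np.ndarray  # samples x k
    k: int
    method: str = "residual-svd-permutation"
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def filter_missing(e: ExpressionMatrix, max_missing: float = 0.5) -> ExpressionMatrix:
    """Drop genes missing in strictly more than ``max_missing`` of samples."""
    if e.stage != "raw":
        raise ValueError("filter_missing expects a raw-stage matrix")
    frac = np.isnan(e.values).mean(axis=1)
    keep = frac <= max_missing
    if not keep.any():
        raise ValueError("all genes removed by missingness filter")
    return ExpressionMatrix(
        e.values[keep], [g for g, k in zip(e.gene_ids, keep) if k], e.sample_ids, e.level, "raw"
    )


def normalize_protein(e: ExpressionMatrix) -> ExpressionMatrix:
    """Total-abundance normalization then log2.

    Each sample's abundances are divided by that sample's total over its
    non-missing proteins (controls loading differences), then log2. Missing
    values stay missing.
    """
    if e.stage != "raw":
        raise ValueError("normalize_protein expects a raw-stage matrix")
    v = e.values
    if np.nanmin(v) <= 0:
        raise ValueError("protein abundances must be positive before normalization")
    totals = np.nansum(v, axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total abundance")
    return e.advance(np.log2(v / totals), "normalized")


def remove_outlier_samples(
    e: ExpressionMatrix, sd_cut: float = 4.0, max_iter: int = 20
) -> tuple[ExpressionMatrix, list[str]]:
    """Iterative PCA outlier removal on PC1/PC2 until a fixed point.

    Each round computes the first two sample-space principal components of
    the (gene-centered, mean-imputed) matrix and drops samples beyond
    ``sd_cut`` standard deviations from the mean on either; iterates until
    no sample is removed.
    """
    if e.stage not in ("normalized", "residualized"):
        raise ValueError("remove_outlier_samples expects a normalized matrix")
    if e.n_samples < 10:
        raise ValueError("need at least 10 samples for outlier detection")
    values = e.values.copy()
    sample_ids = list(e.sample_ids)
    removed: list[str] = []
    for _ in range(max_iter):
        X = values.copy()
        mu = np.nanmean(X, axis=1, keepdims=True)
        idx = np.where(np.isnan(X))
        X[idx] = mu[idx[0], 0]
        X = X - X.mean(axis=1, keepdims=True)
        # sample-space PCs from the thin SVD of genes x samples
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        pcs = (Vt[:2].T) * s[:2]
        z = (pcs - pcs.mean(axis=0)) / pcs.std(axis=0, ddof=1)
        bad = (np.abs(z) > sd_cut).any(axis=1)
        if not bad.any():
            return (
                ExpressionMatrix(values, e.gene_ids, sample_ids, e.level, e.stage),
                removed,
            )
        removed.extend([sid for sid, b in zip(sample_ids, bad) if b])
        values = values[:, ~bad]
        sample_ids = [sid for sid, b in zip(sample_ids, bad) if not b]
    raise RuntimeError(f"outlier removal did not converge in {max_iter} iterations")


def _design_from_covariates(s: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Intercept + covariates; categoricals one-hot encoded dropping one level."""
    cols = [np.ones(len(s))]
    for c in covariates:
        if c not in s.columns:
            raise KeyError(f"covariate {c!r} not in sample table")
        col = s[c]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy())
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def regress_out(e: ExpressionMatrix, s: pd.DataFrame, covariates: list[str]) -> ExpressionMatrix:
    """Remove covariate effects per gene by OLS; keeps the gene mean.

    ``sex`` is a protected variable and may never be regressed out here.
    Missing expression values are excluded pairwise per gene.
    """
    if any(c.lower() == "sex" for c in covariates):
        raise ValueError("sex is the protected variable and cannot be a covariate")
    X = _design_from_covariates(s, covariates)
    if X.shape[0] != e.n_samples:
        raise ValueError("sample table does not match expression samples")
    out = e.values.copy()
    for i in range(e.n_genes):
        y = e.values[i]
        ok = ~np.isnan(y)
        if ok.sum() <= X.shape[1]:
            continue
        Xo = X[ok]
        # drop constant dummy columns within the observed subset
        keep = [0] + [j for j in range(1, Xo.shape[1]) if np.ptp(Xo[:, j]) > 0]
        fit = ols_fit(Xo[:, keep], y[ok])
        out[i, ok] = fit.residuals + y[ok].mean()
    return e.advance(out, "residualized")


def estimate_svs(
    e: ExpressionMatrix,
    s: pd.DataFrame,
    n_perm: int = 20,
    quantile: float = 0.95,
    seed: int = 0,
    n_sv: int | None = None,
) -> SurrogateVariables:
    """Estimate hidden factors from the sex-residualized expression matrix.

    Expression (genes x samples) is residualized on sex so the returned
    components are orthogonal to the protected variable, then the
    sample-space right singular vectors are kept when their singular value
    exceeds the chosen quantile of singular values from ``n_perm`` row-wise
    permutations (parallel analysis). ``n_sv`` forces a fixed component
    count instead.
    """
    if e.stage not in ("residualized", "normalized"):
        raise ValueError("estimate_svs expects a residualized matrix")
    sex = s["sex"].to_numpy(dtype=float)
    if min((sex == 0).sum(), (sex == 1).sum()) < 3:
        raise ValueError("need at least 3 samples of each sex")
    V = e.values.copy()
    mu = np.nanmean(V, axis=1, keepdims=True)
    idx = np.where(np.isnan(V))
    V[idx] = mu[idx[0], 0]

    # residualize every gene on [1, sex]: projection in sample space
    X = np.column_stack([np.ones(e.n_samples), sex])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    R = V - V @ H.T  # rows orthogonal to 1 and sex

    _, sv, Vt = np.linalg.svd(R, full_matrices=False)
    if n_sv is not None:
        k = int(n_sv)
    else:
        rng = np.random.default_rng(seed)
        max_sv = np.empty(n_perm)
        for b in range(n_perm):
            P = np.array([rng.permutation(row) for row in R])
            max_sv[b] = np.linalg.svd(P, compute_uv=False)[0]
        thresh = np.quantile(max_sv, quantile)
        k = int((sv > thresh).sum())
    k = min(k, Vt.shape[0])
    return SurrogateVariables(Vt[:k].T.copy(), k, singular_values=sv[:k].copy())


def zscore(e: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardization to mean 0, SD 1; constant genes are dropped."""
    if e.stage != "residualized":
        raise ValueError("zscore expects a residualized matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(e.values, axis=1, keepdims=True)
        sd = np.nanstd(e.values, axis=1, keepdims=True)
    keep = sd.ravel() > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance genes", UserWarning, stacklevel=2
        )
    vals = (e.values[keep] - mu[keep]) / sd[keep]
    return e.advance(vals, "zscored", gene_ids=[g for g, k in zip(e.gene_ids, keep) if k])


def prepare_transcripts(
    counts: pd.DataFrame,
    s: pd.DataFrame,
    cpm_min: float = 1.0,
    frac: float = 0.5,
    diagnosis_col: str = "diagnosis",
) -> ExpressionMatrix:
    """Transcript count filtering and log2-CPM normalization.

    A transcript is kept if, within at least one clinical-diagnosis group,
    its CPM reaches ``cpm_min`` in at least ``frac`` of that group's
    samples. Kept counts become log2(CPM + 0.5). (A variance-stabilizing
    transform is a common alternative; log2-CPM keeps this step closed-form
    and leaves the sex effect untouched.)
    """
    v = counts.to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = v.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    cpm = v / lib * 1e6
    diag = s[diagnosis_col].to_numpy()
    keep = np.zeros(v.shape[0], dtype=bool)
    for grp in pd.unique(diag):
        cols = diag == grp
        frac_ok = (cpm[:, cols] >= cpm_min).mean(axis=1)
        keep |= frac_ok >= frac
    if not keep.any():
        raise ValueError("no transcripts pass the CPM filter")
    logcpm = np.log2(cpm[keep] + 0.5)
    return ExpressionMatrix(
        logcpm,
        [str(g) for g, k in zip(counts.index, keep) if k],
        [str(c) for c in counts.columns],
        level="transcript",
        stage="normalized",
    )


def select_isoform(e: ExpressionMatrix, isoform_to_gene: dict[str, str]) -> ExpressionMatrix:
    """Keep the most abundant isoform per gene (ties: lexicographic id)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(e.values, axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    for i, iso in enumerate(e.gene_ids):
        gene = isoform_to_gene.get(iso, iso)
        m = means[i] if np.isfinite(means[i]) else -np.inf
        cur = best.get(gene)
        # higher mean wins; at equal means the lexicographically smaller id
        if cur is None or (m, _neg_str(iso)) > (cur[0], _neg_str(cur[1])):
            best[gene] = (m, iso, i)
    rows = sorted(best.values(), key=lambda t: t[2])
    idx = [i for _, _, i in rows]
    return ExpressionMatrix(
        e.values[idx], [e.gene_ids[i] for i in idx], e.sample_ids, e.level, e.stage
    )


class _neg_str(str):
    """String with reversed ordering, so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
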