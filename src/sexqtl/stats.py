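"""Core statistical primitives shared by every pipeline stage.

Ordinary least squares with t-based inference, Benjamini–Hochberg FDR,
Storey's pi0/pi1 estimator, Fisher's exact test with odds-ratio CI, the
Hardy–Weinberg exact test, and the median-based genomic inflation factor.
Each primitive is small, deterministic, and checkable against a brute-force
oracle; the rest of the package treats these as trusted building blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from scipy import stats as sps

__all__ = [
    "OLSFit",
    "CollinearityError",
    "ols_fit",
    "bh_fdr",
    "storey_pi1",
    "fisher_exact_or",
    "hwe_exact",
    "qq_lambda",
]

# median of the chi-square(1) distribution
_CHI2_1_MEDIAN = 0.4549364231195728


class CollinearityError(ValueError):
    """Raised when a regression design matrix is rank deficient."""


@dataclass(frozen=True)
class OLSFit:
    """Result of an ordinary least-squares fit.

    Attributes
    ----------
    coefficients, standard_errors, t_statistics, p_values
        One entry per design column; p-values are two-sided from the
        t distribution with ``dof`` degrees of freedom.
    residuals
        Response minus fitted values.
    dof
        Residual degrees of freedom, ``n - rank(design)``.
    n
        Number of observations.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    dof: int
    n: int


def ols_fit(design: np.ndarray, response: np.ndarray) -> OLSFit:
    """Fit OLS via QR decomposition with full t-based inference.

    Parameters
    ----------
    design : (n, p) array
        Model matrix including an intercept column. Must be full rank and
        have more rows than columns.
    response : (n,) array
        Outcome vector; no missing values.

    Raises
    ------
    CollinearityError
        If the design is rank deficient; the message names the offending
        columns (by zero-based index).
    ValueError
        If n <= p or inputs contain non-finite values.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("design must be 2-dimensional")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"design has {n} rows but response has {y.shape[0]}")
    if n <= p:
        raise ValueError(f"need more observations than parameters (n={n}, p={p})")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("design/response contain missing or non-finite values")

    # pivoted QR both detects rank deficiency and names the culprits
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * 1e-10 if diag[0] > 0 else 1e-10
    rank = int(np.sum(diag > tol))
    if rank < p:
        dropped = sorted(int(piv[j]) for j in range(rank, p))
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {p} columns); "
            f"collinear columns: {dropped}"
        )

    qty = Q.T @ y
    beta_piv = np.linalg.solve(R, qty)
    beta = np.empty(p)
    beta[piv] = beta_piv

    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    # (X'X)^-1 = P R^-1 R^-T P'
    Rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv_piv = Rinv @ Rinv.T
    var_piv = sigma2 * np.diag(xtx_inv_piv)
    var = np.empty(p)
    var[piv] = var_piv
    se = np.sqrt(np.maximum(var, 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    return OLSFit(beta, se, tstat, np.clip(pvals, 0.0, 1.0), resid, dof, n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaN entries propagate as NaN and are excluded from the test count m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    finite = ~np.isnan(p)
    pf = p[finite]
    if pf.size and ((pf < 0).any() or (pf > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = pf.size
    if m:
        order = np.argsort(pf, kind="mergesort")
        ranked = pf[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(adj, 1.0)
        out[finite] = q
    return out


def storey_pi1(p_values, lambda_grid=None, method: str = "smoother") -> float:
    """Storey's pi1 = 1 - pi0, the estimated fraction of true alternatives.

    pi0 is estimated on a lambda grid (default 0.05..0.95 step 0.05) as
    #{p > lambda} / (m (1 - lambda)), smoothed with a natural cubic
    smoothing spline (GCV-penalized, so the noisy tail estimates are
    pooled across the grid rather than interpolated) and read off at the
    largest lambda, then clipped to [0, 1]. With fewer than 50 p-values a
    conservative fixed-lambda (0.5) estimate is used and a warning emitted.

    Parameters
    ----------
    method : {"smoother", "fixed"}
        "fixed" skips the spline and uses pi0(lambda=0.5) directly.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)

    def _pi0_at(l0: float) -> float:
        return float(np.sum(p > l0)) / (m * (1.0 - l0))

    if m < 50:
        warnings.warn(
            f"only {m} p-values; using conservative fixed-lambda pi0 estimate",
            UserWarning,
            stacklevel=2,
        )
        pi0 = _pi0_at(0.5)
    elif method == "fixed":
        pi0 = _pi0_at(0.5)
    else:
        pi0_lam = np.array([_pi0_at(l0) for l0 in lam])
        try:
            # fixed penalty ~ 3 effective df on the default 19-point grid,
            # the conventional stiffness for this smoother; GCV would chase
            # the high-variance tail estimates
            spline = interpolate.make_smoothing_spline(lam, pi0_lam, lam=0.01)
            pi0 = float(spline(lam[-1]))
        except Exception:  # degenerate grid
            pi0 = _pi0_at(0.5)
    pi0 = min(max(pi0, 0.0), 1.0)
    return 1.0 - pi0


def fisher_exact_or(table) -> tuple[float, float, tuple[float, float]]:
    """Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p_two_sided, (ci_low, ci_high)). The odds ratio is
    the sample OR ad/(bc) (inf when bc = 0 with ad > 0). The two-sided p
    sums hypergeometric outcomes with probability <= the observed one. The
    95% CI uses the log-OR normal approximation with the Haldane +0.5
    correction; for degenerate cells the unbounded side is +/- inf.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = t.ravel()
    if a + b + c + d == 0:
        raise ValueError("all-zero table")

    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)

    _, p = sps.fisher_exact(np.round(t).astype(int), alternative="two-sided")

    # Haldane-corrected Wald interval on log OR
    ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(ah * dh / (bh * ch))
    se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    z = sps.norm.ppf(0.975)
    ci = (float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se)))
    if np.isinf(odds):
        ci = (ci[0], np.inf)
    return float(odds), float(p), ci


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    margin and sums the probabilities of outcomes no more likely than the
    observed one. Monomorphic sites return p = 1 by convention.
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0:
            raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # log P(het = h | margin) up to a constant, via log-gamma
    from scipy.special import gammaln

    rare_hom = (n_rare - hets) // 2
    comm_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(comm_hom + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het]
    if obs.size == 0:  # inconsistent margin (cannot happen for valid input)
        raise ValueError("observed het count incompatible with allele margin")
    return float(min(1.0, prob[prob <= obs[0] * (1 + 1e-12)].sum()))


def qq_lambda(p_values) -> tuple[float, np.ndarray, np.ndarray]:
    """Median-based genomic inflation factor and QQ-plot coordinates.

    Returns (lambda, expected, observed) where expected/observed are
    -log10 p for a QQ plot, both sorted ascending. p = 0 is clamped to the
    smallest positive float with a warning.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 clamped to smallest positive float", UserWarning, stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    chi2 = sps.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / _CHI2_1_MEDIAN)
    obs = -np.log10(np.sort(p))[::-1]
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)[::-1]
    return lam, np.sort(exp), np.sort(obs)
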