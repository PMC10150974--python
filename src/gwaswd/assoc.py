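"""Single-locus logistic association screen.

Each SNP is tested with an additive-coded (0/1/2) logistic regression
of case status on dosage, fitted by iteratively reweighted least
squares.  P-values are two-sided Wald by default, with a
likelihood-ratio fallback when the fit separates.  The module also
provides genomic-inflation (lambda), top-k selection and plot-ready
Manhattan / QQ tables.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .plink import CASE, CONTROL, MISSING, GenotypeMatrix

__all__ = [
    "GENOME_WIDE_SIGNIFICANCE", "fit_snp_logistic", "run_association",
    "select_top_k", "genomic_lambda", "manhattan_table", "qq_table",
]

GENOME_WIDE_SIGNIFICANCE = 5e-8

#: median of the 1-df chi-square distribution
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_MAX_ITER = 50
_TOL = 1e-8
_SEPARATION_BETA = 15.0


class DegeneratePredictorError(ValueError):
    """Genotype constant among the non-missing samples."""


@dataclasses.dataclass
class LogisticFit:
    beta: float
    se: float
    p: float
    n_used: int
    converged: bool
    separated: bool


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically safe Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_snp_logistic(dosages: np.ndarray, phenotype: np.ndarray) -> LogisticFit:
    """Fit ``logit P(case) = b0 + b*g`` by IRLS for one SNP.

    ``phenotype`` may be coded 0/1 or PLINK 1/2 (control/case); missing
    genotypes are dropped listwise.  Convergence is declared at a
    log-likelihood change below 1e-8; if the slope runs past 15 in
    absolute value at the iteration cap the fit is flagged as separated
    and the p-value falls back to the likelihood-ratio test.
    """
    g = np.asarray(dosages, dtype=float)
    ph = np.asarray(phenotype)
    keep = g != MISSING
    g, ph = g[keep], ph[keep]
    y = (ph == CASE).astype(float) if ph.max() > 1 else ph.astype(float)
    n = len(y)
    if n == 0 or y.min() == y.max():
        raise ValueError("both phenotype classes must be present")
    if g.min() == g.max():
        raise DegeneratePredictorError("degenerate predictor: constant genotype")

    X = np.column_stack([np.ones(n), g])
    b = np.zeros(2)
    ll_old = _loglik(X @ b, y)
    converged = False
    for _ in range(_MAX_ITER):
        eta = X @ b
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        XtW = X.T * w
        H = XtW @ X
        score = X.T @ (y - mu)
        try:
            b = b + np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        ll = _loglik(X @ b, y)
        if abs(ll - ll_old) < _TOL:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    mu = expit(X @ b)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (X.T * w) @ X
    cov = np.linalg.inv(H)
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    beta = float(b[1])
    # a slope running far out signals (quasi-)separation even when the
    # log-likelihood has plateaued; Wald inference is meaningless there
    separated = abs(beta) > _SEPARATION_BETA
    if separated or se == 0.0 or not np.isfinite(se):
        # likelihood-ratio fallback against the intercept-only model
        p0 = y.mean()
        ll_null = float(n * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
        lr = max(0.0, 2.0 * (ll_old - ll_null))
        p = float(stats.chi2.sf(lr, 1))
    else:
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return LogisticFit(beta, se, max(p, 5e-324), n, converged, separated)


def run_association(G: GenotypeMatrix) -> pd.DataFrame:
    """Additive logistic scan over every variant, in map order.

    Returns a table with columns SNP, CHR, BP, BETA, SE, Z, P, N and a
    STATUS flag ("ok", "degenerate", "separated"); degenerate SNPs get
    NaN estimates and P = 1 so the scan never aborts.
    """
    ph = G.phenotype
    informative = np.isin(ph, (CONTROL, CASE))
    if not (ph[informative] == CASE).any() or not (ph[informative] == CONTROL).any():
        raise ValueError("both cases and controls required")
    rows = []
    for j in range(G.n_variants):
        v = G.variants.iloc[j]
        g = G.dosages[informative, j]
        try:
            fit = fit_snp_logistic(g, ph[informative])
            status = "separated" if fit.separated else "ok"
            z = fit.beta / fit.se if fit.se > 0 else np.nan
            rows.append((v["snp"], v["chrom"], v["pos"], fit.beta, fit.se, z,
                         fit.p, fit.n_used, status))
        except DegeneratePredictorError:
            n_used = int((g != MISSING).sum())
            rows.append((v["snp"], v["chrom"], v["pos"], np.nan, np.nan, np.nan,
                         1.0, n_used, "degenerate"))
    return pd.DataFrame(
        rows, columns=["SNP", "CHR", "BP", "BETA", "SE", "Z", "P", "N", "STATUS"]
    )


def select_top_k(table: pd.DataFrame, k: int = 1000) -> list[str]:
    """The k smallest-p SNP ids, ties broken by (chromosome, position)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        warnings.warn(f"k={k} exceeds table size {len(table)}; returning all")
        k = len(table)
    ordered = table.sort_values(["P", "CHR", "BP"], kind="mergesort")
    return ordered["SNP"].head(k).tolist()


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median observed chi-square over 0.4549.

    P-values are converted to 1-df chi-square quantiles; under a clean
    null scan the ratio is close to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) < 100:
        raise ValueError("at least 100 p-values required")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("invalid p-value")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def manhattan_table(table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready Manhattan rows: cumulative genome coordinate, -log10 p.

    The 5e-8 genome-wide line is exposed as the constant column
    ``genomewide_line``.
    """
    if table.empty:
        raise ValueError("empty association table")
    df = table.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    offset, cum = 0, []
    for _, sub in df.groupby("CHR", sort=True):
        cum.append(sub["BP"] + offset)
        offset += int(sub["BP"].max())
    df["GENOME_BP"] = pd.concat(cum).to_numpy()
    df["NEG_LOG10_P"] = -np.log10(df["P"])
    df["genomewide_line"] = -np.log10(GENOME_WIDE_SIGNIFICANCE)
    return df[["SNP", "CHR", "BP", "GENOME_BP", "P", "NEG_LOG10_P", "genomewide_line"]]


def qq_table(p_values: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p pairs, expected quantiles (i-0.5)/m."""
    p = np.sort(np.asarray(p_values, dtype=float))
    if len(p) == 0:
        raise ValueError("no p-values")
    m = len(p)
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(p)}
    )
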