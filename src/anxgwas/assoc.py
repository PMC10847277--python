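"""Per-variant genome-wide association scans.

Two models per variant, both adjusted for age, sex and the top structure
PCs:

* binary — maximum-likelihood logistic regression of the anxiety label on
  the alt-allele dosage, fitted by iteratively reweighted least squares
  (IRLS, tolerance 1e-8, at most 100 iterations), with a two-sided Wald
  test on the dosage coefficient;
* continuous — ordinary least squares of the raw 0-21 anxiety score on the
  dosage, with a two-sided t-test.

Samples with a missing dosage are dropped per variant (complete-case).  A
variant whose fit does not converge, separates, or is rank deficient is
flagged unfit (``fit_ok = False``, no p-value) instead of contributing an
unstable estimate; unfit rows are never selected downstream.

Genome-wide significance uses the conventional strict threshold
p < 5e-8.  The genomic inflation factor ``lambda_gc`` is the median of the
1-df chi-square statistics implied by the p-values divided by the
theoretical null median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm, t as t_dist
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix
from .io import SUMMARY_COLUMNS

GENOME_WIDE_ALPHA = 5e-8
_CHI2_NULL_MEDIAN = chi2.ppf(0.5, df=1)  # ~0.4549

# index layout of the per-variant design matrix
_I_INTERCEPT, _I_DOSAGE, _I_AGE, _I_SEX = 0, 1, 2, 3


@dataclass
class GwasDesign:
    model: str = "binary"  # or "continuous"
    n_pcs: int = 10
    alpha_gw: float = GENOME_WIDE_ALPHA

    def __post_init__(self):
        if self.model not in ("binary", "continuous"):
            raise ValueError("model must be 'binary' or 'continuous'")


def _unfit_row(n):
    return {
        "model": None,
        "beta_g": np.nan,
        "se": np.nan,
        "p": np.nan,
        "n": n,
        "beta_age": np.nan,
        "beta_sex": np.nan,
        "intercept": np.nan,
        "fit_ok": False,
    }


def _irls_logistic(X, y, tol=1e-8, max_iter=100):
    """IRLS for logistic regression; returns (beta, se) or None on failure."""
    n, p = X.shape
    beta = np.zeros(p)
    XtWX = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        try:
            new_beta = np.linalg.solve(XtWX, Xw.T @ z)
        except np.linalg.LinAlgError:
            return None
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
            return None  # separation / divergence
        if step < tol:
            try:
                cov = np.linalg.inv(XtWX)
            except np.linalg.LinAlgError:
                return None
            se = np.sqrt(np.diag(cov))
            if not np.all(np.isfinite(se)) or np.any(se <= 0):
                return None
            return beta, se
    return None  # no convergence


def fit_variant_binary(dosage, y, covars) -> dict:
    """Logistic association of a binary label with one variant's dosage.

    ``covars`` is an (n x c) array whose first two columns are age and sex,
    followed by structure PCs.  Returns a summary-statistics row dict.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    covars = np.atleast_2d(np.asarray(covars, dtype=float))
    mask = ~np.isnan(dosage)
    d, yy, cc = dosage[mask], y[mask], covars[mask]
    n = d.size
    if n == 0 or yy.sum() == 0 or yy.sum() == n:
        return _unfit_row(n) | {"model": "binary"}
    if np.ptp(d) == 0:
        return _unfit_row(n) | {"model": "binary"}
    X = np.column_stack([np.ones(n), d, cc])
    res = _irls_logistic(X, yy)
    if res is None:
        return _unfit_row(n) | {"model": "binary"}
    beta, se = res
    zstat = beta[_I_DOSAGE] / se[_I_DOSAGE]
    return {
        "model": "binary",
        "beta_g": beta[_I_DOSAGE],
        "se": se[_I_DOSAGE],
        "p": max(2.0 * norm.sf(abs(zstat)), 1e-300),
        "n": n,
        "beta_age": beta[_I_AGE],
        "beta_sex": beta[_I_SEX],
        "intercept": beta[_I_INTERCEPT],
        "fit_ok": True,
    }


def fit_variant_linear(dosage, score, covars) -> dict:
    """OLS association of the continuous score with one variant's dosage."""
    dosage = np.asarray(dosage, dtype=float)
    score = np.asarray(score, dtype=float)
    covars = np.atleast_2d(np.asarray(covars, dtype=float))
    mask = ~np.isnan(dosage)
    d, yy, cc = dosage[mask], score[mask], covars[mask]
    n = d.size
    X = np.column_stack([np.ones(n), d, cc]) if n else np.empty((0, 2))
    p_params = X.shape[1]
    df = n - p_params
    if df < 3 or np.ptp(d) == 0:
        return _unfit_row(n) | {"model": "continuous"}
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < p_params:
        return _unfit_row(n) | {"model": "continuous"}
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ yy)
    resid = yy - X @ beta
    sigma2 = resid @ resid / df
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0))
    if se[_I_DOSAGE] == 0:
        pval = 1e-300  # exact fit: effectively zero
    else:
        tstat = beta[_I_DOSAGE] / se[_I_DOSAGE]
        pval = max(2.0 * t_dist.sf(abs(tstat), df), 1e-300)
    return {
        "model": "continuous",
        "beta_g": beta[_I_DOSAGE],
        "se": se[_I_DOSAGE],
        "p": pval,
        "n": n,
        "beta_age": beta[_I_AGE],
        "beta_sex": beta[_I_SEX],
        "intercept": beta[_I_INTERCEPT],
        "fit_ok": True,
    }


def build_covariates(table: pd.DataFrame, pcs=None, n_pcs: int = 10) -> np.ndarray:
    """Assemble the (age, sex, PC1..PCk) covariate matrix."""
    cols = [table["age"].to_numpy(float), table["sex"].to_numpy(float)]
    if pcs is not None:
        scores = pcs.scores if hasattr(pcs, "scores") else np.asarray(pcs, float)
        cols.extend(scores[:, : n_pcs].T)
    return np.column_stack(cols)


class GwasScan(BaseEstimator):
    """Per-variant association scan over a genotype matrix.

    After ``fit``, ``results_`` holds one summary-statistics row per
    variant (in variant order) and ``significant_`` the rows passing the
    genome-wide threshold.
    """

    def __init__(
        self,
        model: str = "binary",
        n_pcs: int = 10,
        alpha_gw: float = GENOME_WIDE_ALPHA,
        n_jobs: int = 1,
    ):
        self.model = model
        self.n_pcs = n_pcs
        self.alpha_gw = alpha_gw
        self.n_jobs = n_jobs

    def fit(self, G: GenotypeMatrix, table: pd.DataFrame, pcs=None):
        GwasDesign(self.model, self.n_pcs, self.alpha_gw)  # validates
        if len(table) != G.n_samples:
            raise ValueError("phenotype table and genotype matrix disagree on samples")
        covars = build_covariates(table, pcs, self.n_pcs)
        if self.model == "binary":
            y = table["anxiety"].to_numpy(float)
            fit_one = fit_variant_binary
        else:
            y = table["hads_a"].to_numpy(float)
            fit_one = fit_variant_linear
        if self.n_jobs != 1:
            from joblib import Parallel, delayed

            # per-variant fits are independent, so any worker split returns
            # the same rows in the same order
            rows = Parallel(n_jobs=self.n_jobs)(
                delayed(fit_one)(G.dosages[:, j], y, covars) for j in range(G.n_variants)
            )
        else:
            rows = [fit_one(G.dosages[:, j], y, covars) for j in range(G.n_variants)]
        meta = G.variants
        for j, row in enumerate(rows):
            row.update(
                id=meta["id"].iloc[j],
                chrom=meta["chrom"].iloc[j],
                pos=meta["pos"].iloc[j],
                ref=meta["ref"].iloc[j],
                alt=meta["alt"].iloc[j],
            )
        self.results_ = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
        self.significant_ = call_significant(self.results_, self.alpha_gw)
        return self


def scan(G: GenotypeMatrix, table: pd.DataFrame, pcs=None, design: GwasDesign | None = None) -> pd.DataFrame:
    """Functional wrapper around :class:`GwasScan`."""
    design = design or GwasDesign()
    return GwasScan(design.model, design.n_pcs, design.alpha_gw).fit(G, table, pcs).results_


def call_significant(rows: pd.DataFrame, alpha_gw: float = GENOME_WIDE_ALPHA) -> pd.DataFrame:
    """Rows passing genome-wide significance (strict ``p < alpha``)."""
    if not len(rows):
        return rows
    ok = rows["fit_ok"].astype(bool) & rows["p"].notna()
    return rows[ok & (rows["p"] < alpha_gw)]


def lambda_gc(rows) -> float:
    """Genomic inflation factor from a scan's p-values."""
    p = rows["p"].to_numpy(float) if isinstance(rows, pd.DataFrame) else np.asarray(rows, float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 fitted tests for lambda_gc")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / _CHI2_NULL_MEDIAN)


def plot_data(rows: pd.DataFrame):
    """Manhattan and QQ coordinate tables (pure data, no rendering).

    Returns (manhattan, qq): the first maps each fitted variant to a
    cumulative genome coordinate and -log10 p; the second pairs expected
    and observed -log10 p quantiles.
    """
    fitted = rows[rows["fit_ok"].astype(bool) & rows["p"].notna()] if len(rows) else rows
    if not len(fitted):
        empty_m = pd.DataFrame(columns=["id", "chrom", "pos", "genome_pos", "neglog10_p"])
        empty_q = pd.DataFrame(columns=["expected", "observed"])
        return empty_m, empty_q

    def chrom_key(c):
        try:
            return (0, int(c))
        except (TypeError, ValueError):
            return (1, str(c))

    chroms = sorted(pd.unique(fitted["chrom"]), key=chrom_key)
    offset, offsets = 0, {}
    for c in chroms:
        offsets[c] = offset
        offset += int(fitted.loc[fitted["chrom"] == c, "pos"].max()) + 1
    manhattan = pd.DataFrame(
        {
            "id": fitted["id"].to_numpy(),
            "chrom": fitted["chrom"].to_numpy(),
            "pos": fitted["pos"].to_numpy(),
            "genome_pos": [offsets[c] + p for c, p in zip(fitted["chrom"], fitted["pos"])],
            "neglog10_p": -np.log10(fitted["p"].to_numpy(float)),
        }
    )
    obs = np.sort(fitted["p"].to_numpy(float))
    m = obs.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(obs)}
    )
    return manhattan, qq
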