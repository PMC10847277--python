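"""Polygenic risk score: per-SNP scoring, threshold sweep, ridge fit.

The procedure mirrors a score-threshold PRS pipeline:

1. hold out 10% of samples as a test set, stratified by the anxiety label;
2. run the per-variant GWAS on the remaining 90% only (no test leakage);
3. give each fitted SNP a selection score built from its association fit,
   ``(beta_snp / p) * beta_age + beta_sex + intercept`` (an alternative
   "magnitude" parse ``(beta_snp / p) * (beta_age + beta_sex + intercept)``
   is available — the two differ only in how the covariate terms enter);
4. sweep a grid of score thresholds (default: 20 evenly spaced quantiles
   of the score distribution); for each, fit a ridge regression of the 0/1
   label on the selected SNP dosages plus age, sex and the structure PCs
   on the training 80%, and evaluate ROC AUC on the validation 20%;
5. keep the model with the highest validation AUC (ties favour fewer
   SNPs), then report its AUC on the held-out test set.

The ridge fit is the closed-form minimiser of squared error plus an L2
penalty on all coefficients except the intercept, computed on internally
standardized features; predictions are used purely as ranking scores for
AUC, so the linear-probability formulation is adequate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split

from .assoc import GwasDesign, scan
from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class PRSConfig:
    test_fraction: float = 0.10
    validation_fraction: float = 0.20
    thresholds: list | None = None
    n_quantiles: int = 20
    ridge_lambda: float = 1.0
    score_parse: str = "literal"  # or "magnitude"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1 or not 0 < self.validation_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")
        if self.score_parse not in ("literal", "magnitude"):
            raise ValueError("score_parse must be 'literal' or 'magnitude'")
        if self.thresholds is not None and not len(self.thresholds):
            raise ValueError("thresholds, when given, must be non-empty")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")


@dataclass
class PRSModel:
    selected_threshold: float
    snp_ids: list
    snp_weights: np.ndarray
    covariate_weights: np.ndarray  # age, sex, PC1..PCk
    intercept: float
    validation_auc: float
    test_auc: float
    n_snps: int
    baseline_aucs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.snp_ids) == len(self.snp_weights) == self.n_snps):
            raise ValueError("inconsistent SNP list / weight vector")

    def predict(self, snp_dosages, covariates):
        """Linear risk score for new samples (higher = riskier)."""
        return (
            np.asarray(snp_dosages, float) @ self.snp_weights
            + np.asarray(covariates, float) @ self.covariate_weights
            + self.intercept
        )


def snp_score(row, parse: str = "literal") -> float:
    """Selection score of one SNP from its association fit.

    The default ("literal") reading combines the dosage effect scaled by
    its p-value with the fitted covariate coefficients additively; the
    "magnitude" reading multiplies the scaled effect into the summed
    covariate terms.  Unfit rows score ``nan`` and are never selected.
    """
    get = row.get if hasattr(row, "get") else row.__getitem__
    if not get("fit_ok"):
        return float("nan")
    p = max(float(get("p")), P_FLOOR)
    ratio = float(get("beta_g")) / p
    covar_part = float(get("beta_age")), float(get("beta_sex")), float(get("intercept"))
    if parse == "literal":
        return ratio * covar_part[0] + covar_part[1] + covar_part[2]
    if parse == "magnitude":
        return ratio * sum(covar_part)
    raise ValueError("parse must be 'literal' or 'magnitude'")


def score_table(rows: pd.DataFrame, parse: str = "literal") -> np.ndarray:
    """Vectorised :func:`snp_score` over a summary-statistics table."""
    ok = rows["fit_ok"].to_numpy(bool)
    p = np.maximum(rows["p"].to_numpy(float), P_FLOOR)
    ratio = rows["beta_g"].to_numpy(float) / p
    if parse == "literal":
        s = ratio * rows["beta_age"].to_numpy(float) + rows["beta_sex"].to_numpy(float) + rows["intercept"].to_numpy(float)
    elif parse == "magnitude":
        s = ratio * (
            rows["beta_age"].to_numpy(float)
            + rows["beta_sex"].to_numpy(float)
            + rows["intercept"].to_numpy(float)
        )
    else:
        raise ValueError("parse must be 'literal' or 'magnitude'")
    return np.where(ok, s, np.nan)


def split_data(table: pd.DataFrame, config: PRSConfig | None = None) -> dict:
    """Stratified test / train / validation index sets.

    The test fraction is carved out first; the remainder is split
    80/20 (by default) into train and validation.  All three sets are
    disjoint, exhaustive, stratified by the anxiety label, and reproducible
    from the seed.
    """
    config = config or PRSConfig()
    n = len(table)
    if n < 30:
        raise ValueError("need at least 30 samples to split")
    y = table["anxiety"].to_numpy(bool)
    idx = np.arange(n)
    rest, test = train_test_split(
        idx, test_size=config.test_fraction, stratify=y, random_state=config.seed
    )
    train, val = train_test_split(
        rest,
        test_size=config.validation_fraction,
        stratify=y[rest],
        random_state=config.seed + 1,
    )
    out = {"test": np.sort(test), "train": np.sort(train), "validation": np.sort(val)}
    for name, part in out.items():
        if part.size < 2 or len(np.unique(y[part])) < 2:
            raise ValueError(f"{name} split is degenerate (too small or single-class)")
    return out


class LinearRidge(BaseEstimator, RegressorMixin):
    """Closed-form ridge: squared error + L2 penalty on all non-intercept terms.

    Features are standardized internally (the intercept is unpenalized and
    absorbed by centering); coefficients are returned on the original
    scale.  When the number of features exceeds the number of samples the
    equivalent dual (kernel) form is solved instead.
    """

    def __init__(self, lam: float = 1.0):
        self.lam = lam

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0)
        scale = np.where(x_sd > 0, x_sd, 1.0)
        Z = (X - x_mean) / scale
        y_mean = y.mean()
        yc = y - y_mean
        if self.lam == 0:
            if p >= n or np.linalg.matrix_rank(Z) < p:
                raise ValueError("singular system at lam=0; use lam > 0")
        if p <= n:
            A = Z.T @ Z + self.lam * np.eye(p)
            w = np.linalg.solve(A, Z.T @ yc)
        else:
            K = Z @ Z.T + self.lam * np.eye(n)
            w = Z.T @ np.linalg.solve(K, yc)
        self.coef_ = w / scale
        self.intercept_ = y_mean - x_mean @ self.coef_
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def fit_ridge(X, y, lam: float):
    """Functional wrapper; returns (weights, intercept)."""
    model = LinearRidge(lam=lam).fit(X, y)
    return model.coef_, model.intercept_


def roc_auc(risk_scores, labels) -> float:
    """Midrank ROC AUC: P(random positive outranks random negative).

    Equals the normalized Mann-Whitney rank-sum statistic; ties count 1/2.
    """
    s = np.asarray(risk_scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(s)  # midranks
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


class ThresholdRidgePRS(BaseEstimator):
    """Score-threshold + ridge PRS learner.

    ``fit(X, y)`` expects ``X = [snp dosages | covariates]`` with
    ``n_covariates`` trailing covariate columns and no missing entries.
    Per-SNP selection scores may be supplied (``snp_scores=``, e.g. from an
    external GWAS on the same samples); otherwise each SNP is refitted
    internally against ``y`` with the covariate columns.  An explicit
    boolean ``validation_mask`` may pin the validation rows; by default an
    internal stratified split of ``validation_fraction`` is used.
    """

    def __init__(
        self,
        n_covariates: int = 0,
        thresholds=None,
        n_quantiles: int = 20,
        lam: float = 1.0,
        validation_fraction: float = 0.20,
        score_parse: str = "literal",
        seed: int = 0,
    ):
        self.n_covariates = n_covariates
        self.thresholds = thresholds
        self.n_quantiles = n_quantiles
        self.lam = lam
        self.validation_fraction = validation_fraction
        self.score_parse = score_parse
        self.seed = seed

    # -- internals -------------------------------------------------------
    def _internal_scores(self, X, y):
        from .assoc import fit_variant_binary

        n_snps = X.shape[1] - self.n_covariates
        covars = X[:, n_snps:]
        rows = [fit_variant_binary(X[:, j], y, covars) for j in range(n_snps)]
        return score_table(pd.DataFrame(rows), parse=self.score_parse)

    def fit(self, X, y, snp_scores=None, validation_mask=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        n_snps = p - self.n_covariates
        if n_snps <= 0:
            raise ValueError("X must contain at least one SNP column")
        if np.isnan(X).any():
            raise ValueError("X must have no missing entries (impute upstream)")
        scores = np.asarray(snp_scores, float) if snp_scores is not None else self._internal_scores(X, y)
        if scores.shape != (n_snps,):
            raise ValueError("snp_scores length must match the SNP columns")

        if validation_mask is None:
            idx = np.arange(n)
            tr, va = train_test_split(
                idx, test_size=self.validation_fraction, stratify=y, random_state=self.seed
            )
        else:
            validation_mask = np.asarray(validation_mask, bool)
            va = np.flatnonzero(validation_mask)
            tr = np.flatnonzero(~validation_mask)

        finite = scores[np.isfinite(scores)]
        if finite.size == 0:
            raise ValueError("no fitted SNPs to select from")
        if self.thresholds is not None:
            grid = list(self.thresholds)
        else:
            grid = list(np.unique(np.quantile(finite, np.linspace(0.0, 1.0, self.n_quantiles))))

        best = None
        for thr in sorted(grid, reverse=True):  # fewest SNPs first: ties keep them
            with np.errstate(invalid="ignore"):
                sel = np.flatnonzero(np.isfinite(scores) & (scores >= thr))
            if sel.size == 0:
                logger.warning("threshold %.4g selects no SNPs; skipped", thr)
                continue
            cols = np.concatenate([sel, np.arange(n_snps, p)])
            model = LinearRidge(lam=self.lam).fit(X[np.ix_(tr, cols)], y[tr])
            auc = roc_auc(model.predict(X[np.ix_(va, cols)]), y[va] > 0.5)
            if best is None or auc > best[0]:
                best = (auc, thr, sel, model)
        if best is None:
            raise ValueError("every threshold selected zero SNPs")

        auc, thr, sel, model = best
        self.validation_auc_ = auc
        self.selected_threshold_ = thr
        self.snp_indices_ = sel
        self.snp_scores_ = scores
        self.coef_snp_ = model.coef_[: sel.size]
        self.coef_covar_ = model.coef_[sel.size :]
        self.intercept_ = model.intercept_
        self.n_snps_ = int(sel.size)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        n_snps = X.shape[1] - self.n_covariates
        return (
            X[:, self.snp_indices_] @ self.coef_snp_
            + X[:, n_snps:] @ self.coef_covar_
            + self.intercept_
        )


def _imputed_dosages(G: GenotypeMatrix) -> np.ndarray:
    X = G.dosages.copy()
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
    return X


def train_prs(
    G: GenotypeMatrix,
    table: pd.DataFrame,
    pcs,
    summary_rows: pd.DataFrame,
    config: PRSConfig | None = None,
    splits: dict | None = None,
) -> PRSModel:
    """Threshold sweep + ridge fit from precomputed summary statistics.

    ``summary_rows`` must come from a GWAS that excluded the test split
    (see :func:`run_prs_pipeline`, which enforces this end to end).
    """
    from .assoc import build_covariates

    config = config or PRSConfig()
    splits = splits or split_data(table, config)
    y = table["anxiety"].to_numpy(float)
    dos = _imputed_dosages(G)
    covars = build_covariates(table, pcs)

    order = G.variant_index(summary_rows["id"])
    scores = score_table(summary_rows, parse=config.score_parse)

    model_rows = np.concatenate([splits["train"], splits["validation"]])
    model_rows.sort()
    X_model = np.column_stack([dos[:, order], covars])[model_rows]
    val_mask = np.isin(model_rows, splits["validation"])

    est = ThresholdRidgePRS(
        n_covariates=covars.shape[1],
        thresholds=config.thresholds,
        n_quantiles=config.n_quantiles,
        lam=config.ridge_lambda,
        score_parse=config.score_parse,
        seed=config.seed,
    )
    est.fit(X_model, y[model_rows], snp_scores=scores, validation_mask=val_mask)

    X_test = np.column_stack([dos[:, order], covars])[splits["test"]]
    test_auc = roc_auc(est.decision_function(X_test), y[splits["test"]] > 0.5)

    sel = est.snp_indices_
    return PRSModel(
        selected_threshold=float(est.selected_threshold_),
        snp_ids=[summary_rows["id"].iloc[i] for i in sel],
        snp_weights=est.coef_snp_,
        covariate_weights=est.coef_covar_,
        intercept=float(est.intercept_),
        validation_auc=float(est.validation_auc_),
        test_auc=float(test_auc),
        n_snps=int(sel.size),
    )


def covariate_only_model(
    table: pd.DataFrame, pcs, config: PRSConfig | None = None, splits: dict | None = None
) -> dict:
    """Baseline test AUCs from (age, sex) and (age, sex, PCs) ridge models."""
    from .assoc import build_covariates

    config = config or PRSConfig()
    splits = splits or split_data(table, config)
    y = table["anxiety"].to_numpy(float)
    out = {}
    for name, X in {
        "age_sex": build_covariates(table, None),
        "age_sex_pcs": build_covariates(table, pcs),
    }.items():
        model = LinearRidge(lam=config.ridge_lambda).fit(X[splits["train"]], y[splits["train"]])
        out[name] = float(roc_auc(model.predict(X[splits["test"]]), y[splits["test"]] > 0.5))
    return out


def run_prs_pipeline(
    G: GenotypeMatrix, table: pd.DataFrame, pcs, config: PRSConfig | None = None
):
    """End-to-end PRS with the no-leakage guard built in.

    Carves out the test split first, runs the binary GWAS on the remaining
    samples only, scores and sweeps thresholds, and evaluates the selected
    model and covariate-only baselines on the held-out test set.

    Returns (PRSModel with baselines attached, splits dict).
    """
    config = config or PRSConfig()
    splits = split_data(table, config)
    model_rows = np.concatenate([splits["train"], splits["validation"]])
    model_rows.sort()

    G_model = GenotypeMatrix(
        dosages=G.dosages[model_rows],
        variants=G.variants,
        samples=[G.samples[i] for i in model_rows],
    )
    scores_arr = pcs.scores if hasattr(pcs, "scores") else np.asarray(pcs, float)
    summary = scan(
        G_model,
        table.iloc[model_rows].reset_index(drop=True),
        scores_arr[model_rows],
        GwasDesign(model="binary"),
    )
    model = train_prs(G, table, pcs, summary, config, splits=splits)
    model.baseline_aucs = covariate_only_model(table, pcs, config, splits=splits)
    return model, splits
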