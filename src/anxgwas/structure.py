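"""Population-structure PCA used as association covariates.

A random subsample of common variants (default 15,000 with MAF >= 5%)
stands in for a fixed genotyping-array SNP list; the top principal
components (default 10) of the standardized dosage matrix are used as
covariates downstream.  A subsample-stability check repeats the
select-and-decompose step and reports the mean (1 - |Pearson r|) between
each run's component scores and a reference run, matched per component
index; below 0.05 counts as stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

STABILITY_CUTOFF = 0.05


@dataclass
class PCResult:
    scores: np.ndarray  # samples x k
    component_variances: np.ndarray
    snp_subset_ids: list
    stability: float | None = None


def _column_mafs(dosages: np.ndarray) -> np.ndarray:
    n_obs = (~np.isnan(dosages)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.nansum(dosages, axis=0) / (2.0 * n_obs)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    maf[n_obs == 0] = np.nan
    return maf


def select_pca_snps(
    G: GenotypeMatrix, maf_min: float = 0.05, n_snps: int = 15000, seed: int = 0
) -> list:
    """Uniform random subsample (without replacement) of common variants."""
    maf = _column_mafs(G.dosages)
    qualifying = np.flatnonzero(maf >= maf_min)
    if qualifying.size == 0:
        raise ValueError(f"no variants with MAF >= {maf_min}")
    rng = np.random.default_rng(seed)
    if qualifying.size <= n_snps:
        if qualifying.size < n_snps:
            logger.warning(
                "only %d variants qualify for PCA (requested %d); using all",
                qualifying.size,
                n_snps,
            )
        chosen = qualifying
    else:
        chosen = rng.choice(qualifying, size=n_snps, replace=False)
    chosen = np.sort(chosen)
    return [G.variants["id"].iloc[i] for i in chosen]


class GenotypePCA(BaseEstimator, TransformerMixin):
    """PCA of a standardized dosage matrix.

    Missing dosages are mean-imputed per variant; columns are centered and
    scaled to unit sample standard deviation (zero-variance columns are
    dropped).  Each component's sign is fixed by making its
    largest-magnitude loading positive, so results are fully deterministic.
    """

    def __init__(self, n_components: int = 10, standardize: bool = True):
        self.n_components = n_components
        self.standardize = standardize

    def _prepare(self, X):
        X = np.asarray(X, dtype=float)[:, self.kept_features_].copy()
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = self.mean_[nan_c]
        return (X - self.mean_) / self.scale_

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        Ximp = np.where(np.isnan(X), col_mean, X)
        sd = Ximp.std(axis=0)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d zero-variance columns before PCA", (~keep).sum())
        self.kept_features_ = np.flatnonzero(keep)
        self.mean_ = Ximp[:, keep].mean(axis=0)
        self.scale_ = sd[keep] if self.standardize else np.ones(keep.sum())
        Z = self._prepare(X)

        max_k = min(Z.shape[0], Z.shape[1])
        k = min(self.n_components, max_k)
        if k < self.n_components:
            logger.warning("reducing n_components from %d to rank %d", self.n_components, k)
        self._pca = PCA(n_components=k, svd_solver="full")
        scores = self._pca.fit_transform(Z)
        # deterministic sign: largest-|loading| entry of each component positive
        comp = self._pca.components_
        flip = comp[np.arange(k), np.abs(comp).argmax(axis=1)] < 0
        comp[flip] *= -1
        scores[:, flip] *= -1
        self.components_ = comp
        self.explained_variance_ = self._pca.explained_variance_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.scores_ = scores
        return self

    def transform(self, X):
        # components_ were sign-fixed in place, so the fitted PCA projects
        # with the same orientation as fit_transform
        return self._pca.transform(self._prepare(X))

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_


def compute_pcs(G: GenotypeMatrix, subset_ids, k: int = 10) -> PCResult:
    """Top-k structure PCs on the selected variant subset."""
    if not len(subset_ids):
        raise ValueError("PCA subset is empty")
    idx = G.variant_index(subset_ids)
    pca = GenotypePCA(n_components=k)
    scores = pca.fit_transform(G.dosages[:, idx])
    return PCResult(
        scores=scores,
        component_variances=pca.explained_variance_,
        snp_subset_ids=list(subset_ids),
    )


def assess_stability(
    G: GenotypeMatrix,
    runs: int = 50,
    k: int = 10,
    maf_min: float = 0.05,
    n_snps: int = 15000,
    seed: int = 0,
) -> float:
    """Mean per-component score discrepancy across variant subsamples.

    For each of ``runs`` independent subsamples the PCs are recomputed and
    compared with the first (reference) run: variability is the mean over
    runs and components of ``1 - |corr(scores_ref, scores_run)|``.
    """
    if runs < 2:
        raise ValueError("stability assessment needs at least 2 runs")
    results = []
    for r in range(runs):
        ids = select_pca_snps(G, maf_min=maf_min, n_snps=n_snps, seed=seed + r)
        results.append(compute_pcs(G, ids, k=k))
    ref = results[0].scores
    k_eff = min(res.scores.shape[1] for res in results)
    discrepancies = []
    for res in results[1:]:
        for c in range(k_eff):
            r_c = np.corrcoef(ref[:, c], res.scores[:, c])[0, 1]
            discrepancies.append(1.0 - abs(r_c))
    variability = float(np.mean(discrepancies))
    if variability >= STABILITY_CUTOFF:
        logger.warning("PCA subsample variability %.3f >= %.2f: unstable", variability, STABILITY_CUTOFF)
    return variability
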