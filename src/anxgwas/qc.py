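"""Variant-level quality control.

Filters applied, in order: caller FILTER status (keep PASS), multiallelic
records, Hardy–Weinberg disequilibrium (exact test p < 1e-6), and minor
allele frequency (< 1% removed).  A variant with MAF exactly at the
threshold is retained: the rule removes frequencies *below* the cutoff.

The Hardy–Weinberg test is the exact conditional test: conditioning on the
observed allele counts, the p-value sums the probabilities of all
heterozygote counts whose probability does not exceed the observed one.
Probabilities are computed by the standard two-sided recurrence over
heterozygote counts, which is numerically stable and O(rare-allele count)
per variant; a chi-square approximation is used only when the enumeration
would exceed a configurable cost bound.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    require_pass: bool = True
    biallelic_only: bool = True

    def __post_init__(self):
        if not 0 <= self.hwe_p_min < 1:
            raise ValueError("hwe_p_min must lie in [0, 1)")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")


@dataclass
class QCReport:
    """Per-variant QC metrics and the removal ledger."""

    variants: pd.DataFrame  # id, maf, hwe_p, fail_flags (frozenset)
    counts: dict = field(default_factory=dict)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int, *, max_enumeration: int = 10_000_000) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Parameters are genotype counts; the test is symmetric in the two
    homozygote counts.  Returns a p-value in (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("Hardy-Weinberg test undefined for zero genotypes")

    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:  # monomorphic: single attainable configuration
        return 1.0
    if rare > max_enumeration:
        return _hwe_chisq(n_hom_ref, n_het, n_hom_alt)

    # distribution of the heterozygote count given the allele counts
    probs = np.zeros(rare + 1)
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / (4 * hom_r(h-2+..) ...), standard ratios
    h = mid
    while h > 1:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_rare + 1) * (hom_common + 1))
        h -= 2
    h = mid
    while h <= rare - 2:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        probs[h + 2] = probs[h] * 4.0 * hom_rare * hom_common / ((h + 2) * (h + 1))
        h += 2
    probs /= probs.sum()
    p_obs = probs[n_het]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_chisq(n_hom_ref, n_het, n_hom_alt):
    """1-df chi-square goodness-of-fit fallback for huge allele counts."""
    n = n_hom_ref + n_het + n_hom_alt
    p_alt = (2 * n_hom_alt + n_het) / (2.0 * n)
    exp = n * np.array([(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt**2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum((obs - exp) ** 2 / np.where(exp > 0, exp, np.nan))
    return float(chi2.sf(stat, df=1))


def minor_allele_frequency(dosages) -> float:
    """MAF over non-missing dosages: min(f_alt, 1 - f_alt)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    f_alt = d.sum() / (2.0 * d.size)
    return float(min(f_alt, 1.0 - f_alt))


def _genotype_counts(dosage_col):
    d = dosage_col[~np.isnan(dosage_col)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


class VariantQC(BaseEstimator):
    """Variant filter with per-variant QC metrics.

    ``fit`` computes per-variant MAF, exact HWE p-values and failure flags;
    ``transform`` drops the failing variants.  Filters are applied in a
    fixed order (non-PASS, multiallelic, HWE, MAF) and each removal count
    in the report is taken against the set surviving the previous filter,
    so the ledger adds up.
    """

    def __init__(
        self,
        hwe_p_min: float = 1e-6,
        maf_min: float = 0.01,
        require_pass: bool = True,
        biallelic_only: bool = True,
        max_enumeration: int = 10_000_000,
    ):
        self.hwe_p_min = hwe_p_min
        self.maf_min = maf_min
        self.require_pass = require_pass
        self.biallelic_only = biallelic_only
        self.max_enumeration = max_enumeration

    def fit(self, G: GenotypeMatrix, y=None):
        QCThresholds(self.hwe_p_min, self.maf_min)  # validates
        m = G.n_variants
        maf = np.full(m, np.nan)
        hwe_p = np.full(m, np.nan)
        for j in range(m):
            col = G.dosages[:, j]
            counts = _genotype_counts(col)
            if sum(counts) == 0:
                continue  # all-missing: metrics undefined, fails MAF below
            maf[j] = minor_allele_frequency(col)
            hwe_p[j] = hwe_exact_test(*counts, max_enumeration=self.max_enumeration)

        alive = np.ones(m, dtype=bool)
        flags = [set() for _ in range(m)]
        removed = {}

        def apply(name, fails):
            hit = alive & fails
            for j in np.flatnonzero(hit):
                flags[j].add(name)
            removed[name] = int(hit.sum())
            alive[hit] = False

        filt = G.variants["filter"].to_numpy()
        n_alt = G.variants["n_alt"].to_numpy()
        apply("non_pass", (filt != "PASS") if self.require_pass else np.zeros(m, bool))
        apply("multiallelic", (n_alt > 1) if self.biallelic_only else np.zeros(m, bool))
        with np.errstate(invalid="ignore"):
            apply("hwe", np.nan_to_num(hwe_p, nan=1.0) < self.hwe_p_min)
            # an all-missing variant cannot demonstrate MAF >= a positive cutoff
            maf_fail = maf < self.maf_min
            if self.maf_min > 0:
                maf_fail |= np.isnan(maf)
            apply("maf", maf_fail)

        self.maf_ = maf
        self.hwe_p_ = hwe_p
        self.support_ = alive
        self.report_ = QCReport(
            variants=pd.DataFrame(
                {
                    "id": G.variants["id"],
                    "maf": maf,
                    "hwe_p": hwe_p,
                    "fail_flags": [frozenset(f) for f in flags],
                }
            ),
            counts={
                "input": m,
                **{f"removed_{k}": v for k, v in removed.items()},
                "surviving": int(alive.sum()),
            },
        )
        if alive.sum() == 0 and m > 0:
            warnings.warn("all variants removed by QC", stacklevel=2)
        return self

    def transform(self, G: GenotypeMatrix) -> GenotypeMatrix:
        return G.subset_variants(self.support_)

    def fit_transform(self, G: GenotypeMatrix, y=None) -> GenotypeMatrix:
        return self.fit(G).transform(G)


def apply_qc(G: GenotypeMatrix, thresholds: QCThresholds | None = None):
    """Filter a genotype matrix; returns (filtered matrix, QCReport)."""
    t = thresholds or QCThresholds()
    qc = VariantQC(
        hwe_p_min=t.hwe_p_min,
        maf_min=t.maf_min,
        require_pass=t.require_pass,
        biallelic_only=t.biallelic_only,
    )
    filtered = qc.fit_transform(G)
    logger.info("QC: %s", qc.report_.counts)
    return filtered, qc.report_
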