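"""Core in-memory containers shared across the pipeline.

Genotypes are held as a dense samples x variants dosage matrix (count of
alternate alleles per diploid call, ``numpy.nan`` for a missing call) next to
a per-variant metadata frame.  Phenotypes and covariates live in a plain
:class:`pandas.DataFrame` with a validated schema (:func:`validate_cohort`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every variant metadata frame carries, in order.
VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "filter", "n_alt"]

#: Phenotype columns required by the association and epidemiology stages.
REQUIRED_PHENO_COLUMNS = ["sample_id", "age", "sex", "hads_a"]

#: Optional behavioural / marker columns with their admissible values.
CATEGORICAL_LEVELS = {
    "alcohol_group": {1, 2, 3},
    "smoking": {"never", "former", "current"},
    "met_category": {"sedentary", "low", "moderate", "high"},
    "marital_status": {"never_married", "married", "divorced", "widowed"},
    "employment": {"employed", "never_employed", "unemployed", "retired", "disabled"},
    "rs762551": {"AA", "AC", "CC"},
    "rs5751876": {"CC", "CT", "TT"},
    "rs671": {"GG", "AG", "AA"},
    "rs1229984": {"CC", "CT", "TT"},
}

#: HADS-A clinical-anxiety cutoff: a score of 11 or more is a case.
ANXIETY_CUTOFF = 11

#: HADS-A support.
HADS_A_MIN, HADS_A_MAX = 0, 21


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix plus per-variant metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_samples, n_variants)
        Count of alternate alleles (0, 1 or 2); ``nan`` marks a missing call.
    variants : DataFrame
        One row per variant with columns :data:`VARIANT_COLUMNS`.
    samples : list of str
        Sample identifiers, aligned with the rows of ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"dosage matrix has {self.dosages.shape[1]} variants but "
                f"metadata has {len(self.variants)} rows"
            )
        if self.samples and len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list does not match dosage matrix rows")
        if not self.samples:
            self.samples = [f"S{i:06d}" for i in range(self.dosages.shape[0])]
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata lacks columns: {missing}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        """Return a new matrix restricted to the selected variants."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def variant_index(self, ids) -> np.ndarray:
        """Column indices of the given variant ids (order preserved)."""
        lookup = {v: i for i, v in enumerate(self.variants["id"])}
        try:
            return np.array([lookup[v] for v in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown variant id {exc}") from exc


def binarize_score(score) -> np.ndarray:
    """Binary anxiety label: True iff the HADS-A score is >= 11."""
    score = np.asarray(score)
    if np.any((score < HADS_A_MIN) | (score > HADS_A_MAX)):
        raise ValueError(f"HADS-A scores must lie in [{HADS_A_MIN}, {HADS_A_MAX}]")
    return score >= ANXIETY_CUTOFF


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a phenotype table.

    Checks the required columns, restricts HADS-A to integers in [0, 21],
    rejects unknown categorical levels, and (re)derives the binary
    ``anxiety`` label from the score.
    """
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {missing}")
    table = table.copy()
    score = table["hads_a"]
    if not np.all(np.asarray(score, dtype=float) == np.asarray(score, dtype=int)):
        raise ValueError("hads_a must be integer-valued")
    table["hads_a"] = score.astype(int)
    table["anxiety"] = binarize_score(table["hads_a"].to_numpy())
    sex = set(pd.unique(table["sex"].dropna()))
    if not sex <= {0, 1}:
        raise ValueError(f"sex must be coded 0 (male) / 1 (female); saw {sex}")
    for col, levels in CATEGORICAL_LEVELS.items():
        if col in table.columns:
            seen = set(pd.unique(table[col].dropna()))
            if not seen <= levels:
                raise ValueError(f"column {col!r} has unknown levels {seen - levels}")
    return table
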