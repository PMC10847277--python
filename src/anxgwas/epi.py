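"""Non-genetic association statistics for the anxiety cohort.

Crude odds ratios come straight from 2x2 contingency tables with Woolf
confidence intervals; adjusted odds ratios come from logistic regressions
with age and sex as covariates.  Genotype-defined caffeine- and
alcohol-metabolism groups count risk substitutions across two marker SNPs
each.  All multiple-testing adjustment is plain Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ANXIETY_CUTOFF, binarize_score
from .prs import roc_auc


def binarize_hads(score):
    """Anxiety label: True iff the 0-21 HADS-A score is >= 11."""
    return binarize_score(score)


@dataclass
class ContingencyResult:
    or_estimate: float
    ci95: tuple
    p: float
    counts: tuple  # (exposed_case, exposed_control, unexposed_case, unexposed_control)
    zero_cell_corrected: bool = False


def contingency_or(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Crude odds ratio from a 2x2 table.

    Cells: ``a`` exposed cases, ``b`` exposed controls, ``c`` unexposed
    cases, ``d`` unexposed controls.  OR = (a*d)/(b*c) with a Woolf 95% CI
    on the log scale; the p-value is a two-sided chi-square test
    (continuity-corrected when any cell is below 5).  A 0.5
    (Haldane-Anscombe) correction is applied to every cell only when a
    zero cell occurs, and flagged in the result.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    table = cells.reshape(2, 2)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("a zero row or column makes the odds ratio undefined")
    corrected = bool(np.any(cells == 0))
    w = cells + 0.5 if corrected else cells
    log_or = np.log(w[0] * w[3] / (w[1] * w[2]))
    se = np.sqrt((1.0 / w).sum())
    ci = (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se)))
    correction = bool(np.any(cells < 5))
    chi2_stat, p, _, _ = stats.chi2_contingency(table if not corrected else w, correction=correction)
    return ContingencyResult(
        or_estimate=float(np.exp(log_or)),
        ci95=ci,
        p=float(p),
        counts=(a, b, c, d),
        zero_cell_corrected=corrected,
    )


def adjusted_or(variable, y, age=None, sex=None) -> dict:
    """Age/sex-adjusted odds ratio per unit of ``variable``.

    Fits a logistic regression of the binary outcome on the variable plus
    age and sex, and exponentiates the variable's coefficient.  Separation
    or non-convergence is reported through the ``flagged`` field rather
    than raised.
    """
    variable = np.asarray(variable, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = [variable]
    names = ["variable"]
    for extra, name in ((age, "age"), (sex, "sex")):
        if extra is not None:
            cols.append(np.asarray(extra, dtype=float))
            names.append(name)
    X = sm.add_constant(np.column_stack(cols))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise ValueError("no convergence")
        beta, se = fit.params[1], fit.bse[1]
        if not np.isfinite(se) or se > 50:
            raise ValueError("separation")
    except Exception:
        return {"or": np.nan, "ci95": (np.nan, np.nan), "p": np.nan, "flagged": True}
    return {
        "or": float(np.exp(beta)),
        "ci95": (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        "p": float(fit.pvalues[1]),
        "flagged": False,
    }


_CAFFEINE_ALPHABETS = {"rs762551": {"AA", "AC", "CC"}, "rs5751876": {"CC", "CT", "TT"}}
_ALCOHOL_ALPHABETS = {"rs671": {"GG", "AG", "AA"}, "rs1229984": {"CC", "CT", "TT"}}


def _check_gt(gt, marker, alphabet):
    if gt not in alphabet:
        raise ValueError(f"invalid {marker} genotype {gt!r}; expected one of {sorted(alphabet)}")


def assign_caffeine_group(gt_rs762551: str, gt_rs5751876: str) -> int:
    """Caffeine-intolerance group: number of risk substitutions (0, 1 or 2).

    Substitution one: rs762551 carries a C allele (slow metabolizer, AC or
    CC); substitution two: rs5751876 is TT (caffeine-sensitivity genotype).
    """
    _check_gt(gt_rs762551, "rs762551", _CAFFEINE_ALPHABETS["rs762551"])
    _check_gt(gt_rs5751876, "rs5751876", _CAFFEINE_ALPHABETS["rs5751876"])
    return int(gt_rs762551 in ("AC", "CC")) + int(gt_rs5751876 == "TT")


def assign_alcohol_group(gt_rs671: str, gt_rs1229984: str) -> int:
    """Alcohol-intolerance group: number of risk substitutions (0, 1 or 2).

    Substitution one: rs671 carries an A allele (AA or AG); substitution
    two: rs1229984 carries a T allele (TT or CT).
    """
    _check_gt(gt_rs671, "rs671", _ALCOHOL_ALPHABETS["rs671"])
    _check_gt(gt_rs1229984, "rs1229984", _ALCOHOL_ALPHABETS["rs1229984"])
    return int(gt_rs671 in ("AA", "AG")) + int(gt_rs1229984 in ("TT", "CT"))


def group_summary(values, groups) -> pd.DataFrame:
    """Per-group mean +- SD and a test of each group against the cohort mean.

    Each group's values are compared with the overall cohort mean by a
    two-sided one-sample t-test.  Groups of size one report no SD and no
    test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    overall = values.mean()
    rows = []
    for g in sorted(labels):
        v = values[groups == g]
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        if v.size == 1:
            rows.append({"group": g, "n": 1, "mean": v[0], "sd": np.nan, "p": np.nan})
            continue
        t, p = stats.ttest_1samp(v, popmean=overall)
        rows.append({"group": g, "n": v.size, "mean": v.mean(), "sd": v.std(ddof=1), "p": p})
    return pd.DataFrame(rows)


def bonferroni_adjust(pvals) -> np.ndarray:
    """Bonferroni: min(1, m * p) with m the number of tests."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p * p.size)


#: Reference levels for the one-hot encodings in the multivariate model.
_MULTIVARIATE_REFERENCES = {
    "marital_status": "never_married",
    "alcohol_group": 1,
    "n_children": 0,
}


def multivariate_model(table: pd.DataFrame) -> dict:
    """Joint logistic model of anxiety on sociodemographic/lifestyle factors.

    Covariates: age, sex, number of children, marital status, alcohol
    consumption group, daily coffee cups and nightly sleep hours, with
    categorical variables one-hot encoded against fixed reference levels.
    Reports the coefficient table (with odds ratios) and the in-sample ROC
    AUC of the fitted model.
    """
    needed = ["age", "sex", "n_children", "marital_status", "alcohol_group", "coffee_cups", "sleep_hours"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    y = table["anxiety"].to_numpy(float)
    parts = [
        table[["age", "sex", "coffee_cups", "sleep_hours"]].astype(float).reset_index(drop=True)
    ]
    for col, ref in _MULTIVARIATE_REFERENCES.items():
        dummies = pd.get_dummies(table[col], prefix=col).astype(float).reset_index(drop=True)
        ref_col = f"{col}_{ref}"
        parts.append(dummies.drop(columns=[ref_col], errors="ignore"))
    X = pd.concat(parts, axis=1)
    Xc = sm.add_constant(X)
    fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    coef = pd.DataFrame(
        {
            "term": Xc.columns,
            "coef": fit.params.to_numpy(),
            "or": np.exp(fit.params.to_numpy()),
            "ci_low": np.exp(fit.conf_int()[0].to_numpy()),
            "ci_high": np.exp(fit.conf_int()[1].to_numpy()),
            "p": fit.pvalues.to_numpy(),
        }
    )
    auc = roc_auc(fit.predict(Xc), y > 0.5)
    return {"coefficients": coef, "auc": float(auc), "fit": fit}
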