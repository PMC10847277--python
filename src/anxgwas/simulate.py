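"""Synthetic cohort generator with known ground truth.

Genotypes follow the Balding–Nichols model: each variant has an ancestral
allele frequency, each subpopulation draws its own frequency from a Beta
distribution whose spread is controlled by FST, and diploid genotypes are
Binomial(2, population frequency).  This produces the kind of population
structure that genotype PCA recovers and that association scans must adjust
for.

Phenotypes follow a liability construction: a standardized-genotype burden
over a sparse set of causal variants, plus covariate terms (age, sex, sleep,
coffee, alcohol, smoking, physical activity, caffeine/alcohol metabolism
markers), plus Gaussian noise.  The anxiety questionnaire score is drawn as
Binomial(21, logistic(baseline + scale * liability)) so it is a genuine
bounded integer on the 0–21 scale, and the binary anxiety label is
``score >= 11``.  Default effect sizes are calibrated so the marginal
prevalence of the label is about 14% and the female:male odds ratio for the
label is about 2, matching the cohort the generator emulates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import GenotypeMatrix, binarize_score, validate_cohort

#: Number of questionnaire items contributing to the 0-21 anxiety score.
N_TRIALS = 21

#: Default per-trial (logit-scale) covariate effects.  ``female`` and
#: ``baseline_logit`` are calibrated (see docs/methods.md) so that the
#: simulated label prevalence is ~0.14 and the female:male odds ratio for
#: the binary label is ~2; the remaining effects are modest per-trial
#: versions of the corresponding observed associations.
DEFAULT_COVARIATE_EFFECTS = {
    "age_per_decade": -0.083,
    "female": 0.65,
    "sleep_per_hour": -0.10,
    "coffee_per_cup": 0.035,
    "alcohol_group2": 0.10,
    "alcohol_group3": 0.40,
    "smoking_former": 0.02,
    "smoking_current": 0.07,
    "met_sedentary": 0.07,
    "met_high": 0.20,
    "children_2": 0.20,
    "widowed": 0.10,
    "unemployed": 0.20,
    "retired": 0.20,
    "caffeine_substitution": 0.0,
    "alcohol_substitution": 0.0,
}

#: Marginal category frequencies used for the behavioural covariates.
_SMOKING_LEVELS = (["never", "former", "current"], [0.645, 0.163, 0.192])
_MET_LEVELS = (["sedentary", "low", "moderate", "high"], [0.279, 0.418, 0.169, 0.134])
_MARITAL_LEVELS = (
    ["never_married", "married", "divorced", "widowed"],
    [0.127, 0.657, 0.129, 0.087],
)
_EMPLOYMENT_LEVELS = (
    ["employed", "never_employed", "unemployed", "retired", "disabled"],
    [0.632, 0.103, 0.064, 0.078, 0.123],
)
_CHILDREN_LEVELS = ([0, 1, 2, 3], [0.318, 0.165, 0.493, 0.024])
_ALCOHOL_LEVELS = ([1, 2, 3], [0.333, 0.654, 0.013])

#: Alternate (substitution) allele frequencies for the metabolism markers.
_MARKER_ALT_FREQ = {
    # genotype alphabets: (homozygous-reference, het, homozygous-alt)
    "rs762551": (("AA", "AC", "CC"), 0.31),
    "rs5751876": (("CC", "CT", "TT"), 0.42),
    "rs671": (("GG", "AG", "AA"), 0.02),
    "rs1229984": (("CC", "CT", "TT"), 0.05),
}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic cohort.

    All covariate effects are per-trial logit-scale coefficients entering
    the Binomial(21, logistic(.)) score model through the liability.
    """

    n_samples: int = 2000
    n_variants: int = 5000
    n_populations: int = 2
    fst: float = 0.05
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 20
    causal_effect_sd: float = 0.25
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    baseline_logit: float = -2.53
    liability_scale: float = 1.0
    noise_sd: float = 1.0
    female_fraction: float = 0.626
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        effects = dict(DEFAULT_COVARIATE_EFFECTS)
        effects.update(self.covariate_effects)
        unknown = set(effects) - set(DEFAULT_COVARIATE_EFFECTS)
        if unknown:
            raise ValueError(f"unknown covariate effects: {sorted(unknown)}")
        self.covariate_effects = effects

    def replace(self, **kw) -> "SimulationSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """What the generator knows and downstream stages must recover."""

    causal_variant_ids: list
    causal_betas: np.ndarray
    population_labels: np.ndarray
    ancestral_freqs: np.ndarray = None
    population_freqs: np.ndarray = None

    def __post_init__(self):
        if len(self.causal_variant_ids) != len(self.causal_betas):
            raise ValueError("causal ids and betas must have equal length")


def simulate_genotypes(spec: SimulationSpec):
    """Draw a structured genotype matrix under the Balding–Nichols model.

    Returns
    -------
    (GenotypeMatrix, GroundTruth)
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_variants

    lo, hi = spec.maf_range
    ancestral = rng.uniform(lo, hi, size=m)
    pops = rng.integers(0, spec.n_populations, size=n)

    if spec.fst > 0 and spec.n_populations > 1:
        a = ancestral * (1 - spec.fst) / spec.fst
        b = (1 - ancestral) * (1 - spec.fst) / spec.fst
        pop_freqs = rng.beta(
            a[None, :], b[None, :], size=(spec.n_populations, m)
        )
        # keep frequencies away from fixation so every variant stays usable
        pop_freqs = np.clip(pop_freqs, 1e-4, 1 - 1e-4)
    else:
        pop_freqs = np.broadcast_to(ancestral, (spec.n_populations, m)).copy()

    dosages = rng.binomial(2, pop_freqs[pops, :]).astype(float) if m else np.empty((n, 0))
    if spec.missing_rate > 0 and m:
        dosages[rng.random(size=dosages.shape) < spec.missing_rate] = np.nan

    variants = pd.DataFrame(
        {
            "chrom": [str(1 + i % 22) for i in range(m)],
            "pos": np.arange(1, m + 1) * 100,
            "id": [f"var{i:06d}" for i in range(m)],
            "ref": "A",
            "alt": "G",
            "filter": "PASS",
            "n_alt": 1,
        }
    )
    samples = [f"S{i:06d}" for i in range(n)]
    G = GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)

    causal_idx = rng.choice(m, size=spec.n_causal, replace=False) if spec.n_causal else np.array([], dtype=int)
    causal_idx.sort()
    betas = rng.normal(0.0, spec.causal_effect_sd, size=spec.n_causal)
    truth = GroundTruth(
        causal_variant_ids=[variants["id"].iloc[i] for i in causal_idx],
        causal_betas=betas,
        population_labels=pops,
        ancestral_freqs=ancestral,
        population_freqs=pop_freqs,
    )
    return G, truth


def _genetic_liability(G: GenotypeMatrix, truth: GroundTruth) -> np.ndarray:
    """Standardized-genotype burden over the causal variants."""
    if not truth.causal_variant_ids:
        return np.zeros(G.n_samples)
    idx = G.variant_index(truth.causal_variant_ids)
    X = G.dosages[:, idx].copy()
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd @ truth.causal_betas


def _marker_genotypes(rng, n, marker):
    labels, q = _MARKER_ALT_FREQ[marker]
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    return rng.choice(labels, size=n, p=probs)


def _substitution_count(gt, marker):
    """0/1 indicator that a marker genotype carries its risk substitution."""
    hom_ref, het, hom_alt = _MARKER_ALT_FREQ[marker][0]
    if marker == "rs762551":  # slow metabolizers: any C allele
        return np.isin(gt, [het, hom_alt]).astype(float)
    if marker == "rs5751876":  # caffeine sensitivity: TT only
        return (gt == hom_alt).astype(float)
    # alcohol intolerance markers: any substitution allele
    return np.isin(gt, [het, hom_alt]).astype(float)


def simulate_phenotypes(
    G: GenotypeMatrix, truth: GroundTruth, spec: SimulationSpec
) -> pd.DataFrame:
    """Draw phenotypes and covariates on top of simulated genotypes."""
    if G.n_samples != spec.n_samples:
        raise ValueError(
            f"genotype matrix has {G.n_samples} samples, spec says {spec.n_samples}"
        )
    rng = np.random.default_rng(spec.seed + 1)
    n = G.n_samples
    eff = spec.covariate_effects

    age = rng.integers(18, 81, size=n)
    sex = (rng.random(n) < spec.female_fraction).astype(int)
    sleep = np.clip(rng.normal(7.0, 1.5, size=n), 3.0, 12.0).round(1)
    coffee = np.minimum(rng.poisson(1.25, size=n), 6)
    alcohol = rng.choice(_ALCOHOL_LEVELS[0], size=n, p=_ALCOHOL_LEVELS[1])
    smoking = rng.choice(_SMOKING_LEVELS[0], size=n, p=_SMOKING_LEVELS[1])
    met = rng.choice(_MET_LEVELS[0], size=n, p=_MET_LEVELS[1])
    marital = rng.choice(_MARITAL_LEVELS[0], size=n, p=_MARITAL_LEVELS[1])
    children = rng.choice(_CHILDREN_LEVELS[0], size=n, p=_CHILDREN_LEVELS[1])
    employment = rng.choice(_EMPLOYMENT_LEVELS[0], size=n, p=_EMPLOYMENT_LEVELS[1])
    markers = {m: _marker_genotypes(rng, n, m) for m in _MARKER_ALT_FREQ}

    caffeine_subs = _substitution_count(markers["rs762551"], "rs762551") + _substitution_count(
        markers["rs5751876"], "rs5751876"
    )
    alcohol_subs = _substitution_count(markers["rs671"], "rs671") + _substitution_count(
        markers["rs1229984"], "rs1229984"
    )

    covariate_term = (
        eff["age_per_decade"] * (age - 50) / 10.0
        + eff["female"] * sex
        + eff["sleep_per_hour"] * (sleep - 7.0)
        + eff["coffee_per_cup"] * coffee
        + eff["alcohol_group2"] * (alcohol == 2)
        + eff["alcohol_group3"] * (alcohol == 3)
        + eff["smoking_former"] * (smoking == "former")
        + eff["smoking_current"] * (smoking == "current")
        + eff["met_sedentary"] * (met == "sedentary")
        + eff["met_high"] * (met == "high")
        + eff["children_2"] * (children == 2)
        + eff["widowed"] * (marital == "widowed")
        + eff["unemployed"] * (employment == "unemployed")
        + eff["retired"] * (employment == "retired")
        + eff["caffeine_substitution"] * caffeine_subs
        + eff["alcohol_substitution"] * alcohol_subs
    )

    liability = (
        _genetic_liability(G, truth)
        + covariate_term
        + rng.normal(0.0, spec.noise_sd, size=n)
    )
    eta = spec.baseline_logit + spec.liability_scale * liability
    hads_a = rng.binomial(N_TRIALS, expit(eta))
    # depression-like half of the total questionnaire, weakly coupled to the
    # same liability so HADS > HADS-A and the two co-vary
    hads_dep = rng.binomial(N_TRIALS, expit(-1.6 + 0.5 * spec.liability_scale * liability))
    table = pd.DataFrame(
        {
            "sample_id": G.samples,
            "age": age,
            "sex": sex,
            "hads_a": hads_a,
            "hads": hads_a + hads_dep,
            "anxiety": binarize_score(hads_a),
            "sleep_hours": sleep,
            "coffee_cups": coffee,
            "alcohol_group": alcohol,
            "smoking": smoking,
            "met_category": met,
            "marital_status": marital,
            "n_children": children,
            "employment": employment,
            **{m: markers[m] for m in _MARKER_ALT_FREQ},
        }
    )
    return validate_cohort(table)


def simulate_cohort(spec: SimulationSpec):
    """Convenience wrapper: genotypes + phenotypes in one call."""
    G, truth = simulate_genotypes(spec)
    table = simulate_phenotypes(G, truth, spec)
    return G, table, truth


def calibrate_baseline_logit(
    spec: SimulationSpec,
    target_prevalence: float = 0.14,
    n: int = 10000,
    tol: float = 0.002,
    lo: float = -6.0,
    hi: float = 2.0,
) -> float:
    """Bisection on ``baseline_logit`` to hit a target label prevalence.

    Prevalence is monotone non-decreasing in the baseline, so plain
    bisection on the empirical prevalence at sample size ``n`` converges;
    the same seed is reused at every evaluation so the objective is a fixed
    monotone function of the baseline.
    """
    probe = spec.replace(n_samples=n)

    def prevalence(b):
        G, table, _ = simulate_cohort(probe.replace(baseline_logit=b))
        return table["anxiety"].mean()

    f_lo, f_hi = prevalence(lo), prevalence(hi)
    if not f_lo <= target_prevalence <= f_hi:
        raise ValueError("target prevalence not bracketed by [lo, hi]")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = prevalence(mid)
        if abs(f_mid - target_prevalence) <= tol:
            return mid
        if f_mid < target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def write_cohort(G: GenotypeMatrix, table: pd.DataFrame, out_dir) -> dict:
    """Write the cohort as a VCF + phenotype TSV pair (see the io module)."""
    from . import io as _io
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / "cohort.vcf"
    pheno_path = out_dir / "phenotypes.tsv"
    _io.write_vcf(G, vcf_path)
    _io.write_phenotypes(table, pheno_path)
    return {"vcf": vcf_path, "phenotypes": pheno_path}
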