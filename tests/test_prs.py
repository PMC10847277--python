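"""PRS machinery: SNP scoring, splits, closed-form ridge, AUC, sweep."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge as SkRidge
from sklearn.metrics import roc_auc_score

from anxgwas.prs import (
    LinearRidge,
    PRSConfig,
    ThresholdRidgePRS,
    covariate_only_model,
    roc_auc,
    run_prs_pipeline,
    score_table,
    snp_score,
    split_data,
    train_prs,
)


def _row(beta_g, p, beta_age, beta_sex, intercept, fit_ok=True):
    return {
        "beta_g": beta_g,
        "p": p,
        "beta_age": beta_age,
        "beta_sex": beta_sex,
        "intercept": intercept,
        "fit_ok": fit_ok,
    }


class TestSnpScore:
    def test_literal_formula(self):
        # (0.5 / 0.01) * 0.02 + 0.7 - 1.0 = 0.7
        assert snp_score(_row(0.5, 0.01, 0.02, 0.7, -1.0)) == pytest.approx(0.7)

    def test_zero_effect_reduces_to_covariate_terms(self):
        assert snp_score(_row(0.0, 0.3, 0.02, 0.7, -1.0)) == pytest.approx(-0.3)

    def test_magnitude_parse(self):
        got = snp_score(_row(0.5, 0.01, 0.02, 0.7, -1.0), parse="magnitude")
        assert got == pytest.approx((0.5 / 0.01) * (0.02 + 0.7 - 1.0))

    def test_unfit_rows_score_nan(self):
        assert np.isnan(snp_score(_row(0.5, 0.01, 0.02, 0.7, -1.0, fit_ok=False)))

    def test_table_ranking_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame(
            {
                "beta_g": rng.normal(size=50),
                "p": rng.uniform(1e-10, 1, size=50),
                "beta_age": rng.normal(scale=0.05, size=50),
                "beta_sex": rng.normal(size=50),
                "intercept": rng.normal(size=50),
                "fit_ok": [True] * 50,
            }
        )
        scores = score_table(rows)
        direct = rows.beta_g / rows.p * rows.beta_age + rows.beta_sex + rows.intercept
        np.testing.assert_allclose(scores, direct, rtol=1e-12)
        assert list(np.argsort(-np.abs(scores))) == list(np.argsort(-np.abs(direct)))


class TestSplit:
    def _table(self, n=1000, prev=0.14, seed=1):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: int(round(n * prev))] = 1
        rng.shuffle(labels)
        return pd.DataFrame({"anxiety": labels.astype(bool)})

    def test_fraction_arithmetic(self):
        parts = split_data(self._table(), PRSConfig(seed=0))
        assert len(parts["test"]) == 100
        assert abs(len(parts["train"]) - 720) <= 1
        assert abs(len(parts["validation"]) - 180) <= 1

    def test_disjoint_exhaustive_reproducible(self):
        t = self._table()
        a = split_data(t, PRSConfig(seed=3))
        b = split_data(t, PRSConfig(seed=3))
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        allidx = np.concatenate(list(a.values()))
        assert len(allidx) == len(t) and len(np.unique(allidx)) == len(t)

    def test_stratification(self):
        t = self._table(2000)
        parts = split_data(t, PRSConfig(seed=4))
        overall = t["anxiety"].mean()
        for idx in parts.values():
            assert abs(t["anxiety"].to_numpy()[idx].mean() - overall) <= 0.02

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_data(self._table(20))


class TestLinearRidge:
    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + rng.normal(size=60)
        model = LinearRidge(lam=0.0).fit(X, y)
        Xc = np.column_stack([np.ones(60), X])
        ols, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        assert model.intercept_ == pytest.approx(ols[0], abs=1e-8)
        np.testing.assert_allclose(model.coef_, ols[1:], atol=1e-8)

    def test_three_point_closed_form(self):
        # x=(0,1,2), y=(0,1,2), lam=1; centered x=(-1,0,1), population SD
        # s=sqrt(2/3): slope = sum(xc*yc) / (sum(xc^2) + lam*s^2)
        #            = 2 / (2 + 2/3) = 0.75, intercept = 1 - 0.75*1 = 0.25
        model = LinearRidge(lam=1.0).fit(np.array([[0.0], [1.0], [2.0]]), np.array([0.0, 1.0, 2.0]))
        assert model.coef_[0] == pytest.approx(0.75, abs=1e-10)
        assert model.intercept_ == pytest.approx(0.25, abs=1e-10)

    def test_infinite_penalty_shrinks_to_mean(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        model = LinearRidge(lam=1e9).fit(X, y)
        np.testing.assert_allclose(model.coef_, 0, atol=1e-6)
        assert model.intercept_ == pytest.approx(y.mean(), abs=1e-4)

    def test_singular_at_zero_penalty_raises(self):
        X = np.ones((10, 12))
        with pytest.raises(ValueError, match="lam"):
            LinearRidge(lam=0.0).fit(X, np.zeros(10))

    def test_matches_sklearn_on_standardized_features(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 5))
        Z = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=80)
        mine = LinearRidge(lam=2.5).fit(Z, y)
        ref = SkRidge(alpha=2.5).fit(Z, y)
        np.testing.assert_allclose(mine.coef_, ref.coef_, atol=1e-8)
        assert mine.intercept_ == pytest.approx(ref.intercept_, abs=1e-8)

    def test_dual_and_primal_agree(self):
        rng = np.random.default_rng(8)
        Xwide = rng.normal(size=(30, 50))
        y = rng.normal(size=30)
        wide = LinearRidge(lam=1.0).fit(Xwide, y)  # dual path (p > n)
        A_pred = wide.predict(Xwide)
        # primal path on the same problem via explicit p x p solve
        Z = (Xwide - Xwide.mean(0)) / np.where(Xwide.std(0) > 0, Xwide.std(0), 1)
        w = np.linalg.solve(Z.T @ Z + np.eye(50), Z.T @ (y - y.mean()))
        coef = w / np.where(Xwide.std(0) > 0, Xwide.std(0), 1)
        np.testing.assert_allclose(wide.coef_, coef, atol=1e-8)
        np.testing.assert_allclose(A_pred, Xwide @ coef + (y.mean() - Xwide.mean(0) @ coef), atol=1e-8)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_ties_match_exhaustive_pair_counting(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            scores = rng.integers(0, 4, size=20).astype(float)
            labels = rng.integers(0, 2, size=20).astype(bool)
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            brute = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
            assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=500).round(1)  # rounding forces ties
        labels = rng.integers(0, 2, size=500).astype(bool)
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_null_is_half(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=10000)
        labels = rng.integers(0, 2, size=10000).astype(bool)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


@pytest.fixture(scope="module")
def prs_cohort():
    from anxgwas.simulate import SimulationSpec, simulate_cohort
    from anxgwas.structure import compute_pcs, select_pca_snps

    spec = SimulationSpec(
        n_samples=1200,
        n_variants=600,
        n_populations=1,
        fst=0.0,
        n_causal=15,
        causal_effect_sd=0.5,
        seed=23,
    )
    G, table, truth = simulate_cohort(spec)
    pcs = compute_pcs(G, select_pca_snps(G, n_snps=400, seed=0), k=10)
    return G, table, pcs


class TestPipeline:
    def test_reproducible_model(self, prs_cohort):
        G, table, pcs = prs_cohort
        m1, _ = run_prs_pipeline(G, table, pcs.scores, PRSConfig(seed=5))
        m2, _ = run_prs_pipeline(G, table, pcs.scores, PRSConfig(seed=5))
        assert m1.snp_ids == m2.snp_ids
        np.testing.assert_array_equal(m1.snp_weights, m2.snp_weights)
        assert m1.test_auc == m2.test_auc

    def test_select_all_threshold_is_single_ridge_fit(self, prs_cohort):
        G, table, pcs = prs_cohort
        cfg = PRSConfig(thresholds=[-np.inf], seed=6)
        model, splits = run_prs_pipeline(G, table, pcs.scores, cfg)
        assert model.n_snps == G.n_variants

    def test_no_leakage_splits(self, prs_cohort):
        G, table, pcs = prs_cohort
        _, splits = run_prs_pipeline(G, table, pcs.scores, PRSConfig(seed=7))
        test = set(splits["test"])
        assert not test & set(splits["train"])
        assert not test & set(splits["validation"])
        assert len(test) == round(0.10 * len(table))

    def test_signal_beats_covariate_baseline(self, prs_cohort):
        G, table, pcs = prs_cohort
        model, _ = run_prs_pipeline(G, table, pcs.scores, PRSConfig(seed=8))
        assert model.test_auc > max(model.baseline_aucs.values())

    def test_heavier_penalty_no_systematic_gain(self, prs_cohort):
        G, table, pcs = prs_cohort
        cfg = PRSConfig(thresholds=[-np.inf], seed=9)
        light, _ = run_prs_pipeline(G, table, pcs.scores, cfg)
        heavy, _ = run_prs_pipeline(
            G, table, pcs.scores, PRSConfig(thresholds=[-np.inf], ridge_lambda=1e6, seed=9)
        )
        assert heavy.validation_auc <= light.validation_auc + 0.05

    def test_covariate_only_sex_age_signal(self, prs_cohort):
        G, table, pcs = prs_cohort
        aucs = covariate_only_model(table, pcs.scores, PRSConfig(seed=10))
        assert aucs["age_sex"] > 0.5

    def test_covariate_only_null_when_effects_zero(self):
        from anxgwas.simulate import SimulationSpec, simulate_cohort

        zero = {k: 0.0 for k in SimulationSpec().covariate_effects}
        spec = SimulationSpec(
            n_samples=1500, n_variants=20, n_causal=0, covariate_effects=zero,
            baseline_logit=-1.2, seed=12,
        )
        _, table, _ = simulate_cohort(spec)
        aucs = covariate_only_model(table, np.zeros((1500, 10)), PRSConfig(seed=0))
        assert abs(aucs["age_sex"] - 0.5) < 0.12  # test split holds 150 samples

    def test_estimator_internal_scoring_path(self):
        rng = np.random.default_rng(13)
        n = 400
        snps = rng.binomial(2, 0.3, size=(n, 15)).astype(float)
        covars = np.column_stack([rng.integers(18, 80, n), rng.integers(0, 2, n)]).astype(float)
        from scipy.special import expit

        y = (rng.random(n) < expit(-1.0 + 0.8 * snps[:, 0] - 0.8 * snps[:, 1])).astype(float)
        est = ThresholdRidgePRS(n_covariates=2, n_quantiles=5, seed=0)
        est.fit(np.column_stack([snps, covars]), y)
        assert est.n_snps_ >= 1
        assert est.decision_function(np.column_stack([snps, covars])).shape == (n,)

    def test_estimator_requires_complete_data(self):
        est = ThresholdRidgePRS(n_covariates=1)
        X = np.array([[np.nan, 1.0], [0.0, 2.0]])
        with pytest.raises(ValueError, match="missing"):
            est.fit(X, np.array([0.0, 1.0]))
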