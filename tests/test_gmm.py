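"""Tests of growth curves, the conditional mixture EM and selection stats."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from healthtraj.gmm import (
    GmmParameters,
    GrowthMixtureModel,
    GrowthSpec,
    bic_ssabic,
    bootstrap_lrt,
    class_membership_or,
    count_parameters,
    covariance_coverage,
    entropy,
    fit_growth_single,
    lmr_lrt,
    select_n_classes,
)
from healthtraj.simulate import (
    COVARIATE_COLUMNS,
    covariate_design_frame,
    default_config,
    generate_cohort,
)


def _well_conditioned_params():
    return GmmParameters(
        alpha=np.array([[70.0, -20.0], [50.0, -5.0]]),
        gamma=np.array([[[1.0], [0.5]], [[-1.0], [0.2]]]),
        beta=np.array([[0.3, -0.4]]),
        pi=np.array([0.7, 0.2]),
        lam=np.array([0.0, 0.2, 0.7, 1.0]),
        psi=np.array([[25.0, 10.0], [10.0, 20.0]]),
        sigma2=np.array([30.0, 35.0, 40.0, 45.0]),
    )


class TestLikelihoodOracle:
    def test_mixture_ll_equals_enumeration(self, toy_mixture_data):
        scores, covariates, mortality = toy_mixture_data
        spec = GrowthSpec(
            pattern="latent_basis", n_classes=2, covariates=("z",), distal_outcome=True
        )
        m = GrowthMixtureModel(scores, covariates, mortality, spec)
        p = _well_conditioned_params()
        ll = m.loglik(p)
        L = np.column_stack([np.ones(4), p.lam])
        total = 0.0
        for i in range(m.n):
            o = ~np.isnan(m.y[i])
            logits = np.array([p.beta[0, 0] + p.beta[0, 1] * m.x[i, 0], 0.0])
            pri = np.exp(logits) / np.exp(logits).sum()
            tot = 0.0
            for k in range(2):
                mu = (p.alpha[k] + p.gamma[k] @ m.x[i]) @ L[o].T
                sig = L[o] @ p.psi @ L[o].T + np.diag(p.sigma2[o])
                dens = multivariate_normal.pdf(m.y[i][o], mean=mu, cov=sig)
                if not np.isnan(m.d[i]):
                    dens *= p.pi[k] ** m.d[i] * (1 - p.pi[k]) ** (1 - m.d[i])
                tot += pri[k] * dens
            total += np.log(tot)
        assert ll == pytest.approx(total, abs=1e-10)

    def test_em_loglik_monotone(self, gmm_inputs_small):
        coh, scores, design = gmm_inputs_small
        spec = GrowthSpec(
            n_classes=2, covariates=tuple(COVARIATE_COLUMNS), distal_outcome=True
        )
        m = GrowthMixtureModel(scores, design, coh.mortality, spec)
        p = m._base_params()
        r, ll = m._responsibilities(p)
        for _ in range(25):
            p = m._m_step(p, r)
            r, ll_new = m._responsibilities(p)
            assert ll_new >= ll - 1e-8 * max(1.0, abs(ll))
            ll = ll_new

    def test_posterior_bayes_rule_one_person(self, toy_mixture_data):
        scores, covariates, mortality = toy_mixture_data
        spec = GrowthSpec(n_classes=2, covariates=("z",), distal_outcome=True)
        m = GrowthMixtureModel(scores, covariates, mortality, spec)
        p = _well_conditioned_params()
        r, _ = m._responsibilities(p)
        i = 0
        L = np.column_stack([np.ones(4), p.lam])
        o = ~np.isnan(m.y[i])
        logits = np.array([p.beta[0, 0] + p.beta[0, 1] * m.x[i, 0], 0.0])
        pri = np.exp(logits) / np.exp(logits).sum()
        comp = np.empty(2)
        for k in range(2):
            mu = (p.alpha[k] + p.gamma[k] @ m.x[i]) @ L[o].T
            sig = L[o] @ p.psi @ L[o].T + np.diag(p.sigma2[o])
            comp[k] = pri[k] * multivariate_normal.pdf(m.y[i][o], mean=mu, cov=sig)
            comp[k] *= p.pi[k] ** m.d[i] * (1 - p.pi[k]) ** (1 - m.d[i])
        assert np.allclose(r[i], comp / comp.sum(), atol=1e-12)
        assert np.allclose(r.sum(axis=1), 1.0, atol=1e-10)


class TestEntropyAndInformationCriteria:
    def test_entropy_limits(self):
        assert entropy(np.full((5, 3), 1 / 3)) == pytest.approx(0.0, abs=1e-12)
        one_hot = np.eye(4)[np.array([0, 1, 2, 3, 0])]
        assert entropy(one_hot) == pytest.approx(1.0)

    def test_entropy_hand_computed_example(self):
        # independent hand computation for rows (.9,.1) and (.8,.2):
        # 1 - (0.3250830 + 0.5004024) / (2 ln 2) = 0.4045381
        val = entropy(np.array([[0.9, 0.1], [0.8, 0.2]]))
        assert val == pytest.approx(0.4045381, abs=1e-6)

    def test_entropy_rejects_bad_rows(self):
        with pytest.raises(ValueError):
            entropy(np.array([[0.9, 0.3], [0.5, 0.5]]))

    def test_bic_ssabic_published_arithmetic(self):
        bic, _ = bic_ssabic(-166428.21, 46, 13988)
        assert bic == pytest.approx(333295.53, abs=0.05)
        _, ssabic = bic_ssabic(-165836.24, 90, 13988)
        assert ssabic == pytest.approx(332245.60, abs=0.05)
        b0, s0 = bic_ssabic(-100.0, 0, 50)
        assert b0 == s0 == 200.0

    def test_parameter_count_progression(self):
        for k, expected in zip((2, 3, 4, 5), (46, 68, 90, 112)):
            spec = GrowthSpec(
                n_classes=k, covariates=tuple("abcdef"), distal_outcome=True
            )
            assert count_parameters(spec, 4) == expected == 22 * k + 2
        bare = GrowthSpec(n_classes=1)
        assert count_parameters(bare, 4) == 11


class TestSingleGroupGrowth:
    def test_latent_basis_preferred_on_latent_basis_truth(self):
        # light check here; the 10-seed version runs in the acceptance suite
        wins = 0
        for s in range(3):
            coh = generate_cohort(
                default_config(
                    600, seed=300 + s, n_classes=1,
                    growth_means_per_class=np.array([[70.0, -15.0]]),
                    basis_loadings=np.array([0.0, 0.45, 0.8, 1.0]),
                )
            )
            bics = {
                pat: fit_growth_single(coh.observed_scores(), pattern=pat, seed=s).bic
                for pat in ("linear", "latent_basis", "quadratic")
            }
            wins += min(bics, key=bics.get) == "latent_basis"
        assert wins == 3

    def test_variance_floor_guards_noise_free_fit(self):
        rng = np.random.default_rng(1)
        eta = np.column_stack([rng.normal(70, 5, 80), rng.normal(-12, 4, 80)])
        t = np.array([0.0, 2 / 14, 11 / 14, 1.0])
        y = eta[:, [0]] + np.outer(eta[:, 1], t)  # exactly linear, no noise
        pid, wj = np.nonzero(np.ones_like(y, dtype=bool))
        scores = pd.DataFrame(
            {"person_id": pid, "wave": wj + 1, "score": y[pid, wj]}
        )
        res = fit_growth_single(scores, pattern="linear", seed=0, max_iter=150)
        assert np.isfinite(res.ll)
        assert np.all(res.params.sigma2 >= 1e-4)

    def test_k1_mixture_equals_single_group(self):
        coh = generate_cohort(
            default_config(
                400, seed=9, n_classes=1,
                growth_means_per_class=np.array([[70.0, -15.0]]),
            )
        )
        sc = coh.observed_scores()
        r1 = fit_growth_single(sc, pattern="latent_basis", seed=1)
        r2 = GrowthMixtureModel(
            sc, spec=GrowthSpec(pattern="latent_basis", n_classes=1)
        ).fit(n_starts=1, seed=1)
        assert abs(r1.ll - r2.ll) < 1e-6


@pytest.fixture(scope="module")
def two_class_fit(gmm_inputs_small):
    coh, scores, design = gmm_inputs_small
    spec = GrowthSpec(
        n_classes=2, covariates=tuple(COVARIATE_COLUMNS), distal_outcome=True
    )
    return GrowthMixtureModel(scores, design, coh.mortality, spec).fit(
        n_starts=10, seed=3
    )


class TestConditionalMixtureFit:
    def test_two_class_recovery_with_covariates(self, two_class_fit):
        res = two_class_fit
        alpha = res.params.alpha[np.argsort(-res.params.alpha[:, 0])]
        assert abs(alpha[0, 0] - 72.0) < 2.0
        assert abs(alpha[1, 0] - 45.0) < 3.0
        assert res.posterior.shape == (res.model.n, 2)
        assert np.allclose(res.posterior.sum(axis=1), 1.0, atol=1e-10)
        # death probabilities ordered with the generating truth
        k_low = int(np.argmin(res.params.alpha[:, 0]))
        assert res.params.pi[k_low] > 0.6

    def test_odds_ratio_table_consistency(self, two_class_fit):
        ors = two_class_fit.odds_ratios()
        assert np.allclose(ors["odds_ratio"], np.exp(ors["logit"]), atol=1e-10)
        assert (ors["or_low"] <= ors["odds_ratio"]).all()
        assert (ors["odds_ratio"] <= ors["or_high"]).all()

    def test_covariate_logit_coverage_under_null(self):
        # truth has zero covariate effects on membership; 95% CIs should
        # cover zero at roughly nominal rate
        hits = total = 0
        for s in range(8):
            cfg = default_config(
                400, seed=700 + s, n_classes=2,
                growth_means_per_class=np.array([[72.0, -12.0], [45.0, -6.0]]),
                distal_death_prob_per_class=np.array([0.15, 0.7]),
                class_logit_coefficients=np.array([[-1.0, 0, 0, 0, 0, 0, 0.0]]),
                reference_class=0,
            )
            coh = generate_cohort(cfg)
            design = covariate_design_frame(coh.covariates)
            spec = GrowthSpec(
                n_classes=2, covariates=tuple(COVARIATE_COLUMNS), distal_outcome=True
            )
            res = GrowthMixtureModel(
                coh.observed_scores(), design, coh.mortality, spec
            ).fit(n_starts=4, seed=s, max_iter=200)
            ors = res.odds_ratios()
            cov_rows = ors[ors["covariate"] != "intercept"]
            hits += ((cov_rows["or_low"] <= 1.0) & (1.0 <= cov_rows["or_high"])).sum()
            total += len(cov_rows)
        assert hits / total >= 0.85

    def test_listwise_deletion_counted(self, gmm_inputs_small):
        coh, scores, design = gmm_inputs_small
        spec = GrowthSpec(
            n_classes=1, covariates=tuple(COVARIATE_COLUMNS), distal_outcome=True
        )
        m = GrowthMixtureModel(scores, design, coh.mortality, spec)
        expected = int(
            design.set_index("person_id")
            .reindex(scores["person_id"].unique())[list(COVARIATE_COLUMNS)]
            .isna()
            .any(axis=1)
            .sum()
        )
        assert m.n_dropped_covariates == expected


class TestLmrAndBootstrap:
    def test_identical_loglik_gives_p_one(self):
        fit_k = SimpleNamespace(ll=-100.0, n_parameters=46)
        fit_km1 = SimpleNamespace(ll=-100.0, n_parameters=24)
        out = lmr_lrt(fit_k, fit_km1, n=500)
        assert out["lr"] == 0.0 and out["p_value"] == pytest.approx(1.0)

    def test_optimization_failure_detected(self):
        fit_k = SimpleNamespace(ll=-120.0, n_parameters=46)
        fit_km1 = SimpleNamespace(ll=-100.0, n_parameters=24)
        with pytest.raises(ValueError):
            lmr_lrt(fit_k, fit_km1, n=500)

    def test_size_and_power(self):
        # size: 1-class truth, reject 1-vs-2 rarely; power: well-separated
        # 2-class truth, reject nearly always
        rejections_null = rejections_alt = 0
        n_rep = 8
        for s in range(n_rep):
            coh = generate_cohort(
                default_config(
                    250, seed=500 + s, n_classes=1,
                    growth_means_per_class=np.array([[65.0, -10.0]]),
                )
            )
            sc = coh.observed_scores()
            f1 = GrowthMixtureModel(sc, spec=GrowthSpec(n_classes=1)).fit(
                seed=s, max_iter=150, tol=1e-7
            )
            f2 = GrowthMixtureModel(sc, spec=GrowthSpec(n_classes=2)).fit(
                n_starts=4, seed=s, max_iter=150, tol=1e-7
            )
            if f2.ll >= f1.ll and lmr_lrt(f2, f1)["p_value"] < 0.05:
                rejections_null += 1
            coh2 = generate_cohort(
                default_config(
                    250, seed=600 + s, n_classes=2,
                    growth_means_per_class=np.array([[75.0, -10.0], [40.0, -25.0]]),
                    class_logit_coefficients=np.zeros((1, 7)),
                    reference_class=0,
                    distal_death_prob_per_class=np.array([0.1, 0.8]),
                )
            )
            sc2 = coh2.observed_scores()
            g1 = GrowthMixtureModel(sc2, spec=GrowthSpec(n_classes=1)).fit(
                seed=s, max_iter=150, tol=1e-7
            )
            g2 = GrowthMixtureModel(sc2, spec=GrowthSpec(n_classes=2)).fit(
                n_starts=4, seed=s, max_iter=150, tol=1e-7
            )
            if g2.ll >= g1.ll and lmr_lrt(g2, g1)["p_value"] < 0.05:
                rejections_alt += 1
        assert rejections_null <= 0.3 * n_rep
        assert rejections_alt >= 0.9 * n_rep

    def test_bootstrap_lrt_runs_and_bounds_p(self):
        coh = generate_cohort(
            default_config(
                200, seed=9, n_classes=2,
                growth_means_per_class=np.array([[75.0, -10.0], [40.0, -25.0]]),
                class_logit_coefficients=np.zeros((1, 7)),
                reference_class=0,
            )
        )
        sc = coh.observed_scores()
        f1 = GrowthMixtureModel(sc, spec=GrowthSpec(n_classes=1)).fit(
            seed=1, max_iter=150, tol=1e-7
        )
        f2 = GrowthMixtureModel(sc, spec=GrowthSpec(n_classes=2)).fit(
            n_starts=4, seed=1, max_iter=150, tol=1e-7
        )
        out = bootstrap_lrt(f2, f1, n_boot=3, seed=3, n_starts=2, max_iter=100)
        assert 0.0 < out["p_value"] <= 1.0
        assert out["lr"] >= 0.0


class TestReportingHelpers:
    def test_class_membership_or_from_printed_logits(self):
        logits = np.array([[0.0, 0.33, -0.39, 0.19], [0.0, 0.0, 0.0, 0.0]])
        table = class_membership_or(logits, 1, ["pa", "smoke", "alcohol"])
        by = {r["covariate"]: r["odds_ratio"] for _, r in table.iterrows()}
        assert round(by["pa"], 2) == 1.39
        assert round(by["smoke"], 2) == 0.68
        assert round(by["alcohol"], 2) == 1.21

    def test_covariance_coverage_complete_and_constructed(self):
        full = pd.DataFrame(
            {"person_id": np.repeat(np.arange(10), 4),
             "wave": np.tile([1, 2, 3, 4], 10),
             "score": np.random.default_rng(0).normal(size=40)}
        )
        cov, m = covariance_coverage(full)
        assert np.allclose(cov, 1.0) and m == 1.0
        half = full.copy()
        half.loc[(half["wave"] == 4) & (half["person_id"] < 5), "score"] = np.nan
        cov2, _ = covariance_coverage(half)
        assert cov2[0, 3] == pytest.approx(0.5)

    def test_covariance_coverage_matches_brute_force(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(40, 4))
        y[rng.random((40, 4)) < 0.3] = np.nan
        keep = ~np.isnan(y).all(axis=1)
        y = y[keep]
        pid, wj = np.nonzero(~np.isnan(y))
        df = pd.DataFrame({"person_id": pid, "wave": wj + 1, "score": y[pid, wj]})
        cov, m = covariance_coverage(df)
        for a in range(4):
            for b_ in range(4):
                brute = np.mean(~np.isnan(y[:, a]) & ~np.isnan(y[:, b_]))
                assert cov[a, b_] == pytest.approx(brute)

    def test_classes_reported_by_descending_intercept(self, two_class_fit):
        res = two_class_fit
        assert np.all(np.diff(res.params.alpha[:, 0]) <= 0)
        row = res.selection_row()
        assert row["n_parameters"] == count_parameters(res.model.spec, 4)
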