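"""Tests of the multilevel 2PNO IRT sampler and its diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import norm

from healthtraj.irt import (
    HealthIRTModel,
    compare_variants,
    compute_dic,
    eap_reliability,
    enforce_identification,
    item_response_prob,
    precision_curve,
    rescale_0_100,
    rhat,
)
from healthtraj.simulate import default_config, generate_cohort


class TestResponseProbability:
    @pytest.mark.parametrize(
        "theta,a,b,expected",
        [(0.0, 1.0, 0.0, 0.5), (1.0, 1.0, 0.0, norm.cdf(1.0)), (0.0, 2.0, 1.0, norm.cdf(-1.0))],
    )
    def test_values(self, theta, a, b, expected):
        assert item_response_prob(theta, a, b) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_theta(self):
        grid = np.linspace(-4, 4, 101)
        p = item_response_prob(grid, 1.3, 0.4)
        assert np.all(np.diff(p) > 0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            item_response_prob(0.0, -1.0, 0.0)
        with pytest.raises(ValueError):
            item_response_prob(np.inf, 1.0, 0.0)


class TestIdentification:
    def test_already_identified_unchanged(self):
        d = enforce_identification(
            {"b": np.array([1.0, -1.0]), "a": np.array([1.0, 1.0]),
             "theta": np.array([0.3, -0.2])}
        )
        assert np.allclose(d["b"], [1, -1]) and np.allclose(d["theta"], [0.3, -0.2])

    def test_recentring_preserves_probabilities(self):
        b = np.array([2.0, 0.0])
        a = np.array([1.0, 1.0])
        theta = np.array([0.5, -1.2, 2.0])
        d = enforce_identification({"b": b, "a": a, "theta": theta})
        assert np.allclose(d["b"], [1.0, -1.0])
        before = ndtr(a[None] * theta[:, None] - b[None])
        after = ndtr(d["a"][None] * d["theta"][:, None] - d["b"][None])
        assert np.allclose(before, after, atol=1e-12)

    def test_rescaling_preserves_probabilities(self):
        b = np.array([0.5, -0.5])
        a = np.array([2.0, 2.0])
        theta = np.array([0.7, -0.3])
        d = enforce_identification({"b": b, "a": a, "theta": theta})
        assert np.allclose(d["a"], [1.0, 1.0])
        before = ndtr(a[None] * theta[:, None] - b[None])
        after = ndtr(d["a"][None] * d["theta"][:, None] - d["b"][None])
        assert np.allclose(before, after, atol=1e-12)

    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(ValueError):
            enforce_identification(
                {"b": np.zeros(2), "a": np.array([1.0, -0.1]), "theta": np.zeros(1)}
            )


class TestSamplerOnSyntheticPanel:
    def test_difficulty_recovery_and_constraints(self, clean_cohort, irt_fit_small):
        res = irt_fit_small
        corr = np.corrcoef(
            clean_cohort.truth["item_difficulty"], res.item_means["b_mean"]
        )[0, 1]
        assert corr > 0.95
        b = res.draws("b_ij")
        a = res.draws("a_ij")
        assert np.nanmax(np.abs(np.nansum(b, axis=2))) < 1e-8
        assert np.nanmax(np.abs(np.nansum(np.log(a), axis=2))) < 1e-8

    def test_wave_means_reproduce_declining_trend(self, irt_fit_small):
        wave_means = irt_fit_small.scores().groupby("wave")["theta_eap"].mean()
        assert np.all(np.diff(wave_means.to_numpy()) < 0)

    def test_scores_table_schema(self, clean_cohort, irt_fit_small):
        s = irt_fit_small.scores()
        assert set(s.columns) >= {"person_id", "wave", "theta_eap", "theta_sd", "score_0_100"}
        assert s["score_0_100"].between(0, 100).all()
        assert (s["theta_sd"] > 0).all()
        obs = clean_cohort.responses.groupby(["person_id", "wave"]).size()
        assert len(s) == len(obs)

    def test_variant1_wave_estimates_equal_across_waves(self):
        cfg = default_config(
            120, seed=8, n_anchor_items=12, n_extra_items=0,
            difficulty_wave_sd=0.0, admin_missing_rate=0.0, attrition_hazard=None,
        )
        coh = generate_cohort(cfg)
        res = HealthIRTModel(coh.responses, variant=1).fit(
            n_iterations=200, n_burnin=50, n_chains=1, seed=2
        )
        b = res.draws("b_ij")
        assert np.nanmax(np.abs(b - b[:, [0], :])) < 1e-10

    def test_variant4_recovers_heterogeneous_items(self):
        from scipy.stats import spearmanr

        n_items = 30
        cfg = default_config(
            2000, seed=42, admin_missing_rate=0.0, attrition_hazard=None,
            n_anchor_items=n_items, n_extra_items=0,
            item_discrimination_means=np.linspace(0.6, 1.6, n_items),
            difficulty_wave_sd=np.linspace(0.05, 0.5, n_items),
            discrimination_wave_sd=0.15,
        )
        coh = generate_cohort(cfg)
        res = HealthIRTModel(coh.responses, variant=4).fit(
            n_iterations=1200, n_burnin=200, n_chains=2, seed=9
        )
        im = res.item_means
        assert np.corrcoef(coh.truth["item_difficulty"], im["b_mean"])[0, 1] > 0.95
        assert np.corrcoef(coh.truth["item_discrimination"], im["a_mean"])[0, 1] > 0.85
        rho = spearmanr(np.linspace(0.05, 0.5, n_items) ** 2, im["sigma2_b"]).statistic
        assert rho > 0

    def test_toy_posterior_matches_grid_integration(self):
        # 2 items, 3 persons, variant 1 with fixed person prior N(0,1) and
        # difficulty prior N(0,1); no identification rescaling, so the
        # sampler targets the plain Bayesian 2PNO posterior.
        panel = pd.DataFrame(
            {
                "person_id": [1, 1, 2, 2, 3, 3],
                "wave": [1] * 6,
                "item_id": [0, 1] * 3,
                "response": [1, 1, 1, 0, 0, 0],
            }
        )
        model = HealthIRTModel(panel, variant=1)
        chains = []
        for seed in range(4):
            res = model.fit(
                n_iterations=4000, n_burnin=500, n_chains=1, seed=seed,
                sample_person_population=False, identify=False,
                difficulty_prior=(0.0, 1.0),
            )
            chains.append(res.theta_eap[:, 0])
        est = np.mean(chains, axis=0)
        mc_se = np.std(chains, axis=0, ddof=1) / 2.0

        # brute-force grid integration over (b1, b2, theta_p)
        bg = np.linspace(-4, 4, 161)
        tg = np.linspace(-6, 6, 241)
        y = np.array([[1, 1], [1, 0], [0, 0]], float)
        pb = norm.pdf(bg)
        pt = norm.pdf(tg)
        num = np.zeros(3)
        den = np.zeros(3)
        # likelihood per person over (theta, b1, b2) factorizes across items
        lik_t_b = {}
        for j in range(2):
            p = ndtr(tg[:, None] - bg[None, :])
            lik_t_b[j] = (p, 1 - p)
        for i in range(3):
            l1 = lik_t_b[0][0 if y[i, 0] else 1]
            l2 = lik_t_b[1][0 if y[i, 1] else 1]
            # L_i(theta, b1, b2) = l1(theta,b1) * l2(theta,b2)
            per_person = np.einsum("tb,tc->tbc", l1, l2)
            lik_t_b[f"L{i}"] = per_person
        for i in range(3):
            integrand = lik_t_b[f"L{i}"] * pt[:, None, None]
            others = [k for k in range(3) if k != i]
            marg_others = np.ones((161, 161))
            for k in others:
                marg_others *= np.einsum(
                    "tbc,t->bc", lik_t_b[f"L{k}"], pt
                )
            joint_b = np.einsum("tbc,bc->tbc", integrand, marg_others)
            w = joint_b * pb[None, :, None] * pb[None, None, :]
            den[i] = w.sum()
            num[i] = (w * tg[:, None, None]).sum()
        grid_eap = num / den
        assert np.all(np.abs(est - grid_eap) < 3 * mc_se + 0.01)


class TestDiagnostics:
    def test_dic_deterministic_given_draws(self, irt_fit_small):
        d1 = compute_dic(irt_fit_small)
        d2 = compute_dic(irt_fit_small)
        assert d1 == d2

    def test_dic_needs_enough_draws(self, clean_cohort):
        res = HealthIRTModel(clean_cohort.responses, variant=1).fit(
            n_iterations=60, n_burnin=20, n_chains=1, seed=0
        )
        with pytest.raises(ValueError, match="100"):
            compute_dic(res)

    def test_eap_reliability_limits(self):
        s = pd.DataFrame({"theta_eap": [0.0, 1.0, 2.0], "theta_sd": [0.0, 0.0, 0.0]})
        assert eap_reliability(s) == pytest.approx(1.0)
        v = np.var([0.0, 1.0, 2.0], ddof=1)
        s2 = pd.DataFrame(
            {"theta_eap": [0.0, 1.0, 2.0], "theta_sd": np.sqrt([v, v, v])}
        )
        assert eap_reliability(s2) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            eap_reliability(pd.DataFrame({"theta_eap": [1.0], "theta_sd": [1.0]}))

    def test_eap_reliability_matches_analytic_target(self, clean_cohort, irt_fit_small):
        rel = eap_reliability(irt_fit_small.scores())
        theta = clean_cohort.truth["theta"]
        b = clean_cohort.truth["item_difficulty_wave"]
        a = clean_cohort.truth["item_discrimination_wave"]
        m = a.T[None] * theta[:, :, None] - b.T[None]
        p = np.clip(ndtr(m), 1e-9, 1 - 1e-9)
        phi = np.exp(-0.5 * m**2) / np.sqrt(2 * np.pi)
        info = np.nansum(a.T[None] ** 2 * phi**2 / (p * (1 - p)), axis=2)
        target = theta.var() / (theta.var() + (1.0 / info).mean())
        assert abs(rel - target) < 0.05

    def test_rhat_on_constructed_chains(self):
        rng = np.random.default_rng(0)
        white = rng.standard_normal((1, 2000))
        two = np.vstack([white, white])
        assert rhat(two) < 1.01
        offset = np.vstack([white, white + 5.0])
        # independent oracle: classic PSRF formula on the four half-chains
        halves = np.concatenate([offset[:, :1000], offset[:, 1000:]], axis=0)
        w = halves.var(axis=1, ddof=1).mean()
        bvar = 1000 * halves.mean(axis=1).var(ddof=1)
        expected = np.sqrt((999 / 1000 * w + bvar / 1000) / w)
        assert rhat(offset) == pytest.approx(expected, rel=1e-12)
        assert rhat(offset) > 1.5

    def test_rhat_affine_invariant_and_matches_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((2, 500)) + np.array([[0.0], [0.3]])
        assert rhat(chains) == pytest.approx(rhat(5.0 * chains - 2.0), rel=1e-12)
        ref = float(arviz.rhat(arviz.convert_to_dataset(chains), method="split")["x"].values)
        assert rhat(chains) == pytest.approx(ref, rel=1e-9)

    def test_rhat_rejects_unsplittable(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 3)))

    def test_rescale_limits_and_clamping(self):
        vals = np.array([-2.0, 0.0, 3.0])
        scores, tr = rescale_0_100(vals)
        assert scores[0] == 0.0 and scores[-1] == 100.0
        assert np.all(np.diff(scores) > 0)
        new, _ = rescale_0_100(np.array([-5.0, 4.0]), tr)
        assert new[0] == 0.0 and new[1] == 100.0
        with pytest.raises(ValueError):
            rescale_0_100(np.array([1.0, 1.0]))

    def test_precision_curve_shape_and_additivity(self):
        grid = np.linspace(-3, 3, 61)
        a = np.ones(30)
        b = np.zeros(30)
        se = precision_curve(a, b, grid)
        assert np.argmin(se) == 30  # information peaks at theta = b = 0
        se2 = precision_curve(np.ones(60), np.zeros(60), grid)
        assert np.allclose(se2, se / np.sqrt(2), atol=1e-12)

    def test_precision_matches_numeric_information(self):
        # expected information = -E[d2/dtheta2 log p(y|theta)], by finite
        # differences of the per-response log-probabilities
        a, b = np.array([1.3]), np.array([0.4])
        grid = np.array([-1.0, 0.0, 0.7, 2.0])
        se = precision_curve(a, b, grid)
        h = 1e-5
        for g, s in zip(grid, se):
            info = 0.0
            for t, lp in [(1, lambda x: np.log(ndtr(a[0] * x - b[0]))),
                          (0, lambda x: np.log(ndtr(-(a[0] * x - b[0]))))]:
                d2 = (lp(g + h) - 2 * lp(g) + lp(g - h)) / h**2
                p = ndtr(a[0] * g - b[0])
                info -= (p if t == 1 else 1 - p) * d2
            assert 1.0 / np.sqrt(info) == pytest.approx(s, abs=1e-4)

    def test_precision_curve_empty_grid(self):
        with pytest.raises(ValueError):
            precision_curve(np.ones(3), np.zeros(3), np.array([]))


class TestVariantComparison:
    def test_comparison_table_and_selection(self, clean_cohort):
        fits = {}
        for v in (1, 2, 3, 4):
            fits[v] = HealthIRTModel(clean_cohort.responses, variant=v).fit(
                n_iterations=250, n_burnin=50, n_chains=2, seed=3 + v
            )
        table, selected = compare_variants(fits)
        assert len(table) == 4
        assert set(table["variant"]) == {1, 2, 3, 4}
        assert {"dic", "eap_reliability", "rhat_max", "converged"} <= set(table.columns)
        assert selected in (1, 2, 3, 4)

    def test_tie_break_is_deterministic(self, irt_fit_small):
        table, selected = compare_variants({1: irt_fit_small, 2: irt_fit_small})
        # identical fits: lower variant id wins the documented tie-break
        assert selected == 1
        assert len(table) == 2
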