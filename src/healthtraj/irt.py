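"""Bayesian multilevel two-parameter normal-ogive (2PNO) IRT health metric.

The measurement model for binary difficulty indicators is

    P(y_pij = 1 | theta_pj) = Phi(a_ij * theta_pj - b_ij)

with person-wave latent health ``theta_pj ~ N(mu_j, sigma_j^2)`` and
wave-varying item parameters treated as random deviations from item-level
means: ``b_ij ~ N(b_i, sigma_b,i^2)``, ``a_ij ~ N(a_i, sigma_a,i^2)``.
Item means carry hyperpriors ``b_i ~ N(mu_b, omega_b^2)`` and
``a_i ~ N(1, omega_a^2)`` (truncated positive).

Four variance-structure variants are supported:

1. no wave variance in either parameter (``b_ij = b_i``, ``a_ij = 1``);
2. item-specific difficulty variance, discriminations fixed at 1;
3. a single difficulty variance shared by all items, discriminations 1;
4. item-specific difficulty *and* discrimination variances with the
   hyperprior parameters (``mu_b``, ``omega_b^2``, ``omega_a^2``) estimated.

Estimation is by Gibbs sampling with truncated-normal data augmentation
for the probit likelihood. For identification, on every iteration and in
every wave the difficulties are recentred so they sum to zero and the
discriminations rescaled so their product is one, with the transformation
absorbed into the latent trait (likelihood-invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "HealthIRTModel",
    "IRTResults",
    "IrtDiagnostics",
    "item_response_prob",
    "enforce_identification",
    "compute_dic",
    "eap_reliability",
    "rhat",
    "rescale_0_100",
    "precision_curve",
    "compare_variants",
]

_EPS = 1e-12


def item_response_prob(theta, a, b):
    """2PNO response probability Phi(a*theta - b)."""
    theta, a, b = (np.asarray(v, float) for v in (theta, a, b))
    if np.any(a <= 0):
        raise ValueError("discrimination must be positive")
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite input")
    return ndtr(a * theta - b)


def _sample_truncnorm(rng, mean, y):
    """Truncated-normal draws for probit augmentation, unit variance.

    y = 1 -> truncated to (0, inf); y = 0 -> (-inf, 0). NaN passes through.
    Inverse-CDF method on ndtr/ndtri, stable for |mean| up to ~8.
    """
    u = rng.random(mean.shape)
    lo = ndtr(-mean)  # P(Z + mean <= 0)
    p = np.where(y == 1.0, lo + u * (1.0 - lo), u * lo)
    p = np.clip(p, 1e-15, 1.0 - 1e-15)
    z = mean + ndtri(p)
    return np.where(np.isnan(y), np.nan, z)


def enforce_identification(draw: dict) -> dict:
    """Rescale one wave's parameters onto the identified scale.

    Difficulties are recentred (``b_ij -= a_ij * delta`` with
    ``delta = sum(b)/sum(a)``, so they sum to zero) and discriminations
    divided by their geometric mean; the trait absorbs both so that every
    response probability Phi(a*theta - b) is unchanged.
    """
    b = np.asarray(draw["b"], float).copy()
    a = np.asarray(draw["a"], float).copy()
    theta = np.asarray(draw["theta"], float).copy()
    if np.any(a <= 0):
        raise ValueError("discrimination must be positive")
    delta = b.sum() / a.sum()
    b -= a * delta
    theta -= delta
    g = np.exp(np.mean(np.log(a)))
    a /= g
    theta *= g
    out = {"b": b, "a": a, "theta": theta}
    if "mu" in draw:
        out["mu"] = (draw["mu"] - delta) * g
    if "sigma" in draw:
        out["sigma"] = draw["sigma"] * g
    return out


@dataclass
class IrtDiagnostics:
    eap_reliability: float
    dic: float
    p_d: float
    se_grid: np.ndarray
    se_values: np.ndarray
    frac_se_below_half: float
    rhat: dict
    rhat_max: float
    converged: bool
    warnings: list = field(default_factory=list)


class HealthIRTModel:
    """Multilevel 2PNO IRT model for a long-format binary response panel.

    Parameters
    ----------
    panel : DataFrame with columns person_id, wave, item_id, response.
    variant : 1..4, the wave-variance structure (see module docstring).
    """

    def __init__(self, panel: pd.DataFrame, variant: int = 3):
        if variant not in (1, 2, 3, 4):
            raise ValueError("variant must be 1, 2, 3 or 4")
        self.variant = variant
        panel = panel.dropna(subset=["response"])
        self.person_ids = np.sort(panel["person_id"].unique())
        self.item_ids = np.sort(panel["item_id"].unique())
        self.waves = np.sort(panel["wave"].unique())
        p_idx = pd.Series(np.arange(len(self.person_ids)), index=self.person_ids)
        i_idx = pd.Series(np.arange(len(self.item_ids)), index=self.item_ids)
        w_idx = pd.Series(np.arange(len(self.waves)), index=self.waves)
        P, I, J = len(self.person_ids), len(self.item_ids), len(self.waves)
        y = np.full((P, J, I), np.nan)
        y[
            p_idx[panel["person_id"]].to_numpy(),
            w_idx[panel["wave"]].to_numpy(),
            i_idx[panel["item_id"]].to_numpy(),
        ] = panel["response"].to_numpy(float)
        self.y = y
        self.item_in_wave = np.zeros((J, I), dtype=bool)
        for j in range(J):
            self.item_in_wave[j] = ~np.isnan(y[:, j, :]).all(axis=0)
        for j in range(J):
            if self.item_in_wave[j].sum() < 2:
                raise ValueError(f"wave {self.waves[j]} has fewer than 2 items")
        # constant items cannot inform their wave parameters
        self.degenerate = np.zeros((J, I), dtype=bool)
        for j in range(J):
            for i in np.nonzero(self.item_in_wave[j])[0]:
                vals = y[:, j, i]
                vals = vals[~np.isnan(vals)]
                if vals.size and (vals.min() == vals.max()):
                    self.degenerate[j, i] = True

    # -- Gibbs sampler ------------------------------------------------------

    def fit(
        self,
        n_iterations: int = 7000,
        n_burnin: int = 100,
        n_chains: int = 2,
        thin: int = 1,
        seed: int | None = None,
        sample_person_population: bool = True,
        identify: bool = True,
        difficulty_prior: tuple[float, float] = (0.0, 100.0),
    ) -> "IRTResults":
        if n_burnin >= n_iterations:
            raise ValueError("burn-in must be shorter than the chain")
        if n_chains < 1:
            raise ValueError("need at least one chain")
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        chains = [
            self._run_chain(
                n_iterations,
                n_burnin,
                thin,
                child,
                sample_person_population,
                identify,
                difficulty_prior,
            )
            for child in ss.spawn(n_chains)
        ]
        return IRTResults(self, chains, n_iterations, n_burnin, n_chains)

    def _run_chain(
        self,
        n_iter,
        burnin,
        thin,
        seedseq,
        sample_pop,
        identify,
        difficulty_prior,
    ):
        rng = np.random.default_rng(seedseq)
        y = self.y
        P, J, I = y.shape
        obs = ~np.isnan(y)
        n_obs_pw = obs.sum(axis=2)  # persons x waves
        has_wave = n_obs_pw > 0
        variant = self.variant
        b0_mean, b0_var = difficulty_prior

        # state
        theta = np.zeros((P, J))
        mu = np.zeros(J)
        sigma2 = np.ones(J)
        b_i = np.zeros(I)
        a_i = np.ones(I)
        b_ij = np.zeros((J, I))
        a_ij = np.ones((J, I))
        s2_b = np.full(I, 0.1)  # difficulty wave variance (shared if variant 3)
        s2_a = np.full(I, 0.05)
        mu_b, om2_b, om2_a = 0.0, 1.0, 0.25
        iw = self.item_in_wave
        deg = self.degenerate
        active = iw & ~deg  # item-waves whose parameters are updated

        n_keep = (n_iter - burnin) // thin
        store = {
            "b_i": np.empty((n_keep, I)),
            "a_i": np.empty((n_keep, I)),
            "b_ij": np.empty((n_keep, J, I)),
            "a_ij": np.empty((n_keep, J, I)),
            "mu": np.empty((n_keep, J)),
            "sigma2": np.empty((n_keep, J)),
            "s2_b": np.empty((n_keep, I)),
            "s2_a": np.empty((n_keep, I)),
            "hyper": np.empty((n_keep, 3)),
            "deviance": np.empty(n_keep),
        }
        # running moments for theta (full draws are too large to keep)
        t_sum = np.zeros((P, J))
        t_sumsq = np.zeros((P, J))
        kept = 0

        yj_cols = [np.nonzero(iw[j])[0] for j in range(J)]

        for it in range(n_iter):
            # 1) augmented responses
            m = a_ij[None] * theta[:, :, None] - b_ij[None]
            z = _sample_truncnorm(rng, m, y)

            # 2) latent trait per person-wave
            a2 = np.where(obs, a_ij[None] ** 2, 0.0).sum(axis=2)
            prec = 1.0 / sigma2 + a2
            num = mu / sigma2 + np.nansum(a_ij[None] * (z + b_ij[None]), axis=2)
            # persons unobserved in a wave fall back to the prior automatically
            theta = num / prec + rng.standard_normal((P, J)) / np.sqrt(prec)

            # 3) wave population
            if sample_pop:
                for j in range(J):
                    tj = theta[has_wave[:, j], j]
                    nj = tj.size
                    v = 1.0 / (nj / sigma2[j] + 1.0 / 100.0)
                    mu[j] = v * (tj.sum() / sigma2[j]) + np.sqrt(v) * rng.standard_normal()
                    sse = np.sum((tj - mu[j]) ** 2)
                    sigma2[j] = 1.0 / rng.gamma(1.0 + nj / 2.0, 1.0 / (1.0 + sse / 2.0))

            # 4) item parameters
            resid_b = a_ij[None] * theta[:, :, None] - z  # = b + noise where obs
            if variant == 1:
                # single b per item pooled over waves
                cnt = obs.sum(axis=(0, 1))
                s = np.nansum(resid_b, axis=(0, 1))
                prec_b = cnt + 1.0 / b0_var
                mean_b = (s + b0_mean / b0_var) / prec_b
                b_i = mean_b + rng.standard_normal(I) / np.sqrt(prec_b)
                b_ij = np.where(iw, b_i[None], np.nan)
            else:
                cnt = obs.sum(axis=0)  # J x I
                s = np.nansum(resid_b, axis=0)
                prec_b = cnt + 1.0 / s2_b[None]
                mean_b = (s + b_i[None] / s2_b[None]) / prec_b
                prop = mean_b + rng.standard_normal((J, I)) / np.sqrt(prec_b)
                b_ij = np.where(active, prop, b_ij)
                b_ij = np.where(deg & iw, b_i[None], b_ij)
                b_ij[~iw] = np.nan
                # item-mean difficulties given wave deviations
                J_i = active.sum(axis=0).astype(float)
                sb = np.where(active, b_ij, 0.0).sum(axis=0)
                prec_bi = J_i / s2_b + 1.0 / (om2_b if variant == 4 else b0_var)
                mean_bi = (sb / s2_b + (mu_b if variant == 4 else b0_mean) / (om2_b if variant == 4 else b0_var)) / prec_bi
                b_i = mean_bi + rng.standard_normal(I) / np.sqrt(prec_bi)
                # variance components
                dev2 = np.where(active, (b_ij - b_i[None]) ** 2, 0.0).sum(axis=0)
                if variant == 3:
                    sse = dev2.sum()
                    ndev = active.sum()
                    s2 = 1.0 / rng.gamma(2.0 + ndev / 2.0, 1.0 / (0.2 + sse / 2.0))
                    s2_b[:] = s2
                else:
                    s2_b = 1.0 / rng.gamma(2.0 + J_i / 2.0, 1.0 / (0.2 + dev2 / 2.0))

            if variant == 4:
                # wave discriminations (truncated positive)
                th2 = np.where(obs, theta[:, :, None] ** 2, 0.0).sum(axis=0)
                szb = np.nansum(theta[:, :, None] * (z + b_ij[None]), axis=0)
                prec_a = th2 + 1.0 / s2_a[None]
                mean_a = (szb + a_i[None] / s2_a[None]) / prec_a
                sd_a = 1.0 / np.sqrt(prec_a)
                u = rng.random((J, I))
                lo = ndtr(-mean_a / sd_a)
                prop = mean_a + sd_a * ndtri(np.clip(lo + u * (1 - lo), 1e-15, 1 - 1e-15))
                a_ij = np.where(active, np.maximum(prop, 1e-6), a_ij)
                a_ij = np.where(deg & iw, a_i[None], a_ij)
                a_ij[~iw] = np.nan
                J_i = active.sum(axis=0).astype(float)
                sa = np.where(active, a_ij, 0.0).sum(axis=0)
                prec_ai = J_i / s2_a + 1.0 / om2_a
                mean_ai = (sa / s2_a + 1.0 / om2_a) / prec_ai
                sd_ai = 1.0 / np.sqrt(prec_ai)
                u = rng.random(I)
                lo = ndtr(-mean_ai / sd_ai)
                a_i = mean_ai + sd_ai * ndtri(np.clip(lo + u * (1 - lo), 1e-15, 1 - 1e-15))
                a_i = np.maximum(a_i, 1e-6)
                dev2 = np.where(active, (a_ij - a_i[None]) ** 2, 0.0).sum(axis=0)
                s2_a = 1.0 / rng.gamma(2.0 + J_i / 2.0, 1.0 / (0.05 + dev2 / 2.0))
                # hyperparameters
                v = 1.0 / (I / om2_b + 1.0 / 100.0)
                mu_b = v * b_i.sum() / om2_b + np.sqrt(v) * rng.standard_normal()
                om2_b = 1.0 / rng.gamma(
                    2.0 + I / 2.0, 1.0 / (0.2 + np.sum((b_i - mu_b) ** 2) / 2.0)
                )
                om2_a = 1.0 / rng.gamma(
                    2.0 + I / 2.0, 1.0 / (0.2 + np.sum((a_i - 1.0) ** 2) / 2.0)
                )
            else:
                a_ij = np.where(iw, 1.0, np.nan)
                a_i = np.ones(I)

            # 5) identification
            if identify:
                for j in range(J):
                    cols = yj_cols[j]
                    bj, aj = b_ij[j, cols], a_ij[j, cols]
                    delta = bj.sum() / aj.sum()
                    b_ij[j, cols] = bj - aj * delta
                    theta[:, j] -= delta
                    mu[j] -= delta
                    if variant == 4:
                        g = np.exp(np.mean(np.log(aj)))
                        a_ij[j, cols] = aj / g
                        theta[:, j] *= g
                        mu[j] *= g
                        sigma2[j] *= g * g
                # keep item means consistent with recentred wave parameters
                if variant == 1:
                    b_i = np.array(
                        [np.nanmean(b_ij[iw[:, i], i]) if iw[:, i].any() else b_i[i] for i in range(I)]
                    )

            # 6) store
            if it >= burnin and (it - burnin) % thin == 0:
                k = kept
                store["b_i"][k] = b_i
                store["a_i"][k] = a_i
                store["b_ij"][k] = b_ij
                store["a_ij"][k] = a_ij
                store["mu"][k] = mu
                store["sigma2"][k] = sigma2
                store["s2_b"][k] = s2_b
                store["s2_a"][k] = s2_a
                store["hyper"][k] = (mu_b, om2_b, om2_a)
                m = a_ij[None] * theta[:, :, None] - b_ij[None]
                p = np.clip(ndtr(m), _EPS, 1 - _EPS)
                ll = np.where(y == 1.0, np.log(p), np.log1p(-p))
                store["deviance"][k] = -2.0 * np.nansum(ll)
                t_sum += theta
                t_sumsq += theta**2
                kept += 1

        for key in store:
            store[key] = store[key][:kept]
        return {
            "store": store,
            "theta_mean": t_sum / kept,
            "theta_var": np.maximum(t_sumsq / kept - (t_sum / kept) ** 2, 0.0),
            "n_kept": kept,
        }


class IRTResults:
    """Posterior summaries, health scores and diagnostics for a fitted
    :class:`HealthIRTModel`."""

    def __init__(self, model, chains, n_iterations, n_burnin, n_chains):
        self.model = model
        self.chains = chains
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.n_chains = n_chains
        self._diag = None
        self._scores = None
        self._transform = None

    # pooled draws across chains
    def draws(self, name) -> np.ndarray:
        return np.concatenate([c["store"][name] for c in self.chains], axis=0)

    @property
    def theta_eap(self) -> np.ndarray:
        w = np.array([c["n_kept"] for c in self.chains], float)
        stacked = np.stack([c["theta_mean"] for c in self.chains])
        return np.einsum("c,cpj->pj", w / w.sum(), stacked)

    @property
    def theta_sd(self) -> np.ndarray:
        w = np.array([c["n_kept"] for c in self.chains], float)
        w = w / w.sum()
        means = np.stack([c["theta_mean"] for c in self.chains])
        variances = np.stack([c["theta_var"] for c in self.chains])
        grand = np.einsum("c,cpj->pj", w, means)
        total = np.einsum("c,cpj->pj", w, variances + (means - grand) ** 2)
        return np.sqrt(np.maximum(total, 1e-12))

    @property
    def item_params(self) -> pd.DataFrame:
        """EAP item-parameter table (one row per item-wave present)."""
        b = self.draws("b_ij")
        a = self.draws("a_ij")
        rows = []
        for j, wave in enumerate(self.model.waves):
            for i, item in enumerate(self.model.item_ids):
                if not self.model.item_in_wave[j, i]:
                    continue
                rows.append(
                    {
                        "item_id": item,
                        "wave": wave,
                        "b": b[:, j, i].mean(),
                        "b_sd": b[:, j, i].std(),
                        "a": a[:, j, i].mean(),
                        "a_sd": a[:, j, i].std(),
                    }
                )
        return pd.DataFrame(rows)

    @property
    def item_means(self) -> pd.DataFrame:
        b = self.draws("b_i")
        a = self.draws("a_i")
        s2b = self.draws("s2_b")
        s2a = self.draws("s2_a")
        return pd.DataFrame(
            {
                "item_id": self.model.item_ids,
                "b_mean": b.mean(axis=0),
                "b_mean_sd": b.std(axis=0),
                "a_mean": a.mean(axis=0),
                "a_mean_sd": a.std(axis=0),
                "sigma2_b": s2b.mean(axis=0),
                "sigma2_a": s2a.mean(axis=0),
            }
        )

    def scores(self) -> pd.DataFrame:
        """HealthScoreTable: one row per observed person-wave."""
        if self._scores is None:
            eap, sd = self.theta_eap, self.theta_sd
            obs = ~np.isnan(self.model.y).all(axis=2)
            pid, wj = np.nonzero(obs)
            vals = eap[pid, wj]
            scored, transform = rescale_0_100(vals, self._transform)
            self._transform = transform
            self._scores = pd.DataFrame(
                {
                    "person_id": self.model.person_ids[pid],
                    "wave": self.model.waves[wj],
                    "theta_eap": vals,
                    "theta_sd": sd[pid, wj],
                    "score_0_100": scored,
                }
            )
        return self._scores

    @property
    def transform(self):
        self.scores()
        return self._transform

    # -- diagnostics --------------------------------------------------------

    def _monitored(self) -> dict:
        """Per-chain draws of monitored scalar parameters."""
        out = {}
        for j, wave in enumerate(self.model.waves):
            out[f"mu[{wave}]"] = np.stack(
                [c["store"]["mu"][:, j] for c in self.chains]
            )
            out[f"sigma2[{wave}]"] = np.stack(
                [c["store"]["sigma2"][:, j] for c in self.chains]
            )
        b = [c["store"]["b_i"] for c in self.chains]
        for i, item in enumerate(self.model.item_ids):
            out[f"b[{item}]"] = np.stack([bb[:, i] for bb in b])
        if self.model.variant == 4:
            a = [c["store"]["a_i"] for c in self.chains]
            for i, item in enumerate(self.model.item_ids):
                out[f"a[{item}]"] = np.stack([aa[:, i] for aa in a])
        if self.model.variant in (2, 3, 4):
            s = [c["store"]["s2_b"] for c in self.chains]
            if self.model.variant == 3:
                out["sigma2_b"] = np.stack([ss[:, 0] for ss in s])
            else:
                for i, item in enumerate(self.model.item_ids):
                    out[f"sigma2_b[{item}]"] = np.stack([ss[:, i] for ss in s])
        return out

    def diagnostics(self, se_grid=None) -> IrtDiagnostics:
        if self._diag is not None and se_grid is None:
            return self._diag
        warns = []
        rel = eap_reliability(self.scores())
        dic, p_d = compute_dic(self)
        if se_grid is None:
            se_grid = np.linspace(-3, 3, 61)
        ip = self.item_params
        first = ip[ip["wave"] == self.model.waves[0]]
        se_vals = precision_curve(first["a"].to_numpy(), first["b"].to_numpy(), se_grid)
        frac = float(np.mean(se_vals < 0.5))
        rh = {}
        if self.n_chains >= 2 or self.chains[0]["n_kept"] >= 4:
            for name, arr in self._monitored().items():
                rh[name] = rhat(arr)
        rmax = max(rh.values()) if rh else np.nan
        converged = bool(rmax <= 1.1) if np.isfinite(rmax) else False
        if not converged:
            warns.append(f"max R-hat {rmax:.3f} exceeds 1.1; treat results with caution")
            warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)
        self._diag = IrtDiagnostics(
            eap_reliability=rel,
            dic=dic,
            p_d=p_d,
            se_grid=np.asarray(se_grid),
            se_values=se_vals,
            frac_se_below_half=frac,
            rhat=rh,
            rhat_max=rmax,
            converged=converged,
            warnings=warns,
        )
        return self._diag

    def summary(self) -> str:
        d = self.diagnostics()
        lines = [
            "Bayesian multilevel 2PNO IRT fit",
            "=" * 40,
            f"variant:            {self.model.variant}",
            f"persons:            {len(self.model.person_ids)}",
            f"items:              {len(self.model.item_ids)}",
            f"waves:              {len(self.model.waves)}",
            f"chains x draws:     {self.n_chains} x {self.chains[0]['n_kept']}",
            f"EAP reliability:    {d.eap_reliability:.3f}",
            f"DIC:                {d.dic:.1f} (p_D = {d.p_d:.1f})",
            f"SE<0.5 fraction:    {d.frac_se_below_half:.2f}",
            f"max R-hat:          {d.rhat_max:.3f} ({'ok' if d.converged else 'NOT converged'})",
        ]
        wave_means = self.scores().groupby("wave")["score_0_100"].mean()
        lines.append("mean score by wave: " + ", ".join(f"{w}:{m:.1f}" for w, m in wave_means.items()))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# diagnostics as standalone operations


def compute_dic(fit: IRTResults) -> tuple[float, float]:
    """Deviance information criterion with Spiegelhalter's p_D
    (mean deviance minus deviance at posterior means)."""
    dev = fit.draws("deviance")
    if dev.size < 100:
        raise ValueError("need at least 100 post-burn-in draws for DIC")
    mean_dev = float(dev.mean())
    b = fit.draws("b_ij").mean(axis=0)
    a = fit.draws("a_ij").mean(axis=0)
    theta = fit.theta_eap
    y = fit.model.y
    m = a[None] * theta[:, :, None] - b[None]
    p = np.clip(ndtr(m), _EPS, 1 - _EPS)
    ll = np.where(y == 1.0, np.log(p), np.log1p(-p))
    dev_at_mean = float(-2.0 * np.nansum(ll))
    p_d = mean_dev - dev_at_mean
    return mean_dev + p_d, p_d


def eap_reliability(scores: pd.DataFrame) -> float:
    """EAP reliability: var(EAP) / (var(EAP) + mean posterior variance),
    pooled over person-waves."""
    if len(scores) < 2:
        raise ValueError("need at least two person-waves")
    v_eap = float(np.var(scores["theta_eap"], ddof=1))
    m_pv = float(np.mean(scores["theta_sd"] ** 2))
    if v_eap + m_pv <= 0:
        raise ValueError("degenerate: no variance in EAPs or posteriors")
    return v_eap / (v_eap + m_pv)


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is (n_chains, n_draws); each chain is split in half, then
    the classic PSRF formula is applied to the 2*n_chains half-chains.
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-D (n_chains, n_draws)")
    n = chains.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short to split")
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w <= 1e-300:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def rescale_0_100(theta, transform=None):
    """Affine map of EAP traits onto 0-100 (higher = better health).

    With ``transform=None`` the pooled min/max of ``theta`` define the map
    and are returned for reuse; with stored constants, new values are
    mapped and clamped to [0, 100].
    """
    theta = np.asarray(theta, float)
    if theta.size == 0:
        raise ValueError("empty input")
    if transform is None:
        lo, hi = float(np.nanmin(theta)), float(np.nanmax(theta))
        if hi <= lo:
            raise ValueError("degenerate range: min equals max")
        transform = (lo, hi)
    lo, hi = transform
    scores = 100.0 * (theta - lo) / (hi - lo)
    return np.clip(scores, 0.0, 100.0), transform


def precision_curve(a, b, theta_grid) -> np.ndarray:
    """Probit-scale standard error of measurement over a trait grid:
    SE(theta) = 1/sqrt(I(theta)) with Fisher information
    I = sum_i a_i^2 phi(a theta - b)^2 / (P (1 - P))."""
    theta_grid = np.asarray(theta_grid, float)
    if theta_grid.size == 0:
        raise ValueError("empty grid")
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[:, None]
    m = a * theta_grid[None] - b
    p = np.clip(ndtr(m), _EPS, 1 - _EPS)
    phi = np.exp(-0.5 * m**2) / np.sqrt(2 * np.pi)
    info = (a**2 * phi**2 / (p * (1 - p))).sum(axis=0)
    return 1.0 / np.sqrt(info)


def compare_variants(fits: dict) -> tuple[pd.DataFrame, int]:
    """Variant comparison table and the selected variant.

    Selection: lowest DIC among converged fits (max R-hat <= 1.1); ties
    broken by higher EAP reliability, then lower variant id. If no fit
    converged, the rule is applied to all fits and a warning recorded.
    """
    rows = []
    for vid, fit in sorted(fits.items()):
        d = fit.diagnostics()
        rows.append(
            {
                "variant": vid,
                "eap_reliability": d.eap_reliability,
                "dic": d.dic,
                "frac_se_below_half": d.frac_se_below_half,
                "rhat_max": d.rhat_max,
                "converged": d.converged,
            }
        )
    table = pd.DataFrame(rows)
    pool = table[table["converged"]] if table["converged"].any() else table
    pool = pool.sort_values(
        ["dic", "eap_reliability", "variant"], ascending=[True, False, True]
    )
    return table, int(pool.iloc[0]["variant"])
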