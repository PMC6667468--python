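"""Growth curves and conditional growth mixture models (GMM).

The trajectory model for a health score measured at ``J`` waves is a latent
growth curve: person ``p`` in class ``k`` has growth factors
``eta_p = (I_p, S_p)`` (intercept and total-change slope; plus a quadratic
factor when requested) with

    eta_p | C=k, x_p  ~  N(alpha_k + Gamma_k x_p, Psi)
    y_pj              =  [1, lambda_j] eta_p + eps_pj,   eps_pj ~ N(0, s2_j)

``lambda`` is anchored at 0 (first wave) and 1 (last wave); under the
latent-basis pattern the middle loadings are free, so the slope is the
total first-to-last-wave change and the loadings trace its shape. The
growth covariance ``Psi`` and the wave residual variances are shared
across classes. Class membership follows a multinomial logistic model on
the covariates (one-step inclusion), and a binary distal outcome (death
by end of follow-up) is Bernoulli with class-specific probability,
conditionally independent of the trajectory given class:

    L_p = sum_k P(C=k|x_p) N(y_p,obs; mu_k, Sigma_obs) pi_k^d (1-pi_k)^(1-d)

Estimation is maximum likelihood via EM (full-information over observed
waves, i.e. MAR missingness handled without imputation), with multistart
to escape local maxima. Robust (sandwich) standard errors are available
by numerical differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import chi2

__all__ = [
    "GrowthSpec",
    "GmmParameters",
    "GrowthCurveModel",
    "GrowthMixtureModel",
    "GMMResults",
    "fit_growth_single",
    "posterior_classes",
    "entropy",
    "bic_ssabic",
    "count_parameters",
    "lmr_lrt",
    "bootstrap_lrt",
    "class_membership_or",
    "covariance_coverage",
    "select_n_classes",
]

_VAR_FLOOR = 1e-4
_DEFAULT_TIMES = np.array([0.0, 2.0, 11.0, 14.0])


@dataclass
class GrowthSpec:
    """Shape and structure of a (mixture of) growth model(s)."""

    pattern: str = "latent_basis"  # linear | latent_basis | quadratic
    n_classes: int = 1
    covariates: tuple = ()
    distal_outcome: bool = False
    times: np.ndarray | None = None

    def __post_init__(self):
        if self.pattern not in ("linear", "latent_basis", "quadratic"):
            raise ValueError("pattern must be linear, latent_basis or quadratic")
        if self.n_classes < 1:
            raise ValueError("need at least one class")

    @property
    def n_factors(self) -> int:
        return 3 if self.pattern == "quadratic" else 2


def count_parameters(spec: GrowthSpec, n_waves: int = 4) -> int:
    """Free-parameter count of the declared parameterization.

    Class-specific: growth-factor means, covariate effects on each factor,
    and (optionally) a distal threshold. Non-reference class logits.
    Shared: free basis loadings, growth (co)variances, wave residuals.
    """
    k, f, q = spec.n_classes, spec.n_factors, len(spec.covariates)
    free_load = n_waves - 2 if spec.pattern == "latent_basis" else 0
    per_class = f + f * q + (1 if spec.distal_outcome else 0)
    logits = (k - 1) * (q + 1)
    shared = free_load + f * (f + 1) // 2 + n_waves
    return k * per_class + logits + shared


def bic_ssabic(ll: float, n_parameters: int, n: int) -> tuple[float, float]:
    """BIC and the sample-size-adjusted BIC (penalty log((n+2)/24))."""
    if n <= 0:
        raise ValueError("n must be positive")
    bic = -2.0 * ll + n_parameters * np.log(n)
    ssabic = -2.0 * ll + n_parameters * np.log((n + 2.0) / 24.0)
    return float(bic), float(ssabic)


def entropy(posterior: np.ndarray) -> float:
    """Relative entropy of a posterior class-probability matrix:
    1 - sum(-p log p) / (N log K); 1 = perfect separation."""
    p = np.asarray(posterior, float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("posterior must be (N, K) with K >= 2")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    n, k = p.shape
    return float(1.0 + plogp.sum() / (n * np.log(k)))


def covariance_coverage(scores: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Pairwise proportion of persons with both waves observed.

    Returns the wave-pair coverage matrix and its minimum; warns when the
    minimum drops below 0.10, a conventional feasibility floor for FIML.
    """
    wide = scores.pivot_table(index="person_id", columns="wave", values="score")
    obs = wide.notna().to_numpy(float)
    n = obs.shape[0]
    cov = obs.T @ obs / n
    m = float(cov.min())
    if m < 0.10:
        warnings.warn(f"minimum covariance coverage {m:.3f} below 0.10", RuntimeWarning)
    return cov, m


# ---------------------------------------------------------------------------


class _EmptyClassError(RuntimeError):
    pass


@dataclass
class GmmParameters:
    alpha: np.ndarray  # (K, F)
    gamma: np.ndarray  # (K, F, q)
    beta: np.ndarray  # (K-1, q+1), logits vs internal reference (last class)
    pi: np.ndarray  # (K,)
    lam: np.ndarray  # (J,) loadings of the slope factor (0..1 anchored)
    psi: np.ndarray  # (F, F)
    sigma2: np.ndarray  # (J,)

    def copy(self):
        return GmmParameters(*(np.array(getattr(self, f.name)) for f in
                         self.__dataclass_fields__.values()))


class GrowthMixtureModel:
    """Conditional growth mixture model with a distal binary outcome.

    Parameters
    ----------
    scores : long DataFrame (person_id, wave, score).
    covariates : DataFrame indexed or keyed by person_id containing the
        columns named in ``spec.covariates`` (listwise deletion applied;
        the dropped count is stored as ``n_dropped_covariates``).
    mortality : DataFrame (person_id, dead) or None; persons with missing
        status contribute no distal factor.
    spec : GrowthSpec.
    """

    def __init__(self, scores, covariates=None, mortality=None, spec=None):
        self.spec = spec or GrowthSpec()
        wide = scores.pivot_table(index="person_id", columns="wave", values="score")
        wide = wide.sort_index()
        self.waves = np.sort(np.asarray(wide.columns))
        self.n_dropped_empty = int((wide.isna().all(axis=1)).sum())
        wide = wide.dropna(how="all")

        q = len(self.spec.covariates)
        if q and covariates is None:
            raise ValueError("spec names covariates but none were supplied")
        if q:
            cov = covariates.set_index("person_id") if "person_id" in covariates else covariates
            cov = cov.reindex(wide.index)[list(self.spec.covariates)]
            keep = cov.notna().all(axis=1)
            self.n_dropped_covariates = int((~keep).sum())
            wide, cov = wide[keep.to_numpy()], cov[keep.to_numpy()]
            self.x = cov.to_numpy(float)
        else:
            self.n_dropped_covariates = 0
            self.x = np.empty((len(wide), 0))

        self.person_ids = wide.index.to_numpy()
        self.y = wide.to_numpy(float)
        self.n, self.J = self.y.shape
        if self.J < 3:
            raise ValueError("need at least three waves")
        if self.spec.pattern == "quadratic" and self.J < 4:
            raise ValueError("quadratic pattern needs four waves")

        if self.spec.distal_outcome:
            if mortality is None:
                raise ValueError("distal outcome requested but no mortality given")
            mort = mortality.set_index("person_id")["dead"].reindex(self.person_ids)
            self.d = mort.to_numpy(float)  # NaN = unknown status
        else:
            self.d = np.full(self.n, np.nan)

        t = self.spec.times
        if t is None:
            t = _DEFAULT_TIMES[: self.J] if self.J <= 4 else np.arange(self.J, dtype=float)
        t = np.asarray(t, float)
        self.times = (t - t[0]) / (t[-1] - t[0])

        # missing-data patterns
        obs = ~np.isnan(self.y)
        codes = obs @ (1 << np.arange(self.J))
        self.pattern_of = np.unique(codes, return_inverse=True)[1]
        self.patterns = []
        for c in np.unique(self.pattern_of):
            rows = np.nonzero(self.pattern_of == c)[0]
            self.patterns.append((rows, np.nonzero(obs[rows[0]])[0]))

        self.u = np.column_stack([np.ones(self.n), self.x])  # logit design

    # -- likelihood machinery ----------------------------------------------

    def _basis(self, lam: np.ndarray) -> np.ndarray:
        if self.spec.pattern == "quadratic":
            return np.column_stack([np.ones(self.J), self.times, self.times**2])
        return np.column_stack([np.ones(self.J), lam])

    def _log_components(self, p: GmmParameters):
        """(n, K) matrix: log P(C=k|x) + log N(y_obs) + log Bern(d)."""
        K = self.spec.n_classes
        out = np.empty((self.n, K))
        # class priors
        if K > 1:
            logits = np.zeros((self.n, K))
            logits[:, :-1] = self.u @ p.beta.T
            out[:] = logits - logsumexp(logits, axis=1, keepdims=True)
        else:
            out[:] = 0.0
        lamfull = self._basis(p.lam)
        for rows, o in self.patterns:
            L = lamfull[o]  # |o| x F
            sig = L @ p.psi @ L.T + np.diag(p.sigma2[o])
            sign, logdet = np.linalg.slogdet(sig)
            siginv = np.linalg.inv(sig)
            yo = self.y[np.ix_(rows, o)]
            for k in range(K):
                mu = (p.alpha[k] + self.x[rows] @ p.gamma[k].T) @ L.T
                r = yo - mu
                quad = np.einsum("ij,jk,ik->i", r, siginv, r)
                out[rows, k] += -0.5 * (len(o) * np.log(2 * np.pi) + logdet + quad)
        if self.spec.distal_outcome:
            known = ~np.isnan(self.d)
            dd = self.d[known, None]
            pi = np.clip(p.pi, 1e-10, 1 - 1e-10)
            out[known] += dd * np.log(pi)[None] + (1 - dd) * np.log1p(-pi)[None]
        return out

    def loglik(self, p: GmmParameters) -> float:
        return float(logsumexp(self._log_components(p), axis=1).sum())

    def _responsibilities(self, p: GmmParameters):
        lc = self._log_components(p)
        ll = logsumexp(lc, axis=1)
        return np.exp(lc - ll[:, None]), float(ll.sum())

    # -- EM ----------------------------------------------------------------

    def _m_step(self, p: GmmParameters, r: np.ndarray) -> GmmParameters:
        K, F = self.spec.n_classes, self.spec.n_factors
        q = self.x.shape[1]
        new = p.copy()
        lamfull = self._basis(p.lam)
        U = np.column_stack([np.ones(self.n), self.x])  # (n, q+1) regression design

        # factor posterior moments per class (depends on pattern)
        ehat = np.empty((self.n, K, F))
        vmat = np.empty((self.n, K, F, F))
        for rows, o in self.patterns:
            L = lamfull[o]
            sig = L @ p.psi @ L.T + np.diag(p.sigma2[o])
            siginv = np.linalg.inv(sig)
            B = p.psi @ L.T @ siginv  # F x |o|
            V = p.psi - B @ L @ p.psi
            yo = self.y[np.ix_(rows, o)]
            for k in range(K):
                M = p.alpha[k] + self.x[rows] @ p.gamma[k].T  # n_pat x F
                e = M + (yo - M @ L.T) @ B.T
                ehat[rows, k] = e
                vmat[rows, k] = V

        # class-specific mean structure: eta ~ A_k u
        for k in range(K):
            w = r[:, k]
            uw = U * w[:, None]
            g = np.linalg.solve(uw.T @ U, uw.T @ ehat[:, k])  # (q+1, F)
            new.alpha[k] = g[0]
            new.gamma[k] = g[1:].T

        # shared growth covariance
        psi = np.zeros((F, F))
        for k in range(K):
            mu = new.alpha[k] + self.x @ new.gamma[k].T
            dev = ehat[:, k] - mu
            psi += np.einsum("n,nij->ij", r[:, k], vmat[:, k])
            psi += (dev * r[:, [k]]).T @ dev
        psi /= self.n
        psi = (psi + psi.T) / 2
        ev, evec = np.linalg.eigh(psi)
        new.psi = (evec * np.maximum(ev, 1e-8)) @ evec.T

        # second moments of eta for loadings / residuals
        m2 = vmat + np.einsum("nkf,nkg->nkfg", ehat, ehat)  # (n,K,F,F)

        # free basis loadings (latent basis pattern, middle waves)
        if self.spec.pattern == "latent_basis":
            for j in range(1, self.J - 1):
                ok = ~np.isnan(self.y[:, j])
                num = den = 0.0
                yj = self.y[ok, j]
                rw = r[ok]
                num = np.sum(rw * (yj[:, None] * ehat[ok, :, 1] - m2[ok, :, 0, 1]))
                den = np.sum(rw * m2[ok, :, 1, 1])
                new.lam[j] = num / den
            new.lam[0], new.lam[-1] = 0.0, 1.0
        lamnew = self._basis(new.lam)

        # wave residual variances (shared across classes)
        for j in range(self.J):
            ok = ~np.isnan(self.y[:, j])
            lj = lamnew[j]
            yj = self.y[ok, j]
            fitted = np.einsum("nkf,f->nk", ehat[ok], lj)
            quad = np.einsum("f,nkfg,g->nk", lj, m2[ok], lj)
            val = np.sum(r[ok] * (yj[:, None] ** 2 - 2 * yj[:, None] * fitted + quad))
            new.sigma2[j] = max(val / r[ok].sum(), _VAR_FLOOR)

        # distal probabilities
        if self.spec.distal_outcome:
            known = ~np.isnan(self.d)
            if known.any():
                rk = r[known]
                new.pi = np.clip(
                    (rk * self.d[known, None]).sum(axis=0) / rk.sum(axis=0),
                    1e-6,
                    1 - 1e-6,
                )

        # class-membership logits: damped Newton on expected log-lik
        if K > 1:
            new.beta = self._update_beta(p.beta, r)

        if np.any(r.sum(axis=0) < 1.0):
            raise _EmptyClassError("a class emptied during EM")
        return new

    def _update_beta(self, beta, r, n_newton=4):
        K = self.spec.n_classes
        u = self.u
        nb, d = beta.shape

        def probs(b):
            logits = np.zeros((self.n, K))
            logits[:, :-1] = u @ b.T
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            return e / e.sum(axis=1, keepdims=True)

        def qfun(b):
            logits = np.zeros((self.n, K))
            logits[:, :-1] = u @ b.T
            lse = logsumexp(logits, axis=1, keepdims=True)
            return float((r * (logits - lse)).sum())

        b = beta.copy()
        q0 = qfun(b)
        for _ in range(n_newton):
            pr = probs(b)
            grad = ((r - pr)[:, :-1, None] * u[:, None, :]).sum(axis=0)  # (K-1, d)
            H = np.zeros((nb * d, nb * d))
            for k in range(nb):
                for l in range(nb):
                    w = pr[:, k] * ((k == l) - pr[:, l])
                    H[k * d : (k + 1) * d, l * d : (l + 1) * d] = -(u * w[:, None]).T @ u
            try:
                step = np.linalg.solve(H - 1e-8 * np.eye(nb * d), grad.ravel())
            except np.linalg.LinAlgError:
                break
            step = -step.reshape(nb, d)
            t = 1.0
            for _ in range(20):
                cand = b + t * step
                qc = qfun(cand)
                if qc >= q0:
                    b, q0 = cand, qc
                    break
                t /= 2
            else:
                break
        return b

    def _em(self, p: GmmParameters, max_iter: int, tol: float):
        r, ll = self._responsibilities(p)
        for it in range(max_iter):
            p = self._m_step(p, r)
            r, ll_new = self._responsibilities(p)
            if ll_new < ll - 1e-8 * max(1.0, abs(ll)):
                raise RuntimeError(
                    f"EM log-likelihood decreased ({ll:.6f} -> {ll_new:.6f})"
                )
            done = ll_new - ll < tol * max(1.0, abs(ll))
            ll = ll_new
            if done:
                break
        return p, ll, r

    # -- initialization ----------------------------------------------------

    def _ols_factors(self) -> np.ndarray:
        """Per-person OLS growth factors on the fixed linear basis
        (crude starting values; NaN-safe)."""
        L = np.column_stack([np.ones(self.J), self.times])
        if self.spec.pattern == "quadratic":
            L = np.column_stack([L, self.times**2])
        F = L.shape[1]
        eta = np.zeros((self.n, F))
        for rows, o in self.patterns:
            Lo = L[o]
            if len(o) >= F:
                pinv = np.linalg.pinv(Lo)
                eta[rows] = self.y[np.ix_(rows, o)] @ pinv.T
            else:
                mean_y = np.nanmean(self.y[rows], axis=1)
                eta[rows, 0] = mean_y
        return eta

    def _base_params(self) -> GmmParameters:
        K, F = self.spec.n_classes, self.spec.n_factors
        q = self.x.shape[1]
        eta = self._ols_factors()
        centers = np.quantile(
            eta[:, 0], np.linspace(0.1, 0.9, K) if K > 1 else [0.5]
        )
        alpha = np.zeros((K, F))
        alpha[:, 0] = centers[::-1]
        alpha[:, 1] = np.nanmedian(eta[:, 1])
        pooled = np.cov(eta[:, :2].T)
        psi = np.eye(F) * np.maximum(np.diag(np.atleast_2d(pooled)).mean(), 1.0)
        resid = np.nanvar(self.y) * 0.3
        d_known = self.d[~np.isnan(self.d)]
        base_pi = d_known.mean() if d_known.size else 0.5
        return GmmParameters(
            alpha=alpha,
            gamma=np.zeros((K, F, q)),
            beta=np.zeros((max(K - 1, 0), q + 1)),
            pi=np.clip(np.full(K, base_pi) + np.linspace(-0.1, 0.1, K), 0.02, 0.98),
            lam=self.times.copy(),
            psi=psi,
            sigma2=np.full(self.J, max(resid, 1.0)),
        )

    def _perturbed(self, base: GmmParameters, rng) -> GmmParameters:
        p = base.copy()
        sd = np.nanstd(self.y)
        p.alpha[:, 0] += rng.uniform(-2, 2, size=p.alpha.shape[0]) * sd * 0.5
        p.alpha[:, 1:] += rng.uniform(-1, 1, size=p.alpha[:, 1:].shape) * sd * 0.3
        if p.beta.size:
            p.beta[:, 0] += rng.normal(0, 0.5, size=p.beta.shape[0])
        p.pi = np.clip(p.pi + rng.uniform(-0.2, 0.2, size=p.pi.shape), 0.02, 0.98)
        return p

    # -- public fit --------------------------------------------------------

    def fit(
        self,
        n_starts: int = 250,
        seed: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-8,
        n_short: int = 15,
        n_final: int = 5,
    ) -> "GMMResults":
        rng = np.random.default_rng(np.random.SeedSequence([seed or 0, 77]))
        base = self._base_params()
        starts = [base] + [self._perturbed(base, rng) for _ in range(n_starts - 1)]
        shorts = []
        for p0 in starts:
            try:
                p1, ll1, _ = self._em(p0, n_short, tol)
                shorts.append((ll1, p1))
            except (_EmptyClassError, np.linalg.LinAlgError):
                continue
        if not shorts:
            raise RuntimeError("no admissible start converged")
        shorts.sort(key=lambda t: -t[0])
        finals = []
        for ll1, p1 in shorts[:n_final]:
            try:
                p2, ll2, r2 = self._em(p1, max_iter, tol)
                finals.append((ll2, p2, r2))
            except (_EmptyClassError, np.linalg.LinAlgError):
                continue
        if not finals:
            raise RuntimeError("no start reached an admissible optimum")
        finals.sort(key=lambda t: -t[0])
        best_ll, best_p, best_r = finals[0]
        replications = sum(1 for ll, *_ in finals if best_ll - ll < 0.01)
        if replications < 2 and len(finals) > 1:
            warnings.warn(
                "best log-likelihood replicated only once across starts",
                RuntimeWarning,
            )
        return GMMResults(self, best_p, best_ll, best_r, replications)


class GrowthCurveModel(GrowthMixtureModel):
    """Single-group latent growth curve (linear, latent basis or quadratic)."""

    def __init__(self, scores, pattern="latent_basis", times=None):
        super().__init__(
            scores, spec=GrowthSpec(pattern=pattern, n_classes=1, times=times)
        )

    def fit(self, seed=None, max_iter=500, tol=1e-8, **kw):
        return super().fit(n_starts=1, seed=seed, max_iter=max_iter, tol=tol)


def fit_growth_single(scores, pattern="latent_basis", times=None, **kw):
    """Convenience wrapper: fit a single-group growth model and return its
    results (growth means, Psi, residuals, LL, BIC, SSABIC)."""
    return GrowthCurveModel(scores, pattern=pattern, times=times).fit(**kw)


# ---------------------------------------------------------------------------


class GMMResults:
    """Estimates, posterior classification and fit statistics for a GMM.

    Classes are relabelled in descending order of intercept mean; logits
    are reported against the largest class as reference.
    """

    def __init__(self, model, params, ll, resp, replications):
        self.model = model
        self.ll = float(ll)
        self.replications = replications
        K = model.spec.n_classes
        order = np.argsort(-params.alpha[:, 0])
        self.params = params.copy()
        self.params.alpha = params.alpha[order]
        self.params.gamma = params.gamma[order]
        self.params.pi = params.pi[order]
        self.posterior = resp[:, order]
        # full logit matrix on the sorted labels, vs largest class
        full = np.zeros((K, model.u.shape[1]))
        if K > 1:
            full[:-1] = params.beta
            full = full[order]
        self.class_shares = self.posterior.mean(axis=0)
        self.reference_class = int(np.argmax(self.class_shares))
        self.logits = full - full[self.reference_class]
        self._se = None

    # -- fit statistics ----------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.model.spec, self.model.J)

    @property
    def bic(self) -> float:
        return bic_ssabic(self.ll, self.n_parameters, self.model.n)[0]

    @property
    def ssabic(self) -> float:
        return bic_ssabic(self.ll, self.n_parameters, self.model.n)[1]

    @property
    def entropy(self) -> float:
        if self.model.spec.n_classes < 2:
            return 1.0
        return entropy(self.posterior)

    @property
    def trajectories(self) -> np.ndarray:
        """Model-implied mean score per class and wave (at covariate 0)."""
        L = self.model._basis(self.params.lam)
        return self.params.alpha @ L.T

    def modal_class(self) -> np.ndarray:
        return self.posterior.argmax(axis=1) + 1

    # -- standard errors ---------------------------------------------------

    def _pack(self):
        p, spec = self.params, self.model.spec
        K, F, q, J = spec.n_classes, spec.n_factors, self.model.x.shape[1], self.model.J
        parts = [p.alpha.ravel(), p.gamma.ravel()]
        names = [f"alpha[{k+1},{f}]" for k in range(K) for f in range(F)]
        names += [
            f"gamma[{k+1},{f},{c}]"
            for k in range(K)
            for f in range(F)
            for c in range(q)
        ]
        if spec.distal_outcome:
            parts.append(np.log(p.pi / (1 - p.pi)))
            names += [f"tau[{k+1}]" for k in range(K)]
        if K > 1:
            nonref = [k for k in range(K) if k != self.reference_class]
            parts.append(self.logits[nonref].ravel())
            names += [f"beta[{k+1},{c}]" for k in nonref for c in range(q + 1)]
        if spec.pattern == "latent_basis":
            parts.append(p.lam[1:-1])
            names += [f"lambda[{j+1}]" for j in range(1, J - 1)]
        tri = np.tril_indices(F)
        parts.append(p.psi[tri])
        names += [f"psi[{i},{j}]" for i, j in zip(*tri)]
        parts.append(p.sigma2)
        names += [f"sigma2[{j+1}]" for j in range(J)]
        return np.concatenate(parts), names

    def _unpack(self, vec):
        spec = self.model.spec
        K, F, q, J = spec.n_classes, spec.n_factors, self.model.x.shape[1], self.model.J
        p = self.params.copy()
        i = 0
        p.alpha = vec[i : i + K * F].reshape(K, F); i += K * F
        p.gamma = vec[i : i + K * F * q].reshape(K, F, q); i += K * F * q
        if spec.distal_outcome:
            p.pi = expit(vec[i : i + K]); i += K
        if K > 1:
            nonref = [k for k in range(K) if k != self.reference_class]
            logits = np.zeros((K, q + 1))
            logits[nonref] = vec[i : i + (K - 1) * (q + 1)].reshape(K - 1, q + 1)
            i += (K - 1) * (q + 1)
            # internal beta is vs last sorted class
            p.beta = (logits - logits[-1])[:-1]
        if spec.pattern == "latent_basis":
            p.lam = np.concatenate([[0.0], vec[i : i + J - 2], [1.0]]); i += J - 2
        tri = np.tril_indices(F)
        psi = np.zeros((F, F))
        psi[tri] = vec[i : i + len(tri[0])]; i += len(tri[0])
        p.psi = psi + np.tril(psi, -1).T
        p.sigma2 = vec[i : i + J]
        return p

    def _per_person_ll(self, vec):
        p = self._unpack(vec)
        return logsumexp(self.model._log_components(p), axis=1)

    def standard_errors(self, step=1e-5):
        """Sandwich (robust) standard errors by numerical differentiation
        of the observed-data log-likelihood."""
        if self._se is not None:
            return self._se
        # reorder internal params to match the sorted labels
        theta, names = self._pack()
        npar = len(theta)
        scores = np.zeros((self.model.n, npar))
        h = step * np.maximum(1.0, np.abs(theta))
        for i in range(npar):
            up, dn = theta.copy(), theta.copy()
            up[i] += h[i]
            dn[i] -= h[i]
            scores[:, i] = (self._per_person_ll(up) - self._per_person_ll(dn)) / (2 * h[i])
        bmat = scores.T @ scores
        # Hessian of the total log-likelihood (central differences)
        def f(v):
            return float(self._per_person_ll(v).sum())

        amat = np.zeros((npar, npar))
        f0 = f(theta)
        fp = np.empty(npar)
        fm = np.empty(npar)
        for i in range(npar):
            up, dn = theta.copy(), theta.copy()
            up[i] += h[i]
            dn[i] -= h[i]
            fp[i], fm[i] = f(up), f(dn)
            amat[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(npar):
            for j in range(i + 1, npar):
                vpp, vmm = theta.copy(), theta.copy()
                vpp[[i, j]] += h[[i, j]]
                vmm[[i, j]] -= h[[i, j]]
                fij = (f(vpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + f(vmm)) / (
                    2 * h[i] * h[j]
                )
                amat[i, j] = amat[j, i] = fij
        ainv = np.linalg.pinv(-amat)
        cov = ainv @ bmat @ ainv
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        self._se = pd.Series(se, index=names)
        return self._se

    def odds_ratios(self) -> pd.DataFrame:
        """Class-membership odds ratios vs the reference class with 95% CIs
        (normal on the log scale)."""
        if self.model.spec.n_classes < 2:
            raise ValueError("odds ratios need at least two classes")
        se = self.standard_errors()
        return class_membership_or(
            self.logits,
            self.reference_class,
            list(self.model.spec.covariates),
            se,
        )

    # -- reporting ---------------------------------------------------------

    def selection_row(self) -> dict:
        return {
            "n_classes": self.model.spec.n_classes,
            "ll": self.ll,
            "n_parameters": self.n_parameters,
            "bic": self.bic,
            "ssabic": self.ssabic,
            "entropy": self.entropy,
            "class_shares": np.round(self.class_shares, 4).tolist(),
            "replications": self.replications,
        }

    def summary(self) -> str:
        spec = self.model.spec
        K = spec.n_classes
        lines = [
            f"Growth mixture model ({spec.pattern}, {K} class{'es' if K > 1 else ''})",
            "=" * 56,
            f"persons: {self.model.n}   waves: {self.model.J}   "
            f"covariate-dropped: {self.model.n_dropped_covariates}",
            f"LL = {self.ll:.2f}   parameters = {self.n_parameters}   "
            f"BIC = {self.bic:.2f}   SSABIC = {self.ssabic:.2f}",
            f"entropy = {self.entropy:.3f}   best-LL replications = {self.replications}",
            f"loadings: {np.round(self.params.lam, 3).tolist()}",
            f"Psi: {np.round(self.params.psi, 2).tolist()}",
            f"residual variances: {np.round(self.params.sigma2, 2).tolist()}",
        ]
        for k in range(K):
            tag = " (reference)" if k == self.reference_class and K > 1 else ""
            lines.append(
                f"class {k+1}{tag}: share {self.class_shares[k]:.3f}  "
                f"intercept {self.params.alpha[k, 0]:.2f}  "
                f"slope {self.params.alpha[k, 1]:.2f}  "
                + (
                    f"death prob {self.params.pi[k]:.3f}"
                    if spec.distal_outcome
                    else ""
                )
            )
        return "\n".join(lines)

    def plot_trajectories(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.trajectories
        for k in range(traj.shape[0]):
            ax.plot(
                self.model.waves,
                traj[k],
                marker="D",
                label=f"class {k+1} ({self.class_shares[k]:.0%})",
            )
        ax.set_xlabel("wave")
        ax.set_ylabel("health score")
        ax.legend()
        return ax

    # -- simulation (used by the bootstrap LRT) ----------------------------

    def simulate(self, seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Draw a dataset from the fitted model, preserving the observed
        covariates and missingness patterns. Returns (scores, mortality)."""
        rng = np.random.default_rng(seed)
        m = self.model
        p = self.params
        K = m.spec.n_classes
        if K > 1:
            logits = np.zeros((m.n, K))
            nonzero = self.logits
            logits = m.u @ nonzero.T
            pr = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
            u = rng.random(m.n)
            cls = (pr.cumsum(axis=1) < u[:, None]).sum(axis=1)
        else:
            cls = np.zeros(m.n, dtype=int)
        mu = p.alpha[cls] + np.einsum("nfq,nq->nf", p.gamma[cls], m.x)
        chol = np.linalg.cholesky(p.psi + 1e-10 * np.eye(p.psi.shape[0]))
        eta = mu + rng.standard_normal(mu.shape) @ chol.T
        L = m._basis(p.lam)
        y = eta @ L.T + rng.standard_normal((m.n, m.J)) * np.sqrt(p.sigma2)
        y[np.isnan(m.y)] = np.nan
        pid, wj = np.nonzero(~np.isnan(y))
        scores = pd.DataFrame(
            {
                "person_id": m.person_ids[pid],
                "wave": m.waves[wj],
                "score": y[pid, wj],
            }
        )
        dead = (rng.random(m.n) < p.pi[cls]).astype(float)
        dead[np.isnan(m.d)] = np.nan
        mortality = pd.DataFrame({"person_id": m.person_ids, "dead": dead})
        return scores, mortality


def posterior_classes(results: GMMResults) -> np.ndarray:
    """Bayes-rule posterior class probabilities (rows sum to one)."""
    return results.posterior


def class_membership_or(logits, reference_class, covariate_names, se=None):
    """Odds-ratio table from a (K, q+1) logit matrix vs ``reference_class``."""
    logits = np.asarray(logits, float)
    K, d = logits.shape
    rows = []
    names = ["intercept"] + list(covariate_names)
    for k in range(K):
        if k == reference_class:
            continue
        for c, nm in enumerate(names):
            est = logits[k, c]
            row = {
                "class": k + 1,
                "covariate": nm,
                "logit": est,
                "odds_ratio": float(np.exp(est)),
            }
            if se is not None:
                key = f"beta[{k+1},{c}]"
                s = float(se[key]) if key in se.index else np.nan
                row["se"] = s
                row["or_low"] = float(np.exp(est - 1.96 * s))
                row["or_high"] = float(np.exp(est + 1.96 * s))
            rows.append(row)
    return pd.DataFrame(rows)


def lmr_lrt(fit_k: GMMResults, fit_km1: GMMResults, n: int | None = None):
    """Adjusted Lo-Mendell-Rubin likelihood-ratio test of K-1 vs K classes.

    The statistic 2(LL_K - LL_{K-1}) is shrunk by the small-sample factor
    1/(1 + ((p_K - p_{K-1}) ln n)^-1) and referred to a chi-square with
    the parameter-count difference as degrees of freedom. This reference
    is an approximation; :func:`bootstrap_lrt` gives a simulation-based
    alternative.
    """
    if n is None:
        n = fit_k.model.n
    ll_k, ll_m = fit_k.ll, fit_km1.ll
    if ll_k < ll_m - 1e-6:
        raise ValueError("K-class LL below (K-1)-class LL: optimization failure")
    dp = fit_k.n_parameters - fit_km1.n_parameters
    lr = max(2.0 * (ll_k - ll_m), 0.0)
    c = 1.0 + 1.0 / (dp * np.log(n))
    adj = lr / c
    p = float(chi2.sf(adj, df=dp))
    return {"lr": lr, "adjusted_lr": adj, "df": dp, "p_value": p}


def bootstrap_lrt(
    fit_k: GMMResults,
    fit_km1: GMMResults,
    n_boot: int = 50,
    seed: int = 0,
    n_starts: int = 10,
    max_iter: int = 200,
):
    """Parametric bootstrap LRT: simulate from the (K-1)-class fit, refit
    both models, and compare the observed 2*dLL with the null distribution."""
    observed = 2.0 * (fit_k.ll - fit_km1.ll)
    m1, mk = fit_km1.model, fit_k.model
    exceed = 0
    rng = np.random.default_rng(seed)
    for b in range(n_boot):
        s = int(rng.integers(2**31 - 1))
        scores, mort = fit_km1.simulate(seed=s)
        cov = None
        if len(m1.spec.covariates):
            cov = pd.DataFrame(m1.x, columns=list(m1.spec.covariates))
            cov["person_id"] = m1.person_ids
        f1 = GrowthMixtureModel(scores, cov, mort, m1.spec).fit(
            n_starts=n_starts, seed=s, max_iter=max_iter
        )
        fk = GrowthMixtureModel(scores, cov, mort, mk.spec).fit(
            n_starts=n_starts, seed=s, max_iter=max_iter
        )
        if 2.0 * (fk.ll - f1.ll) >= observed:
            exceed += 1
    return {"lr": observed, "p_value": (exceed + 1) / (n_boot + 1)}


def select_n_classes(
    scores,
    covariates,
    mortality,
    k_range=(2, 3, 4, 5),
    pattern="latent_basis",
    covariate_names=(),
    distal=True,
    n_starts=50,
    seed=0,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Fit a GMM per class count and assemble the selection table
    (LL, parameters, BIC, SSABIC, entropy, aLMR-LRT p, shares).

    Extra keyword arguments (max_iter, tol, n_short, n_final) are
    forwarded to :meth:`GrowthMixtureModel.fit`.
    """
    fits = {}
    rows = []
    prev = None
    for k in k_range:
        spec = GrowthSpec(
            pattern=pattern,
            n_classes=k,
            covariates=tuple(covariate_names),
            distal_outcome=distal,
        )
        res = GrowthMixtureModel(scores, covariates, mortality, spec).fit(
            n_starts=n_starts, seed=seed + k, **fit_kwargs
        )
        fits[k] = res
        row = res.selection_row()
        if prev is not None and res.ll >= prev.ll - 1e-6:
            row["lmr_p"] = lmr_lrt(res, prev)["p_value"]
        else:
            row["lmr_p"] = np.nan
        rows.append(row)
        prev = res
    return pd.DataFrame(rows), fits
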