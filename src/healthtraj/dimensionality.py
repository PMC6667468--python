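"""Unidimensionality checks for the binary health items.

The IRT metric assumes one dominant health dimension. Following common
practice for binary items, the check works on tetrachoric correlations
(the correlation of an assumed underlying bivariate normal generating
each dichotomous pair): split the baseline sample, run exploratory
factor analysis (minres extraction, oblique geomin rotation) on the
exploration part, and test whether the first-order factors themselves
collapse onto a single general factor (a rank-1 fit to the inter-factor
correlation matrix).

Fit indices use the ML discrepancy with a Bartlett-corrected chi-square,
RMSEA with a 90% noncentral-chi-square CI, and CFI against the
independence model. Conventional acceptability thresholds: CFI >= 0.90,
RMSEA <= 0.06.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import ndtri
from scipy.stats import multivariate_normal, ncx2

__all__ = [
    "EfaResult",
    "split_sample",
    "tetrachoric",
    "tetrachoric_matrix",
    "efa",
    "geomin_rotate",
    "general_factor_check",
]

_RHO_CAP = 0.999


def split_sample(person_ids, fraction: float, seed: int):
    """Random, reproducible split into exploration/validation subsets
    (disjoint and exhaustive)."""
    ids = np.asarray(person_ids)
    if ids.size == 0:
        raise ValueError("empty input")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    k = int(round(fraction * ids.size))
    return ids[perm[:k]], ids[perm[k:]]


def tetrachoric(x, y) -> float:
    """ML tetrachoric correlation of two binary vectors.

    Thresholds are fixed at the sample margins; rho solves
    P(Z1 < t1, Z2 < t2; rho) = p00. Empty cells get a 0.5 continuity
    correction and estimates are capped at +-0.999.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    table = np.array(
        [
            [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
            [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
        ],
        float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("an item has zero variance")
    if (table == 0).any():
        table = table + 0.5
    n = table.sum()
    p00 = table[0, 0] / n
    t1 = ndtri(table[0].sum() / n)  # P(x = 0)
    t2 = ndtri(table[:, 0].sum() / n)

    def cell(rho):
        cov = np.array([[1.0, rho], [rho, 1.0]])
        return multivariate_normal(mean=[0, 0], cov=cov, allow_singular=True).cdf(
            [t1, t2]
        )

    f = lambda rho: cell(rho) - p00
    lo, hi = -_RHO_CAP, _RHO_CAP
    if f(lo) * f(hi) > 0:
        return _RHO_CAP if abs(f(hi)) < abs(f(lo)) else -_RHO_CAP
    return float(brentq(f, lo, hi, xtol=1e-10))


def tetrachoric_matrix(panel: pd.DataFrame, wave=None):
    """Pairwise tetrachoric correlation matrix from a long response panel.

    Zero-variance items are excluded with a warning; the matrix is
    symmetrized and eigenvalue-clipped to the nearest SPD matrix when
    needed (``repaired`` flags it).

    Returns (matrix DataFrame, kept item ids, repaired flag).
    """
    df = panel if wave is None else panel[panel["wave"] == wave]
    wide = df.pivot_table(index="person_id", columns="item_id", values="response")
    keep = []
    for c in wide.columns:
        v = wide[c].dropna()
        if v.nunique() < 2:
            warnings.warn(f"item {c} has zero variance; excluded", RuntimeWarning)
        else:
            keep.append(c)
    wide = wide[keep]
    p = len(keep)
    r = np.eye(p)
    arr = wide.to_numpy(float)
    for i in range(p):
        for j in range(i + 1, p):
            r[i, j] = r[j, i] = tetrachoric(arr[:, i], arr[:, j])
    repaired = False
    ev = np.linalg.eigvalsh(r)
    if ev.min() < 1e-8:
        repaired = True
        w, v = np.linalg.eigh(r)
        r = (v * np.maximum(w, 1e-3)) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return pd.DataFrame(r, index=keep, columns=keep), keep, repaired


# ---------------------------------------------------------------------------
# minres extraction + geomin rotation


def _minres_loadings(r: np.ndarray, k: int):
    """Minimum-residual factor extraction: optimize uniquenesses so the
    off-diagonal residuals of R - LL' are smallest."""
    p = r.shape[0]
    off = ~np.eye(p, dtype=bool)

    def loadings_from(u):
        rr = r - np.diag(u)
        w, v = np.linalg.eigh(rr)
        idx = np.argsort(w)[::-1][:k]
        lam = v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))
        return lam

    def objective(u):
        lam = loadings_from(u)
        resid = r - lam @ lam.T
        return np.sum(resid[off] ** 2)

    # start from 1 - squared multiple correlation (standard minres start)
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(r))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    u0 = np.clip(1.0 - smc, 0.005, 1.0)
    res = minimize(
        objective,
        u0,
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": 500},
    )
    lam = loadings_from(res.x)
    heywood = bool(np.any((lam**2).sum(axis=1) > 1.0))
    if heywood:
        warnings.warn("Heywood case: communality above 1; loadings capped", RuntimeWarning)
        norms = np.sqrt((lam**2).sum(axis=1))
        scale = np.minimum(1.0, 0.9995 / np.maximum(norms, 1e-12))
        lam = lam * scale[:, None]
    return lam, res.x, heywood


def _geomin_criterion(lam: np.ndarray, eps: float):
    p, k = lam.shape
    l2 = lam**2 + eps
    logs = np.log(l2)
    g = np.exp(logs.mean(axis=1))  # row geometric means
    q = g.sum()
    grad = (2.0 / k) * g[:, None] * lam / l2
    return q, grad


def _gpa_oblique(lam, t0, eps, max_iter, tol):
    t = t0.copy()
    al = 1.0
    tinv = np.linalg.inv(t)
    L = lam @ tinv.T
    q, gq = _geomin_criterion(L, eps)
    g = -(L.T @ gq @ tinv).T
    for _ in range(max_iter):
        gp = g - t @ np.diag(np.diag(t.T @ g))
        s = np.linalg.norm(gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(40):
            tt = t - al * gp
            tt = tt @ np.diag(1.0 / np.sqrt(np.diag(tt.T @ tt)))
            tinv = np.linalg.inv(tt)
            Lt = lam @ tinv.T
            qt, gqt = _geomin_criterion(Lt, eps)
            if qt < q - 0.5 * s**2 * al:
                break
            al /= 2.0
        t, q = tt, qt
        L = Lt
        g = -(L.T @ gqt @ tinv).T
    return L, t.T @ t, q


def geomin_rotate(
    lam: np.ndarray, eps: float = 0.01, max_iter: int = 500, tol=1e-7, n_starts: int = 10
):
    """Oblique geomin rotation by gradient projection.

    The geomin criterion is multimodal, so the identity start is
    supplemented with seeded random orthonormal starts and the lowest
    criterion value kept. Returns (rotated loadings, factor correlations).
    """
    p, k = lam.shape
    if k == 1:
        return lam.copy(), np.ones((1, 1))
    rng = np.random.default_rng(1234)
    starts = [np.eye(k)]
    for _ in range(n_starts - 1):
        qm, _ = np.linalg.qr(rng.standard_normal((k, k)))
        starts.append(qm)
    best = None
    for t0 in starts:
        L, phi, q = _gpa_oblique(lam, t0, eps, max_iter, tol)
        if best is None or q < best[2]:
            best = (L, phi, q)
    L, phi, _ = best
    # canonical signs: each factor's loading sum positive
    signs = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    return L * signs, phi * np.outer(signs, signs)


@dataclass
class EfaResult:
    n_factors: int
    loadings: pd.DataFrame
    factor_corr: np.ndarray
    communalities: np.ndarray
    chi_square: float
    df: int
    rmsea: float
    rmsea_ci: tuple
    cfi: float
    heywood: bool = False


def _fit_indices(r, sigma, n_obs, k):
    p = r.shape[0]
    sign, ld_s = np.linalg.slogdet(sigma)
    _, ld_r = np.linalg.slogdet(r)
    f_ml = ld_s - ld_r + np.trace(np.linalg.solve(sigma, r)) - p
    f_ml = max(f_ml, 0.0)
    mult = n_obs - 1 - (2 * p + 5) / 6.0 - (2 * k) / 3.0  # Bartlett correction
    chi = mult * f_ml
    df = ((p - k) ** 2 - (p + k)) // 2
    f_null = max(-np.linalg.slogdet(r)[1], 0.0)
    chi_null = (n_obs - 1 - (2 * p + 5) / 6.0) * f_null
    df_null = p * (p - 1) // 2
    if df > 0:
        rmsea = np.sqrt(max(chi - df, 0.0) / (df * (n_obs - 1)))
        lo = _ncp_limit(chi, df, 0.95)
        hi = _ncp_limit(chi, df, 0.05)
        ci = (
            np.sqrt(lo / (df * (n_obs - 1))),
            np.sqrt(hi / (df * (n_obs - 1))),
        )
    else:
        rmsea, ci = 0.0, (0.0, 0.0)
    denom = max(chi_null - df_null, chi - df, 0.0)
    cfi = 1.0 - max(chi - df, 0.0) / denom if denom > 0 else 1.0
    return float(chi), int(df), float(rmsea), ci, float(min(cfi, 1.0))


def _ncp_limit(chi, df, q):
    """Noncentrality lambda with ncx2.cdf(chi; df, lambda) = q."""
    if chi <= df or ncx2.cdf(chi, df, 1e-8) < q:
        return 0.0
    lo, hi = 1e-8, chi * 2 + 100
    while ncx2.cdf(chi, df, hi) > q:
        hi *= 2
    return brentq(lambda l: ncx2.cdf(chi, df, l) - q, lo, hi, xtol=1e-6)


def efa(corr, n_factors: int, n_obs: int, rotation: str = "geomin", geomin_eps=0.01) -> EfaResult:
    """Exploratory factor analysis of a correlation matrix.

    minres extraction; oblique geomin rotation (or none); chi-square /
    RMSEA(90% CI) / CFI from the ML discrepancy.
    """
    names = list(corr.index) if isinstance(corr, pd.DataFrame) else None
    r = np.asarray(corr, float)
    p = r.shape[0]
    if n_factors >= p / 2:
        raise ValueError("too many factors for the number of items")
    lam0, uniq, heywood = _minres_loadings(r, n_factors)
    if rotation == "geomin" and n_factors > 1:
        lam, phi = geomin_rotate(lam0, eps=geomin_eps)
    else:
        lam, phi = lam0, np.eye(n_factors)
    sigma = lam0 @ lam0.T + np.diag(np.clip(uniq, 1e-3, None))
    chi, df, rmsea, ci, cfi = _fit_indices(r, sigma, n_obs, n_factors)
    load_df = pd.DataFrame(
        lam,
        index=names if names is not None else range(p),
        columns=[f"F{i+1}" for i in range(n_factors)],
    )
    return EfaResult(
        n_factors=n_factors,
        loadings=load_df,
        factor_corr=phi,
        communalities=1.0 - uniq,
        chi_square=chi,
        df=df,
        rmsea=rmsea,
        rmsea_ci=ci,
        cfi=cfi,
        heywood=heywood,
    )


def general_factor_check(factor_corr: np.ndarray) -> dict:
    """Rank-1 (single general factor) fit to the inter-factor correlation
    matrix; supports the higher-order-factor reading when the residual
    norm is small."""
    phi = np.asarray(factor_corr, float)
    k = phi.shape[0]
    if k < 3:
        raise ValueError("need at least three first-order factors")
    lam, uniq, _ = _minres_loadings(phi, 1)
    g = lam[:, 0]
    if g.sum() < 0:
        g = -g
    resid = phi - np.outer(g, g)
    off = ~np.eye(k, dtype=bool)
    return {
        "loadings": g,
        "residual_norm": float(np.sqrt(np.mean(resid[off] ** 2))),
        "mean_loading": float(g.mean()),
    }
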