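"""Predictive validity of the health metric: (sex-stratified) ROC analysis.

The baseline health score is evaluated against mortality at fixed
horizons. Because mortality differs by sex, the adjusted analysis
compares scores only within sex: the AUC is computed per stratum and
pooled with weights proportional to the number of case-control pairs
(cases x controls), with a DeLong variance pooled the same way.

Orientation: lower health scores are expected in decedents, so the AUC
is reported for the *negated* score as a predictor of death (values
above 0.5 mean the metric discriminates in the expected direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["RocResult", "auc", "gender_adjusted_auc"]


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    by_stratum: dict | None = None
    horizon: str | None = None


def _delong(scores: np.ndarray, outcome: np.ndarray):
    """Mann-Whitney AUC (midrank ties) with the DeLong variance.

    Computed for `scores` as a predictor of outcome==1.
    """
    cases = scores[outcome == 1]
    controls = scores[outcome == 0]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("both outcome levels must be present")
    all_ranks = rankdata(np.concatenate([cases, controls]))
    r_cases = rankdata(cases)
    r_controls = rankdata(controls)
    # placements: fraction of the other group below each observation
    v10 = (all_ranks[:m] - r_cases) / n
    v01 = 1.0 - (all_ranks[m:] - r_controls) / m
    a = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    return a, var, m, n


def auc(scores, outcomes, orient_low_risk: bool = True) -> RocResult:
    """AUC of a health score for a binary death outcome with 95% DeLong CI.

    With ``orient_low_risk`` (default) the score is negated first, so an
    informative metric (lower health -> death) yields AUC > 0.5. Missing
    outcomes are excluded.
    """
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, float)
    keep = ~np.isnan(scores) & ~np.isnan(outcomes)
    scores, outcomes = scores[keep], outcomes[keep]
    pred = -scores if orient_low_risk else scores
    a, var, m, n = _delong(pred, outcomes)
    half = 1.96 * np.sqrt(var)
    return RocResult(
        auc=float(a),
        ci_low=float(np.clip(a - half, 0, 1)),
        ci_high=float(np.clip(a + half, 0, 1)),
        n_cases=m,
        n_controls=n,
    )


def gender_adjusted_auc(scores, outcomes, sex, orient_low_risk: bool = True) -> RocResult:
    """Sex-adjusted AUC: within-stratum AUCs pooled with weights
    proportional to cases x controls; DeLong variances pooled with the
    squared weights. Strata missing an outcome level are excluded."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, float)
    sex = np.asarray(sex, float)
    keep = ~np.isnan(scores) & ~np.isnan(outcomes) & ~np.isnan(sex)
    scores, outcomes, sex = scores[keep], outcomes[keep], sex[keep]
    by = {}
    aucs, variances, weights = [], [], []
    for s in np.unique(sex):
        mask = sex == s
        o = outcomes[mask]
        if len(np.unique(o)) < 2:
            warnings.warn(
                f"sex stratum {s:g} lacks an outcome level; excluded", RuntimeWarning
            )
            continue
        pred = -scores[mask] if orient_low_risk else scores[mask]
        a, var, m, n = _delong(pred, o)
        by[float(s)] = {"auc": float(a), "n_cases": m, "n_controls": n}
        aucs.append(a)
        variances.append(var)
        weights.append(m * n)
    if not aucs:
        raise ValueError("no sex stratum has both outcome levels")
    w = np.asarray(weights, float)
    w = w / w.sum()
    pooled = float(np.dot(w, aucs))
    pooled_var = float(np.dot(w**2, variances))
    half = 1.96 * np.sqrt(pooled_var)
    return RocResult(
        auc=pooled,
        ci_low=float(np.clip(pooled - half, 0, 1)),
        ci_high=float(np.clip(pooled + half, 0, 1)),
        n_cases=int(sum(b["n_cases"] for b in by.values())),
        n_controls=int(sum(b["n_controls"] for b in by.values())),
        by_stratum=by,
    )
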