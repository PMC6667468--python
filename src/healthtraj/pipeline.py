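"""End-to-end orchestration: simulate -> IRT metric -> dimensionality ->
growth mixture trajectories -> predictive validity, with persisted
artifacts and a consolidated report.

Each stage reads only persisted artifacts of earlier stages, so a run can
be resumed or repeated stage by stage. All randomness derives from one
master seed: stage ``k`` uses ``SeedSequence([master_seed, k])`` (the
generator itself consumes its config seed the same way), which makes the
whole run bit-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dimensionality as dim
from . import gmm as gmm_mod
from . import irt as irt_mod
from . import roc as roc_mod
from . import simulate as sim

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "make_report"]

_STAGE_SEEDS = {"simulate": 0, "irt": 1, "dimensionality": 2, "gmm": 3, "roc": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``sim`` (a SimConfig-style mapping) or ``inputs``
    (paths to panel/covariates/mortality CSVs) must be given.
    """

    out_dir: str
    seed: int = 0
    sim: dict | None = None
    inputs: dict | None = None
    irt_variants: tuple = (1, 3)
    irt_iterations: int = 2000
    irt_burnin: int = 200
    irt_chains: int = 2
    efa_wave: int = 1
    efa_split: float = 0.7
    efa_max_factors: int = 4
    gmm_pattern: str = "latent_basis"
    gmm_k_range: tuple = (2, 3, 4)
    gmm_starts: int = 25
    verbose: bool = True

    def __post_init__(self):
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of 'sim' or 'inputs' must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def validate_inputs(paths: dict) -> dict:
    """Schema and missingness diagnostics for input CSVs.

    Returns {"errors": [...], "missingness": {...}}; an empty error list
    means the inputs are usable.
    """
    errors = []
    summary = {}
    panel = pd.read_csv(paths["panel"])
    need = {"person_id", "wave", "item_id", "response"}
    if not need <= set(panel.columns):
        errors.append(f"panel: missing columns {sorted(need - set(panel.columns))}")
    else:
        bad = panel[~panel["response"].isin([0, 1]) & panel["response"].notna()]
        for idx in bad.index[:20]:
            errors.append(f"panel row {idx}: response {panel.loc[idx, 'response']!r} not in {{0,1,missing}}")
        summary["item_missing_pct"] = float(panel["response"].isna().mean() * 100)
        summary["waves"] = sorted(panel["wave"].unique().tolist())
    cov = pd.read_csv(paths["covariates"])
    if "person_id" not in cov.columns:
        errors.append("covariates: missing person_id column")
    else:
        cols = [c for c in cov.columns if c != "person_id"]
        summary["covariate_missing_pct"] = {
            c: float(cov[c].isna().mean() * 100) for c in cols
        }
        if "education" in cov.columns:
            edu = cov["education"].dropna()
            if ((edu < 1) | (edu > 8)).any():
                errors.append("covariates: education outside 1..8")
    mort = pd.read_csv(paths["mortality"])
    if not {"person_id", "dead"} <= set(mort.columns):
        errors.append("mortality: need person_id and dead columns")
    return {"errors": errors, "missingness": summary}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return the report dict (also persisted to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "errors": {}}
    t_start = time.time()

    def log(msg):
        if config.verbose:
            print(f"[healthtraj] {msg}", flush=True)

    def clock(stage, t0):
        report["stages"][stage] = round(time.time() - t0, 2)

    # ---- stage 1: data -------------------------------------------------
    t0 = time.time()
    try:
        if config.sim is not None:
            simcfg = dict(config.sim)
            simcfg.setdefault("seed", stage_seed(config.seed, "simulate"))
            n = simcfg.pop("n_persons")
            cohort = sim.generate_cohort(sim.default_config(n, **simcfg))
            paths = sim.write_cohort_csv(cohort, out / "data")
            truth_scores = cohort.observed_scores()
            truth_scores.to_csv(out / "data" / "true_scores.csv", index=False)
            death_wave = cohort.truth["death_wave"]
            horizons = pd.DataFrame({"person_id": cohort.covariates["person_id"]})
            for j in range(2, cohort.config.n_waves + 1):
                horizons[f"dead_by_wave{j}"] = (death_wave <= j).astype(float)
            horizons["dead_end"] = cohort.mortality["dead"]
            horizons.to_csv(out / "data" / "mortality_horizons.csv", index=False)
            paths["horizons"] = str(out / "data" / "mortality_horizons.csv")
        else:
            paths = dict(config.inputs)
        diag = validate_inputs(paths)
        report["input_validation"] = diag
        if diag["errors"]:
            raise ValueError("input validation failed: " + "; ".join(diag["errors"]))
        panel = sim.read_panel_csv(paths["panel"])
        covariates = pd.read_csv(paths["covariates"])
        mortality = pd.read_csv(paths["mortality"])
    except Exception as exc:  # noqa: BLE001 - report and truncate
        report["errors"]["data"] = repr(exc)
        _persist(report, out)
        return report
    clock("data", t0)
    log(f"data ready ({panel['person_id'].nunique()} persons)")

    # ---- stage 2: IRT health metric ------------------------------------
    t0 = time.time()
    try:
        fits = {}
        for v in config.irt_variants:
            model = irt_mod.HealthIRTModel(panel, variant=v)
            fits[v] = model.fit(
                n_iterations=config.irt_iterations,
                n_burnin=config.irt_burnin,
                n_chains=config.irt_chains,
                seed=stage_seed(config.seed, "irt") + v,
            )
            log(f"IRT variant {v} done (DIC {fits[v].diagnostics().dic:.0f})")
        var_table, selected = irt_mod.compare_variants(fits)
        best = fits[selected]
        scores = best.scores()
        scores.to_csv(out / "scores.csv", index=False)
        best.item_params.to_csv(out / "item_parameters.csv", index=False)
        var_table.to_csv(out / "variant_comparison.csv", index=False)
        wave_trend = (
            scores.groupby("wave")["score_0_100"].agg(["mean", "std", "count"]).reset_index()
        )
        wave_trend.to_csv(out / "wave_trend.csv", index=False)
        d = best.diagnostics()
        report["irt"] = {
            "variant_comparison": var_table.to_dict(orient="records"),
            "selected_variant": selected,
            "eap_reliability": d.eap_reliability,
            "dic": d.dic,
            "frac_se_below_half": d.frac_se_below_half,
            "rhat_max": d.rhat_max,
            "wave_mean_scores": wave_trend["mean"].round(3).tolist(),
        }
    except Exception as exc:  # noqa: BLE001
        report["errors"]["irt"] = repr(exc)
        _persist(report, out)
        return report
    clock("irt", t0)

    # ---- stage 3: dimensionality ---------------------------------------
    t0 = time.time()
    try:
        ids = panel["person_id"].unique()
        explore, _hold = dim.split_sample(
            ids, config.efa_split, stage_seed(config.seed, "dimensionality")
        )
        sub = panel[panel["person_id"].isin(explore)]
        corr, kept, repaired = dim.tetrachoric_matrix(sub, wave=config.efa_wave)
        efa_rows = []
        res_by_k = {}
        for k in range(1, config.efa_max_factors + 1):
            r = dim.efa(corr, k, n_obs=len(explore))
            res_by_k[k] = r
            efa_rows.append(
                {
                    "n_factors": k,
                    "chi_square": r.chi_square,
                    "df": r.df,
                    "rmsea": r.rmsea,
                    "cfi": r.cfi,
                }
            )
        top = res_by_k[config.efa_max_factors]
        gfc = (
            dim.general_factor_check(top.factor_corr)
            if config.efa_max_factors >= 3
            else None
        )
        pd.DataFrame(efa_rows).to_csv(out / "efa_fit.csv", index=False)
        top.loadings.to_csv(out / "efa_loadings.csv")
        report["dimensionality"] = {
            "fit_by_n_factors": efa_rows,
            "matrix_repaired": repaired,
            "general_factor": None
            if gfc is None
            else {
                "loadings": np.round(gfc["loadings"], 4).tolist(),
                "residual_norm": gfc["residual_norm"],
            },
        }
    except Exception as exc:  # noqa: BLE001
        report["errors"]["dimensionality"] = repr(exc)
        _persist(report, out)
        return report
    clock("dimensionality", t0)
    log("dimensionality done")

    # ---- stage 4: growth mixture trajectories --------------------------
    t0 = time.time()
    try:
        design = sim.covariate_design_frame(covariates)
        _, min_cov = gmm_mod.covariance_coverage(scores.rename(columns={"score_0_100": "score"}))
        gscores = scores.rename(columns={"score_0_100": "score"})[
            ["person_id", "wave", "score"]
        ]
        table, fits_k = gmm_mod.select_n_classes(
            gscores,
            design,
            mortality,
            k_range=config.gmm_k_range,
            pattern=config.gmm_pattern,
            covariate_names=sim.COVARIATE_COLUMNS,
            n_starts=config.gmm_starts,
            seed=stage_seed(config.seed, "gmm"),
        )
        k_bic = int(table.loc[table["bic"].idxmin(), "n_classes"])
        k_ssabic = int(table.loc[table["ssabic"].idxmin(), "n_classes"])
        best_gmm = fits_k[k_bic]
        table.to_csv(out / "gmm_selection.csv", index=False)
        est_rows = []
        for k in range(best_gmm.model.spec.n_classes):
            est_rows.append(
                {
                    "class": k + 1,
                    "share": best_gmm.class_shares[k],
                    "intercept_mean": best_gmm.params.alpha[k, 0],
                    "slope_mean": best_gmm.params.alpha[k, 1],
                    "death_prob": best_gmm.params.pi[k],
                    "reference": k == best_gmm.reference_class,
                }
            )
        est = pd.DataFrame(est_rows)
        est.to_csv(out / "gmm_class_estimates.csv", index=False)
        ors = best_gmm.odds_ratios()
        ors.to_csv(out / "gmm_odds_ratios.csv", index=False)
        pd.DataFrame(
            best_gmm.posterior,
            columns=[f"p_class{k+1}" for k in range(best_gmm.posterior.shape[1])],
        ).assign(person_id=best_gmm.model.person_ids).to_csv(
            out / "gmm_posterior.csv", index=False
        )
        report["gmm"] = {
            "covariance_coverage_min": min_cov,
            "n_dropped_covariates": best_gmm.model.n_dropped_covariates,
            "selection": table.drop(columns=["class_shares"]).to_dict(orient="records"),
            "selected_k_bic": k_bic,
            "selected_k_ssabic": k_ssabic,
            "class_estimates": est.round(4).to_dict(orient="records"),
            "odds_ratios": ors.round(4).to_dict(orient="records"),
        }
    except Exception as exc:  # noqa: BLE001
        report["errors"]["gmm"] = repr(exc)
        _persist(report, out)
        return report
    clock("gmm", t0)
    log(f"GMM done (BIC selects K={report['gmm']['selected_k_bic']})")

    # ---- stage 5: predictive validity ----------------------------------
    t0 = time.time()
    try:
        base = scores[scores["wave"] == scores["wave"].min()][
            ["person_id", "score_0_100"]
        ]
        merged = base.merge(covariates[["person_id", "sex"]], on="person_id").merge(
            mortality, on="person_id"
        )
        roc_rows = []
        horizon_path = (paths or {}).get("horizons")
        if horizon_path:
            hz = pd.read_csv(horizon_path)
            hz_cols = [c for c in hz.columns if c.startswith("dead_by_wave")]
            hm = base.merge(covariates[["person_id", "sex"]], on="person_id").merge(
                hz, on="person_id"
            )
            for c in hz_cols:
                r = roc_mod.gender_adjusted_auc(hm["score_0_100"], hm[c], hm["sex"])
                roc_rows.append(
                    {"horizon": c, "auc": r.auc, "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "n_cases": r.n_cases, "n_controls": r.n_controls}
                )
        r = roc_mod.gender_adjusted_auc(merged["score_0_100"], merged["dead"], merged["sex"])
        roc_rows.append(
            {"horizon": "end_of_followup", "auc": r.auc, "ci_low": r.ci_low,
             "ci_high": r.ci_high, "n_cases": r.n_cases, "n_controls": r.n_controls}
        )
        roc_df = pd.DataFrame(roc_rows)
        roc_df.to_csv(out / "roc.csv", index=False)
        report["roc"] = roc_df.round(4).to_dict(orient="records")
    except Exception as exc:  # noqa: BLE001
        report["errors"]["roc"] = repr(exc)
        _persist(report, out)
        return report
    clock("roc", t0)
    report["total_seconds"] = round(time.time() - t_start, 2)
    _persist(report, out)
    log(f"pipeline finished in {report['total_seconds']}s")
    return report


def _persist(report: dict, out: Path):
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    (out / "report.txt").write_text(make_report(report))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def make_report(report: dict) -> str:
    """Deterministic human-readable rendering of the pipeline report."""
    lines = ["healthtraj pipeline report", "=" * 60]
    if report.get("errors"):
        for stage, err in sorted(report["errors"].items()):
            lines.append(f"!! stage '{stage}' failed: {err}")

    def section(title, present):
        lines.append("")
        lines.append(f"--- {title} " + "-" * max(0, 50 - len(title)))
        if not present:
            lines.append("  [absent]")
        return present

    if section("IRT variant comparison", "irt" in report):
        irt = report["irt"]
        for row in irt["variant_comparison"]:
            lines.append(
                f"  variant {row['variant']}: DIC {row['dic']:.1f}  "
                f"reliability {row['eap_reliability']:.3f}  "
                f"R-hat {row['rhat_max']:.3f}"
            )
        lines.append(f"  selected variant: {irt['selected_variant']}")
    if section("Wave mean score trend", "irt" in report):
        means = report["irt"]["wave_mean_scores"]
        lines.append("  " + " -> ".join(f"{m:.1f}" for m in means))
    if section("Dimensionality", "dimensionality" in report):
        for row in report["dimensionality"]["fit_by_n_factors"]:
            lines.append(
                f"  {row['n_factors']} factors: chi2 {row['chi_square']:.1f} "
                f"(df {row['df']})  RMSEA {row['rmsea']:.3f}  CFI {row['cfi']:.3f}"
            )
        gf = report["dimensionality"]["general_factor"]
        if gf:
            lines.append(
                f"  general factor loadings {gf['loadings']} "
                f"(residual norm {gf['residual_norm']:.4f})"
            )
    if section("GMM class selection", "gmm" in report):
        for row in report["gmm"]["selection"]:
            lines.append(
                f"  K={row['n_classes']}: LL {row['ll']:.1f} ({row['n_parameters']})  "
                f"BIC {row['bic']:.1f}  SSABIC {row['ssabic']:.1f}  "
                f"entropy {row['entropy']:.3f}"
            )
        lines.append(
            f"  BIC selects K={report['gmm']['selected_k_bic']}; "
            f"SSABIC selects K={report['gmm']['selected_k_ssabic']}"
        )
    if section("Class estimates", "gmm" in report):
        for row in report["gmm"]["class_estimates"]:
            ref = " (ref)" if row["reference"] else ""
            lines.append(
                f"  class {row['class']}{ref}: share {row['share']:.3f}  "
                f"intercept {row['intercept_mean']:.2f}  slope {row['slope_mean']:.2f}  "
                f"death prob {row['death_prob']:.3f}"
            )
    if section("Class-membership odds ratios", "gmm" in report):
        for row in report["gmm"]["odds_ratios"]:
            ci = ""
            if "or_low" in row and row.get("or_low") == row.get("or_low"):
                ci = f" (95% CI {row['or_low']:.2f}-{row['or_high']:.2f})"
            lines.append(
                f"  class {row['class']} ~ {row['covariate']}: "
                f"logit {row['logit']:.3f}  OR {row['odds_ratio']:.2f}{ci}"
            )
    if section("Predictive validity (sex-adjusted ROC)", "roc" in report):
        for row in report["roc"]:
            lines.append(
                f"  {row['horizon']}: AUC {row['auc']:.3f} "
                f"({row['ci_low']:.3f}-{row['ci_high']:.3f}), "
                f"{row['n_cases']} cases / {row['n_controls']} controls"
            )
    return "\n".join(lines) + "\n"
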