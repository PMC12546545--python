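"""Monte Carlo evaluation of the SAM estimators.

Reproduces the evaluation framework of the simulation studies: per
condition (design x cluster count x cluster size) and estimator, bias of
the interaction coefficient, average absolute bias of all slope
coefficients at a level against the true-model benchmark (OLS on the exact
generated latent values), the SD of estimates across converged
replications, RMSE (sqrt of squared bias vs the population value plus
sampling variance), and the convergence-failure rate.  Metrics are
tabulated over converged replications only; the failure rate over all
replications.

Replication seeds are derived deterministically from the master seed as
``(master * 100003 + condition_index * 1009 + rep) % 2**31`` so any single
replication can be re-run in isolation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import (
    MultilevelDataset,
    PartiallyNestedDataset,
    generate_mlsem,
    generate_pn,
)
from .params import PopulationParams, default_params
from .pn import compute_effects, pn_estimate_many
from .sam import (
    CONVERGED,
    StructuralFit,
    estimate_paths,
    product_label,
    sam_estimate_many,
)

__all__ = [
    "StudyConfig",
    "MetricsTable",
    "replication_seed",
    "true_empirical_fit",
    "true_empirical_pn_effects",
    "run_condition",
    "run_pn_condition",
    "run_study",
    "bootstrap_ci",
]

# coefficient naming per design/level: (score label -> reported name)
COEF_NAMES = {
    "within": {"within": {"x": "beta1", "z": "beta2",
                          product_label("x", "z"): "beta3"},
               "between": {"x": "gamma1", "z": "gamma2"}},
    "cross": {"within": {"x": "beta1", "z": "beta2",
                         product_label("x", "z"): "beta3"},
              "between": {"x": "gamma1", "z": "gamma2"}},
    "between": {"between": {"x": "gamma1", "z": "gamma2",
                            product_label("x", "z"): "gamma3"}},
}

INTERACTION = {"within": ("within", product_label("x", "z")),
               "cross": ("within", product_label("x", "z")),
               "between": ("between", product_label("x", "z"))}

PN_EFFECTS = ("main", "mediation", "moderation")


def replication_seed(master_seed: int, condition_index: int, rep: int) -> int:
    return (master_seed * 100003 + condition_index * 1009 + rep) % (2 ** 31)


@dataclass
class StudyConfig:
    """Monte Carlo study configuration."""

    study: str = "fully_nested"  # or "partially_nested"
    designs: tuple[str, ...] = ("within", "cross", "between")
    estimators: tuple[str, ...] = ("fs", "croon")
    grid: tuple[tuple[int, int], ...] = ((30, 50), (60, 50), (90, 50),
                                         (30, 20), (60, 20), (90, 20))
    replications: int = 500
    master_seed: int = 20260101
    params: PopulationParams | None = None

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


@dataclass
class MetricsTable:
    """Per-condition Monte Carlo summaries.

    ``coefficients`` has one row per condition x estimator x coefficient
    (bias, mean, SD, RMSE, abs bias vs the true-model benchmark);
    ``levels`` aggregates per level (average absolute bias, average SD,
    average RMSE); ``convergence`` has the failure rates; ``raw`` keeps
    every replication's estimates for exact recomputation.
    """

    coefficients: pd.DataFrame
    levels: pd.DataFrame
    convergence: pd.DataFrame
    raw: pd.DataFrame


def _population_values(params: PopulationParams, design: str) -> dict:
    b0, b1, b2, b3 = params.beta
    g0, g1, g2, g3 = params.gamma
    vals = {"beta1": b1, "beta2": b2, "beta3": b3,
            "gamma1": g1, "gamma2": g2, "gamma3": g3}
    return vals


def true_empirical_fit(dataset: MultilevelDataset,
                       design: str | None = None) -> dict[str, StructuralFit]:
    """'True model' benchmark: OLS on the exact generated latent values.

    Uses the latent sidecar (values drawn prior to indicator generation):
    the within model regresses the exact latent outcome on the exact latent
    predictors and their exact product; the between model likewise at the
    cluster level.
    """
    if dataset.sidecar is None:
        raise ValueError("dataset has no latent sidecar")
    design = dataset.design if design is None else design
    side = dataset.sidecar
    out: dict[str, StructuralFit] = {}

    if design in ("within", "cross"):
        tab = pd.DataFrame({"x": side["eta_x_w"], "z": side["eta_z_w"],
                            "y": side["eta_y_w"]})
        other = side["eta_z_w"] if design == "within" else side["eta_z_b"]
        tab[product_label("x", "z")] = (
            (side["eta_x_w"] - side["eta_x_w"].mean())
            * (other - other.mean()))
        from .sam import MomentMatrix
        mm = MomentMatrix(cov=tab.cov(ddof=1), means=tab.mean(),
                          level="within", n=len(tab))
        out["within"] = estimate_paths(mm, "y",
                                       ["x", "z", product_label("x", "z")],
                                       estimator="true")
    cl = side.groupby("cluster_id")
    bt = pd.DataFrame({"x": cl["eta_x_b"].first(), "z": cl["eta_z_b"].first(),
                       "y": cl["eta_y_b"].first()})
    preds = ["x", "z"]
    if design == "between":
        bt[product_label("x", "z")] = ((bt["x"] - bt["x"].mean())
                                       * (bt["z"] - bt["z"].mean()))
        preds = ["x", "z", product_label("x", "z")]
    from .sam import MomentMatrix
    mm = MomentMatrix(cov=bt.cov(ddof=1), means=bt.mean(),
                      level="between", n=len(bt))
    out["between"] = estimate_paths(mm, "y", preds, estimator="true")
    return out


def true_empirical_pn_effects(dataset: PartiallyNestedDataset) -> dict[str, float]:
    """PN benchmark effects from the exact latent values."""
    if dataset.sidecar is None:
        raise ValueError("dataset has no latent sidecar")
    side = dataset.sidecar
    t = side[side["arm"] == "treatment"]
    c = side[side["arm"] == "control"]
    cl = t.groupby("cluster_id")
    bt = pd.DataFrame({"m": cl["eta_m_b"].first(), "z": cl["eta_z_b"].first(),
                       "y": cl["eta_y_b"].first()})
    prod = (bt["m"] - bt["m"].mean()) * (bt["z"] - bt["z"].mean())
    bt[product_label("m", "z")] = prod
    from .sam import MomentMatrix
    mm = MomentMatrix(cov=bt.cov(ddof=1), means=bt.mean(),
                      level="between", n=len(bt))
    fitb = estimate_paths(mm, "y", ["m", "z", product_label("m", "z")],
                          estimator="true")
    a_true = float(bt["m"].mean() - c["eta_m_b"].mean())
    B_true = float(fitb.coefficients["m"])
    xi2_true = float(fitb.coefficients[product_label("m", "z")])
    y_contrast = float(bt["y"].mean() - c["eta_y_b"].mean())
    main_true = y_contrast - B_true * a_true - xi2_true * float(prod.mean())
    return {"main": main_true, "mediation": a_true * B_true,
            "moderation": xi2_true, "a_path": a_true, "b_path": B_true}


# ---------------------------------------------------------------------------
# fully nested conditions
# ---------------------------------------------------------------------------

def run_condition(design: str, n2: int, n1: int, R: int, master_seed: int,
                  params: PopulationParams | None = None,
                  estimators: tuple[str, ...] = ("fs", "croon"),
                  condition_index: int = 0) -> MetricsTable:
    """Generate R datasets, estimate with each estimator, summarise."""
    p = params if params is not None else default_params()
    names = COEF_NAMES[design]
    records = []
    for rep in range(R):
        seed = replication_seed(master_seed, condition_index, rep)
        ds = generate_mlsem(p, design, n2, n1, seed=seed)
        t0 = time.perf_counter()
        results = sam_estimate_many(ds, estimators=estimators)
        runtime = time.perf_counter() - t0
        true_fits = true_empirical_fit(ds)
        for level, fit in true_fits.items():
            if level not in names:
                continue
            for label, name in names[level].items():
                records.append({"rep": rep, "estimator": "true",
                                "level": level, "coefficient": name,
                                "estimate": float(fit.coefficients[label]),
                                "converged": True, "runtime": np.nan})
        for est, res in results.items():
            conv = res.converged
            for level, fit in (("within", res.within), ("between", res.between)):
                if fit is None or level not in names:
                    continue
                for label, name in names[level].items():
                    est_val = (float(fit.coefficients[label])
                               if conv else np.nan)
                    records.append({"rep": rep, "estimator": est,
                                    "level": level, "coefficient": name,
                                    "estimate": est_val, "converged": conv,
                                    "runtime": runtime / len(estimators)})
    raw = pd.DataFrame(records)
    return _summarize(raw, design, n2, n1, p, estimators)


def _summarize(raw: pd.DataFrame, design: str, n2: int, n1: int,
               params: PopulationParams,
               estimators: tuple[str, ...]) -> MetricsTable:
    pop = _population_values(params, design)
    coef_rows, level_rows, conv_rows = [], [], []
    R = raw["rep"].nunique()
    for est in estimators:
        sub = raw[raw["estimator"] == est]
        conv_by_rep = sub.groupby("rep")["converged"].first()
        failure = 1.0 - conv_by_rep.mean()
        conv_rows.append({"design": design, "n2": n2, "n1": n1,
                          "estimator": est, "replications": R,
                          "failure_rate": failure,
                          "mean_runtime": sub["runtime"].mean()})
        ok = sub[sub["converged"]]
        for level in sorted(sub["level"].unique()):
            abs_biases, sds, rmses = [], [], []
            for coef in sorted(sub[sub["level"] == level]["coefficient"].unique()):
                vals = ok[(ok["level"] == level)
                          & (ok["coefficient"] == coef)]["estimate"]
                reps_ok = ok[(ok["level"] == level)
                             & (ok["coefficient"] == coef)]["rep"]
                true_vals = raw[(raw["estimator"] == "true")
                                & (raw["coefficient"] == coef)
                                & (raw["rep"].isin(reps_ok))]["estimate"]
                mean = vals.mean()
                sd = vals.std(ddof=1)
                bias = mean - pop[coef]
                rmse = float(np.sqrt(bias ** 2 + vals.var(ddof=1)))
                abs_bias_true = abs(mean - true_vals.mean())
                coef_rows.append({"design": design, "n2": n2, "n1": n1,
                                  "estimator": est, "level": level,
                                  "coefficient": coef, "mean": mean,
                                  "bias": bias, "sd": sd, "rmse": rmse,
                                  "abs_bias_vs_true": abs_bias_true,
                                  "n_converged": len(vals)})
                abs_biases.append(abs_bias_true)
                sds.append(sd)
                rmses.append(rmse)
            level_rows.append({"design": design, "n2": n2, "n1": n1,
                               "estimator": est, "level": level,
                               "avg_abs_bias": float(np.mean(abs_biases)),
                               "avg_sd": float(np.mean(sds)),
                               "avg_rmse": float(np.mean(rmses))})
    return MetricsTable(coefficients=pd.DataFrame(coef_rows),
                        levels=pd.DataFrame(level_rows),
                        convergence=pd.DataFrame(conv_rows), raw=raw)


# ---------------------------------------------------------------------------
# partially nested conditions
# ---------------------------------------------------------------------------

def run_pn_condition(n2_t: int, n1_t: int, R: int, master_seed: int,
                     params: PopulationParams | None = None,
                     estimators: tuple[str, ...] = ("fs", "croon"),
                     condition_index: int = 0) -> MetricsTable:
    """PN study condition: effect bias/SD, per-component RMSE, failure rates."""
    p = params if params is not None else default_params()
    pop_effects = {"main": p.mu0_t - p.mu0_c, "mediation": p.a_t * p.B_t,
                   "moderation": p.xi2_t}
    # slope estimands per model component (centred-product parameterisation)
    pop_coefs = {"treatment_between": {"m": p.B_t,
                                       "z": p.xi1_t + p.xi2_t * p.a_t,
                                       product_label("m", "z"): p.xi2_t},
                 "treatment_within": {"m": p.b1_t},
                 "control": {"m": p.b1_c}}
    records = []
    for rep in range(R):
        seed = replication_seed(master_seed, condition_index, rep)
        ds = generate_pn(p, n2_t, n1_t, seed=seed)
        t0 = time.perf_counter()
        results = pn_estimate_many(ds, estimators=estimators)
        runtime = time.perf_counter() - t0
        true_eff = true_empirical_pn_effects(ds)
        for name in PN_EFFECTS:
            records.append({"rep": rep, "estimator": "true", "kind": "effect",
                            "component": "effects", "name": name,
                            "estimate": true_eff[name], "treat_converged": True,
                            "control_converged": True, "runtime": np.nan})
        for est, (meas, structural, eff) in results.items():
            t_ok = eff.treatment_status == CONVERGED
            c_ok = eff.control_status == CONVERGED
            eff_vals = {"main": eff.main_effect, "mediation": eff.mediation,
                        "moderation": eff.moderation}
            for name in PN_EFFECTS:
                records.append({"rep": rep, "estimator": est, "kind": "effect",
                                "component": "effects", "name": name,
                                "estimate": eff_vals[name] if t_ok else np.nan,
                                "treat_converged": t_ok,
                                "control_converged": c_ok,
                                "runtime": runtime / len(estimators)})
            for comp, coefs in pop_coefs.items():
                fit = structural[comp]
                conv = (c_ok if comp == "control" else t_ok) and fit.converged
                for label in coefs:
                    records.append({"rep": rep, "estimator": est,
                                    "kind": "coef", "component": comp,
                                    "name": label,
                                    "estimate": (float(fit.coefficients[label])
                                                 if conv else np.nan),
                                    "treat_converged": t_ok,
                                    "control_converged": c_ok,
                                    "runtime": runtime / len(estimators)})
    raw = pd.DataFrame(records)
    return _summarize_pn(raw, n2_t, n1_t, pop_effects, pop_coefs, estimators)


def _summarize_pn(raw, n2_t, n1_t, pop_effects, pop_coefs, estimators):
    coef_rows, level_rows, conv_rows = [], [], []
    R = raw["rep"].nunique()
    for est in estimators:
        sub = raw[raw["estimator"] == est]
        by_rep = sub.groupby("rep")[["treat_converged", "control_converged"]].first()
        conv_rows.append({"n2_t": n2_t, "n1_t": n1_t,
                          "n_c": n2_t * n1_t, "estimator": est,
                          "replications": R,
                          "treatment_failure_rate": 1.0 - by_rep["treat_converged"].mean(),
                          "control_failure_rate": 1.0 - by_rep["control_converged"].mean(),
                          "mean_runtime": sub["runtime"].mean()})
        # effects
        for name in PN_EFFECTS:
            vals = sub[(sub["kind"] == "effect") & (sub["name"] == name)
                       & sub["treat_converged"]]["estimate"].dropna()
            bias = vals.mean() - pop_effects[name]
            coef_rows.append({"n2_t": n2_t, "n1_t": n1_t, "estimator": est,
                              "component": "effects", "name": name,
                              "mean": vals.mean(), "bias": bias,
                              "sd": vals.std(ddof=1),
                              "rmse": float(np.sqrt(bias ** 2 + vals.var(ddof=1))),
                              "n_converged": len(vals)})
        # component RMSE over slope coefficients
        for comp, coefs in pop_coefs.items():
            rmses, sds, abias = [], [], []
            for label, popv in coefs.items():
                vals = sub[(sub["kind"] == "coef") & (sub["component"] == comp)
                           & (sub["name"] == label)]["estimate"].dropna()
                if len(vals) < 2:
                    continue
                bias = vals.mean() - popv
                rmses.append(float(np.sqrt(bias ** 2 + vals.var(ddof=1))))
                sds.append(vals.std(ddof=1))
                abias.append(abs(bias))
            if rmses:
                level_rows.append({"n2_t": n2_t, "n1_t": n1_t,
                                   "estimator": est, "level": comp,
                                   "avg_abs_bias": float(np.mean(abias)),
                                   "avg_sd": float(np.mean(sds)),
                                   "avg_rmse": float(np.mean(rmses))})
    return MetricsTable(coefficients=pd.DataFrame(coef_rows),
                        levels=pd.DataFrame(level_rows),
                        convergence=pd.DataFrame(conv_rows), raw=raw)


# ---------------------------------------------------------------------------
# whole-study driver
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run a full study and assemble tables mirroring the reported layout.

    Fully nested: convergence-failure table, interaction-bias table,
    average-absolute-bias table, RMSE table.  Partially nested: failure,
    effect-bias and RMSE tables.  An empty grid yields empty tables.
    """
    if config.study == "partially_nested":
        parts = []
        for i, (n2, n1) in enumerate(config.grid):
            parts.append(run_pn_condition(n2, n1, config.replications,
                                          config.master_seed, config.params,
                                          config.estimators, condition_index=i))
        if not parts:
            return {"pn_convergence": pd.DataFrame(),
                    "pn_effect_bias": pd.DataFrame(),
                    "pn_rmse": pd.DataFrame()}
        conv = pd.concat([p.convergence for p in parts], ignore_index=True)
        eff = pd.concat([p.coefficients for p in parts], ignore_index=True)
        lev = pd.concat([p.levels for p in parts], ignore_index=True)
        return {"pn_convergence": conv, "pn_effect_bias": eff, "pn_rmse": lev}

    parts = []
    idx = 0
    for design in config.designs:
        for (n2, n1) in config.grid:
            parts.append(run_condition(design, n2, n1, config.replications,
                                       config.master_seed, config.params,
                                       config.estimators, condition_index=idx))
            idx += 1
    if not parts:
        empty = pd.DataFrame()
        return {"convergence": empty, "interaction_bias": empty,
                "avg_abs_bias": empty, "rmse": empty}
    conv = pd.concat([p.convergence for p in parts], ignore_index=True)
    coef = pd.concat([p.coefficients for p in parts], ignore_index=True)
    lev = pd.concat([p.levels for p in parts], ignore_index=True)
    inter = coef[coef["coefficient"].isin(["beta3", "gamma3"])
                 & coef.apply(lambda r: INTERACTION[r["design"]][0] == r["level"],
                              axis=1)].reset_index(drop=True)
    return {"convergence": conv, "interaction_bias": inter,
            "avg_abs_bias": lev, "rmse": lev, "coefficients": coef}


# ---------------------------------------------------------------------------
# cluster bootstrap
# ---------------------------------------------------------------------------

def _cluster_row_positions(data: pd.DataFrame) -> dict:
    pos: dict = {}
    for cid, idx in data.groupby("cluster_id").indices.items():
        pos[cid] = idx
    return pos


def _resample_mlsem(dataset: MultilevelDataset, rng,
                    positions: dict | None = None) -> MultilevelDataset:
    positions = (_cluster_row_positions(dataset.data)
                 if positions is None else positions)
    ids = list(positions)
    draw = rng.choice(len(ids), size=len(ids), replace=True)
    take = np.concatenate([positions[ids[j]] for j in draw])
    new_ids = np.repeat(np.arange(len(draw)),
                        [len(positions[ids[j]]) for j in draw])
    out = dataset.data.iloc[take].reset_index(drop=True)
    out["cluster_id"] = new_ids
    return MultilevelDataset(data=out, design=dataset.design,
                             params=dataset.params)


def _resample_pn(dataset: PartiallyNestedDataset, rng) -> PartiallyNestedDataset:
    treat = dataset.arm("treatment")
    control = dataset.arm("control")
    positions = _cluster_row_positions(treat)
    ids = list(positions)
    draw = rng.choice(len(ids), size=len(ids), replace=True)
    take = np.concatenate([positions[ids[j]] for j in draw])
    new_ids = np.repeat(np.arange(len(draw)),
                        [len(positions[ids[j]]) for j in draw])
    t_out = treat.iloc[take].reset_index(drop=True)
    t_out["cluster_id"] = new_ids
    c_take = rng.integers(len(control), size=len(control))
    c_out = control.iloc[c_take].reset_index(drop=True)
    c_out["cluster_id"] = np.arange(len(draw), len(draw) + len(c_out))
    return PartiallyNestedDataset(data=pd.concat([t_out, c_out],
                                                 ignore_index=True),
                                  params=dataset.params)


def bootstrap_ci(dataset, design: str | None = None, estimator: str = "croon",
                 B: int = 1000, seed: int | None = None,
                 lower: float = 2.5, upper: float = 97.5) -> pd.DataFrame:
    """Cluster-bootstrap percentile confidence intervals.

    Clusters are resampled with replacement (arm-stratified for partially
    nested data, control singletons resampled as units) and the full SAM
    pipeline is re-run per replicate.  Returns per-quantity percentile
    bounds and the fraction of non-converged replicates.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    pn = isinstance(dataset, PartiallyNestedDataset)
    positions = None if pn else _cluster_row_positions(dataset.data)
    values: dict[str, list[float]] = {}
    failed = 0
    for _ in range(B):
        if pn:
            bs = _resample_pn(dataset, rng)
            try:
                _, structural, eff = pn_estimate_many(bs, estimators=(estimator,))[estimator]
            except ValueError:
                failed += 1
                continue
            if not eff.available:
                failed += 1
                continue
            rep_vals = {"main": eff.main_effect, "mediation": eff.mediation,
                        "moderation": eff.moderation, "a_path": eff.a_path,
                        "b_path": eff.b_path}
        else:
            bs = _resample_mlsem(dataset, rng, positions)
            res = sam_estimate_many(bs, design=design or dataset.design,
                                    estimators=(estimator,))[estimator]
            if not res.converged:
                failed += 1
            # harvest whichever structural fits converged: a degenerate
            # between level must not void the within-level intervals
            rep_vals = {}
            names = COEF_NAMES[bs.design]
            for level, fit in (("within", res.within), ("between", res.between)):
                if fit is None or level not in names or not fit.converged:
                    continue
                for label, name in names[level].items():
                    rep_vals[name] = float(fit.coefficients[label])
            if not rep_vals:
                continue
        for k, v in rep_vals.items():
            values.setdefault(k, []).append(v)
    rows = []
    for k, v in values.items():
        arr = np.asarray(v)
        rows.append({"quantity": k,
                     "lower": float(np.percentile(arr, lower)),
                     "upper": float(np.percentile(arr, upper)),
                     "n_replicates": len(arr),
                     "failure_fraction": failed / B})
    if not rows:
        raise ValueError("all bootstrap replicates failed to converge")
    return pd.DataFrame(rows).set_index("quantity")
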