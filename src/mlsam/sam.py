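"""SAM estimation core: score moment matrices, Croon corrections, path models.

Both estimators share the same first two steps: per-variable ML measurement
models and regression factor scores, assembled into level-specific moment
matrices (with product columns for latent interactions).  SAM-FS feeds the
raw score moments straight into the structural stage; SAM-Croon first
disattenuates every covariance by the product of the score validities
involved (three validities for an interaction-outcome covariance), replaces
latent variances with their measurement-model estimates, recomputes the
product variance from the corrected first-order moments via
var(ab) = var(a) var(b) + cov(a, b)^2, and removes the cluster-mean
contamination of between-level moments (the within-level moment divided by
the cluster size) for variables whose between components are estimated
from observed cluster means.

Convergence failure is an outcome, not an exception: non-positive-definite
moment matrices, boundary variance estimates in any measurement model
(Croon only -- uncorrected scores remain computable), or negative residual
variances mark the estimate ``non_convergence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import DESIGNS, MultilevelDataset
from .measurement import (
    BOUNDARY,
    CONVERGED,
    NON_PD,
    FactorModelFit,
    ScoreMatrix,
    TwoLevelFactorFit,
    cluster_decompose,
    cluster_mean_reliability,
    fit_single_factor_ml,
    fit_two_level_measurement,
    regression_score_matrix,
)

__all__ = [
    "MomentMatrix",
    "StructuralFit",
    "SamResult",
    "assemble_score_moments",
    "croon_correct",
    "product_variance",
    "estimate_paths",
    "sam_estimate",
    "sam_estimate_many",
]

NON_CONVERGENCE = "non_convergence"
VALIDITY_TOL = 1e-3

PRODUCT_SEP = ":"


def product_label(a: str, b: str) -> str:
    return f"{a}{PRODUCT_SEP}{b}"


def is_product(label: str) -> bool:
    return PRODUCT_SEP in label


def product_factors(label: str) -> tuple[str, str]:
    a, b = label.split(PRODUCT_SEP)
    return a, b


@dataclass
class MomentMatrix:
    """Level-specific covariance matrix over factor scores and product terms.

    ``product_terms`` maps a product label to its two factors as
    ``((var, level), (var, level))``; a cross-level interaction pairs a
    within-level factor with a between-level one.
    """

    cov: pd.DataFrame
    means: pd.Series
    level: str
    n: int
    corrected: bool = False
    status: str = CONVERGED
    product_terms: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.cov.columns)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "cov": self.cov.to_numpy().tolist(),
            "means": self.means.to_list(),
            "level": self.level,
            "n": int(self.n),
            "corrected": self.corrected,
            "status": self.status,
        }


@dataclass
class StructuralFit:
    """Path model estimated from a moment matrix by normal equations."""

    outcome: str
    predictors: list[str]
    coefficients: pd.Series
    intercept: float
    residual_variance: float
    level: str
    estimator: str
    status: str = CONVERGED

    @property
    def converged(self) -> bool:
        return self.status == CONVERGED

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictors": self.predictors,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "residual_variance": float(self.residual_variance),
            "level": self.level,
            "estimator": self.estimator,
            "status": self.status,
        }


@dataclass
class SamResult:
    """End-to-end SAM output for one dataset and estimator."""

    estimator: str
    design: str
    within: StructuralFit | None
    between: StructuralFit
    status: str
    fits: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.status == CONVERGED

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "design": self.design,
            "status": self.status,
            "within": None if self.within is None else self.within.to_dict(),
            "between": self.between.to_dict(),
        }


# ---------------------------------------------------------------------------
# moment assembly
# ---------------------------------------------------------------------------

def product_variance(var_a: float, var_b: float, cov_ab: float) -> float:
    """Variance of the product of two centred jointly normal variables."""
    if var_a < 0 or var_b < 0:
        raise ValueError("variances must be non-negative")
    if cov_ab * cov_ab > var_a * var_b * (1 + 1e-12):
        raise ValueError("covariance violates the Cauchy-Schwarz bound")
    return var_a * var_b + cov_ab * cov_ab


def assemble_score_moments(scores: pd.DataFrame | dict,
                           products: list[tuple[str, str]] = (),
                           level: str = "single") -> MomentMatrix:
    """Covariance of factor scores plus product columns of centred scores.

    ``scores`` maps variable label -> score column (aligned on the same
    units).  For each requested pair a product of the mean-centred scores is
    appended under the label ``'a:b'``.  Missing values propagate row-wise.
    """
    table = pd.DataFrame(scores).copy()
    n = len(table)
    if n < 3:
        raise ValueError("need at least three rows to form score moments")
    product_terms = {}
    for a, b in products:
        ca = table[a] - table[a].mean()
        cb = table[b] - table[b].mean()
        table[product_label(a, b)] = ca * cb
        product_terms[product_label(a, b)] = ((a, level), (b, level))
    cov = table.cov(ddof=1)
    means = table.mean()
    return MomentMatrix(cov=cov, means=means, level=level, n=n, corrected=False,
                        product_terms=product_terms)


# ---------------------------------------------------------------------------
# Croon correction
# ---------------------------------------------------------------------------

@dataclass
class _VarInfo:
    validity: float
    psi: float          # corrected (measurement-model) latent variance
    contaminated: bool  # between component estimated from raw cluster means


def _variable_info(label: str, fit, level: str) -> _VarInfo:
    """Validity / corrected variance / contamination flag for one latent."""
    if isinstance(fit, TwoLevelFactorFit):
        if level == "within":
            sm = regression_score_matrix(fit.within)
            return _VarInfo(sm.validity, fit.within.psi, False)
        sm = regression_score_matrix(fit.between)
        return _VarInfo(sm.validity, fit.psi_between_adj, fit.between_contaminated)
    sm = regression_score_matrix(fit)
    return _VarInfo(sm.validity, fit.psi, False)


def croon_correct(raw: MomentMatrix, fits: dict, n1: float | None = None,
                  within_corrected: MomentMatrix | None = None,
                  zero_product_covariances: bool = False,
                  ) -> MomentMatrix:
    """Disattenuate a raw score moment matrix using the measurement models.

    ``fits`` maps each first-order label to its ``FactorModelFit`` or
    ``TwoLevelFactorFit``.  Every covariance is divided by the product of
    the score validities it involves (a product term contributes the
    validities of both of its factors); latent variances are replaced by
    their measurement-model estimates; product variances are recomputed
    from the corrected first-order moments.  For between-level matrices
    built from cluster means, ``within_corrected`` (the corrected within
    moment matrix) and ``n1`` supply the subtraction that removes the
    within-level contamination of order 1/n1 from covariances between two
    cluster-mean-based variables.

    ``zero_product_covariances`` forces the covariance between each product
    term and its own first-order factors to the population value 0 implied
    by latent normality, instead of keeping the (validity-corrected)
    empirical estimate; this stabilises the corrected matrix in very small
    cluster samples at the cost of discarding sampling information.

    An inadmissible measurement fit or a validity below 1e-3 yields a
    ``non_convergence`` matrix (a recorded convergence-failure event)
    rather than exploded estimates.
    """
    if raw.corrected:
        raise ValueError("moment matrix is already corrected")
    labels = raw.labels
    first_order = [l for l in labels if not is_product(l)]

    def bad() -> MomentMatrix:
        return MomentMatrix(cov=raw.cov * np.nan, means=raw.means * np.nan,
                            level=raw.level, n=raw.n, corrected=True,
                            status=NON_CONVERGENCE,
                            product_terms=dict(raw.product_terms))

    # collect (var, level) pairs appearing in the matrix
    needed: set[tuple[str, str]] = {(l, raw.level) for l in first_order}
    for label in labels:
        if is_product(label):
            terms = raw.product_terms.get(
                label, tuple((v, raw.level) for v in product_factors(label)))
            needed.update(terms)
    info: dict[tuple[str, str], _VarInfo] = {}
    for var, level in needed:
        if var not in fits:
            raise KeyError(f"no measurement fit supplied for {var!r}")
        fit = fits[var]
        if getattr(fit, "status", CONVERGED) != CONVERGED:
            return bad()
        info[(var, level)] = _variable_info(var, fit, level)
    if any(v.validity < VALIDITY_TOL or not np.isfinite(v.psi)
           for v in info.values()):
        return bad()

    def factors_of(label: str) -> tuple[tuple[str, str], tuple[str, str]]:
        return raw.product_terms.get(
            label, tuple((v, raw.level) for v in product_factors(label)))

    def validity(label: str) -> float:
        if is_product(label):
            (a, la), (b, lb) = factors_of(label)
            return info[(a, la)].validity * info[(b, lb)].validity
        return info[(label, raw.level)].validity

    def within_cov(a: str, b: str) -> float:
        if within_corrected is None:
            return 0.0
        try:
            return float(within_corrected.cov.loc[a, b])
        except KeyError:
            return 0.0

    cov = raw.cov.copy()
    means = raw.means.copy()
    for i, a in enumerate(labels):
        for b in labels[i:]:
            value = raw.cov.loc[a, b] / (validity(a) * validity(b))
            if (not is_product(a) and not is_product(b) and a != b
                    and info[(a, raw.level)].contaminated
                    and info[(b, raw.level)].contaminated):
                if n1 is None:
                    raise ValueError(
                        "n1 required to de-contaminate cluster-mean moments")
                value -= within_cov(a, b) / n1
            cov.loc[a, b] = cov.loc[b, a] = value
    # replace latent variances by their measurement-model values
    for l in first_order:
        cov.loc[l, l] = info[(l, raw.level)].psi
        means[l] = means[l] / info[(l, raw.level)].validity
    # product variances from corrected first-order moments (normality)
    for label in labels:
        if not is_product(label):
            continue
        (a, la), (b, lb) = factors_of(label)
        if la == lb == raw.level and a in labels and b in labels:
            cab = float(cov.loc[a, b])
        else:
            # factors at different levels are orthogonal by decomposition
            cab = 0.0
        cov.loc[label, label] = info[(a, la)].psi * info[(b, lb)].psi + cab * cab
        means[label] = cab  # centred product: its mean is the factor covariance
        if zero_product_covariances:
            for factor in (a, b):
                if factor in labels and factor != label:
                    cov.loc[label, factor] = cov.loc[factor, label] = 0.0
    return MomentMatrix(cov=cov, means=means, level=raw.level, n=raw.n,
                        corrected=True, product_terms=dict(raw.product_terms))


# ---------------------------------------------------------------------------
# structural stage
# ---------------------------------------------------------------------------

def estimate_paths(moments: MomentMatrix, outcome: str,
                   predictors: list[str], estimator: str = "croon",
                   ) -> StructuralFit:
    """Solve the normal equations of the path model from a moment matrix.

    Coefficients are the predictor-block inverse times the
    predictor-outcome covariances; the residual variance is the outcome
    variance minus the explained part, and the intercept follows from the
    means.  A non-PD predictor block or negative residual variance flags
    ``non_convergence``.
    """
    if moments.status != CONVERGED:
        return StructuralFit(outcome=outcome, predictors=list(predictors),
                             coefficients=pd.Series(np.nan, index=list(predictors)),
                             intercept=np.nan, residual_variance=np.nan,
                             level=moments.level, estimator=estimator,
                             status=NON_CONVERGENCE)
    P = moments.cov.loc[predictors, predictors].to_numpy()
    s = moments.cov.loc[predictors, outcome].to_numpy()
    vy = float(moments.cov.loc[outcome, outcome])
    status = CONVERGED
    if len(predictors) == 0:
        beta = np.array([])
    elif not (np.all(np.isfinite(P)) and np.all(np.isfinite(s))
              and np.isfinite(vy)):
        beta = np.full(len(predictors), np.nan)
        status = NON_CONVERGENCE
    else:
        try:
            np.linalg.cholesky(P)
            beta = np.linalg.solve(P, s)
        except np.linalg.LinAlgError:
            beta = np.full(len(predictors), np.nan)
            status = NON_CONVERGENCE
    resid = vy - float(s @ beta) if status == CONVERGED else np.nan
    if status == CONVERGED and (not np.isfinite(resid) or resid < 0 or vy < 0):
        status = NON_CONVERGENCE
    mean_pred = moments.means[predictors].to_numpy()
    intercept = (float(moments.means[outcome] - beta @ mean_pred)
                 if status == CONVERGED else np.nan)
    return StructuralFit(outcome=outcome, predictors=list(predictors),
                         coefficients=pd.Series(beta, index=list(predictors)),
                         intercept=intercept, residual_variance=resid,
                         level=moments.level, estimator=estimator, status=status)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _score_weights(fit: FactorModelFit, strict: bool) -> ScoreMatrix | None:
    """Score matrix; for FS, boundary fits are still scored (strict=False)."""
    if fit.status == NON_PD:
        return None
    if fit.status == BOUNDARY and strict:
        return None
    if fit.admissible:
        return regression_score_matrix(fit)
    lam = np.asarray(fit.loadings, float)
    sigma = fit.implied_cov()
    try:
        weights = fit.psi * np.linalg.solve(sigma, lam)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(weights)):
        return None
    return ScoreMatrix(weights=weights, validity=float(weights @ lam),
                       level=fit.level)


@dataclass
class _Pipeline:
    """Shared measurement/score/moment state for one dataset.

    Either raw moment matrix may be missing when the scores feeding it could
    not be computed (e.g. a degenerate between level); estimation then
    proceeds for the levels that remain and the overall status reflects the
    failure.
    """

    design: str
    fits: dict
    raw_within: MomentMatrix | None
    raw_between: MomentMatrix | None
    measurement_admissible: bool


def _prepare(dataset: MultilevelDataset, design: str) -> _Pipeline:
    data = dataset.data
    two_level = ["x", "z", "y"] if design in ("within", "cross") else ["y"]
    between_only = [] if design in ("within", "cross") else ["x", "z"]

    fits: dict[str, object] = {}
    for v in two_level:
        fits[v] = fit_two_level_measurement(dataset, v, identification="marker")
    for v in between_only:
        cols = dataset.indicator_columns(v)
        between_tab, _ = cluster_decompose(data, cols)
        S_b = np.cov(between_tab.to_numpy(), rowvar=False, ddof=1)
        fits[v] = fit_single_factor_ml(S_b, between_tab.to_numpy().mean(axis=0),
                                       n=len(between_tab),
                                       identification="marker", level="between")

    admissible = all(f.status == CONVERGED for f in fits.values())

    # factor scores per level (missing when a fit cannot be scored)
    cluster_id = data["cluster_id"].to_numpy()
    w_scores: dict[str, np.ndarray] = {}
    b_scores: dict[str, np.ndarray] = {}
    for v, fit in fits.items():
        cols = dataset.indicator_columns(v)
        between_tab, within_tab = cluster_decompose(data, cols)
        if isinstance(fit, TwoLevelFactorFit):
            sw = _score_weights(fit.within, strict=False)
            sb = _score_weights(fit.between, strict=False)
            if sw is not None:
                w_scores[v] = within_tab.to_numpy() @ sw.weights
            if sb is not None:
                bt = between_tab.to_numpy()
                b_scores[v] = (bt - bt.mean(axis=0)) @ sb.weights
        else:
            sb = _score_weights(fit, strict=False)
            if sb is not None:
                bt = between_tab.to_numpy()
                b_scores[v] = (bt - bt.mean(axis=0)) @ sb.weights

    raw_within = None
    raw_between = None
    if {"x", "z", "y"} <= set(b_scores):
        if design == "between":
            raw_between = assemble_score_moments(
                pd.DataFrame(b_scores), products=[("x", "z")], level="between")
        else:
            raw_between = assemble_score_moments(
                pd.DataFrame(b_scores), level="between")
    if design == "within" and {"x", "z", "y"} <= set(w_scores):
        raw_within = assemble_score_moments(
            pd.DataFrame(w_scores), products=[("x", "z")], level="within")
    elif design == "cross" and {"x", "z", "y"} <= set(w_scores) \
            and "z" in b_scores:
        wtab = pd.DataFrame(w_scores)
        cluster_index = pd.Index(
            cluster_decompose(data, dataset.indicator_columns("z"))[0].index)
        z_b_per_row = b_scores["z"][cluster_index.get_indexer(cluster_id)]
        xw = wtab["x"] - wtab["x"].mean()
        wtab[product_label("x", "z")] = xw * (z_b_per_row - z_b_per_row.mean())
        raw_within = MomentMatrix(
            cov=wtab.cov(ddof=1), means=wtab.mean(), level="within",
            n=len(wtab),
            product_terms={product_label("x", "z"): (("x", "within"),
                                                     ("z", "between"))})

    return _Pipeline(design=design, fits=fits, raw_within=raw_within,
                     raw_between=raw_between,
                     measurement_admissible=admissible)


def _estimate_from_pipeline(pipe: _Pipeline, estimator: str,
                            harmonic_n1: float) -> SamResult:
    design = pipe.design
    if estimator not in ("fs", "croon"):
        raise ValueError("estimator must be 'fs' or 'croon'")

    def missing(level: str, predictors: list[str]) -> StructuralFit:
        return StructuralFit(outcome="y", predictors=predictors,
                             coefficients=pd.Series(np.nan, index=predictors),
                             intercept=np.nan, residual_variance=np.nan,
                             level=level, estimator=estimator,
                             status=NON_CONVERGENCE)

    if estimator == "croon" and not pipe.measurement_admissible:
        within_fit = (missing("within", ["x", "z", product_label("x", "z")])
                      if design in ("within", "cross") else None)
        return SamResult(estimator=estimator, design=design, within=within_fit,
                         between=missing("between", ["x", "z"]),
                         status=NON_CONVERGENCE, fits=pipe.fits)

    if estimator == "croon":
        within_m = (None if pipe.raw_within is None
                    else croon_correct(pipe.raw_within, pipe.fits))
        between_m = (None if pipe.raw_between is None
                     else croon_correct(pipe.raw_between, pipe.fits,
                                        n1=harmonic_n1,
                                        within_corrected=within_m))
    else:
        within_m, between_m = pipe.raw_within, pipe.raw_between

    within_fit = None
    if design in ("within", "cross"):
        preds_w = ["x", "z", product_label("x", "z")]
        within_fit = (estimate_paths(within_m, "y", preds_w,
                                     estimator=estimator)
                      if within_m is not None else missing("within", preds_w))
        preds_b = ["x", "z"]
    else:
        preds_b = ["x", "z", product_label("x", "z")]
    between_fit = (estimate_paths(between_m, "y", preds_b, estimator=estimator)
                   if between_m is not None else missing("between", preds_b))

    parts = [f for f in (within_fit, between_fit) if f is not None]
    status = CONVERGED if all(f.converged for f in parts) else NON_CONVERGENCE
    return SamResult(estimator=estimator, design=design, within=within_fit,
                     between=between_fit, status=status, fits=pipe.fits)


def population_score_moments(params=None, design: str = "within",
                             n1: float = 50.0):
    """Analytic raw factor-score moment matrices at the population.

    Evaluates the whole measurement stage at the generating parameters:
    measurement fits equal their probability limits (the between fit is the
    contaminated cluster-mean fit at cluster size ``n1``), and the raw score
    moments are the validity-attenuated latent moments.  Returns
    ``(raw_within | None, raw_between, fits)`` shaped exactly like the
    sample pipeline, so SAM-FS and SAM-Croon can be run on them; SAM-Croon
    must reproduce the generating structural coefficients exactly.
    """
    from .datagen import population_moments
    from .params import default_params

    p = params if params is not None else default_params()
    pm = population_moments(p, design)
    lam = np.asarray(p.loadings, float)
    nu = np.asarray(p.indicator_intercepts, float)
    k = lam.size

    def make_fit(psi_f: float, theta: float, level: str) -> FactorModelFit:
        # marker scale: loadings divided by the first loading, variance
        # absorbed accordingly
        lam_m = lam / lam[0]
        return FactorModelFit(loadings=lam_m, theta=np.full(k, theta),
                              psi=psi_f * lam[0] ** 2, indicator_means=nu,
                              n=10 ** 9, status=CONVERGED,
                              identification="marker", level=level)

    def two_level(psi_w: float, psi_b: float) -> TwoLevelFactorFit:
        w = make_fit(psi_w, p.theta_within, "within")
        b = make_fit(psi_b + psi_w / n1, p.theta_between + p.theta_within / n1,
                     "between")
        fit = TwoLevelFactorFit(between=b, within=w, n1=n1,
                                between_contaminated=True)
        fit.r_b = cluster_mean_reliability(fit, n1)
        fit.psi_between_adj = float(b.psi - w.psi / n1)
        fit.theta_between_adj = (np.asarray(b.theta, float)
                                 - np.asarray(w.theta, float) / n1)
        return fit

    W, B = pm.within, pm.between
    fits: dict[str, object] = {}
    if design in ("within", "cross"):
        for v in ("x", "z", "y"):
            fits[v] = two_level(float(W.loc[v, v]), float(B.loc[v, v]))
    else:
        fits["y"] = two_level(float(W.loc["y", "y"]), float(B.loc["y", "y"]))
        for v in ("x", "z"):
            fits[v] = make_fit(float(B.loc[v, v]), p.theta_between, "between")

    def score_info(v: str, level: str):
        return _variable_info(v, fits[v], level)

    def raw_level(latent: pd.DataFrame, level: str,
                  product_terms: dict) -> MomentMatrix:
        labels = list(latent.columns)
        cov = pd.DataFrame(0.0, index=labels, columns=labels)
        inf = {}
        for l in labels:
            if not is_product(l):
                inf[l] = score_info(l, level)
        for i, a in enumerate(labels):
            for b in labels[i:]:
                if is_product(a) or is_product(b):
                    continue
                if a == b:
                    # var(score) = psi_fit * c on the marker scale
                    fit = fits[a]
                    f = (fit.within if isinstance(fit, TwoLevelFactorFit)
                         and level == "within" else
                         fit.between if isinstance(fit, TwoLevelFactorFit)
                         else fit)
                    cov.loc[a, a] = f.psi * inf[a].validity
                else:
                    # latent f-covariance, contaminated at the between level
                    sigma = float(latent.loc[a, b])
                    if level == "between" and inf[a].contaminated and inf[b].contaminated:
                        sigma = sigma + float(pm.within.loc[a, b]) / n1 \
                            if a in pm.within.columns and b in pm.within.columns else sigma
                    cov.loc[a, b] = cov.loc[b, a] = (
                        inf[a].validity * inf[b].validity * sigma)
        means = pd.Series(0.0, index=labels)
        for l in labels:
            if not is_product(l):
                continue
            (a, la), (b, lb) = product_terms[l]
            ia, ib = score_info(a, la), score_info(b, lb)
            if la == lb == level:
                sab = float(cov.loc[a, b])
            else:
                sab = 0.0
            va = (fits[a].within.psi if la == "within" else
                  (fits[a].between.psi if isinstance(fits[a], TwoLevelFactorFit)
                   else fits[a].psi)) * ia.validity
            vb = (fits[b].within.psi if lb == "within" else
                  (fits[b].between.psi if isinstance(fits[b], TwoLevelFactorFit)
                   else fits[b].psi)) * ib.validity
            cov.loc[l, l] = va * vb + sab * sab
            means[l] = sab
            # product-outcome covariance from the structural equation
            cy = score_info("y", level).validity
            cov.loc[l, "y"] = cov.loc["y", l] = (
                ia.validity * ib.validity * cy * float(latent.loc[l, "y"]))
        return MomentMatrix(cov=cov, means=means, level=level,
                            n=10 ** 9, product_terms=product_terms)

    raw_within = None
    if design == "within":
        raw_within = raw_level(W, "within",
                               {product_label("x", "z"): (("x", "within"),
                                                          ("z", "within"))})
        raw_between = raw_level(B, "between", {})
    elif design == "cross":
        raw_within = raw_level(W, "within",
                               {product_label("x", "z"): (("x", "within"),
                                                          ("z", "between"))})
        raw_between = raw_level(B, "between", {})
    else:
        raw_between = raw_level(B, "between",
                                {product_label("x", "z"): (("x", "between"),
                                                           ("z", "between"))})
    return raw_within, raw_between, fits


def sam_estimate(dataset: MultilevelDataset, design: str | None = None,
                 estimator: str = "croon") -> SamResult:
    """Full SAM pipeline for one fully nested dataset.

    Runs two-level measurement models for every latent variable, computes
    level-specific regression factor scores, places the interaction product
    at the level the design dictates, optionally applies the Croon
    correction, and estimates the structural models of the design.
    """
    design = dataset.design if design is None else design
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    if design != dataset.design:
        raise ValueError(f"dataset was generated for design {dataset.design!r}")
    sizes = dataset.data.groupby("cluster_id").size().to_numpy()
    harmonic_n1 = float(sizes.size / np.sum(1.0 / sizes))
    pipe = _prepare(dataset, design)
    return _estimate_from_pipeline(pipe, estimator, harmonic_n1)


def sam_estimate_many(dataset: MultilevelDataset, design: str | None = None,
                      estimators: tuple[str, ...] = ("fs", "croon"),
                      ) -> dict[str, SamResult]:
    """Run several estimators on one dataset, sharing the measurement stage."""
    design = dataset.design if design is None else design
    sizes = dataset.data.groupby("cluster_id").size().to_numpy()
    harmonic_n1 = float(sizes.size / np.sum(1.0 / sizes))
    pipe = _prepare(dataset, design)
    return {e: _estimate_from_pipeline(pipe, e, harmonic_n1) for e in estimators}
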