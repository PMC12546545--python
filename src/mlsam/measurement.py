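"""Single-factor measurement models, factor scoring and cluster-mean reliability.

Single-factor models are estimated by normal-theory ML.  Internally every
fit is computed on the marker scale (first loading fixed at 1, factor
variance free), which anchors the latent scale to the indicators; the
unit-factor-variance view is available via ``identification='variance'``
(the two are the same model up to a rescaling, and the score validity
``A @ Lambda`` is identical under both).

Two-level measurement follows the univariate cluster-means route: the
within model is fit to the pooled within-cluster covariance of the
group-mean-centred indicators and the between model to the raw covariance
of observed cluster means.  The cluster-mean covariance is contaminated by
within-level sampling noise of order 1/n1; the per-indicator cluster-mean
reliability R^B quantifies that contamination and the structural-stage
corrections remove it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FactorModelFit",
    "TwoLevelFactorFit",
    "ScoreMatrix",
    "cluster_decompose",
    "fit_single_factor_ml",
    "fit_two_level_measurement",
    "regression_score_matrix",
    "compute_scores",
    "cluster_mean_reliability",
]

BOUNDARY_TOL = 1e-6

CONVERGED = "converged"
BOUNDARY = "boundary"
NON_PD = "non_PD"


@dataclass
class FactorModelFit:
    """Estimated single-factor measurement model.

    ``loadings``/``theta``/``psi`` are on the scale fixed by
    ``identification``; ``latent_mean`` defaults to 0 and is set by the
    pooled mean model used for arm contrasts.
    """

    loadings: np.ndarray
    theta: np.ndarray
    psi: float
    indicator_means: np.ndarray
    n: int
    status: str = CONVERGED
    identification: str = "marker"
    latent_mean: float = 0.0
    level: str = "single"

    @property
    def admissible(self) -> bool:
        return self.status == CONVERGED

    def implied_cov(self) -> np.ndarray:
        lam = np.asarray(self.loadings, float)
        return self.psi * np.outer(lam, lam) + np.diag(self.theta)

    def as_variance_identified(self) -> "FactorModelFit":
        """Rescale to the unit-factor-variance identification."""
        if self.identification == "variance":
            return self
        s = np.sqrt(self.psi)
        return FactorModelFit(
            loadings=np.asarray(self.loadings, float) * s,
            theta=np.asarray(self.theta, float).copy(),
            psi=1.0,
            indicator_means=np.asarray(self.indicator_means, float).copy(),
            n=self.n, status=self.status, identification="variance",
            latent_mean=self.latent_mean / s if s > 0 else np.nan,
            level=self.level,
        )

    def to_dict(self) -> dict:
        return {
            "loadings": list(map(float, self.loadings)),
            "theta": list(map(float, self.theta)),
            "psi": float(self.psi),
            "indicator_means": list(map(float, self.indicator_means)),
            "latent_mean": float(self.latent_mean),
            "n": int(self.n),
            "status": self.status,
            "identification": self.identification,
            "level": self.level,
        }


@dataclass
class TwoLevelFactorFit:
    """Level-specific measurement fits for one two-level latent variable.

    ``psi_between_adj`` / ``theta_between_adj`` are the between-level
    variance components after removing the within-level contamination of
    order 1/n1 from the raw cluster-mean fit (cross-level loading equality
    assumed, as in the generating model).
    """

    between: FactorModelFit
    within: FactorModelFit
    n1: float  # harmonic-mean cluster size used in the decomposition
    r_b: np.ndarray = field(default_factory=lambda: np.array([]))
    psi_between_adj: float = np.nan
    theta_between_adj: np.ndarray = field(default_factory=lambda: np.array([]))
    # True when the between fit was estimated on raw cluster means (and so
    # absorbs within-level noise of order 1/n1); False when constructed from
    # clean between-level parameters.
    between_contaminated: bool = True

    @property
    def status(self) -> str:
        for s in (NON_PD, BOUNDARY):
            if self.between.status == s or self.within.status == s:
                return s
        return CONVERGED

    @property
    def admissible(self) -> bool:
        return self.status == CONVERGED

    def to_dict(self) -> dict:
        return {
            "between": self.between.to_dict(),
            "within": self.within.to_dict(),
            "n1": float(self.n1),
            "r_b": list(map(float, self.r_b)),
            "psi_between_adj": float(self.psi_between_adj),
            "status": self.status,
        }


@dataclass
class ScoreMatrix:
    """Regression-method factor-score weights and their validity c = A @ Lambda."""

    weights: np.ndarray
    validity: float
    level: str = "single"


# ---------------------------------------------------------------------------
# cluster decomposition
# ---------------------------------------------------------------------------

def cluster_decompose(data: pd.DataFrame, columns: list[str] | None = None,
                      cluster_col: str = "cluster_id",
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split indicators into observed cluster means and within deviations.

    Returns ``(between, within)`` where ``between`` has one row per cluster
    (the observed cluster means, indexed by cluster id) and ``within`` is
    row-aligned with ``data`` (each value minus its own cluster mean).
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    if columns is None:
        columns = [c for c in data.columns
                   if c not in (cluster_col, "unit_id", "arm")
                   and pd.api.types.is_numeric_dtype(data[c])]
    grouped = data.groupby(cluster_col)[columns]
    between = grouped.mean()
    within = data[columns] - grouped.transform("mean")
    return between, within


# ---------------------------------------------------------------------------
# single-factor ML
# ---------------------------------------------------------------------------

def _closed_form_marker(S: np.ndarray) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Exact ML solution for the just-identified three-indicator model.

    With p = 3 the single-factor model saturates the covariance matrix, so
    the ML estimates solve the moment equations exactly (when admissible).
    """
    if S.shape[0] != 3:
        return None
    s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
    if abs(s23) < 1e-12 or abs(s13) < 1e-12 or abs(s12) < 1e-12:
        return None
    psi = s12 * s13 / s23
    if psi <= 0:
        return None
    lam = np.array([1.0, s23 / s13, s23 / s12])
    theta = np.diag(S) - lam ** 2 * psi
    return lam, theta, psi


def _ml_discrepancy(S: np.ndarray, lam: np.ndarray, theta: np.ndarray,
                    psi: float) -> float:
    sigma = psi * np.outer(lam, lam) + np.diag(theta)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        # large finite penalty keeps quasi-Newton line searches stable
        return 1e10
    return float(logdet + np.trace(np.linalg.solve(sigma, S)))


def _optimize_marker(S: np.ndarray, starts: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float, bool]:
    p = S.shape[0]
    lo = np.log(1e-8)

    def unpack(x):
        lam = np.concatenate([[1.0], x[: p - 1]])
        psi = np.exp(x[p - 1])
        theta = np.exp(x[p:])
        return lam, theta, psi

    def obj(x):
        return _ml_discrepancy(S, *_reorder(unpack(x)))

    def _reorder(t):
        lam, theta, psi = t
        return lam, theta, psi

    best, best_f = None, np.inf
    ok = False
    for x0 in starts:
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B",
            bounds=[(None, None)] * (p - 1) + [(lo, 20.0)] * (p + 1))
        if res.fun < best_f:
            best, best_f, ok = res.x, res.fun, bool(res.success)
    lam, theta, psi = unpack(best)
    return lam, theta, psi, ok


def _optimize_given_loadings(S: np.ndarray, lam: np.ndarray,
                             ) -> tuple[np.ndarray, float, bool]:
    """ML over (psi, theta) with the loading vector held fixed."""
    p = S.shape[0]
    lo = np.log(1e-8)
    diag = np.diag(S)

    def unpack(x):
        return np.exp(x[1:]), np.exp(x[0])

    def obj(x):
        theta, psi = unpack(x)
        return _ml_discrepancy(S, lam, theta, psi)

    common0 = max(np.mean(np.abs(S[np.triu_indices(p, 1)])), 1e-3)
    start1 = np.log(np.concatenate([[common0],
                                    np.maximum(diag - common0, 1e-3)]))
    start2 = np.log(np.concatenate([[common0 / 2.0],
                                    np.maximum(diag / 2.0, 1e-3)]))
    best, best_f, ok = None, np.inf, False
    for x0 in (start1, start2):
        res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                bounds=[(lo, 20.0)] * (p + 1))
        if res.fun < best_f:
            best, best_f, ok = res.x, res.fun, bool(res.success)
    theta, psi = unpack(best)
    return theta, psi, ok


def fit_single_factor_ml(S: np.ndarray, means: np.ndarray | None = None,
                         n: int = 0, identification: str = "variance",
                         level: str = "single",
                         fixed_loadings: np.ndarray | None = None,
                         ) -> FactorModelFit:
    """ML fit of a single-factor model to a sample covariance matrix.

    ``fixed_loadings`` holds the loading vector fixed (used for the
    between-level fit of a two-level variable, whose loadings are tied to
    the within-level estimates under cross-level invariance); only the
    factor and residual variances are then estimated.

    Admissibility flags: ``non_PD`` when the input covariance is not
    positive definite (returned, not raised); ``boundary`` when any residual
    variance or the factor variance is estimated at (or below) the 1e-6
    tolerance, including Heywood cases.
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("covariance matrix must be square and symmetric")
    if n and n <= p:
        raise ValueError("n must exceed the number of indicators")
    means = np.zeros(p) if means is None else np.asarray(means, float)

    def finish(lam, theta, psi, status):
        fit = FactorModelFit(loadings=np.asarray(lam, float),
                             theta=np.asarray(theta, float), psi=float(psi),
                             indicator_means=means, n=int(n), status=status,
                             identification="marker", level=level)
        if identification == "variance":
            fit = fit.as_variance_identified()
        return fit

    eigvals = np.linalg.eigvalsh((S + S.T) / 2.0)
    if eigvals.min() <= 0:
        nanp = np.full(p, np.nan)
        return finish(nanp, nanp, np.nan, NON_PD)

    if fixed_loadings is not None:
        lam = np.asarray(fixed_loadings, float)
        theta, psi, ok = _optimize_given_loadings(S, lam)
        status = CONVERGED if (ok and theta.min() > BOUNDARY_TOL
                               and psi > BOUNDARY_TOL) else BOUNDARY
        return finish(lam, theta, psi, status)

    cf = _closed_form_marker(S)
    if cf is not None:
        lam, theta, psi = cf
        if theta.min() > BOUNDARY_TOL and psi > BOUNDARY_TOL:
            return finish(lam, theta, psi, CONVERGED)

    # optimizer path (p != 3, degenerate closed form, or Heywood case):
    # log-variance parameterisation, two starts
    diag = np.diag(S)
    start1 = np.concatenate([np.ones(p - 1),
                             [np.log(max(np.abs(S[0, 1]), 0.1))],
                             np.log(np.maximum(diag / 2.0, 1e-3))])
    start2 = np.concatenate([0.5 * np.ones(p - 1), [np.log(0.5)],
                             np.log(np.maximum(diag, 1e-3)) - 1.0])
    lam, theta, psi, ok = _optimize_marker(S, [start1, start2])
    status = CONVERGED if (ok and theta.min() > BOUNDARY_TOL
                           and psi > BOUNDARY_TOL) else BOUNDARY
    if status == CONVERGED:
        # a fit indistinguishable from the diagonal-only model has no
        # identifiable common factor: boundary (Lambda psi -> 0)
        f_fit = _ml_discrepancy(S, lam, theta, psi)
        f_diag = float(np.sum(np.log(diag)) + p)
        if f_diag - f_fit < 1e-6:
            status = BOUNDARY
    return finish(lam, theta, psi, status)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def regression_score_matrix(fit: FactorModelFit) -> ScoreMatrix:
    """Regression-method factor-score weights A = psi Lambda' Sigma^{-1}."""
    if not fit.admissible:
        raise ValueError(f"cannot score an inadmissible fit (status={fit.status})")
    lam = np.asarray(fit.loadings, float)
    sigma = fit.implied_cov()
    weights = fit.psi * np.linalg.solve(sigma, lam)
    return ScoreMatrix(weights=weights, validity=float(weights @ lam),
                       level=fit.level)


def compute_scores(score_matrix: ScoreMatrix, table: pd.DataFrame | np.ndarray,
                   means: np.ndarray) -> np.ndarray:
    """Weighted sum of mean-centred indicators; missing rows stay missing."""
    values = np.asarray(table, float)
    return (values - np.asarray(means, float)[None, :]) @ score_matrix.weights


# ---------------------------------------------------------------------------
# two-level measurement
# ---------------------------------------------------------------------------

def _harmonic_mean(sizes: np.ndarray) -> float:
    sizes = np.asarray(sizes, float)
    return float(sizes.size / np.sum(1.0 / sizes))


def fit_two_level_measurement(dataset, variable: str,
                              identification: str = "marker",
                              tie_loadings: bool = True,
                              ) -> TwoLevelFactorFit:
    """Two-level single-factor fit via the univariate cluster-means route.

    The within fit uses the pooled within covariance of the
    group-mean-centred data; the between fit uses the raw covariance of
    observed cluster means (one record per cluster).  Under
    ``tie_loadings`` (default) the between-level loadings are held at the
    within-level estimates -- cross-level loading invariance, which
    stabilises the between fit whose effective sample size is only the
    number of clusters.  R^B and the contamination-adjusted between
    variance components are attached.
    """
    cols = dataset.indicator_columns(variable)
    data = dataset.data if hasattr(dataset, "data") else dataset
    sizes = data.groupby("cluster_id").size().to_numpy()
    n2 = sizes.size
    if n2 < 2:
        raise ValueError("at least two clusters are required")
    if sizes.max() < 2:
        raise ValueError("within model inestimable: every cluster has a single row")

    between_tab, within_tab = cluster_decompose(data, cols)
    N = len(data)
    W = within_tab.to_numpy()
    S_w = W.T @ W / (N - n2)  # pooled within covariance, unbiased
    S_b = np.cov(between_tab.to_numpy(), rowvar=False, ddof=1)
    n1 = _harmonic_mean(sizes)

    within_fit = fit_single_factor_ml(S_w, np.zeros(len(cols)), n=N,
                                      identification=identification,
                                      level="within")
    fixed = (within_fit.loadings if tie_loadings and within_fit.admissible
             else None)
    between_fit = fit_single_factor_ml(
        S_b, between_tab.to_numpy().mean(axis=0), n=n2,
        identification=identification, level="between",
        fixed_loadings=fixed)

    fit = TwoLevelFactorFit(between=between_fit, within=within_fit, n1=n1)
    if fit.admissible:
        fit.r_b = cluster_mean_reliability(fit, n1)
        fit.psi_between_adj = float(between_fit.psi - within_fit.psi / n1)
        fit.theta_between_adj = (np.asarray(between_fit.theta, float)
                                 - np.asarray(within_fit.theta, float) / n1)
    return fit


def cluster_mean_reliability(fit: TwoLevelFactorFit, n1: float | None = None,
                             ) -> np.ndarray:
    """Per-indicator reliability of the cluster mean for its between part.

    R^B_m = (lam_B_m^2 psi_B + theta_B_m) /
            (lam_B_m^2 psi_B + theta_B_m + (lam_W_m^2 psi_W + theta_W_m) / n1)

    where the between variance components are the contamination-adjusted
    ones (the raw cluster-mean fit absorbs (lam_W^2 psi_W + theta_W)/n1, so
    the adjusted numerator is the raw between indicator variance minus the
    within term).  Tends to 1 as n1 grows.
    """
    if not (fit.between.admissible and fit.within.admissible):
        raise ValueError("both level fits must be admissible")
    n1 = float(fit.n1 if n1 is None else n1)
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    lam_w = np.asarray(fit.within.loadings, float)
    within_total = lam_w ** 2 * fit.within.psi + np.asarray(fit.within.theta, float)
    lam_b = np.asarray(fit.between.loadings, float)
    between_total = lam_b ** 2 * fit.between.psi + np.asarray(fit.between.theta, float)
    if fit.between_contaminated:
        # raw cluster-mean variance minus the within contamination at the
        # fit's own cluster size
        between_total = between_total - within_total / fit.n1
    return between_total / (between_total + within_total / n1)
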