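"""Synthetic data generation and analytic population moments.

Three fully nested two-level designs are supported, differing in where the
latent interaction lives:

``within``
    X, Z, Y are level-1 latent variables with within and between
    components; the product ``eta_X^W eta_Z^W`` enters the within-level
    outcome equation.
``cross``
    As above, but the product is ``eta_X^W eta_Z^B`` (the between component
    of the moderator crossed with the within component of the focal
    predictor).
``between``
    X and Z live solely at the cluster level (standard between-only factor
    models, cluster-level indicators); the product ``eta_X^B eta_Z^B``
    enters the between-level outcome equation.

The partially nested (2/1) generator produces a clustered treatment arm
(mediator M, between-only moderator Z, outcome Y) and an unclustered
control arm of singleton clusters (M and Y only; the moderator does not
exist in the control arm and its indicator columns are missing there).

Every generator returns the exact latent draws in a sidecar table so that
"true model" benchmark fits can be computed on the latent values
themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PopulationParams, default_params

__all__ = [
    "DESIGNS",
    "MultilevelDataset",
    "PartiallyNestedDataset",
    "PopulationMoments",
    "generate_mlsem",
    "generate_pn",
    "population_moments",
]

DESIGNS = ("within", "cross", "between")


@dataclass
class MultilevelDataset:
    """Long-format indicator data with cluster structure.

    ``data`` holds one row per individual with ``cluster_id``, ``unit_id``
    and indicator columns ``x1..x_p``, ``z1..z_p``, ``y1..y_p``.
    ``sidecar`` holds the exact generated latent values, aligned 1:1 with
    ``data`` rows (between-level values repeated within cluster).
    """

    data: pd.DataFrame
    design: str
    sidecar: pd.DataFrame | None = None
    params: PopulationParams | None = None

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        if self.sidecar is not None and len(self.sidecar) != len(self.data):
            raise ValueError("sidecar must align 1:1 with data rows")

    @property
    def n_clusters(self) -> int:
        return self.data["cluster_id"].nunique()

    def indicator_columns(self, variable: str) -> list[str]:
        cols = [c for c in self.data.columns if c.startswith(variable)
                and c[len(variable):].isdigit()]
        if not cols:
            raise KeyError(f"no indicator columns for variable {variable!r}")
        return sorted(cols, key=lambda c: int(c[len(variable):]))


@dataclass
class PartiallyNestedDataset:
    """2/1 partially nested indicator data (clustered treatment, singleton control)."""

    data: pd.DataFrame
    sidecar: pd.DataFrame | None = None
    params: PopulationParams | None = None

    def __post_init__(self) -> None:
        arms = set(self.data["arm"].unique())
        if not arms <= {"treatment", "control"}:
            raise ValueError(f"unexpected arm labels: {arms}")
        ctrl = self.data[self.data["arm"] == "control"]
        if len(ctrl) and ctrl.groupby("cluster_id").size().max() > 1:
            raise ValueError("control clusters must be singletons")

    def arm(self, label: str) -> pd.DataFrame:
        return self.data[self.data["arm"] == label]

    def indicator_columns(self, variable: str) -> list[str]:
        cols = [c for c in self.data.columns if c.startswith(variable)
                and c[len(variable):].isdigit()]
        if not cols:
            raise KeyError(f"no indicator columns for variable {variable!r}")
        return sorted(cols, key=lambda c: int(c[len(variable):]))


@dataclass
class PopulationMoments:
    """Exact level-specific latent covariance matrices, with product terms.

    ``within`` / ``between`` are labelled covariance DataFrames over the
    latent variables of that level (product term included where the design
    places one).  ``means`` are the latent means (zero in the fully nested
    designs except for the product term, whose mean under centering is the
    latent covariance of its factors).
    """

    design: str
    within: pd.DataFrame
    between: pd.DataFrame
    means_within: pd.Series
    means_between: pd.Series
    reliability_within: float
    reliability_between: float


def _product_variance(va: float, vb: float, cab: float) -> float:
    return va * vb + cab * cab


def _indicators(latent: np.ndarray, loadings: np.ndarray, resid: np.ndarray,
                intercepts: np.ndarray) -> np.ndarray:
    """latent (n,) -> indicator matrix (n, p)."""
    return intercepts[None, :] + np.outer(latent, loadings) + resid


def generate_mlsem(params: PopulationParams | None = None, design: str = "within",
                   n2: int = 30, n1: int = 50, seed: int | None = None,
                   ) -> MultilevelDataset:
    """Generate a balanced two-level dataset from the population model.

    Parameters
    ----------
    params : PopulationParams, optional
        Generating parameters (defaults to the study's fixed values).
    design : {'within', 'cross', 'between'}
        Location of the latent interaction.
    n2, n1 : int
        Number of clusters and individuals per cluster (``n2 >= 2``,
        ``n1 >= 2``).
    seed : int
        Seed for the random generator; identical seeds give identical data.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    if n2 < 2 or n1 < 2:
        raise ValueError("n2 and n1 must both be >= 2")
    p = params if params is not None else default_params()
    rng = np.random.default_rng(seed)
    lam = np.asarray(p.loadings, float)
    nu = np.asarray(p.indicator_intercepts, float)
    k = lam.size
    N = n2 * n1

    rho_b = p.latent_corr_between
    cov_b = np.array([[p.psi_between, rho_b * p.psi_between],
                      [rho_b * p.psi_between, p.psi_between]])
    eta_xz_b = rng.multivariate_normal([0.0, 0.0], cov_b, size=n2)
    eta_x_b, eta_z_b = eta_xz_b[:, 0], eta_xz_b[:, 1]

    b0, b1, b2, b3 = p.beta
    g0, g1, g2, g3 = p.gamma

    if design == "between":
        eta_y_b = (g0 + g1 * eta_x_b + g2 * eta_z_b + g3 * eta_x_b * eta_z_b
                   + rng.normal(0.0, np.sqrt(p.tau2_y), n2))
    else:
        eta_y_b = (g0 + g1 * eta_x_b + g2 * eta_z_b
                   + rng.normal(0.0, np.sqrt(p.tau2_y), n2))

    rho_w = p.latent_corr_within
    cov_w = np.array([[p.psi_within, rho_w * p.psi_within],
                      [rho_w * p.psi_within, p.psi_within]])
    cluster_id = np.repeat(np.arange(n2), n1)
    unit_id = np.tile(np.arange(n1), n2)

    if design == "between":
        eta_x_w = eta_z_w = None
        eta_y_w = b0 + rng.normal(0.0, np.sqrt(p.sigma2_y), N)
    else:
        eta_xz_w = rng.multivariate_normal([0.0, 0.0], cov_w, size=N)
        eta_x_w, eta_z_w = eta_xz_w[:, 0], eta_xz_w[:, 1]
        eps_w = rng.normal(0.0, np.sqrt(p.sigma2_y), N)
        if design == "within":
            prod = eta_x_w * eta_z_w
        else:  # cross
            prod = eta_x_w * eta_z_b[cluster_id]
        eta_y_w = b0 + b1 * eta_x_w + b2 * eta_z_w + b3 * prod + eps_w

    def resid_b():
        return rng.normal(0.0, np.sqrt(p.theta_between), (n2, k))

    def resid_w():
        return rng.normal(0.0, np.sqrt(p.theta_within), (N, k))

    cols: dict[str, np.ndarray] = {"cluster_id": cluster_id, "unit_id": unit_id}
    side: dict[str, np.ndarray] = {"cluster_id": cluster_id, "unit_id": unit_id}

    for name, e_b, e_w in (("x", eta_x_b, eta_x_w), ("z", eta_z_b, eta_z_w)):
        if design == "between":
            # between-only variable: cluster-level indicators, replicated per row
            ind = _indicators(e_b, lam, resid_b(), nu)[cluster_id]
        else:
            ind = (_indicators(e_b, lam, resid_b(), nu)[cluster_id]
                   + np.outer(e_w, lam) + resid_w())
        for m in range(k):
            cols[f"{name}{m + 1}"] = ind[:, m]
        side[f"eta_{name}_b"] = e_b[cluster_id]
        if e_w is not None:
            side[f"eta_{name}_w"] = e_w

    ind_y = (_indicators(eta_y_b, lam, resid_b(), nu)[cluster_id]
             + np.outer(eta_y_w, lam) + resid_w())
    for m in range(k):
        cols[f"y{m + 1}"] = ind_y[:, m]
    side["eta_y_b"] = eta_y_b[cluster_id]
    side["eta_y_w"] = eta_y_w

    return MultilevelDataset(data=pd.DataFrame(cols), design=design,
                             sidecar=pd.DataFrame(side), params=p)


def generate_pn(params: PopulationParams | None = None, n2_t: int = 30,
                n1_t: int = 20, seed: int | None = None) -> PartiallyNestedDataset:
    """Generate a balanced 2/1 partially nested dataset.

    The treatment arm has ``n2_t`` clusters of ``n1_t`` individuals; the
    control arm has ``n2_t * n1_t`` unclustered individuals (singleton
    clusters), matching the balanced design n(c) = n2(t) x n1(t).
    """
    if n2_t < 2 or n1_t < 1:
        raise ValueError("n2_t must be >= 2 and n1_t >= 1")
    p = params if params is not None else default_params()
    rng = np.random.default_rng(seed)
    lam = np.asarray(p.loadings, float)
    nu = np.asarray(p.indicator_intercepts, float)
    k = lam.size
    n_t = n2_t * n1_t
    n_c = n2_t * n1_t

    # --- treatment arm (two-level) ---
    eta_m_b = p.a_t + rng.normal(0.0, np.sqrt(p.tau2_t), n2_t)
    eta_z_b = rng.normal(0.0, np.sqrt(p.psi_z_b), n2_t)
    if p.cov_MZ != 0.0:
        # regenerate jointly when a mediator-moderator covariance is requested
        cov = np.array([[p.tau2_t, p.cov_MZ], [p.cov_MZ, p.psi_z_b]])
        draw = rng.multivariate_normal([p.a_t, 0.0], cov, size=n2_t)
        eta_m_b, eta_z_b = draw[:, 0], draw[:, 1]
    eta_y_b = (p.mu0_t + p.B_t * eta_m_b + p.xi1_t * eta_z_b
               + p.xi2_t * eta_m_b * eta_z_b
               + rng.normal(0.0, np.sqrt(p.tau2_t), n2_t))

    cl_t = np.repeat(np.arange(n2_t), n1_t)
    eta_m_w = rng.normal(0.0, np.sqrt(p.sigma2_t), n_t)
    eta_y_w = p.b1_t * eta_m_w + rng.normal(0.0, np.sqrt(p.sigma2_t), n_t)

    def t_resid_b():
        return rng.normal(0.0, np.sqrt(p.tau2_t), (n2_t, k))

    def t_resid_w():
        return rng.normal(0.0, np.sqrt(p.sigma2_t), (n_t, k))

    m_t = (_indicators(eta_m_b, lam, t_resid_b(), nu)[cl_t]
           + np.outer(eta_m_w, lam) + t_resid_w())
    y_t = (_indicators(eta_y_b, lam, t_resid_b(), nu)[cl_t]
           + np.outer(eta_y_w, lam) + t_resid_w())
    z_t = _indicators(eta_z_b, lam, t_resid_b(), nu)[cl_t]

    # --- control arm (single level, singleton clusters) ---
    eta_m_c = p.a_c + rng.normal(0.0, np.sqrt(p.sigma2_c), n_c)
    eta_y_c = (p.mu0_c + p.b1_c * eta_m_c
               + rng.normal(0.0, np.sqrt(p.sigma2_c), n_c))
    m_c = _indicators(eta_m_c, lam,
                      rng.normal(0.0, np.sqrt(p.sigma2_c), (n_c, k)), nu)
    y_c = _indicators(eta_y_c, lam,
                      rng.normal(0.0, np.sqrt(p.sigma2_c), (n_c, k)), nu)

    cols: dict[str, np.ndarray] = {
        "arm": np.concatenate([np.full(n_t, "treatment"), np.full(n_c, "control")]),
        "cluster_id": np.concatenate([cl_t, n2_t + np.arange(n_c)]),
        "unit_id": np.concatenate([np.tile(np.arange(n1_t), n2_t), np.zeros(n_c, int)]),
    }
    for mcol in range(k):
        cols[f"m{mcol + 1}"] = np.concatenate([m_t[:, mcol], m_c[:, mcol]])
    for mcol in range(k):
        cols[f"y{mcol + 1}"] = np.concatenate([y_t[:, mcol], y_c[:, mcol]])
    for mcol in range(k):
        # the moderator does not exist in the control arm: missing, never zero
        cols[f"z{mcol + 1}"] = np.concatenate([z_t[:, mcol], np.full(n_c, np.nan)])

    side = {
        "arm": cols["arm"], "cluster_id": cols["cluster_id"], "unit_id": cols["unit_id"],
        "eta_m_b": np.concatenate([eta_m_b[cl_t], eta_m_c]),
        "eta_m_w": np.concatenate([eta_m_w, np.full(n_c, np.nan)]),
        "eta_z_b": np.concatenate([eta_z_b[cl_t], np.full(n_c, np.nan)]),
        "eta_y_b": np.concatenate([eta_y_b[cl_t], eta_y_c]),
        "eta_y_w": np.concatenate([eta_y_w, np.full(n_c, np.nan)]),
    }
    return PartiallyNestedDataset(data=pd.DataFrame(cols),
                                  sidecar=pd.DataFrame(side), params=p)


def population_moments(params: PopulationParams | None = None,
                       design: str = "within") -> PopulationMoments:
    """Exact latent covariance matrices implied by the generating model.

    Product-term variances follow var(ab) = var(a) var(b) + cov(a, b)^2 for
    centred normal factors; covariances between a product and a first-order
    factor are zero (odd moments of centred normals vanish); the
    product-outcome covariance is the interaction slope times the product
    variance.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    p = params if params is not None else default_params()
    b0, b1, b2, b3 = p.beta
    g0, g1, g2, g3 = p.gamma
    pw, pb = p.psi_within, p.psi_between
    cw = p.latent_corr_within * pw
    cb = p.latent_corr_between * pb

    def block(labels, cov, means=None):
        m = pd.Series(0.0 if means is None else means, index=labels, dtype=float)
        return pd.DataFrame(cov, index=labels, columns=labels), m

    if design == "within":
        vprod = _product_variance(pw, pw, cw)
        cxy = b1 * pw + b2 * cw
        czy = b2 * pw + b1 * cw
        cpy = b3 * vprod
        vy = b1 * cxy + b2 * czy + b3 * cpy + p.sigma2_y
        W, mW = block(
            ["x", "z", "x:z", "y"],
            [[pw, cw, 0.0, cxy],
             [cw, pw, 0.0, czy],
             [0.0, 0.0, vprod, cpy],
             [cxy, czy, cpy, vy]],
            {"x": 0.0, "z": 0.0, "x:z": cw, "y": b3 * cw},
        )
        cxy_b = g1 * pb + g2 * cb
        czy_b = g2 * pb + g1 * cb
        vy_b = g1 * cxy_b + g2 * czy_b + p.tau2_y
        B, mB = block(["x", "z", "y"],
                      [[pb, cb, cxy_b], [cb, pb, czy_b], [cxy_b, czy_b, vy_b]])
    elif design == "cross":
        vprod = pw * pb  # eta_X^W independent of eta_Z^B across levels
        cxy = b1 * pw + b2 * cw
        czy = b2 * pw + b1 * cw
        cpy = b3 * vprod
        vy = b1 * cxy + b2 * czy + b3 * cpy + p.sigma2_y
        W, mW = block(
            ["x", "z", "x:z", "y"],
            [[pw, cw, 0.0, cxy],
             [cw, pw, 0.0, czy],
             [0.0, 0.0, vprod, cpy],
             [cxy, czy, cpy, vy]])
        cxy_b = g1 * pb + g2 * cb
        czy_b = g2 * pb + g1 * cb
        vy_b = g1 * cxy_b + g2 * czy_b + p.tau2_y
        B, mB = block(["x", "z", "y"],
                      [[pb, cb, cxy_b], [cb, pb, czy_b], [cxy_b, czy_b, vy_b]])
    else:  # between
        W, mW = block(["y"], [[p.sigma2_y]])
        vprod = _product_variance(pb, pb, cb)
        cxy_b = g1 * pb + g2 * cb
        czy_b = g2 * pb + g1 * cb
        cpy_b = g3 * vprod
        vy_b = g1 * cxy_b + g2 * czy_b + g3 * cpy_b + p.tau2_y
        B, mB = block(
            ["x", "z", "x:z", "y"],
            [[pb, cb, 0.0, cxy_b],
             [cb, pb, 0.0, czy_b],
             [0.0, 0.0, vprod, cpy_b],
             [cxy_b, czy_b, cpy_b, vy_b]],
            {"x": 0.0, "z": 0.0, "x:z": cb, "y": g3 * cb},
        )
    return PopulationMoments(
        design=design, within=W, between=B, means_within=mW, means_between=mB,
        reliability_within=p.composite_reliability("within"),
        reliability_between=p.composite_reliability("between"),
    )
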