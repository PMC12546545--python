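"""Population parameters for the simulation designs.

The default instance encodes the generating model used throughout the
package: three indicators per latent variable with unit loadings and zero
intercepts, unit-variance latent predictor factors at each level with a
latent correlation of 0.25, indicator residual variances of 0.8 (within)
and 0.2 (between), structural slopes of 0.4 for first-order predictors and
0.2 for the latent interaction, and conditional outcome residual variances
of 0.8 (within) and 0.2 (between).  The partially nested (2/1) arm-specific
parameters encode a latent moderated mediation with a treatment-mediator
path of 0.5, mediator-outcome path of 0.4, moderation slope 0.15 and a
main effect of 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PopulationParams", "default_params"]


@dataclass(frozen=True)
class PopulationParams:
    """All generating quantities of the simulation designs.

    Parameters
    ----------
    loadings : tuple of float
        Factor loadings, one per indicator (same for every latent block).
    indicator_intercepts : tuple of float
        Indicator intercepts (means), one per indicator.
    theta_within, theta_between : float
        Indicator residual variances at the within / between level.
    psi_within, psi_between : float
        Latent predictor factor variances per level (identification scale).
    latent_corr_within, latent_corr_between : float
        Correlation between the two predictor factors at each level.
    beta : tuple of float
        Within-level structural coefficients ``(beta0, beta1, beta2, beta3)``.
    gamma : tuple of float
        Between-level structural coefficients ``(gamma0, gamma1, gamma2,
        gamma3)``; ``gamma3`` is used only in the between-interaction design.
    sigma2_y, tau2_y : float
        Conditional residual variances of the latent outcome per level.

    Arm-specific parameters of the partially nested design
    ------------------------------------------------------
    a_t, a_c : float
        Latent mediator means in the treatment / control arm.
    mu0_t, mu0_c : float
        Conditional latent outcome intercepts per arm.
    B_t : float
        Between-level mediator->outcome slope in the treatment arm.
    b1_t, b1_c : float
        Within-treatment and control mediator->outcome slopes.
    xi1_t, xi2_t : float
        Moderator slope and moderation (interaction) slope.
    sigma2_t, tau2_t : float
        Treatment-arm conditional outcome residual variances (within/between);
        the same decomposition is used for the mediator residuals and the
        treatment indicator residuals.
    sigma2_c : float
        Control-arm residual variance (single level); also the control
        indicator residual variance.
    psi_z_b : float
        Variance of the between-only latent moderator in the treatment arm.
    cov_MZ : float
        Mediator-moderator latent covariance (between level, treatment arm).
    """

    loadings: tuple[float, ...] = (1.0, 1.0, 1.0)
    indicator_intercepts: tuple[float, ...] = (0.0, 0.0, 0.0)
    theta_within: float = 0.8
    theta_between: float = 0.2
    psi_within: float = 1.0
    psi_between: float = 1.0
    latent_corr_within: float = 0.25
    latent_corr_between: float = 0.25
    beta: tuple[float, float, float, float] = (0.0, 0.4, 0.4, 0.2)
    gamma: tuple[float, float, float, float] = (0.0, 0.4, 0.4, 0.2)
    sigma2_y: float = 0.8
    tau2_y: float = 0.2
    # --- partially nested (2/1) design ---
    a_t: float = 0.5
    a_c: float = 0.0
    mu0_t: float = 0.7
    mu0_c: float = 0.0
    B_t: float = 0.4
    b1_t: float = 0.0
    b1_c: float = 0.4
    xi1_t: float = 0.2
    xi2_t: float = 0.15
    sigma2_t: float = 0.8
    tau2_t: float = 0.2
    sigma2_c: float = 1.0
    psi_z_b: float = 1.0
    cov_MZ: float = 0.0

    def __post_init__(self) -> None:
        if len(self.loadings) < 2:
            raise ValueError("at least two indicators per factor are required")
        if len(self.indicator_intercepts) != len(self.loadings):
            raise ValueError("indicator_intercepts must match loadings in length")
        for name in ("theta_within", "theta_between", "psi_within", "psi_between",
                     "sigma2_y", "tau2_y", "sigma2_t", "tau2_t", "sigma2_c",
                     "psi_z_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("latent_corr_within", "latent_corr_between"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        if abs(self.cov_MZ) >= np.sqrt(self.tau2_t * self.psi_z_b):
            raise ValueError("cov_MZ violates the Cauchy-Schwarz bound")

    @property
    def n_indicators(self) -> int:
        return len(self.loadings)

    def composite_reliability(self, level: str) -> float:
        """Implied composite reliability (omega) of a unit-variance factor.

        omega = (sum Lambda)^2 psi / ((sum Lambda)^2 psi + sum Theta) for the
        given ``level`` ('within' or 'between').
        """
        lam = np.asarray(self.loadings, dtype=float)
        if level == "within":
            psi, theta = self.psi_within, self.theta_within
        elif level == "between":
            psi, theta = self.psi_between, self.theta_between
        else:
            raise ValueError("level must be 'within' or 'between'")
        common = lam.sum() ** 2 * psi
        return float(common / (common + theta * lam.size))

    def with_overrides(self, **kwargs) -> "PopulationParams":
        return replace(self, **kwargs)


def default_params() -> PopulationParams:
    """The default generating parameters of both simulation studies."""
    return PopulationParams()
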