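"""SAM estimation for 2/1 partially nested SEMs with latent moderated mediation.

The treatment arm is a two-level system: a level-1 latent mediator M and
outcome Y (decomposed into within/between components) and a between-only
latent moderator Z that does not exist in the control arm.  The control arm
is single level (singleton clusters).  Three structural models are
estimated from arm/level-specific factor scores:

* treatment-between:  Y^B ~ M^B + Z^B + M^B x Z^B  (slopes B, xi1, xi2)
* treatment-within:   Y^W ~ M^W                     (slope b1_t)
* control:            Y   ~ M                       (slope b1_c)

Because study arm is the focal predictor, the treatment-mediator (a path)
and treatment-outcome (main effect) relationships are carried by latent
mean contrasts: loadings are tied across arms for the mean model, control
latent means are fixed at zero, and the treatment latent means are freely
estimated.  The effects are then

* main effect  = (latent outcome contrast) - sum(coef * predictor latent mean)
* mediation    = ME = a_hat(t) * B_hat(t)
* moderation   = xi2_hat(t)

SAM-Croon uses disattenuated coefficients; SAM-FS uses raw score
coefficients.  Both use the measurement-model latent means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import PartiallyNestedDataset
from .measurement import (
    CONVERGED,
    FactorModelFit,
    TwoLevelFactorFit,
    cluster_decompose,
    fit_single_factor_ml,
    fit_two_level_measurement,
)
from .sam import (
    NON_CONVERGENCE,
    MomentMatrix,
    SamResult,
    StructuralFit,
    _score_weights,
    croon_correct,
    estimate_paths,
    product_label,
)

__all__ = [
    "PnMeasurement",
    "EffectEstimates",
    "fit_pn_measurement",
    "estimate_pn_structural",
    "compute_effects",
    "pn_estimate",
    "pn_estimate_many",
]


@dataclass
class PnMeasurement:
    """Arm/level-specific measurement fits and latent means.

    Control latent means are fixed at 0; ``a_t`` and ``y_contrast`` are the
    treatment latent means of the mediator and outcome estimated from the
    pooled mean model with loadings tied across arms, i.e. the
    treatment-control latent mean contrasts.
    """

    m_treat: TwoLevelFactorFit
    y_treat: TwoLevelFactorFit
    z_treat: FactorModelFit
    m_control: FactorModelFit
    y_control: FactorModelFit
    a_t: float
    y_contrast: float
    a_c: float = 0.0
    n2_t: int = 0
    n1_t: float = 0.0

    @property
    def treatment_admissible(self) -> bool:
        return (self.m_treat.status == CONVERGED
                and self.y_treat.status == CONVERGED
                and self.z_treat.status == CONVERGED)

    @property
    def control_admissible(self) -> bool:
        return (self.m_control.status == CONVERGED
                and self.y_control.status == CONVERGED)


@dataclass
class EffectEstimates:
    """Main, mediation and moderation effects of the 2/1 design."""

    main_effect: float
    a_path: float
    b_path: float
    mediation: float
    moderation: float
    b1_control: float
    b1_treatment_within: float
    estimator: str
    treatment_status: str = CONVERGED
    control_status: str = CONVERGED

    @property
    def available(self) -> bool:
        return self.treatment_status == CONVERGED and self.control_status == CONVERGED

    def to_dict(self) -> dict:
        return {
            "main_effect": float(self.main_effect),
            "a_path": float(self.a_path),
            "b_path": float(self.b_path),
            "mediation": float(self.mediation),
            "moderation": float(self.moderation),
            "b1_control": float(self.b1_control),
            "b1_treatment_within": float(self.b1_treatment_within),
            "estimator": self.estimator,
            "treatment_status": self.treatment_status,
            "control_status": self.control_status,
        }


def _pooled_mean_contrast(treat_rows: pd.DataFrame, control_rows: pd.DataFrame,
                          cols: list[str], lam_t: np.ndarray, theta_t: np.ndarray,
                          lam_c: np.ndarray, theta_c: np.ndarray) -> float:
    """Latent mean contrast with loadings tied across arms.

    GLS estimate: a_hat = w'(xbar_t - xbar_c) / (w' Lambda) with pooled
    loadings and inverse-residual weights.  Control latent mean fixed 0.
    """
    n_t, n_c = len(treat_rows), len(control_rows)
    lam = (n_t * lam_t + n_c * lam_c) / (n_t + n_c)
    theta = (n_t * theta_t + n_c * theta_c) / (n_t + n_c)
    w = lam / np.maximum(theta, 1e-8)
    diff = treat_rows[cols].mean().to_numpy() - control_rows[cols].mean().to_numpy()
    return float(w @ diff / (w @ lam))


def fit_pn_measurement(dataset: PartiallyNestedDataset) -> PnMeasurement:
    """Arm-specific measurement models and latent mean contrasts.

    Treatment arm: two-level fits for M and Y (cluster-means route) and a
    between-only fit for Z on its cluster-level values.  Control arm:
    single-level fits for M and Y.  The pooled mean model fixes control
    latent means to zero and estimates the treatment latent means.
    """
    treat = dataset.arm("treatment")
    control = dataset.arm("control")
    if len(treat) == 0 or len(control) == 0:
        raise ValueError("both study arms must be present")
    sizes = treat.groupby("cluster_id").size().to_numpy()
    if sizes.max() < 2:
        raise ValueError("treatment clusters must have at least two members")

    m_cols = dataset.indicator_columns("m")
    y_cols = dataset.indicator_columns("y")
    z_cols = dataset.indicator_columns("z")

    class _Arm:
        def __init__(self, df):
            self.data = df

        def indicator_columns(self, v):
            return dataset.indicator_columns(v)

    m_treat = fit_two_level_measurement(_Arm(treat), "m", identification="marker")
    y_treat = fit_two_level_measurement(_Arm(treat), "y", identification="marker")
    z_between, _ = cluster_decompose(treat, z_cols)
    S_z = np.cov(z_between.to_numpy(), rowvar=False, ddof=1)
    z_treat = fit_single_factor_ml(S_z, z_between.to_numpy().mean(axis=0),
                                   n=len(z_between), identification="marker",
                                   level="between")

    S_mc = np.cov(control[m_cols].to_numpy(), rowvar=False, ddof=1)
    m_control = fit_single_factor_ml(S_mc, control[m_cols].mean().to_numpy(),
                                     n=len(control), identification="marker")
    S_yc = np.cov(control[y_cols].to_numpy(), rowvar=False, ddof=1)
    y_control = fit_single_factor_ml(S_yc, control[y_cols].mean().to_numpy(),
                                     n=len(control), identification="marker")

    def contrast(cols, t_fit, c_fit):
        lam_t = np.asarray(t_fit.within.loadings, float)
        theta_t = (np.asarray(t_fit.within.theta, float)
                   + np.asarray(t_fit.between.theta, float))
        lam_c = np.asarray(c_fit.loadings, float)
        theta_c = np.asarray(c_fit.theta, float)
        if not (np.all(np.isfinite(lam_t)) and np.all(np.isfinite(lam_c))):
            return np.nan
        return _pooled_mean_contrast(treat, control, cols, lam_t, theta_t,
                                     lam_c, theta_c)

    a_t = contrast(m_cols, m_treat, m_control)
    y_contrast = contrast(y_cols, y_treat, y_control)

    meas = PnMeasurement(m_treat=m_treat, y_treat=y_treat, z_treat=z_treat,
                         m_control=m_control, y_control=y_control,
                         a_t=a_t, y_contrast=y_contrast,
                         n2_t=int(sizes.size),
                         n1_t=float(sizes.size / np.sum(1.0 / sizes)))
    if meas.m_treat.admissible:
        meas.m_treat.between.latent_mean = a_t
    if meas.y_treat.admissible:
        meas.y_treat.between.latent_mean = y_contrast
    return meas


@dataclass
class _PnPipeline:
    meas: PnMeasurement
    raw_between_t: MomentMatrix | None
    raw_within_t: MomentMatrix | None
    raw_control: MomentMatrix | None
    n1_t: float


def _pn_prepare(dataset: PartiallyNestedDataset,
                meas: PnMeasurement | None = None) -> _PnPipeline:
    meas = fit_pn_measurement(dataset) if meas is None else meas
    treat = dataset.arm("treatment")
    control = dataset.arm("control")
    m_cols = dataset.indicator_columns("m")
    y_cols = dataset.indicator_columns("y")
    z_cols = dataset.indicator_columns("z")

    def centred_between_scores(cols, fit):
        between_tab, _ = cluster_decompose(treat, cols)
        sw = _score_weights(fit, strict=False)
        if sw is None:
            return None
        bt = between_tab.to_numpy()
        return (bt - bt.mean(axis=0)) @ sw.weights

    def within_scores(cols, fit):
        _, within_tab = cluster_decompose(treat, cols)
        sw = _score_weights(fit, strict=False)
        if sw is None:
            return None
        return within_tab.to_numpy() @ sw.weights

    b_m = (centred_between_scores(m_cols, meas.m_treat.between)
           if meas.m_treat.between.status != "non_PD" else None)
    b_y = (centred_between_scores(y_cols, meas.y_treat.between)
           if meas.y_treat.between.status != "non_PD" else None)
    b_z = centred_between_scores(z_cols, meas.z_treat)
    w_m = within_scores(m_cols, meas.m_treat.within)
    w_y = within_scores(y_cols, meas.y_treat.within)

    raw_between_t = raw_within_t = raw_control = None
    if all(s is not None for s in (b_m, b_z, b_y)):
        tab = pd.DataFrame({"m": b_m, "z": b_z, "y": b_y})
        pm = (tab["m"] - tab["m"].mean()) * (tab["z"] - tab["z"].mean())
        tab[product_label("m", "z")] = pm
        raw_between_t = MomentMatrix(
            cov=tab.cov(ddof=1), means=tab.mean(), level="between", n=len(tab),
            product_terms={product_label("m", "z"): (("m", "between"),
                                                     ("z", "between"))})
    if w_m is not None and w_y is not None:
        tab = pd.DataFrame({"m": w_m, "y": w_y})
        raw_within_t = MomentMatrix(cov=tab.cov(ddof=1), means=tab.mean(),
                                    level="within", n=len(tab))

    sc_m = _score_weights(meas.m_control, strict=False)
    sc_y = _score_weights(meas.y_control, strict=False)
    if sc_m is not None and sc_y is not None:
        mc = (control[m_cols].to_numpy()
              - control[m_cols].mean().to_numpy()) @ sc_m.weights
        yc = (control[y_cols].to_numpy()
              - control[y_cols].mean().to_numpy()) @ sc_y.weights
        tab = pd.DataFrame({"m": mc, "y": yc})
        raw_control = MomentMatrix(cov=tab.cov(ddof=1), means=tab.mean(),
                                   level="single", n=len(tab))
    return _PnPipeline(meas=meas, raw_between_t=raw_between_t,
                       raw_within_t=raw_within_t, raw_control=raw_control,
                       n1_t=meas.n1_t)


def _fail(level: str, estimator: str, outcome="y", predictors=("m",)) -> StructuralFit:
    return StructuralFit(outcome=outcome, predictors=list(predictors),
                         coefficients=pd.Series(np.nan, index=list(predictors)),
                         intercept=np.nan, residual_variance=np.nan,
                         level=level, estimator=estimator,
                         status=NON_CONVERGENCE)


def _pn_structural(pipe: _PnPipeline, estimator: str) -> dict[str, StructuralFit]:
    """Three structural models; measurement admissibility is required for
    both estimators (latent means feed every PN effect)."""
    meas = pipe.meas
    out: dict[str, StructuralFit] = {}
    preds_b = ["m", "z", product_label("m", "z")]
    treat_ok = meas.treatment_admissible and pipe.raw_between_t is not None \
        and pipe.raw_within_t is not None
    if not treat_ok:
        out["treatment_between"] = _fail("between", estimator, predictors=preds_b)
        out["treatment_within"] = _fail("within", estimator)
    else:
        fits_t = {"m": meas.m_treat, "y": meas.y_treat, "z": meas.z_treat}
        if estimator == "croon":
            within_m = croon_correct(pipe.raw_within_t, fits_t)
            between_m = croon_correct(pipe.raw_between_t, fits_t,
                                      n1=pipe.n1_t, within_corrected=within_m)
        else:
            within_m, between_m = pipe.raw_within_t, pipe.raw_between_t
        out["treatment_between"] = estimate_paths(between_m, "y", preds_b,
                                                  estimator=estimator)
        out["treatment_within"] = estimate_paths(within_m, "y", ["m"],
                                                 estimator=estimator)
    control_ok = meas.control_admissible and pipe.raw_control is not None
    if not control_ok:
        out["control"] = _fail("single", estimator)
    else:
        fits_c = {"m": meas.m_control, "y": meas.y_control}
        cm = (croon_correct(pipe.raw_control, fits_c) if estimator == "croon"
              else pipe.raw_control)
        out["control"] = estimate_paths(cm, "y", ["m"], estimator=estimator)
    return out


def estimate_pn_structural(dataset: PartiallyNestedDataset,
                           estimator: str = "croon",
                           ) -> dict[str, StructuralFit]:
    """Treatment-between, treatment-within and control path models."""
    if estimator not in ("fs", "croon"):
        raise ValueError("estimator must be 'fs' or 'croon'")
    pipe = _pn_prepare(dataset)
    return _pn_structural(pipe, estimator)


def compute_effects(meas: PnMeasurement, structural: dict[str, StructuralFit],
                    estimator: str = "croon") -> EffectEstimates:
    """Main, mediation and moderation effects from measurement + path fits.

    main = y_contrast - B*a_t - xi1*0 - xi2*E[product]; the moderator's
    latent mean is zero by grand-mean centring and the centred product's
    mean is the (corrected, for Croon) mediator-moderator covariance, read
    off the structural stage's product-mean bookkeeping via the intercept:
    estimate_paths already returns intercept = mean_y - sum(coef * mean),
    computed on centred scores, so the main effect uses the latent means
    directly.
    """
    tb = structural["treatment_between"]
    tw = structural["treatment_within"]
    ctrl = structural["control"]
    t_status = CONVERGED if (tb.converged and tw.converged
                             and np.isfinite(meas.a_t)
                             and np.isfinite(meas.y_contrast)) else NON_CONVERGENCE
    c_status = CONVERGED if ctrl.converged else NON_CONVERGENCE
    if t_status == CONVERGED:
        B = float(tb.coefficients["m"])
        xi2 = float(tb.coefficients[product_label("m", "z")])
        # tb.intercept = mean_y_scores - coef'mean_scores on centred scores;
        # re-anchor to latent means: predictors m (mean a_t), z (mean 0),
        # product (mean = its centred-score mean, already inside intercept)
        prod_mean_resid = float(tb.intercept)  # residual centring offset
        main = meas.y_contrast - B * meas.a_t + prod_mean_resid
        a_t = meas.a_t
        me = a_t * B
        b1_t = float(tw.coefficients["m"])
    else:
        B = xi2 = main = a_t = me = b1_t = np.nan
    b1_c = float(ctrl.coefficients["m"]) if c_status == CONVERGED else np.nan
    return EffectEstimates(main_effect=main, a_path=a_t, b_path=B,
                           mediation=me, moderation=xi2,
                           b1_control=b1_c, b1_treatment_within=b1_t,
                           estimator=estimator, treatment_status=t_status,
                           control_status=c_status)


def pn_estimate(dataset: PartiallyNestedDataset, estimator: str = "croon"):
    """Full PN pipeline: returns (measurement, structural fits, effects)."""
    pipe = _pn_prepare(dataset)
    structural = _pn_structural(pipe, estimator)
    effects = compute_effects(pipe.meas, structural, estimator)
    return pipe.meas, structural, effects


def pn_estimate_many(dataset: PartiallyNestedDataset,
                     estimators: tuple[str, ...] = ("fs", "croon")):
    """Run several estimators sharing the measurement stage."""
    pipe = _pn_prepare(dataset)
    out = {}
    for e in estimators:
        structural = _pn_structural(pipe, e)
        out[e] = (pipe.meas, structural, compute_effects(pipe.meas, structural, e))
    return out
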