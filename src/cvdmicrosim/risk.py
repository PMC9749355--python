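"""Per-cycle event probabilities.

First-ever CVD risk follows the published 5-year Cox-form primary-prevention
equation (New Zealand primary-care derivation); recurrent CVD risk follows a
10-year Cox-form equation for patients with established vascular disease.
Both are consumed as coefficient tables: ``p_h = 1 - S0 ** exp(lp)`` at the
model horizon, converted to an annual probability under a constant hazard.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Optional

import numpy as np

from .config import (
    FATAL_SUBTYPES,
    FIRST_EVER_SUBTYPES,
    RECURRENT_SUBTYPES,
    MortalityTable,
    RiskModel,
    RunConfig,
    SubtypeSplit,
)
from .population import IndividualState, SMOKING_LEVELS


@dataclasses.dataclass
class PredictorContext:
    """Covariate arrays a risk equation may draw on.

    ``sbp`` is the *effective* SBP (including any active intervention
    effect); ``years_since_first_event`` is whole years since the first CVD
    event, minimum 1, and may be None for primary-prevention equations.
    """

    age: np.ndarray
    ses_quintile: np.ndarray
    smoking: np.ndarray
    diabetes: np.ndarray
    sbp: np.ndarray
    tc: np.ndarray
    hdl: np.ndarray
    years_since_first_event: Optional[np.ndarray] = None

    @classmethod
    def from_individual(cls, ind: IndividualState, *, effective_sbp=None,
                        years_since_first_event=None) -> "PredictorContext":
        ysfe = None
        if years_since_first_event is not None:
            ysfe = np.array([years_since_first_event], float)
        return cls(
            age=np.array([ind.age], float),
            ses_quintile=np.array([ind.ses_quintile], float),
            smoking=np.array([SMOKING_LEVELS.index(ind.smoking)], np.int8),
            diabetes=np.array([ind.diabetes], bool),
            sbp=np.array(
                [ind.sbp if effective_sbp is None else effective_sbp], float
            ),
            tc=np.array([ind.tc], float),
            hdl=np.array([ind.hdl], float),
            years_since_first_event=ysfe,
        )


def _t_age(ctx, model):
    return ctx.age


def _t_sbp(ctx, model):
    return ctx.sbp


def _t_tc(ctx, model):
    return ctx.tc


def _t_hdl(ctx, model):
    return ctx.hdl


def _t_ratio(ctx, model):
    return ctx.tc / ctx.hdl


def _t_ses(ctx, model):
    return ctx.ses_quintile.astype(float)


def _t_current_smoker(ctx, model):
    return (ctx.smoking == 2).astype(float)


def _t_ex_smoker(ctx, model):
    return (ctx.smoking == 1).astype(float)


def _t_diabetes(ctx, model):
    return ctx.diabetes.astype(float)


def _t_log_ysfe(ctx, model):
    if ctx.years_since_first_event is None:
        raise ValueError(
            "predictor 'log_years_since_first_event' is not resolvable: "
            "no first-event time in context"
        )
    return np.log(np.maximum(ctx.years_since_first_event, 1.0))


def _t_ysfe(ctx, model):
    if ctx.years_since_first_event is None:
        raise ValueError(
            "predictor 'years_since_first_event' is not resolvable: "
            "no first-event time in context"
        )
    return np.maximum(ctx.years_since_first_event, 1.0)


def _t_age_x_diabetes(ctx, model):
    age_c = model.predictor("age").center
    return (ctx.age - age_c) * ctx.diabetes.astype(float)


def _t_age_x_sbp(ctx, model):
    age_c = model.predictor("age").center
    sbp_c = model.predictor("sbp").center
    return (ctx.age - age_c) * (ctx.sbp - sbp_c)


def _t_centered(ctx, model):
    # placeholder for predictors fixed at their centering value
    return np.zeros_like(ctx.age)


TRANSFORMS: dict[str, Callable] = {
    "age": _t_age,
    "sbp": _t_sbp,
    "tc": _t_tc,
    "hdl": _t_hdl,
    "tc_hdl_ratio": _t_ratio,
    "ses_quintile": _t_ses,
    "current_smoker": _t_current_smoker,
    "ex_smoker": _t_ex_smoker,
    "diabetes": _t_diabetes,
    "log_years_since_first_event": _t_log_ysfe,
    "years_since_first_event": _t_ysfe,
    "age_x_diabetes": _t_age_x_diabetes,
    "age_x_sbp": _t_age_x_sbp,
    "centered": _t_centered,
}


def linear_predictor(ctx: PredictorContext | IndividualState,
                     model: RiskModel) -> np.ndarray | float:
    """``sum_j beta_j * (x_j - center_j) / scale_j`` with declared transforms.

    Interaction transforms are computed on covariates centred at the main
    effects' centering values; the ``centered`` transform pins a predictor at
    its reference value (zero contribution).
    """
    scalar = isinstance(ctx, IndividualState)
    if scalar:
        ysfe = None
        if ctx.first_event_cycle is not None:
            ysfe = 1.0  # caller should supply context for a real time
        ctx = PredictorContext.from_individual(ctx, years_since_first_event=ysfe)
    lp = np.zeros_like(ctx.age, dtype=float)
    for p in model.predictors:
        try:
            fn = TRANSFORMS[p.transform]
        except KeyError:
            raise ValueError(
                f"predictor {p.name!r}: unknown transform {p.transform!r}"
            ) from None
        x = fn(ctx, model)
        contribution = x if p.transform.startswith("age_x_") else (x - p.center)
        lp += p.beta * contribution / p.scale
    return float(lp[0]) if scalar else lp


def horizon_risk(lp, model: RiskModel):
    """Cox-form risk ``1 - S0 ** exp(lp)`` at the model horizon."""
    p = 1.0 - model.baseline_survival ** np.exp(np.asarray(lp, float))
    return np.clip(p, 0.0, 1.0) if np.ndim(lp) else float(np.clip(p, 0.0, 1.0))


def horizon_to_annual(p_h, horizon: float):
    """Constant-hazard conversion ``p1 = 1 - (1 - p_h) ** (1/h)``."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1 year")
    p_h_arr = np.asarray(p_h, float)
    if np.any(p_h_arr >= 1.0):
        warnings.warn("horizon probability of 1 converts to annual probability 1")
    p1 = 1.0 - (1.0 - np.clip(p_h_arr, 0.0, 1.0)) ** (1.0 / horizon)
    return p1 if np.ndim(p_h) else float(p1)


def annual_to_horizon(p_1, horizon: float):
    """Inverse of :func:`horizon_to_annual`."""
    p_h = 1.0 - (1.0 - np.asarray(p_1, float)) ** horizon
    return p_h if np.ndim(p_1) else float(p_h)


def annual_event_probability(ctx: PredictorContext, model: RiskModel) -> np.ndarray:
    """Annual event probability from a horizon risk equation."""
    return horizon_to_annual(horizon_risk(linear_predictor(ctx, model), model),
                             model.horizon_years)


def apply_intervention(individual: IndividualState, cycle: int,
                       cfg: RunConfig) -> tuple[IndividualState, float]:
    """Resolve intervention status for one cycle.

    Returns the (possibly updated) individual and the *effective* SBP to use
    in risk computation.  While adherent (intervention arm, CVD-free, cycle
    within the adherence window) the SBP reduction applies and the annual
    programme cost is triggered; the stored SBP trajectory is never altered.
    The effect may be configured to outlast delivery (``effect_years``).
    """
    if individual.arm != "intervention":
        return dataclasses.replace(individual, on_intervention=False), individual.sbp
    cvd_free = len(individual.cvd_history) == 0
    adherent = cvd_free and cycle < min(cfg.adherence_years, cfg.intervention_years)
    effect_on = cvd_free and cycle < cfg.effective_effect_years
    eff_sbp = individual.sbp + (cfg.intervention_effect_sbp if effect_on else 0.0)
    return dataclasses.replace(individual, on_intervention=adherent), eff_sbp


def _draw_categorical(order, probs: dict[str, float], u) -> np.ndarray:
    p = np.array([probs[k] for k in order], float)
    cdf = np.cumsum(p / p.sum())
    idx = np.searchsorted(cdf, np.asarray(u, float), side="right")
    return np.minimum(idx, len(order) - 1)


def draw_first_event_subtype(split: SubtypeSplit, rng: np.random.Generator) -> str:
    """Categorical draw of the first-ever event subtype."""
    idx = _draw_categorical(FIRST_EVER_SUBTYPES, split.first_ever, rng.random())
    return FIRST_EVER_SUBTYPES[int(idx)]


def draw_recurrent_event_type(rng: np.random.Generator,
                              recurrent_split: dict[str, float]) -> str:
    """Categorical draw of the recurrent event type."""
    idx = _draw_categorical(RECURRENT_SUBTYPES, recurrent_split, rng.random())
    return RECURRENT_SUBTYPES[int(idx)]


def first_subtype_from_uniform(split: SubtypeSplit, u) -> np.ndarray:
    return _draw_categorical(FIRST_EVER_SUBTYPES, split.first_ever, u)


def recurrent_subtype_from_uniform(split: SubtypeSplit, u) -> np.ndarray:
    return _draw_categorical(RECURRENT_SUBTYPES, split.recurrent, u)


def is_fatal(subtype: str) -> bool:
    return subtype in FATAL_SUBTYPES


def noncvd_death_prob(age, table: MortalityTable):
    """Step-function lookup of the annual non-CVD death probability."""
    ages = np.array([r.age for r in table.rows], float)
    probs = np.array([r.p for r in table.rows], float)
    a = np.asarray(age, float)
    if np.any(a < ages[0]):
        raise ValueError(
            f"age below mortality-table coverage (starts at {ages[0]:.0f})"
        )
    idx = np.searchsorted(ages, a, side="right") - 1
    out = probs[idx]
    return out if np.ndim(age) else float(out)
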