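"""Health-economic valuation: utilities, costs, discounting, ICERs.

Discounting uses the half-cycle convention throughout: every payoff in cycle
``t`` is credited at mid-cycle, factor ``(1+r)**-(t+0.5)``.  Quality weights
combine the age curve of the general female population with post-event
utilities (minimum rule by default); after two or more events the generic
post-CVD weight applies.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    EconTable,
    FIRST_EVER_SUBTYPES,
    RECURRENT_SUBTYPES,
    _age_band_key as _age_band_key_for,
)

# Post-event utility slots.  UA has no listed post-event utility and falls
# back to the age curve; fatal subtypes never price a later cycle.
UTILITY_KEYS = (
    "u_MI", "u_stroke_IS", "u_stroke_HE", "u_TIA", "u_CHF", "u_PVD",
    "u_otherCHD", "u_postCVD",
)
_SUBTYPE_UKEY = {
    "MI": "u_MI",
    "UA": None,
    "ischaemic_stroke": "u_stroke_IS",
    "haemorrhagic_stroke": "u_stroke_HE",
    "TIA": "u_TIA",
    "PVD": "u_PVD",
    "CHF": "u_CHF",
    "other_CHD": "u_otherCHD",
    "other_CVD_death": None,
    "nonfatal_stroke": "u_stroke_IS",
    "nonfatal_MI": "u_MI",
    "cvd_death": None,
}

ACUTE_COST_KEY = {
    "MI": "c_MI",
    "UA": "c_UA",
    "ischaemic_stroke": "c_stroke_IS",
    "haemorrhagic_stroke": "c_stroke_HA",
    "TIA": "c_TIA",
    "PVD": "c_PVD",
    "CHF": "c_CHD",
    "other_CHD": "c_otherCVD",
    "other_CVD_death": "c_CVD_death_other",
    "nonfatal_stroke": "c_stroke_IS",
    "nonfatal_MI": "c_MI",
    "cvd_death": "c_CVD_death_other",
}

MGMT_KEYS = (
    "c_mgmt_MI", "c_mgmt_UA", "c_mgmt_otherCVD", "c_mgmt_stroke",
    "c_mgmt_TIA", "c_mgmt_PVD", "c_mgmt_CHD", "c_mgmt_postCVD",
)
_SUBTYPE_MGMT = {
    "MI": "c_mgmt_MI",
    "UA": "c_mgmt_UA",
    "ischaemic_stroke": "c_mgmt_stroke",
    "haemorrhagic_stroke": "c_mgmt_stroke",
    "TIA": "c_mgmt_TIA",
    "PVD": "c_mgmt_PVD",
    "CHF": "c_mgmt_CHD",
    "other_CHD": "c_mgmt_otherCVD",
    "other_CVD_death": None,
    "nonfatal_stroke": "c_mgmt_stroke",
    "nonfatal_MI": "c_mgmt_MI",
    "cvd_death": None,
}

_ALL_SUBTYPES = FIRST_EVER_SUBTYPES + RECURRENT_SUBTYPES


def subtype_utility_key_codes() -> np.ndarray:
    """Subtype code -> index into UTILITY_KEYS (-1 = age curve only)."""
    return np.array(
        [UTILITY_KEYS.index(_SUBTYPE_UKEY[s]) if _SUBTYPE_UKEY[s] else -1
         for s in _ALL_SUBTYPES],
        dtype=np.int8,
    )


def post_event_utility_values(econ: EconTable) -> np.ndarray:
    """Utility per UTILITY_KEYS slot; the ischaemic-stroke slot is the
    mRS-weighted composite."""
    vals = []
    for k in UTILITY_KEYS:
        if k == "u_stroke_IS":
            vals.append(econ.ischaemic_stroke_utility())
        else:
            vals.append(econ.post_event_utilities[k])
    return np.array(vals, dtype=float)


def band_utility_values(econ: EconTable) -> np.ndarray:
    return np.array([b.u for b in econ.utilities_by_age], dtype=float)


def age_band_index(age, econ: EconTable) -> np.ndarray:
    """Index of the age-utility band, clamped to the oldest band."""
    los = np.array([b.lo for b in econ.utilities_by_age], dtype=float)
    a = np.asarray(age, dtype=float)
    idx = np.searchsorted(los, a, side="right") - 1
    return np.clip(idx, 0, len(los) - 1).astype(np.int8)


def utility_weight_from_codes(band_idx, ukey_idx, band_u, pe_u,
                              combination: str = "min") -> np.ndarray:
    u_age = band_u[np.asarray(band_idx)]
    ukey = np.asarray(ukey_idx)
    u_event = np.where(ukey >= 0, pe_u[np.maximum(ukey, 0)], 1.0)
    if combination == "product":
        return u_age * np.where(ukey >= 0, u_event, 1.0)
    return np.minimum(u_age, u_event)


def acute_cost_by_code(econ: EconTable) -> np.ndarray:
    return np.array(
        [econ.acute_costs[ACUTE_COST_KEY[s]] for s in _ALL_SUBTYPES], dtype=float
    )


def mgmt_key_by_code(econ: EconTable) -> np.ndarray:
    """Subtype code -> index into MGMT_KEYS (-1 = no management cost)."""
    keys = []
    for s in _ALL_SUBTYPES:
        k = _SUBTYPE_MGMT[s]
        if k is not None and s in RECURRENT_SUBTYPES and \
                econ.mgmt_after_recurrent == "postCVD":
            k = "c_mgmt_postCVD"
        keys.append(MGMT_KEYS.index(k) if k else -1)
    return np.array(keys, dtype=np.int8)


# ---------------------------------------------------------------------------
# scalar single-cycle operations


def cycle_utility(age: float, n_prior_events: int,
                  last_subtype: Optional[str], econ: EconTable) -> float:
    """Quality weight for a cycle lived at ``age`` with the given history."""
    u_age = econ.age_band_utility(age)
    if n_prior_events == 0:
        return u_age
    if n_prior_events >= 2:
        u_event = econ.post_event_utilities["u_postCVD"]
    else:
        key = _SUBTYPE_UKEY.get(last_subtype)
        if key is None:
            return u_age
        u_event = (econ.ischaemic_stroke_utility() if key == "u_stroke_IS"
                   else econ.post_event_utilities[key])
    if econ.utility_combination == "product":
        return u_age * u_event
    return min(u_age, u_event)


def cycle_cost(econ: EconTable, *, on_intervention: bool = False,
               event_subtype: Optional[str] = None,
               mgmt_subtype: Optional[str] = None) -> float:
    """Undiscounted cost of one cycle from its ledger inputs."""
    total = 0.0
    if on_intervention:
        total += econ.intervention_cost_annual
    if event_subtype is not None:
        if event_subtype not in ACUTE_COST_KEY:
            raise KeyError(f"unknown event subtype {event_subtype!r}")
        total += econ.acute_costs[ACUTE_COST_KEY[event_subtype]]
    if mgmt_subtype is not None:
        if mgmt_subtype not in _SUBTYPE_MGMT:
            raise KeyError(f"unknown event subtype {mgmt_subtype!r}")
        key = _SUBTYPE_MGMT[mgmt_subtype]
        if key is not None:
            total += econ.mgmt_costs_annual[key]
    return total


# ---------------------------------------------------------------------------
# discounting and ICERs


def discount_factors(n_cycles: int, r: float) -> np.ndarray:
    """Mid-cycle discount factors ``(1+r)**-(t+0.5)`` for t = 0..n-1."""
    t = np.arange(n_cycles, dtype=float)
    return (1.0 + r) ** -(t + 0.5)


@dataclasses.dataclass
class ArmTotals:
    """Per-individual discounted totals for one arm."""

    arm: str
    cost: np.ndarray
    qaly: np.ndarray
    ly: np.ndarray
    cost_intervention: np.ndarray
    cost_acute: np.ndarray
    cost_mgmt: np.ndarray

    def means(self) -> dict[str, float]:
        return {
            "cost": float(self.cost.mean()),
            "qaly": float(self.qaly.mean()),
            "ly": float(self.ly.mean()),
            "cost_intervention": float(self.cost_intervention.mean()),
            "cost_acute": float(self.cost_acute.mean()),
            "cost_mgmt": float(self.cost_mgmt.mean()),
        }


def discounted_totals(arm_result, r: float) -> ArmTotals:
    """Discount an arm's cycle matrices to per-individual totals."""
    df = discount_factors(arm_result.n_cycles, r)
    ci = arm_result.cost_intervention @ df
    ca = arm_result.cost_acute @ df
    cm = arm_result.cost_mgmt @ df
    qaly = (arm_result.utility * arm_result.ly) @ df
    ly = arm_result.ly @ df
    return ArmTotals(
        arm=arm_result.arm, cost=ci + ca + cm, qaly=qaly, ly=ly,
        cost_intervention=ci, cost_acute=ca, cost_mgmt=cm,
    )


@dataclasses.dataclass
class CEAResult:
    """Paired-arm cost-effectiveness summary (Table-2-style)."""

    n: int
    arms: dict[str, dict[str, float]]
    increments: dict[str, float]
    icer_qaly: Optional[float]
    icer_ly: Optional[float]
    dominance: str              # "trade-off", "dominant", "dominated", "undefined"
    wtp_threshold: float
    cost_effective: Optional[bool]
    events_per_10000: Optional[dict[str, pd.DataFrame]] = None
    mean_age_first_event: Optional[dict[str, Optional[float]]] = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.events_per_10000 is not None:
            out["events_per_10000"] = {
                arm: df.to_dict("records")
                for arm, df in self.events_per_10000.items()
            }
        return out


def compute_icer(
    totals_intervention: ArmTotals,
    totals_comparator: ArmTotals,
    wtp_threshold: float = 50000.0,
) -> CEAResult:
    """ICERs and dominance labelling for a common-random-number pair."""
    if len(totals_intervention.cost) != len(totals_comparator.cost):
        raise ValueError("arms must share the cohort")
    a, b = totals_intervention.means(), totals_comparator.means()
    inc = {k: a[k] - b[k] for k in a}
    d_cost, d_qaly, d_ly = inc["cost"], inc["qaly"], inc["ly"]

    if d_qaly > 0 and d_cost > 0:
        dominance = "trade-off"
        icer_qaly = d_cost / d_qaly
        icer_ly = d_cost / d_ly if d_ly > 0 else None
    elif d_cost <= 0 and d_qaly >= 0 and (d_cost < 0 or d_qaly > 0):
        dominance, icer_qaly, icer_ly = "dominant", None, None
    elif d_cost >= 0 and d_qaly <= 0 and (d_cost > 0 or d_qaly < 0):
        dominance, icer_qaly, icer_ly = "dominated", None, None
    else:
        dominance, icer_qaly, icer_ly = "undefined", None, None

    if dominance == "dominant":
        cost_effective = True
    elif dominance == "dominated":
        cost_effective = False
    elif icer_qaly is not None:
        cost_effective = icer_qaly <= wtp_threshold
    else:
        cost_effective = None

    return CEAResult(
        n=len(totals_intervention.cost),
        arms={totals_intervention.arm: a, totals_comparator.arm: b},
        increments=inc,
        icer_qaly=icer_qaly,
        icer_ly=icer_ly,
        dominance=dominance,
        wtp_threshold=wtp_threshold,
        cost_effective=cost_effective,
    )
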