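"""Annual-cycle individual-level simulation over the lifetime horizon.

Both arms run on common random numbers: each individual owns a random stream
keyed by ``(master_seed, id)`` and consumes exactly one uniform per purpose
(non-CVD death, CVD event, subtype) per cycle, so arms differ only through
the intervention effect.  Within a cycle, competing risks resolve
sequentially: non-CVD death, then CVD event given survival, then subtype.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    FATAL_SUBTYPES,
    FIRST_EVER_SUBTYPES,
    RECURRENT_SUBTYPES,
    ModelParameters,
)
from .econ import (
    MGMT_KEYS,
    UTILITY_KEYS,
    acute_cost_by_code,
    age_band_index,
    band_utility_values,
    mgmt_key_by_code,
    post_event_utility_values,
    subtype_utility_key_codes,
    utility_weight_from_codes,
)
from .population import Cohort, IndividualState, age_update_arrays
from .risk import (
    PredictorContext,
    annual_event_probability,
    first_subtype_from_uniform,
    noncvd_death_prob,
    recurrent_subtype_from_uniform,
)

ALL_SUBTYPES = FIRST_EVER_SUBTYPES + RECURRENT_SUBTYPES
SUBTYPE_CODE = {s: i for i, s in enumerate(ALL_SUBTYPES)}
FATAL_CODES = np.array([SUBTYPE_CODE[s] for s in sorted(FATAL_SUBTYPES)])
N_FIRST = len(FIRST_EVER_SUBTYPES)

INTERVENTION, USUAL_CARE = "intervention", "usual_care"


@dataclasses.dataclass
class CycleLedger:
    """Undiscounted per-cycle increments for one individual."""

    cycle: int
    cost_intervention: float
    cost_acute: float
    cost_mgmt: float
    utility: float
    ly: float
    discount_factor: float


@dataclasses.dataclass
class EventLog:
    individual_id: int
    cycle: int
    event_subtype: str
    fatal: bool
    first_ever: bool
    age_at_event: float


@dataclasses.dataclass
class ArmResult:
    """Cycle matrices (individual x cycle) plus the event log for one arm."""

    arm: str
    n: int
    n_cycles: int
    cost_intervention: np.ndarray
    cost_acute: np.ndarray
    cost_mgmt: np.ndarray
    utility: np.ndarray      # weight applied in the cycle
    ly: np.ndarray           # life-year fraction (0, 0.5 or 1)
    band_idx: np.ndarray     # age-utility band per cycle, -1 when not alive
    ukey_idx: np.ndarray     # post-event utility key per cycle, -1 = age band
    mgmt_key_idx: np.ndarray  # management cost key per cycle, -1 = none
    adherent: np.ndarray     # bool, intervention delivered this cycle
    events: pd.DataFrame

    def event_logs(self) -> list[EventLog]:
        return [
            EventLog(int(r.id), int(r.cycle), str(r.subtype), bool(r.fatal),
                     bool(r.first_ever), float(r.age))
            for r in self.events.itertuples()
        ]


def draw_uniforms(ids: np.ndarray, master_seed: int, n_cycles: int) -> np.ndarray:
    """Per-individual uniforms, rows = (death, event, subtype) purposes.

    Streams depend only on ``(master_seed, id)``, so results are independent
    of cohort ordering or splitting, and identical across arms.
    """
    U = np.empty((3, len(ids), n_cycles))
    for j, ident in enumerate(ids):
        ss = np.random.SeedSequence(entropy=int(master_seed),
                                    spawn_key=(int(ident),))
        U[:, j, :] = np.random.default_rng(ss).random((3, n_cycles))
    return U


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "id": pd.Series(dtype=np.int64),
        "cycle": pd.Series(dtype=np.int64),
        "age": pd.Series(dtype=float),
        "subtype": pd.Series(dtype=object),
        "fatal": pd.Series(dtype=bool),
        "first_ever": pd.Series(dtype=bool),
    })


def simulate_arm(
    cohort: Cohort,
    arm: str,
    params: ModelParameters,
    master_seed: int,
    uniforms: Optional[np.ndarray] = None,
) -> ArmResult:
    """Simulate one arm; annual cycles until death or the age cap."""
    run = params.run
    econ = params.economics
    n = len(cohort)
    # fixed per-individual cycle budget keyed to the youngest possible entry
    # age keeps streams aligned across cohort subsets and arms
    T = run.age_cap - 30
    if uniforms is None:
        uniforms = draw_uniforms(cohort.id, master_seed, T)

    age = cohort.age.astype(float).copy()
    sbp = cohort.sbp.astype(float).copy()
    tc = cohort.tc.astype(float).copy()
    hdl = cohort.hdl.astype(float).copy()

    alive = np.ones(n, dtype=bool)
    has_hist = np.zeros(n, dtype=bool)
    first_cycle = np.full(n, -1, dtype=np.int64)
    last_sub = np.full(n, -1, dtype=np.int8)
    n_events = np.zeros(n, dtype=np.int16)

    Z = lambda dt=float: np.zeros((n, T), dtype=dt)
    cost_int, cost_acute, cost_mgmt = Z(), Z(), Z()
    util_w, ly = Z(), Z()
    band_idx = np.full((n, T), -1, dtype=np.int8)
    ukey_idx = np.full((n, T), -1, dtype=np.int8)
    mgmt_idx = np.full((n, T), -1, dtype=np.int8)
    adherent_m = Z(bool)

    ev_id, ev_cycle, ev_age, ev_sub, ev_fatal, ev_first = [], [], [], [], [], []

    is_int = arm == INTERVENTION
    adh_window = min(run.adherence_years, run.intervention_years)
    effect_window = run.effective_effect_years
    band_u = band_utility_values(econ)
    pe_u = post_event_utility_values(econ)
    sub_ukey = subtype_utility_key_codes()
    acute_by_code = acute_cost_by_code(econ)
    mgmt_by_code = mgmt_key_by_code(econ)
    mgmt_costs = np.array([econ.mgmt_costs_annual[k] for k in MGMT_KEYS])
    postcvd_key = UTILITY_KEYS.index("u_postCVD")
    from_event_cycle = run.post_event_utility_from_event_cycle

    for t in range(T):
        active = alive & (age < run.age_cap - 1e-9)
        if not active.any():
            break
        cvd_free = ~has_hist

        adherent = active & cvd_free & (t < adh_window) if is_int else np.zeros(n, bool)
        effect_on = active & cvd_free & (t < effect_window) if is_int else np.zeros(n, bool)
        eff_sbp = sbp + np.where(effect_on, run.intervention_effect_sbp, 0.0)

        ysfe = np.maximum(t - first_cycle, 1).astype(float)
        ctx = PredictorContext(
            age=age, ses_quintile=cohort.ses_quintile.astype(float),
            smoking=cohort.smoking, diabetes=cohort.diabetes,
            sbp=eff_sbp, tc=tc, hdl=hdl, years_since_first_event=ysfe,
        )
        p_first = annual_event_probability(ctx, params.risk_first_ever)
        p_rec = annual_event_probability(ctx, params.risk_recurrent)
        p_nd = noncvd_death_prob(np.floor(np.where(active, age, 30.0)),
                                 params.mortality)

        dies_nd = active & (uniforms[0, :, t] < p_nd)
        surv = active & ~dies_nd
        p_event = np.where(has_hist, p_rec, p_first)
        has_event = surv & (uniforms[1, :, t] < p_event)
        first_ev = has_event & cvd_free
        rec_ev = has_event & has_hist

        sub = np.full(n, -1, dtype=np.int8)
        if first_ev.any():
            sub[first_ev] = first_subtype_from_uniform(
                params.subtypes, uniforms[2, first_ev, t]
            )
        if rec_ev.any():
            sub[rec_ev] = N_FIRST + recurrent_subtype_from_uniform(
                params.subtypes, uniforms[2, rec_ev, t]
            )
        fatal_ev = has_event & np.isin(sub, FATAL_CODES)
        died = dies_nd | fatal_ev

        # ---- ledger accrual for every started cycle --------------------
        nev_for_u = n_events + has_event if from_event_cycle else n_events
        last_for_u = np.where(has_event, sub, last_sub) if from_event_cycle else last_sub
        band = age_band_index(np.floor(age), econ)
        ukey = np.where(
            nev_for_u >= 2, postcvd_key,
            np.where(nev_for_u == 1, sub_ukey[np.maximum(last_for_u, 0)], -1),
        ).astype(np.int8)
        ukey[nev_for_u == 0] = -1
        uw = utility_weight_from_codes(band, ukey, band_u, pe_u,
                                       econ.utility_combination)

        ly_t = np.where(died, 0.5, 1.0)
        ly[active, t] = ly_t[active]
        util_w[active, t] = uw[active]
        band_idx[active, t] = band[active]
        ukey_idx[active, t] = ukey[active]
        cost_int[adherent, t] = econ.intervention_cost_annual
        adherent_m[:, t] = adherent
        if has_event.any():
            cost_acute[has_event, t] = acute_by_code[sub[has_event]]
        mg = active & has_hist  # cycles strictly after the first event
        if mg.any():
            mkey = mgmt_by_code[last_sub[mg]]
            cost_mgmt[mg, t] = np.where(mkey >= 0, mgmt_costs[np.maximum(mkey, 0)], 0.0)
            mgmt_idx[mg, t] = mkey

        if has_event.any():
            for i in np.nonzero(has_event)[0]:
                ev_id.append(int(cohort.id[i]))
                ev_cycle.append(t)
                ev_age.append(float(age[i]))
                ev_sub.append(ALL_SUBTYPES[sub[i]])
                ev_fatal.append(bool(fatal_ev[i]))
                ev_first.append(bool(first_ev[i]))

        # ---- state update ----------------------------------------------
        alive &= ~died
        first_cycle = np.where(first_ev, t, first_cycle)
        last_sub = np.where(has_event, sub, last_sub).astype(np.int8)
        n_events = (n_events + has_event).astype(np.int16)
        has_hist |= has_event

        age, sbp, tc, hdl = age_update_arrays(age, sbp, tc, hdl, params.population)

    events = pd.DataFrame({
        "id": np.array(ev_id, dtype=np.int64),
        "cycle": np.array(ev_cycle, dtype=np.int64),
        "age": np.array(ev_age, dtype=float),
        "subtype": np.array(ev_sub, dtype=object),
        "fatal": np.array(ev_fatal, dtype=bool),
        "first_ever": np.array(ev_first, dtype=bool),
    }) if ev_id else _empty_events()

    return ArmResult(
        arm=arm, n=n, n_cycles=T,
        cost_intervention=cost_int, cost_acute=cost_acute, cost_mgmt=cost_mgmt,
        utility=util_w, ly=ly, band_idx=band_idx, ukey_idx=ukey_idx,
        mgmt_key_idx=mgmt_idx, adherent=adherent_m, events=events,
    )


def simulate_pair(
    cohort: Cohort, params: ModelParameters, master_seed: int
) -> tuple[ArmResult, ArmResult]:
    """Simulate both arms on common random numbers."""
    T = params.run.age_cap - 30
    U = draw_uniforms(cohort.id, master_seed, T)
    res_int = simulate_arm(cohort, INTERVENTION, params, master_seed, uniforms=U)
    res_uc = simulate_arm(cohort, USUAL_CARE, params, master_seed, uniforms=U)
    return res_int, res_uc


def simulate_individual(
    individual: IndividualState, params: ModelParameters, master_seed: int
) -> tuple[list[CycleLedger], list[EventLog]]:
    """Single-individual trajectory (thin wrapper over the array engine)."""
    cohort = Cohort.from_individuals([individual])
    res = simulate_arm(cohort, individual.arm, params, master_seed)
    r = params.run.discount_rate
    ledgers = []
    for t in range(res.n_cycles):
        if res.band_idx[0, t] < 0:
            break
        ledgers.append(CycleLedger(
            cycle=t,
            cost_intervention=float(res.cost_intervention[0, t]),
            cost_acute=float(res.cost_acute[0, t]),
            cost_mgmt=float(res.cost_mgmt[0, t]),
            utility=float(res.utility[0, t]),
            ly=float(res.ly[0, t]),
            discount_factor=(1.0 + r) ** -(t + 0.5),
        ))
    return ledgers, res.event_logs()


def count_events(events: pd.DataFrame, n_individuals: int) -> pd.DataFrame:
    """Event counts by subtype, scaled to per 10,000 individuals."""
    rows = []
    for first in (True, False):
        sel = events[events["first_ever"] == first] if len(events) else events
        subtypes = FIRST_EVER_SUBTYPES if first else RECURRENT_SUBTYPES
        counts = sel["subtype"].value_counts() if len(sel) else {}
        for s in subtypes:
            c = int(counts.get(s, 0)) if len(sel) else 0
            rows.append({
                "class": "first_ever" if first else "recurrent",
                "subtype": s,
                "count": c,
                "per_10000": c * 10000.0 / n_individuals if n_individuals else 0.0,
            })
    df = pd.DataFrame(rows)
    totals = df.groupby("class", sort=False)[["count", "per_10000"]].sum()
    for cls in totals.index:
        df.loc[len(df)] = {
            "class": cls, "subtype": "total",
            "count": totals.loc[cls, "count"],
            "per_10000": totals.loc[cls, "per_10000"],
        }
    return df


def mean_age_first_event(events: pd.DataFrame) -> Optional[float]:
    """Arithmetic mean age at the first-ever event; None if no events."""
    first = events[events["first_ever"]] if len(events) else events
    if len(first) == 0:
        return None
    return float(first["age"].mean())
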