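"""Base case, subgroups, deterministic and probabilistic sensitivity,
threshold, extreme-adherence and budget-impact analyses.

All analyses are reproducible bit-for-bit under a fixed master seed; paired
arms always share common random numbers, and one-way sensitivity runs reuse
the base seed so only the varied parameter changes.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ModelParameters, ConfigError
from .econ import (
    ACUTE_COST_KEY,
    MGMT_KEYS,
    UTILITY_KEYS,
    ArmTotals,
    CEAResult,
    _age_band_key_for,
    band_utility_values,
    compute_icer,
    discount_factors,
    discounted_totals,
    post_event_utility_values,
)
from .engine import (
    INTERVENTION,
    USUAL_CARE,
    ArmResult,
    count_events,
    mean_age_first_event,
    simulate_pair,
)
from .population import restrict_to_age_band, sample_cohort


@dataclasses.dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: Optional[float]
    icer_high: Optional[float]
    base_icer: Optional[float]

    @property
    def span(self) -> float:
        if self.icer_low == self.icer_high:
            return 0.0
        # dominance at one endpoint counts as maximal impact
        if self.icer_low is None or self.icer_high is None:
            return math.inf
        return abs(self.icer_high - self.icer_low)


@dataclasses.dataclass
class BudgetResult:
    eligible_n: int
    per_capita_annual_cost: float
    years: int
    discount_rate: float
    total_intervention_cost: float
    total_cost_offset: float


@dataclasses.dataclass
class PSAOutput:
    draws: pd.DataFrame          # draw, sampled params, d_cost, d_qaly, ce flag
    ceac: pd.DataFrame           # wtp, probability cost-effective
    ce_plane: pd.DataFrame       # d_qaly, d_cost per draw
    prob_cost_effective_at_wtp: float


def _paired_run(
    params: ModelParameters,
    n: Optional[int] = None,
    master_seed: Optional[int] = None,
    marginals=None,
) -> tuple[CEAResult, ArmResult, ArmResult]:
    run = params.run
    n = run.n_individuals if n is None else n
    seed = run.master_seed if master_seed is None else master_seed
    marg = marginals if marginals is not None else params.population
    if run.subgroup_age_range is not None and marginals is None:
        marg = restrict_to_age_band(marg, *run.subgroup_age_range)
    cohort = sample_cohort(marg, n, seed, sbp_jitter=run.sbp_band_jitter)
    res_int, res_uc = simulate_pair(cohort, params, seed)
    tot_int = discounted_totals(res_int, run.discount_rate)
    tot_uc = discounted_totals(res_uc, run.discount_rate)
    cea = compute_icer(tot_int, tot_uc, run.wtp_threshold)
    cea.events_per_10000 = {
        INTERVENTION: count_events(res_int.events, n),
        USUAL_CARE: count_events(res_uc.events, n),
    }
    cea.mean_age_first_event = {
        INTERVENTION: mean_age_first_event(res_int.events),
        USUAL_CARE: mean_age_first_event(res_uc.events),
    }
    return cea, res_int, res_uc


def run_base_case(
    params: ModelParameters,
    n: Optional[int] = None,
    master_seed: Optional[int] = None,
) -> CEAResult:
    """Paired-arm base-case cost-effectiveness analysis."""
    cea, _, _ = _paired_run(params, n=n, master_seed=master_seed)
    return cea


def run_subgroup(
    params: ModelParameters, lo: float, hi: float,
    n: Optional[int] = None, master_seed: Optional[int] = None,
) -> CEAResult:
    """Base case on the cohort restricted to baseline ages ``[lo, hi)``."""
    marg = restrict_to_age_band(params.population, lo, hi)
    cea, _, _ = _paired_run(params, n=n, master_seed=master_seed, marginals=marg)
    return cea


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity


_RUN_LEVEL_PARAMS = {"discount_rate", "intervention_effect_sbp", "effect_years",
                     "age_cap", "start_age"}


def _mutate(params: ModelParameters, name: str, value) -> ModelParameters:
    econ = params.economics
    if name in ("discount_rate", "intervention_effect_sbp"):
        return params.mutated(**{f"run.{name}": float(value)})
    if name in ("effect_years", "age_cap"):
        return params.mutated(**{f"run.{name}": int(round(value))})
    if name == "start_age":
        lo = float(value)
        return params.mutated(**{"run.subgroup_age_range": (lo, min(lo + 1.0, 55.0))})
    if name in econ.acute_costs:
        return params.mutated(**{f"economics.acute_costs.{name}": float(value)})
    if name in econ.mgmt_costs_annual:
        return params.mutated(**{f"economics.mgmt_costs_annual.{name}": float(value)})
    if name in econ.post_event_utilities:
        return params.mutated(
            **{f"economics.post_event_utilities.{name}": float(value)}
        )
    raise ConfigError(f"do not know how to vary parameter {name!r}")


def run_dsa(
    params: ModelParameters,
    parameters: Optional[Sequence[str]] = None,
    n: Optional[int] = None,
    master_seed: Optional[int] = None,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis over the configured plausible ranges.

    Every endpoint rerun shares the base master seed so the only change is
    the varied parameter; entries are sorted by decreasing ICER span.
    """
    ranges = params.economics.dsa_ranges
    names = list(parameters) if parameters is not None else list(ranges)
    missing = [p for p in names if p not in ranges]
    if missing:
        raise ConfigError(f"no DSA range configured for: {', '.join(missing)}")
    base = run_base_case(params, n=n, master_seed=master_seed)
    entries = []
    for name in names:
        lo, hi = ranges[name]
        icers = []
        for v in (lo, hi):
            if icers and hi == lo:
                icers.append(icers[0])
                continue
            cea = run_base_case(_mutate(params, name, v), n=n,
                                master_seed=master_seed)
            icers.append(cea.icer_qaly)
        entries.append(TornadoEntry(
            parameter=name, low=lo, high=hi,
            icer_low=icers[0], icer_high=icers[1], base_icer=base.icer_qaly,
        ))
    finite = [e for e in entries if math.isfinite(e.span)]
    infinite = [e for e in entries if not math.isfinite(e.span)]
    return infinite + sorted(finite, key=lambda e: e.span, reverse=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ConfigError(
            f"infeasible beta moments (sd {sd} too large for mean {mean})"
        )
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def sample_psa_parameters(params: ModelParameters, n_draws: int,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Method-of-moments draws: gamma for costs, beta for utilities."""
    econ = params.economics
    cols = {}
    for key, sd in econ.psa_sd.items():
        base = econ._base_value(key)
        if sd == 0:
            cols[key] = np.full(n_draws, base)
        elif key.startswith("u_"):
            try:
                a, b = _beta_params(base, sd)
            except ConfigError as err:
                raise ConfigError(f"{key}: {err}") from None
            cols[key] = rng.beta(a, b, size=n_draws)
        else:
            k = base * base / (sd * sd)
            theta = sd * sd / base
            cols[key] = rng.gamma(k, theta, size=n_draws)
    return pd.DataFrame(cols)


@dataclasses.dataclass
class _PricingCells:
    """Sufficient statistics to re-price one arm's fixed event trajectories."""

    W: np.ndarray            # (n_bands, n_ukeys+1) discounted quality-weights
    acute: dict[str, float]  # acute cost key -> discounted event count
    mgmt: np.ndarray         # discounted person-cycles per MGMT_KEYS entry
    w_intervention: float    # discounted adherent person-cycles


def _pricing_cells(res: ArmResult, r: float, n_bands: int) -> _PricingCells:
    df = discount_factors(res.n_cycles, r)
    K = len(UTILITY_KEYS)
    active = res.band_idx >= 0
    code = res.band_idx.astype(np.int64) * (K + 1) + (res.ukey_idx.astype(np.int64) + 1)
    w = res.ly * df[None, :]
    W = np.bincount(code[active], weights=w[active],
                    minlength=n_bands * (K + 1)).reshape(n_bands, K + 1)
    acute: dict[str, float] = {}
    for row in res.events.itertuples():
        key = ACUTE_COST_KEY[row.subtype]
        acute[key] = acute.get(key, 0.0) + df[row.cycle]
    mg_active = res.mgmt_key_idx >= 0
    dfm = np.broadcast_to(df, res.mgmt_key_idx.shape)
    mgmt = np.bincount(res.mgmt_key_idx[mg_active],
                       weights=dfm[mg_active], minlength=len(MGMT_KEYS))
    w_int = float((res.adherent * df[None, :]).sum())
    return _PricingCells(W=W, acute=acute, mgmt=mgmt, w_intervention=w_int)


def _price(cells: _PricingCells, band_u: np.ndarray, pe_u: np.ndarray,
           acute_costs: dict[str, float], mgmt_costs: np.ndarray,
           c_intervention: float, combination: str) -> tuple[float, float]:
    """(total cost, total QALYs) of one arm under one parameter draw."""
    if combination == "product":
        u_mat = band_u[:, None] * np.concatenate(([1.0], pe_u))[None, :]
    else:
        u_mat = np.minimum(band_u[:, None], np.concatenate(([np.inf], pe_u))[None, :])
    qaly = float((cells.W * u_mat).sum())
    cost = cells.w_intervention * c_intervention
    cost += sum(cells.acute[k] * acute_costs[k] for k in cells.acute)
    cost += float((cells.mgmt * mgmt_costs).sum())
    return cost, qaly


def run_psa(
    params: ModelParameters,
    n_draws: Optional[int] = None,
    seed: Optional[int] = None,
    inner_n: Optional[int] = None,
    wtp_grid: Optional[np.ndarray] = None,
) -> PSAOutput:
    """Probabilistic sensitivity analysis over cost and utility parameters.

    Sampled parameters do not enter transition probabilities, so each draw's
    paired simulation (same seed, same risk inputs) reproduces identical
    event trajectories; the draw therefore re-prices the common trajectories,
    which is exact and fast.
    """
    run = params.run
    econ = params.economics
    n_draws = run.psa_draws if n_draws is None else n_draws
    inner_n = run.psa_inner_n if inner_n is None else inner_n
    seed = run.master_seed if seed is None else seed
    _, res_int, res_uc = _paired_run(params, n=inner_n, master_seed=seed)

    n_bands = len(econ.utilities_by_age)
    cells = {a.arm: _pricing_cells(a, run.discount_rate, n_bands)
             for a in (res_int, res_uc)}

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(7001,)))
    sampled = sample_psa_parameters(params, n_draws, rng)

    base_band_u = band_utility_values(econ)
    base_pe_u = post_event_utility_values(econ)
    band_keys = [_age_band_key_for(b) for b in econ.utilities_by_age]

    d_cost = np.empty(n_draws)
    d_qaly = np.empty(n_draws)
    for i in range(n_draws):
        band_u = base_band_u.copy()
        for j, key in enumerate(band_keys):
            if key in sampled.columns:
                band_u[j] = sampled[key].iat[i]
        acute = dict(econ.acute_costs)
        for k in acute:
            if k in sampled.columns:
                acute[k] = sampled[k].iat[i]
        mgmt = np.array([
            sampled[k].iat[i] if k in sampled.columns
            else econ.mgmt_costs_annual[k]
            for k in MGMT_KEYS
        ])
        per_arm = {}
        for arm in (INTERVENTION, USUAL_CARE):
            per_arm[arm] = _price(
                cells[arm], band_u, base_pe_u, acute, mgmt,
                econ.intervention_cost_annual, econ.utility_combination,
            )
        d_cost[i] = (per_arm[INTERVENTION][0] - per_arm[USUAL_CARE][0]) / inner_n
        d_qaly[i] = (per_arm[INTERVENTION][1] - per_arm[USUAL_CARE][1]) / inner_n

    ce_at_wtp = run.wtp_threshold * d_qaly - d_cost >= 0
    draws = sampled.copy()
    draws.insert(0, "draw", np.arange(n_draws))
    draws["d_cost"] = d_cost
    draws["d_qaly"] = d_qaly
    draws["cost_effective"] = ce_at_wtp

    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200001.0, 2500.0)
    prob = [(float(w) * d_qaly - d_cost >= 0).mean() for w in wtp_grid]
    ceac = pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": prob})
    ce_plane = pd.DataFrame({"d_qaly": d_qaly, "d_cost": d_cost})
    return PSAOutput(
        draws=draws, ceac=ceac, ce_plane=ce_plane,
        prob_cost_effective_at_wtp=float(ce_at_wtp.mean()),
    )


# ---------------------------------------------------------------------------
# threshold, extreme value, budget impact


def run_threshold(
    params: ModelParameters,
    parameter: str = "effect_years",
    target: Optional[float] = None,
    lo: Optional[float] = None,
    hi: float = 40,
    n: Optional[int] = None,
    master_seed: Optional[int] = None,
    rel_tol: float = 1e-4,
) -> Optional[float]:
    """Smallest parameter value at which the ICER crosses the WTP threshold.

    ``effect_years`` is swept over integer years; continuous parameters are
    bisected (assuming the ICER is monotone over the range).  Returns None
    when the target is unreachable within the range.
    """
    target = params.run.wtp_threshold if target is None else target

    def ok(value) -> bool:
        cea = run_base_case(_mutate(params, parameter, value), n=n,
                            master_seed=master_seed)
        if cea.dominance == "dominant":
            return True
        return cea.icer_qaly is not None and cea.icer_qaly <= target

    if parameter == "effect_years":
        start = int(lo) if lo is not None else params.run.effective_effect_years
        for years in range(start, int(hi) + 1):
            if ok(years):
                return float(years)
        return None

    if lo is None:
        raise ValueError("continuous threshold search needs an explicit lo")
    f_lo, f_hi = ok(lo), ok(hi)
    if f_lo == f_hi:
        return lo if f_lo else None
    a, b = lo, hi
    while abs(b - a) > rel_tol * max(1.0, abs(b)):
        mid = 0.5 * (a + b)
        if ok(mid) == f_hi:
            b = mid
        else:
            a = mid
    return b if f_hi else a


def run_extreme_adherence(
    params: ModelParameters,
    n: Optional[int] = None,
    master_seed: Optional[int] = None,
) -> CEAResult:
    """Extreme-value analysis: 0% adherence after one year of programme."""
    p = params.mutated(**{"run.adherence_years": 1, "run.effect_years": 1})
    return run_base_case(p, n=n, master_seed=master_seed)


def annuity_factor(years: int, r: float) -> float:
    """Present value of 1/year for ``years`` payments, first one at t=0."""
    return float(sum((1.0 + r) ** -t for t in range(years)))


def run_budget_impact(
    eligible_n: int,
    per_capita_annual: float,
    years: int,
    r: float,
    per_person_cost_offset: float = 0.0,
) -> BudgetResult:
    """National roll-out cost and lifetime cost offset.

    The intervention stream discounts years 1..years-1 (year 0 paid up
    front); the offset scales the per-person lifetime discounted saving in
    hospitalisation and management costs.
    """
    if eligible_n <= 0:
        raise ValueError("eligible_n must be positive")
    total = eligible_n * per_capita_annual * annuity_factor(years, r)
    return BudgetResult(
        eligible_n=eligible_n,
        per_capita_annual_cost=per_capita_annual,
        years=years,
        discount_rate=r,
        total_intervention_cost=total,
        total_cost_offset=eligible_n * per_person_cost_offset,
    )


def run_budget_from_base(params: ModelParameters,
                         base: CEAResult) -> BudgetResult:
    """Budget impact using the base-case per-person cost offsets."""
    inc = base.increments
    offset = -(inc["cost_acute"] + inc["cost_mgmt"])
    return run_budget_impact(
        params.run.budget_eligible_n,
        params.economics.intervention_cost_annual,
        params.run.budget_years,
        params.run.discount_rate,
        per_person_cost_offset=offset,
    )
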