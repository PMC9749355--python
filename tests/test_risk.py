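"""Risk equations: linear predictors, horizon conversion, subtype draws,
intervention effect, background mortality lookup."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvdmicrosim import (
    annual_to_horizon,
    apply_intervention,
    draw_first_event_subtype,
    draw_recurrent_event_type,
    horizon_risk,
    horizon_to_annual,
    linear_predictor,
    noncvd_death_prob,
)
from cvdmicrosim.config import MortalityTable, RiskModel, SubtypeSplit
from cvdmicrosim.population import IndividualState
from cvdmicrosim.risk import (
    PredictorContext,
    annual_event_probability,
    first_subtype_from_uniform,
)

SETTINGS = dict(deadline=None, derandomize=True, max_examples=60)


def _ind(**kw):
    base = dict(id=0, age=45.0, ses_quintile=3, smoking="never", diabetes=False,
                sbp=120.0, tc=5.0, hdl=1.5)
    base.update(kw)
    return IndividualState(**base)


def test_all_predictors_at_centering_values_give_zero_lp(params):
    model = params.risk_first_ever
    ind = _ind(age=56.1, ses_quintile=3, sbp=129.0, hdl=1.5, tc=1.5 * 3.73)
    assert linear_predictor(ind, model) == pytest.approx(0.0, abs=1e-12)


def test_single_term_linear_predictor():
    model = RiskModel(
        name="first_ever", horizon_years=5, baseline_survival=0.99,
        predictors=[{"name": "sbp", "transform": "sbp", "beta": 0.2,
                     "center": 0.0}],
    )
    assert linear_predictor(_ind(sbp=5.0), model) == pytest.approx(1.0)


def test_full_coefficient_vector_matches_term_by_term_oracle(params):
    """Spreadsheet-style recomputation of every term of the transcribed
    first-ever equation on a fixed individual."""
    model = params.risk_first_ever
    ind = _ind(age=48.0, ses_quintile=5, smoking="current", diabetes=True,
               sbp=142.0, tc=6.2, hdl=1.1)
    b = {p.name: p.beta for p in model.predictors}
    c = {p.name: p.center for p in model.predictors}
    expected = (
        b["age"] * (48.0 - c["age"])
        + b["deprivation"] * (5 - c["deprivation"])
        + b["ex_smoker"] * 0.0
        + b["current_smoker"] * 1.0
        + b["diabetes"] * 1.0
        + b["sbp"] * (142.0 - c["sbp"])
        + b["tc_hdl_ratio"] * (6.2 / 1.1 - c["tc_hdl_ratio"])
        + b["age_x_diabetes"] * (48.0 - c["age"])
        + b["age_x_sbp"] * (48.0 - c["age"]) * (142.0 - c["sbp"])
    )
    assert linear_predictor(ind, model) == pytest.approx(expected, rel=1e-12)


def test_unknown_transform_is_named(params):
    data = params.risk_first_ever.model_dump()
    data["predictors"][0]["transform"] = "bmi"
    model = RiskModel.model_validate(data)
    with pytest.raises(ValueError, match="bmi"):
        linear_predictor(_ind(), model)


def test_unresolvable_time_since_event_predictor_is_named(params):
    ctx = PredictorContext.from_individual(_ind())
    with pytest.raises(ValueError, match="log_years_since_first_event"):
        linear_predictor(ctx, params.risk_recurrent)


def test_horizon_risk_at_zero_lp_is_one_minus_baseline_survival(params):
    model = params.risk_first_ever
    assert horizon_risk(0.0, model) == pytest.approx(
        1.0 - model.baseline_survival
    )


def test_horizon_risk_closed_form():
    model = RiskModel(name="first_ever", horizon_years=5, baseline_survival=0.95,
                      predictors=[])
    expected = 1.0 - 0.95 ** math.exp(0.5)
    assert horizon_risk(0.5, model) == pytest.approx(expected, rel=1e-12)
    assert horizon_risk(0.5, model) == pytest.approx(0.0811, abs=2e-4)
    assert horizon_risk(-50.0, model) == pytest.approx(0.0, abs=1e-12)


def test_probtoprob_closed_form():
    assert horizon_to_annual(0.0, 5) == 0.0
    assert horizon_to_annual(0.05, 5) == pytest.approx(1 - 0.95 ** 0.2, rel=1e-12)
    assert horizon_to_annual(0.05, 5) == pytest.approx(0.010206, abs=1e-6)


def test_probtoprob_certain_event_warns_and_returns_one():
    with pytest.warns(UserWarning):
        assert horizon_to_annual(1.0, 5) == 1.0


@given(p=st.floats(min_value=0.0, max_value=0.999999),
       horizon=st.sampled_from([5, 10]))
@settings(**SETTINGS)
def test_probtoprob_round_trip_identity(p, horizon):
    assert annual_to_horizon(horizon_to_annual(p, horizon), horizon) == \
        pytest.approx(p, abs=1e-12)


@given(lp=st.floats(min_value=-30, max_value=10))
@settings(**SETTINGS)
def test_probabilities_stay_in_unit_interval(params, lp):
    model = params.risk_first_ever
    p = horizon_to_annual(horizon_risk(lp, model), model.horizon_years)
    assert 0.0 <= p <= 1.0


def test_usual_care_individual_is_unchanged(params):
    ind = _ind(arm="usual_care")
    out, eff_sbp = apply_intervention(ind, 0, params.run)
    assert eff_sbp == ind.sbp
    assert not out.on_intervention


def test_intervention_lowers_effective_sbp_within_adherence(params):
    ind = _ind(arm="intervention")
    out, eff_sbp = apply_intervention(ind, 0, params.run)
    assert eff_sbp == pytest.approx(ind.sbp - 3.16)
    assert out.on_intervention
    assert ind.sbp == 120.0  # stored trajectory untouched


def test_intervention_stops_after_adherence_window(params):
    ind = _ind(arm="intervention")
    out, eff_sbp = apply_intervention(ind, 5, params.run)
    assert eff_sbp == ind.sbp
    assert not out.on_intervention


def test_intervention_stops_at_first_cvd_event(params):
    ind = _ind(arm="intervention")
    ind.cvd_history.append(("MI", 1))
    ind.first_event_cycle = 1
    out, eff_sbp = apply_intervention(ind, 2, params.run)
    assert eff_sbp == ind.sbp
    assert not out.on_intervention


@given(sbp=st.floats(min_value=90, max_value=180),
       drop=st.floats(min_value=0.1, max_value=20),
       age=st.floats(min_value=30, max_value=80))
@settings(**SETTINGS)
def test_lowering_sbp_lowers_first_event_risk(params, sbp, drop, age):
    """Monotonicity where the net SBP gradient is positive (ages where the
    negative age-by-SBP interaction does not overturn the main effect)."""
    model = params.risk_first_ever
    lo = linear_predictor(_ind(age=age, sbp=sbp - drop), model)
    hi = linear_predictor(_ind(age=age, sbp=sbp), model)
    assert horizon_risk(lo, model) < horizon_risk(hi, model)


def test_recurrent_risk_declines_with_time_since_event(params):
    """The log-time coefficient is negative in the transcribed set, so risk
    is non-increasing in years since the first event."""
    model = params.risk_recurrent
    beta = model.predictor("log_years_since_first_event").beta
    assert beta < 0
    probs = []
    for years in (1.0, 5.0, 20.0):
        ctx = PredictorContext.from_individual(
            _ind(age=60.0), years_since_first_event=years
        )
        probs.append(float(annual_event_probability(ctx, model)[0]))
    assert probs[0] >= probs[1] >= probs[2]


def _degenerate_split(winner="MI"):
    first = {s: 0.0 for s in ("MI", "UA", "ischaemic_stroke",
                              "haemorrhagic_stroke", "TIA", "PVD", "CHF",
                              "other_CHD", "other_CVD_death")}
    first[winner] = 1.0
    return SubtypeSplit(first_ever=first,
                        recurrent={"nonfatal_stroke": 0.0, "nonfatal_MI": 0.0,
                                   "cvd_death": 1.0})


def test_degenerate_splits_are_deterministic():
    split = _degenerate_split("TIA")
    rng = np.random.default_rng(0)
    assert all(draw_first_event_subtype(split, rng) == "TIA" for _ in range(20))
    assert all(draw_recurrent_event_type(rng, split.recurrent) == "cvd_death"
               for _ in range(20))


def test_subtype_frequencies_within_three_binomial_se(params):
    split = params.subtypes
    n = 100_000
    u = np.random.default_rng(123).random(n)
    codes = first_subtype_from_uniform(split, u)
    for i, (name, mass) in enumerate(split.first_ever.items()):
        freq = (codes == i).mean()
        se = math.sqrt(mass * (1 - mass) / n)
        assert abs(freq - mass) <= 3 * se + 1e-12, name


def test_two_subtype_symmetry():
    split = _degenerate_split()
    split = SubtypeSplit(
        first_ever={**{k: 0.0 for k in split.first_ever}, "MI": 0.5, "UA": 0.5},
        recurrent=split.recurrent,
    )
    u = np.random.default_rng(7).random(40_000)
    codes = first_subtype_from_uniform(split, u)
    assert (codes == 0).mean() == pytest.approx(0.5, abs=0.01)


def test_mortality_lookup_is_verbatim(params):
    table = params.mortality
    assert noncvd_death_prob(47.0, table) == 0.00100
    assert noncvd_death_prob(45.0, table) == 0.00100
    assert noncvd_death_prob(44.9, table) == 0.00065
    assert noncvd_death_prob(99.0, table) == 0.18000


def test_mortality_zero_table():
    table = MortalityTable(rows=[{"age": 30, "p": 0.0}])
    assert noncvd_death_prob(80.0, table) == 0.0


def test_mortality_below_coverage_raises(params):
    with pytest.raises(ValueError, match="coverage"):
        noncvd_death_prob(12.0, params.mortality)


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8,
                unique=True))
@settings(**SETTINGS)
def test_monotone_tables_give_monotone_lookups(probs):
    rows = [{"age": 30 + 5 * i, "p": p} for i, p in enumerate(sorted(probs))]
    table = MortalityTable(rows=rows)
    ages = np.linspace(30, 30 + 5 * len(probs) + 10, 50)
    vals = noncvd_death_prob(ages, table)
    assert np.all(np.diff(vals) >= -1e-15)
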