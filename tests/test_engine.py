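"""Microsimulation engine: coupling, determinism, conservation, oracles."""

import numpy as np
import pandas as pd
import pytest

from cvdmicrosim import (
    count_events,
    mean_age_first_event,
    simulate_arm,
    simulate_individual,
    simulate_pair,
)
from cvdmicrosim.engine import INTERVENTION, USUAL_CARE
from cvdmicrosim.population import IndividualState

from conftest import make_cohort, no_cvd_params


def test_immortal_limit_reaches_age_cap(params):
    p = no_cvd_params(params, mortality_p=0.0)
    cohort = make_cohort(20, age=40.0)
    res = simulate_arm(cohort, USUAL_CARE, p, master_seed=1)
    assert len(res.events) == 0
    undiscounted_ly = res.ly.sum(axis=1)
    assert np.all(undiscounted_ly == p.run.age_cap - 40.0)


def test_immediate_death_gives_half_cycle(params):
    p = no_cvd_params(params, mortality_p=1.0)
    ind = IndividualState(id=0, age=45.0, ses_quintile=3, smoking="never",
                          diabetes=False, sbp=120.0, tc=5.0, hdl=1.5)
    ledgers, events = simulate_individual(ind, p, master_seed=1)
    assert len(ledgers) == 1
    assert ledgers[0].ly == 0.5
    assert ledgers[0].discount_factor == pytest.approx(1.03 ** -0.5)
    assert events == []


def test_zero_effect_arms_identical_under_common_random_numbers(params):
    p = params.mutated(**{"run.intervention_effect_sbp": 0.0})
    cohort = make_cohort(300, age=48.0, sbp=150.0)
    res_int, res_uc = simulate_pair(cohort, p, master_seed=5)
    assert res_int.events.equals(res_uc.events)
    assert np.array_equal(res_int.ly, res_uc.ly)
    assert np.array_equal(res_int.utility, res_uc.utility)
    assert np.array_equal(res_int.cost_acute, res_uc.cost_acute)
    assert np.array_equal(res_int.cost_mgmt, res_uc.cost_mgmt)
    # the arms differ only in the programme cost
    assert res_int.cost_intervention.sum() > 0
    assert res_uc.cost_intervention.sum() == 0


def test_same_seed_is_bitwise_reproducible(params):
    cohort = make_cohort(200, age=50.0, sbp=160.0, smoking=2)
    a = simulate_arm(cohort, USUAL_CARE, params, master_seed=9)
    b = simulate_arm(cohort, USUAL_CARE, params, master_seed=9)
    assert a.events.equals(b.events)
    assert np.array_equal(a.utility, b.utility)
    c = simulate_arm(cohort, USUAL_CARE, params, master_seed=10)
    assert not a.events.equals(c.events)


def test_split_cohort_concatenation_equals_single_run(params):
    """Per-individual streams keyed by id make results independent of how
    the cohort is batched."""
    cohort = make_cohort(120, age=50.0, sbp=160.0, smoking=2, diabetes=True)
    whole = simulate_arm(cohort, USUAL_CARE, params, master_seed=3)
    first = simulate_arm(cohort.subset(slice(0, 60)), USUAL_CARE, params, 3)
    second = simulate_arm(cohort.subset(slice(60, 120)), USUAL_CARE, params, 3)
    combined = pd.concat([first.events, second.events], ignore_index=True)
    key = ["id", "cycle"]
    assert whole.events.sort_values(key).reset_index(drop=True).equals(
        combined.sort_values(key).reset_index(drop=True)
    )
    assert np.array_equal(whole.ly, np.vstack([first.ly, second.ly]))


def test_event_count_conservation(params):
    cohort = make_cohort(800, age=52.0, sbp=165.0, smoking=2, diabetes=True)
    res = simulate_arm(cohort, USUAL_CARE, params, master_seed=21)
    ev = res.events
    assert len(ev) > 0
    n_first = int(ev["first_ever"].sum())
    assert n_first == ev["id"].nunique()
    per_id = ev.groupby("id").size()
    assert int((per_id - 1).sum()) == len(ev) - n_first  # recurrent count
    table = count_events(ev, len(cohort))
    tot = table[table["subtype"] == "total"].set_index("class")
    assert tot.loc["first_ever", "count"] == n_first
    assert tot.loc["recurrent", "count"] == len(ev) - n_first
    # per-10,000 scaling
    assert tot.loc["first_ever", "per_10000"] == pytest.approx(
        n_first * 10000 / len(cohort)
    )


def test_no_ledger_entries_after_fatal_event(params):
    cohort = make_cohort(500, age=52.0, sbp=170.0, smoking=2, diabetes=True)
    res = simulate_arm(cohort, USUAL_CARE, params, master_seed=4)
    fatal = res.events[res.events["fatal"]]
    assert len(fatal) > 0
    for row in fatal.itertuples():
        i = int(np.flatnonzero(cohort.id == row.id)[0])
        assert res.ly[i, int(row.cycle)] == 0.5
        assert np.all(res.ly[i, int(row.cycle) + 1:] == 0.0)
        assert np.all(res.band_idx[i, int(row.cycle) + 1:] == -1)
        # a fatal event is the individual's last record
        later = res.events[(res.events["id"] == row.id)
                           & (res.events["cycle"] > row.cycle)]
        assert len(later) == 0


def test_at_most_one_event_per_individual_per_cycle(params):
    cohort = make_cohort(500, age=50.0, sbp=170.0, smoking=2, diabetes=True)
    res = simulate_arm(cohort, USUAL_CARE, params, master_seed=17)
    assert not res.events.duplicated(subset=["id", "cycle"]).any()


def test_flat_mortality_matches_geometric_lifetime_closed_form(params):
    """With constant annual death probability p and no CVD, mean
    undiscounted LY has the truncated-geometric closed form
    sum_k (1-p)^k (1 - p/2)."""
    p_death = 0.08
    p = no_cvd_params(params, mortality_p=p_death)
    n = 8000
    cohort = make_cohort(n, age=40.0)
    res = simulate_arm(cohort, USUAL_CARE, p, master_seed=12)
    ly = res.ly.sum(axis=1)
    cycles = p.run.age_cap - 40
    expected = sum((1 - p_death) ** k * (1 - 0.5 * p_death)
                   for k in range(cycles))
    se = ly.std(ddof=1) / np.sqrt(n)
    assert abs(ly.mean() - expected) <= 3 * se


def test_intervention_cost_only_in_adherent_cvd_free_cycles(params):
    p = no_cvd_params(params)  # nobody has events or dies
    cohort = make_cohort(10, age=40.0)
    res = simulate_arm(cohort, INTERVENTION, p, master_seed=2)
    c = params.economics.intervention_cost_annual
    assert np.all(res.cost_intervention[:, :5] == c)
    assert np.all(res.cost_intervention[:, 5:] == 0.0)


def test_count_events_empty_and_hand_built():
    empty = pd.DataFrame(columns=["id", "cycle", "age", "subtype", "fatal",
                                  "first_ever"])
    table = count_events(empty, 100)
    assert (table["count"] == 0).all()

    logs = pd.DataFrame({
        "id": [1, 1, 2],
        "cycle": [3, 6, 4],
        "age": [43.0, 46.0, 50.0],
        "subtype": ["MI", "nonfatal_stroke", "TIA"],
        "fatal": [False, False, False],
        "first_ever": [True, False, True],
    })
    table = count_events(logs, 1000).set_index(["class", "subtype"])
    assert table.loc[("first_ever", "MI"), "count"] == 1
    assert table.loc[("first_ever", "TIA"), "per_10000"] == 10.0
    assert table.loc[("recurrent", "nonfatal_stroke"), "count"] == 1
    assert table.loc[("first_ever", "total"), "count"] == 2


def test_mean_age_first_event_small_cases():
    def frame(ages):
        return pd.DataFrame({
            "id": range(len(ages)), "cycle": [0] * len(ages), "age": ages,
            "subtype": ["MI"] * len(ages), "fatal": [False] * len(ages),
            "first_ever": [True] * len(ages),
        })
    assert mean_age_first_event(frame([42.0])) == 42.0
    assert mean_age_first_event(frame([40.0, 60.0])) == 50.0
    assert mean_age_first_event(frame([])) is None


def test_recurrent_risk_requires_history(params):
    cohort = make_cohort(400, age=52.0, sbp=170.0, smoking=2, diabetes=True)
    res = simulate_arm(cohort, USUAL_CARE, params, master_seed=30)
    ev = res.events
    rec = ev[~ev["first_ever"]]
    firsts = ev[ev["first_ever"]].set_index("id")["cycle"]
    for row in rec.itertuples():
        assert row.cycle > firsts.loc[row.id]
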