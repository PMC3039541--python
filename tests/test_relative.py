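"""Cohort life table, Ederer II expected survival, relative ratios and CIs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relsurv import (
    PopulationLifeTable,
    ScenarioConfig,
    StratumSpec,
    cr_confidence_interval,
    ederer2_expected,
    make_lifetable,
    observed_survival,
    relative_ratios,
    run_life_table,
    run_life_table_by,
    simulate_cohort,
    tabulate_intervals,
)

from conftest import toy_cohort


def counts_frame(rows):
    df = pd.DataFrame(rows, columns=["L", "D", "W"])
    df.insert(0, "interval", range(len(df)))
    df.insert(1, "start", df["interval"].astype(float))
    df.insert(2, "end", df["interval"] + 1.0)
    return df


class TestTabulate:
    def test_hand_enumerated_five_record_cohort(self, five_records):
        out = tabulate_intervals(five_records, width=1.0)
        assert out[["L", "D", "W"]].to_numpy().tolist() == [
            [5, 1, 0],
            [4, 1, 0],
            [3, 0, 1],
            [2, 0, 2],
        ]

    def test_counts_are_linear_in_weights(self, five_records):
        doubled = five_records.assign(weight=2.0)
        a = tabulate_intervals(five_records)[["L", "D", "W"]].to_numpy()
        b = tabulate_intervals(doubled)[["L", "D", "W"]].to_numpy()
        assert np.allclose(b, 2 * a)

    def test_single_early_death(self):
        df = toy_cohort().iloc[:1].assign(follow_up=0.2, event=1)
        out = tabulate_intervals(df)
        assert out[["L", "D", "W"]].to_numpy().tolist() == [[1, 1, 0]]

    def test_death_on_boundary_goes_to_starting_interval(self):
        df = toy_cohort().iloc[:1].assign(follow_up=2.0, event=1)
        out = tabulate_intervals(df)
        assert out.loc[2, "D"] == 1 and len(out) == 3

    def test_censoring_on_boundary_goes_to_preceding_interval(self):
        df = toy_cohort().iloc[:1].assign(follow_up=2.0, event=0)
        out = tabulate_intervals(df)
        assert out.loc[1, "W"] == 1 and len(out) == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tabulate_intervals(toy_cohort().iloc[:0])

    def test_unweighted_flag_ignores_weights(self, five_records):
        df = five_records.assign(weight=[1, 2, 3, 4, 5])
        out = tabulate_intervals(df, weighted=False)
        assert out.loc[0, "L"] == 5


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0.01, max_value=6.0),
            st.integers(min_value=0, max_value=1),
            st.floats(min_value=0.5, max_value=3.0),
        ),
        min_size=1,
        max_size=50,
    )
)
def test_tabulation_matches_brute_force(recs):
    """On small cohorts the vectorised tabulation equals a per-record loop."""
    df = pd.DataFrame(
        {
            "id": [str(i) for i in range(len(recs))],
            "entry_age": 70,
            "entry_year": 1996,
            "follow_up": [r[0] for r in recs],
            "event": [r[1] for r in recs],
            "weight": [r[2] for r in recs],
            "stratum": "S",
        }
    )
    out = tabulate_intervals(df, width=1.0)
    n_int = len(out)
    L = np.zeros(n_int)
    D = np.zeros(n_int)
    W = np.zeros(n_int)
    for t, ev, w in recs:
        k = int(math.floor(t / 1.0))
        if ev == 0 and t > 0 and abs(t - k * 1.0) <= 1e-9:
            k -= 1
        for i in range(k + 1):
            L[i] += w
        (D if ev else W)[k] += w
    assert np.allclose(out["L"], L) and np.allclose(out["D"], D) and np.allclose(out["W"], W)

    # count conservation: everyone exits exactly once
    assert out["D"].sum() + out["W"].sum() == pytest.approx(df["weight"].sum(), abs=1e-9)


class TestObservedSurvival:
    @pytest.mark.parametrize(
        "L, D, W, p",
        [
            (12424, 135, 0, 0.989),  # large-cohort first-year survival
            (9460, 398, 707, 0.956),  # final year with administrative withdrawals
        ],
    )
    def test_published_interval_rows(self, L, D, W, p):
        out = observed_survival(counts_frame([(L, D, W)]))
        assert out.loc[0, "L_eff"] == L - W / 2
        assert round(out.loc[0, "P"], 3) == p

    def test_no_deaths_means_flat_survival(self):
        out = observed_survival(counts_frame([(10, 0, 0), (10, 0, 0)]))
        assert (out["P"] == 1).all() and (out["CP"] == 1).all()

    def test_deaths_exceeding_exposure_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            observed_survival(counts_frame([(10, 8, 6)]))

    def test_nonpositive_exposure_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = observed_survival(counts_frame([(10, 2, 0), (0, 0, 0)]))
        assert len(out) == 1


def two_stratum_table(q_by_stratum):
    strata = tuple(q_by_stratum)
    q = np.array([[[q_by_stratum[s]] * 21] * 16 for s in strata])
    return PopulationLifeTable(
        strata=strata, years=np.arange(1995, 2011), ages=np.arange(65, 86), q=q
    )


class TestEderer2:
    def test_homogeneous_cohort_reproduces_q(self, flat_table):
        df = toy_cohort().assign(follow_up=4.0, event=0)
        counts = observed_survival(tabulate_intervals(df))
        exp = ederer2_expected(df, flat_table, counts)
        assert np.allclose(exp["P_star"].iloc[:3], 0.98)

    def test_two_record_hand_sum(self):
        table = two_stratum_table({"lo": 0.01, "hi": 0.03})
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "entry_age": 70,
                "entry_year": 1996,
                "follow_up": 2.0,
                "event": 0,
                "weight": 1.0,
                "stratum": ["lo", "hi"],
            }
        )
        counts = observed_survival(tabulate_intervals(df))
        exp = ederer2_expected(df, table, counts)
        assert exp.loc[0, "D_star"] == pytest.approx(0.04)
        assert exp.loc[0, "P_star"] == pytest.approx(0.98)

    def test_mid_interval_withdrawal_contributes_half(self, flat_table):
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "entry_age": 70,
                "entry_year": 1996,
                "follow_up": [2.0, 0.5],
                "event": 0,
                "weight": 1.0,
                "stratum": "S",
            }
        )
        counts = observed_survival(tabulate_intervals(df))
        exp = ederer2_expected(df, flat_table, counts)
        assert counts.loc[0, "L_eff"] == pytest.approx(1.5)
        assert exp.loc[0, "D_star"] == pytest.approx(0.02 + 0.01)
        assert exp.loc[0, "P_star"] == pytest.approx(0.98)

    def test_unknown_stratum_fails_before_computation(self, flat_table):
        df = toy_cohort().assign(stratum="nope")
        counts = observed_survival(tabulate_intervals(df))
        with pytest.raises(KeyError, match="unknown stratum"):
            ederer2_expected(df, flat_table, counts)


class TestRatios:
    def test_observed_equals_expected_gives_unity(self):
        obs = observed_survival(counts_frame([(100, 2, 0), (98, 2, 0)]))
        exp = pd.DataFrame(
            {"interval": [0, 1], "D_star": obs["D"], "P_star": obs["P"],
             "CP_star": obs["CP"]}
        )
        out = relative_ratios(obs, exp)
        assert np.allclose(out["R"], 1) and np.allclose(out["CR"], 1)

    def test_published_first_interval_ratio(self):
        obs = observed_survival(counts_frame([(12424, 135, 0)]))
        exp = pd.DataFrame({"interval": [0], "D_star": [0.0], "P_star": [0.981],
                            "CP_star": [0.981]})
        assert round(relative_ratios(obs, exp).loc[0, "R"], 3) == 1.008

    def test_zero_expected_survival_identifies_interval(self):
        obs = observed_survival(counts_frame([(100, 2, 0)]))
        exp = pd.DataFrame({"interval": [0], "D_star": [100.0], "P_star": [0.0],
                            "CP_star": [0.0]})
        with pytest.raises(ValueError, match="interval 0"):
            relative_ratios(obs, exp)


class TestGreenwoodCI:
    def test_no_deaths_collapses_interval_to_point(self):
        obs = observed_survival(counts_frame([(100, 0, 0), (100, 0, 0)]))
        obs["R"] = obs["CR"] = 1.0
        out = cr_confidence_interval(obs)
        assert np.allclose(out["ci_low"], out["CR"])
        assert np.allclose(out["ci_high"], out["CR"])

    def test_single_interval_closed_form(self):
        obs = observed_survival(counts_frame([(100, 10, 0)]))
        obs["R"] = obs["CR"] = obs["P"]  # expected survival 1
        out = cr_confidence_interval(obs, level=0.95)
        half = 1.959963984540054 * math.sqrt(10 / (100 * 90))
        assert out.loc[0, "ci_low"] == pytest.approx(0.9 * math.exp(-half))
        assert out.loc[0, "ci_high"] == pytest.approx(0.9 * math.exp(half))

    def test_exhausted_risk_set_rejected(self):
        obs = observed_survival(counts_frame([(10, 10, 0)]))
        obs["R"] = obs["CR"] = obs["P"]
        with pytest.raises(ValueError, match="Greenwood"):
            cr_confidence_interval(obs)

    def test_agrees_with_bootstrap_on_synthetic_cohort(self, gompertz_table, null_scenario):
        """Greenwood CI endpoints sit near the percentile-bootstrap endpoints."""
        cfg = ScenarioConfig(
            n=2000, entry_year=1996,
            entry_age_probs=null_scenario.entry_age_probs,
            strata=[StratumSpec("all", 1.0)], seed=42,
        )
        df = simulate_cohort(cfg, gompertz_table)
        run = run_life_table(df, table=gompertz_table)
        last = run.iloc[-1]
        rng = np.random.default_rng(2024)
        crs = []
        for _ in range(1000):
            boot = df.iloc[rng.integers(0, len(df), len(df))]
            crs.append(run_life_table(boot, table=gompertz_table)["CR"].iloc[-1])
        lo, hi = np.percentile(crs, [2.5, 97.5])
        width = last["ci_high"] - last["ci_low"]
        assert abs(last["ci_low"] - lo) < 0.15 * width
        assert abs(last["ci_high"] - hi) < 0.15 * width


class TestPipeline:
    def test_weight_rescaling_leaves_ratios_unchanged(self, gompertz_table, null_scenario):
        df = simulate_cohort(null_scenario, gompertz_table)
        a = run_life_table(df, table=gompertz_table)
        b = run_life_table(df.assign(weight=df["weight"] * 7.3), table=gompertz_table)
        for col in ("P", "P_star", "R", "CR"):
            assert np.allclose(a[col], b[col])

    def test_injected_expected_vector_of_wrong_length_rejected(self):
        counts = counts_frame([(100, 2, 0), (98, 2, 0)])
        with pytest.raises(ValueError, match="length"):
            run_life_table(counts=counts, expected=[0.98])

    def test_healthier_cohort_shows_advantage_in_every_interval(self, gompertz_table):
        """A cohort with uniformly lower hazard than its reference has CR > 1 throughout."""
        cfg = ScenarioConfig(
            n=20000, entry_year=1996,
            entry_age_probs={a: 0.2 for a in range(70, 75)},
            strata=[StratumSpec("all", 1.0)],
            healthy_volunteer_factor=0.9, seed=5,
        )
        df = simulate_cohort(cfg, gompertz_table)
        run = run_life_table(df, table=gompertz_table)
        assert (run["CR"] > 1).all()
        assert run["CR"].iloc[-1] > run["CR"].iloc[0]

    def test_subgroup_deaths_sum_to_total(self, gompertz_table):
        cfg = ScenarioConfig(
            n=3000, entry_year=1996,
            entry_age_probs={a: 0.2 for a in range(70, 75)},
            strata=[StratumSpec("a", 0.6), StratumSpec("b", 0.4, sampling_fraction=2.0)],
            seed=9,
        )
        table = make_lifetable(strata_multipliers={"a": 1.0, "b": 1.1})
        df = simulate_cohort(cfg, table)
        total = run_life_table(df, table=table)
        parts = run_life_table_by(df, "stratum", table=table)
        pooled = sum(
            p.set_index("interval")["D"].reindex(total["interval"], fill_value=0)
            for p in parts.values()
        )
        assert np.allclose(pooled.to_numpy(), total["D"].to_numpy(), atol=1e-9)
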