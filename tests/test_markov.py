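import numpy as np
import pytest

from copdcea import markov
from copdcea.effects import null_effects
from copdcea.parameters import fixed


def _zeros(params):
    """Sampled overrides: no transitions, no exacerbations, no deaths."""
    out = {"model.death_on_admission": 0.0}
    for st in params.stage_labels:
        out[f"exac.{st}"] = 0.0
    for (i, j) in params.usual_care_matrix.cells:
        out[f"tp.{i}.{j}"] = 0.0
    return out


def _start_all(params, stage):
    return {f"start.{a}.{s}": (1.0 if s == stage else 0.0)
            for a in markov.ARMS for s in params.stage_labels}


class TestStateSpace:
    def test_dimensions(self, session_params):
        space = markov.StateSpace(session_params.stage_labels,
                                  session_params.landing)
        assert space.n_stages == 4
        assert space.n_states == 4 * 4 + 1  # stages + 3 tunnel months each + dead
        assert space.state_names[-1] == "dead"

    def test_landing_rule(self, session_params):
        assert session_params.landing == {"A": "C", "B": "D", "C": "C", "D": "D"}

    def test_invalid_landing_rejected(self):
        with pytest.raises(ValueError):
            markov.StateSpace(("A", "B"), {"A": "Z", "B": "B"})


class TestCycleStep:
    def test_row_a_residual_stay(self, session_params):
        # off-diagonals 0.008 + 0.011 + 0.003 leave 0.978 staying in A
        ri = markov.resolve(session_params)
        space = ri.space
        occ = np.zeros(space.n_states)
        occ[space.stage("A")] = 1.0
        rates = np.zeros(4)
        new, adm = markov.cycle_step(occ, ri.matrices["intervention"][2],
                                     rates, 0.0, space)
        assert new[space.stage("A")] == pytest.approx(0.978)
        assert adm == 0.0

    def test_tunnel_exit(self, session_params):
        ri = markov.resolve(session_params)
        space = ri.space
        occ = np.zeros(space.n_states)
        occ[space.tunnel("D", 3)] = 1.0
        new, _ = markov.cycle_step(occ, ri.matrices["usual_care"][2],
                                   np.zeros(4), 0.0, space)
        assert new[space.stage("D")] == pytest.approx(1.0)

    def test_deterioration_rule_b_to_d(self, session_params):
        ri = markov.resolve(session_params)
        space = ri.space
        occ = np.zeros(space.n_states)
        occ[space.stage("B")] = 1.0
        rates = np.array([0.0, 1.0, 0.0, 0.0])
        new, adm = markov.cycle_step(occ, ri.matrices["usual_care"][2],
                                     rates, 0.0, space)
        assert new[space.tunnel("D", 1)] == pytest.approx(1.0)
        assert adm == pytest.approx(1.0)

    def test_mass_conserved(self, session_params):
        ri = markov.resolve(session_params)
        space = ri.space
        rng = np.random.default_rng(0)
        occ = rng.dirichlet(np.ones(space.n_states))
        new, _ = markov.cycle_step(occ, ri.matrices["usual_care"][2],
                                   np.array([0.1, 0.2, 0.3, 0.4]), 0.3, space)
        assert new.sum() == pytest.approx(1.0, abs=1e-12)


class TestRunCohort:
    def test_start_held_until_month_13(self, session_params):
        tr = markov.run_cohort(session_params, "intervention")
        space = tr.space
        assert tr.occupancy[12, space.stage("D")] == pytest.approx(0.765)
        assert tr.occupancy[12, space.stage("C")] == pytest.approx(0.059)

    def test_fixed_point_without_dynamics(self, params):
        sampled = _zeros(params)
        tr = markov.run_cohort(params, "usual_care", sampled=sampled)
        for t in range(13, 61):
            assert np.allclose(tr.occupancy[t], tr.occupancy[12])

    def test_forced_absorption(self, params):
        sampled = {f"exac.{s}": 1.0 for s in params.stage_labels}
        sampled["model.death_on_admission"] = 1.0
        tr = markov.run_cohort(params, "usual_care", sampled=sampled)
        assert tr.occupancy[14, tr.space.dead] == pytest.approx(1.0)

    def test_mass_conservation_default(self, session_params):
        for arm in markov.ARMS:
            markov.run_cohort(session_params, arm).check_mass(tol=1e-9)

    def test_unknown_arm_rejected(self, session_params):
        with pytest.raises(ValueError):
            markov.run_cohort(session_params, "placebo")

    def test_trace_frame_tidy(self, session_params):
        df = markov.run_cohort(session_params, "usual_care").to_frame()
        assert {"cycle", "state", "occupancy", "cost_inc", "qaly_inc",
                "cost_inc_disc", "qaly_inc_disc"} <= set(df.columns)
        assert df["cycle"].max() == 60


class TestAccrual:
    def test_discount_factor_closed_form(self, session_params):
        ri = markov.resolve(session_params)
        assert ri.discount_factor(24) == pytest.approx(1.035 ** -2, abs=1e-9)
        assert round(ri.discount_factor(24), 5) == 0.93351
        assert ri.discount_factor(12) == 1.0

    def test_stage_d_qaly_increment(self, params):
        sampled = {**_zeros(params), **_start_all(params, "D")}
        tr = markov.run_cohort(params, "usual_care", sampled=sampled)
        assert tr.qaly_inc[13] == pytest.approx(0.59 / 12.0)

    def test_year1_spread_undiscounted(self, session_params):
        tr = markov.run_cohort(session_params, "usual_care")
        y1 = session_params.year1["usual_care"]
        assert np.allclose(tr.cost_inc[1:13], y1["cost"] / 12.0)
        assert np.allclose(tr.qaly_inc[1:13], tr.qaly_inc_disc[1:13])

    def test_zero_rate_removes_discounting(self, params):
        params.discount_rate_annual = 0.0
        tr = markov.run_cohort(params, "usual_care")
        assert tr.cost_inc_disc.sum() == pytest.approx(tr.cost_inc.sum())
        assert tr.qaly_inc_disc.sum() == pytest.approx(tr.qaly_inc.sum())

    def test_discounted_below_undiscounted_after_year1(self, session_params):
        tr = markov.run_cohort(session_params, "usual_care")
        assert np.all(tr.cost_inc_disc[13:] <= tr.cost_inc[13:] + 1e-12)
        assert np.all(tr.qaly_inc_disc[13:] <= tr.qaly_inc[13:] + 1e-12)

    def test_equal_utility_closed_form(self, params):
        u = 0.7
        sampled = {f"util.{s}": u for s in params.stage_labels}
        for s in params.stage_labels:
            sampled[f"exac.{s}"] = 0.0  # no admissions, no deaths, no tunnels
        tr = markov.run_cohort(params, "usual_care", sampled=sampled)
        ri = markov.resolve(params, sampled)
        expected = params.year1["usual_care"]["qaly"] + u / 12.0 * sum(
            ri.discount_factor(t) for t in range(13, 61))
        assert tr.total_qaly == pytest.approx(expected)


class TestCEResult:
    def test_identical_arms_indifferent(self, params):
        params.effects = null_effects(params.effects)
        params.starting_states["intervention"] = dict(
            params.starting_states["usual_care"])
        params.year1["intervention"] = dict(params.year1["usual_care"])
        params.stage_params.intervention_monthly_cost = fixed(0.0)
        res = markov.deterministic_cua(params)
        assert res.delta_cost == pytest.approx(0.0, abs=1e-9)
        assert res.delta_effect == pytest.approx(0.0, abs=1e-9)
        assert res.dominance == "indifferent"
        assert res.icer is None

    def test_naive_icer_arithmetic(self):
        icer, label = markov.icer_and_label(238.16, 0.020)
        assert icer == pytest.approx(11908.0)
        assert label == "north_east"

    @pytest.mark.parametrize("dc,de,label", [
        (-10.0, 0.1, "dominant"),
        (10.0, -0.1, "dominated"),
        (-10.0, 0.0, "dominant"),
        (10.0, 0.0, "dominated"),
        (-10.0, -0.1, "south_west"),
    ])
    def test_dominance_labels(self, dc, de, label):
        _, got = markov.icer_and_label(dc, de)
        assert got == label

    def test_defaults_north_east_quadrant(self, session_params):
        res = markov.deterministic_cua(session_params)
        assert res.delta_cost > 0
        assert res.delta_effect > 0
        assert res.dominance == "north_east"

    def test_nmb_linear_in_wtp(self, session_params):
        res = markov.deterministic_cua(session_params)
        n0, n1, n2 = res.nmb(0), res.nmb(10000), res.nmb(20000)
        assert n2 - n1 == pytest.approx(n1 - n0)
        assert n0 == pytest.approx(-res.delta_cost)

    def test_death_monotonicity(self, params):
        qalys = []
        for d in (0.0, 0.1, 0.3, 0.7, 1.0):
            params.death_on_admission = d
            res = markov.deterministic_cua(params)
            qalys.append(res.arm_effects["usual_care"])
        assert all(b <= a + 1e-12 for a, b in zip(qalys, qalys[1:]))


class TestMicrosim:
    def test_reproducible(self, session_params):
        a = markov.microsim_oracle(session_params, "intervention", 500, seed=3)
        b = markov.microsim_oracle(session_params, "intervention", 500, seed=3)
        assert a == b

    def test_degenerate_probabilities_match_cohort_exactly(self, params):
        sampled = {**_zeros(params), **_start_all(params, "D")}
        tr = markov.run_cohort(params, "usual_care", sampled=sampled)
        ms = markov.microsim_oracle(params, "usual_care", 50, seed=1,
                                    sampled=sampled)
        assert ms["mean_qaly"] == pytest.approx(tr.total_qaly)
        assert ms["mean_cost"] == pytest.approx(tr.total_cost)

    def test_agreement_with_cohort(self, session_params):
        for arm in markov.ARMS:
            tr = markov.run_cohort(session_params, arm)
            ms = markov.microsim_oracle(session_params, arm, 8000, seed=11)
            assert abs(ms["mean_qaly"] - tr.total_qaly) < 4 * ms["se_qaly"]
            assert abs(ms["mean_cost"] - tr.total_cost) < 4 * ms["se_cost"]

    def test_invalid_n_rejected(self, session_params):
        with pytest.raises(ValueError):
            markov.microsim_oracle(session_params, "usual_care", 0, seed=0)


class TestMergedStructure:
    def test_merge_shapes(self, session_params):
        ace = markov.merge_ace(session_params)
        assert ace.stage_labels == ("A", "B", "E")
        assert ace.landing == {"A": "E", "B": "E", "E": "E"}
        assert ace.structure == "ace"

    def test_starting_mass_pooled(self, session_params):
        ace = markov.merge_ace(session_params)
        for arm in markov.ARMS:
            orig = session_params.starting_states[arm]
            assert ace.starting_states[arm]["E"].point == pytest.approx(
                orig["C"].point + orig["D"].point)
            total = sum(s.point for s in ace.starting_states[arm].values())
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_pooled_utility_between_parents(self, session_params):
        ace = markov.merge_ace(session_params)
        u = ace.stage_params.utilities["E"].point
        assert 0.59 <= u <= 0.82

    def test_run_and_mass_conservation(self, session_params):
        ace = markov.merge_ace(session_params)
        for arm in markov.ARMS:
            markov.run_cohort(ace, arm).check_mass(tol=1e-9)

    def test_effect_stages_remapped(self, session_params):
        ace = markov.merge_ace(session_params)
        assert set(ace.effects.effect_stages) == {"B", "E"}

    def test_double_merge_rejected(self, session_params):
        ace = markov.merge_ace(session_params)
        with pytest.raises(ValueError):
            markov.merge_ace(ace)
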