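import copy

import numpy as np
import pandas as pd
import pytest

from copdcea import markov, psa
from copdcea.parameters import DistributionSpec, TransitionMatrix, fixed


def _toy_psa(costs_uc, qalys_uc, costs_iv, qalys_iv, digest=None):
    return psa.PSAOutput(
        costs={"usual_care": np.asarray(costs_uc, dtype=float),
               "intervention": np.asarray(costs_iv, dtype=float)},
        qalys={"usual_care": np.asarray(qalys_uc, dtype=float),
               "intervention": np.asarray(qalys_iv, dtype=float)},
        digest=digest if digest is not None else pd.DataFrame(),
        seed=None)


@pytest.fixture(scope="module")
def psa_small(session_params):
    return psa.run_psa(session_params, n_iter=800, seed=99)


def _freeze(params, keep=()):
    """Replace every sampling distribution by its point except ``keep``."""
    p = copy.deepcopy(params)
    sp = p.stage_params

    def fz(spec):
        return fixed(spec.point)

    for arm in psa.ARMS:
        p.starting_states[arm] = {
            s: (spec if f"start.{arm}.{s}" in keep else fz(spec))
            for s, spec in p.starting_states[arm].items()}
    p.usual_care_matrix = TransitionMatrix(
        p.usual_care_matrix.labels,
        {cell: (spec if f"tp.{cell[0]}.{cell[1]}" in keep else fz(spec))
         for cell, spec in p.usual_care_matrix.cells.items()})
    sp.utilities = {s: (spec if f"util.{s}" in keep else fz(spec))
                    for s, spec in sp.utilities.items()}
    sp.exac_rates = {s: (spec if f"exac.{s}" in keep else fz(spec))
                     for s, spec in sp.exac_rates.items()}
    for name, key in [("exac_disutility", "util.disutility"),
                      ("monthly_cost_b", "cost.stage_b"),
                      ("monthly_cost_d", "cost.stage_d"),
                      ("ac_decrement", "cost.ac_decrement"),
                      ("admission_cost", "cost.admission"),
                      ("bed_day_cost", "cost.bed_day"),
                      ("intervention_monthly_cost", "cost.intervention_monthly")]:
        if key not in keep:
            setattr(sp, name, fz(getattr(sp, name)))
    if "eff.rr_year2" not in keep:
        p.effects.base_rr_year2 = fz(p.effects.base_rr_year2)
    if "eff.bed_day_reduction" not in keep:
        p.effects.bed_day_reduction = fz(p.effects.bed_day_reduction)
    return p


class TestRunPSA:
    def test_degenerate_psa_equals_deterministic(self, session_params):
        det = markov.deterministic_cua(session_params)
        out = psa.run_psa(session_params, n_iter=5, seed=0, variance_scale=0.0)
        assert np.allclose(out.delta_cost, det.delta_cost, atol=1e-6)
        assert np.allclose(out.delta_qaly, det.delta_effect, atol=1e-9)

    def test_all_fixed_specs_equal_deterministic(self, session_params):
        frozen = _freeze(session_params)
        det = markov.deterministic_cua(frozen)
        out = psa.run_psa(frozen, n_iter=4, seed=1)
        assert np.allclose(out.delta_cost, det.delta_cost)
        assert np.allclose(out.delta_qaly, det.delta_effect)

    def test_same_seed_bit_identical(self, session_params):
        a = psa.run_psa(session_params, n_iter=30, seed=12)
        b = psa.run_psa(session_params, n_iter=30, seed=12)
        for arm in psa.ARMS:
            assert np.array_equal(a.costs[arm], b.costs[arm])
            assert np.array_equal(a.qalys[arm], b.qalys[arm])
        pd.testing.assert_frame_equal(a.digest, b.digest)

    def test_qalys_within_horizon_bounds(self, psa_small, session_params):
        for arm in psa.ARMS:
            assert np.all(psa_small.qalys[arm] >= 0)
            assert np.all(psa_small.qalys[arm] <= session_params.horizon_years)

    def test_mean_consistency_with_deterministic(self, session_params, psa_small):
        det = markov.deterministic_cua(session_params)
        for arr, target in ((psa_small.delta_cost, det.delta_cost),
                            (psa_small.delta_qaly, det.delta_effect)):
            se = arr.std(ddof=1) / np.sqrt(arr.size)
            assert abs(arr.mean() - target) < 3 * se

    def test_row_overflow_triggers_resampling_then_error(self, session_params):
        p = copy.deepcopy(session_params)
        cells = dict(p.usual_care_matrix.cells)
        cells[("A", "B")] = DistributionSpec(
            point=0.5, family="beta", params={"alpha": 500, "beta": 1})
        p.usual_care_matrix = TransitionMatrix(p.usual_care_matrix.labels, cells)
        with pytest.raises(RuntimeError, match="resamples"):
            psa.run_psa(p, n_iter=2, seed=0, center="printed")

    def test_partial_overflow_counts_resamples(self, session_params):
        p = copy.deepcopy(session_params)
        cells = dict(p.usual_care_matrix.cells)
        for cell in (("B", "C"), ("B", "D")):
            cells[cell] = DistributionSpec(
                point=0.45, family="beta", params={"alpha": 50, "beta": 50})
        p.usual_care_matrix = TransitionMatrix(p.usual_care_matrix.labels, cells)
        out = psa.run_psa(p, n_iter=40, seed=0, center="printed")
        assert out.resample_count > 0


class TestCEAC:
    def test_certain_gain(self):
        out = _toy_psa([0.0] * 4, [0.0] * 4, [1000.0] * 4, [0.1] * 4)
        assert psa.ceac(out, [20000])[20000.0] == 1.0

    def test_two_point_enumeration(self):
        out = _toy_psa([0, 0], [0, 0], [100, 100], [0.01, -0.01])
        assert psa.ceac(out, [20000])[20000.0] == 0.5

    def test_symmetric_half(self):
        # NMB symmetric about zero at the threshold
        out = _toy_psa([0] * 4, [0] * 4, [100, 300, 100, 300],
                       [0.01, 0.01, 0.015, 0.015])
        assert psa.ceac(out, [20000])[20000.0] == 0.5

    def test_values_in_unit_interval(self, psa_small):
        curve = psa.ceac(psa_small, (0, 10000, 20000, 30000, 50000))
        assert all(0.0 <= v <= 1.0 for v in curve.values())

    def test_zero_threshold_complements_cost_probability(self, psa_small):
        curve = psa.ceac(psa_small, (0,))
        p_costly = float(np.mean(psa_small.delta_cost > 0))
        assert curve[0.0] + p_costly == pytest.approx(1.0)

    def test_empty_psa_rejected(self):
        out = _toy_psa([], [], [], [])
        with pytest.raises(ValueError):
            psa.ceac(out, [20000])


class TestEVPI:
    def test_two_point_brute_force(self):
        # arm NB samples {1, 3} vs {2, 2}: E[max] = 2.5, max E = 2
        out = _toy_psa([-1, -3], [0, 0], [-2, -2], [0, 0])
        assert psa.evpi(out, 0.0) == pytest.approx(0.5)

    def test_dominant_arm_gives_zero(self):
        out = _toy_psa([10, 20], [0, 0], [1, 2], [0, 0])
        assert psa.evpi(out, 0.0) == 0.0

    def test_curve_nonnegative(self, psa_small):
        curve = psa.evpi_curve(psa_small, np.linspace(0, 50000, 11))
        assert all(v >= 0.0 for v in curve.values())

    def test_variance_shrink_drives_evpi_down(self, session_params):
        vals = []
        for scale in (1.0, 0.25, 0.0):
            out = psa.run_psa(session_params, n_iter=300, seed=5,
                              variance_scale=scale)
            vals.append(psa.evpi(out, 20000.0))
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] == pytest.approx(0.0, abs=1e-6)


class TestEVPPI:
    def test_single_driver_toy_regression(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=3000)
        x2 = rng.normal(size=3000)
        out = _toy_psa(np.zeros(3000), np.zeros(3000), -1000 * x1,
                       np.zeros(3000),
                       digest=pd.DataFrame({"x1": x1, "x2": x2}))
        total = psa.evpi(out, 0.0)
        informative = psa.evppi(out, ["x1"], 0.0)
        null = psa.evppi(out, ["x2"], 0.0)
        assert informative == pytest.approx(total, rel=0.05)
        assert null < 0.05 * total

    def test_all_parameters_approaches_evpi(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=3000)
        x2 = rng.normal(size=3000)
        inb = 800 * x1 + 300 * x2
        out = _toy_psa(np.zeros(3000), np.zeros(3000), -inb, np.zeros(3000),
                       digest=pd.DataFrame({"x1": x1, "x2": x2}))
        assert psa.evppi(out, ["x1", "x2"], 0.0) == pytest.approx(
            psa.evpi(out, 0.0), rel=0.05)

    def test_bounds_on_real_psa(self, psa_small):
        total = psa.evpi(psa_small, 20000.0)
        for group in psa.DEFAULT_GROUPS:
            val = psa.evppi(psa_small, group, 20000.0)
            assert 0.0 <= val <= total + 1e-9

    def test_unrecorded_group_rejected(self, psa_small):
        with pytest.raises(KeyError):
            psa.evppi(psa_small, "astrology", 20000.0)

    def test_too_few_iterations_rejected(self):
        out = _toy_psa([0, 1], [0, 0], [1, 0], [0, 0],
                       digest=pd.DataFrame({"x": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="500"):
            psa.evppi(out, ["x"], 0.0)

    def test_nested_oracle_single_driver(self, session_params):
        # only the stage-D utility is uncertain: knowing the utilities group
        # is worth (almost) the whole EVPI, by both estimators
        frozen = _freeze(session_params, keep={"util.D"})
        out = psa.run_psa(frozen, n_iter=600, seed=7)
        total = psa.evpi(out, 20000.0)
        reg = psa.evppi(out, "utilities", 20000.0)
        nested = psa.evppi(out, "utilities", 20000.0, method="nested",
                           seed=3, n_outer=30, n_inner=20)
        if total > 1.0:
            assert reg == pytest.approx(total, rel=0.1)
            assert nested == pytest.approx(total, rel=0.35)

    def test_unknown_method_rejected(self, psa_small):
        with pytest.raises(ValueError):
            psa.evppi(psa_small, "utilities", 20000.0, method="magic")


class TestPopulationVoI:
    def test_identity_case(self):
        assert psa.population_voi(556.0, 1, 1, 0.0) == pytest.approx(556.0)

    def test_published_population_product(self):
        assert psa.population_voi(556.0, 626129, 1, 0.0) == pytest.approx(
            348_127_724.0)

    def test_discounting_bound(self):
        five = psa.population_voi(100.0, 1000, 5, 0.035)
        assert five < 5 * psa.population_voi(100.0, 1000, 1, 0.035)

    def test_positive_population_required(self):
        with pytest.raises(ValueError):
            psa.population_voi(100.0, 0)


def test_value_of_information_summary(psa_small):
    voi = psa.value_of_information(psa_small, (0, 20000, 30000),
                                   groups=("utilities", "costs"),
                                   population=626129)
    assert set(voi.evppi_per_group) == {"utilities", "costs"}
    assert voi.population_evpi >= 0
    d = voi.to_dict()
    assert "evpi_per_patient" in d
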