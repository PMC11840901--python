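"""Unit and property tests for the monthly energy-balance stepper."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normsim.core import (
    InvalidParameterError,
    ModelParams,
    Population,
    SimulationDivergenceError,
    UnsupportedAgeError,
    bmi_from_weight,
    bmr_children,
    group_median_bmi,
    individual_ideal_bmi,
    perceived_norm,
    simulate,
    update_pal,
    update_tdee,
    update_tdei,
    update_weight,
)

from conftest import hand_recurrence, single_girl_population


class TestEquationOperations:
    @pytest.mark.parametrize(
        "hb, norm, w_hb, expected",
        [(21, 25, 0.5, 23.0), (21, 25, 1.0, 21.0), (21, 25, 0.0, 25.0)],
    )
    def test_individual_ideal_bmi_blend(self, hb, norm, w_hb, expected):
        assert individual_ideal_bmi(hb, norm, w_hb) == pytest.approx(expected)

    def test_individual_ideal_bmi_rejects_bad_weight(self):
        with pytest.raises(InvalidParameterError):
            individual_ideal_bmi(21, 25, 1.2)

    @given(
        hb=st.floats(10, 30),
        norm=st.floats(10, 40),
        w=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=50)
    def test_ideal_bmi_lies_between_its_anchors(self, hb, norm, w):
        iib = float(individual_ideal_bmi(hb, norm, w))
        assert min(hb, norm) - 1e-9 <= iib <= max(hb, norm) + 1e-9

    @pytest.mark.parametrize(
        "pal0, intent, disc, delta, expected",
        [
            (1.46, 0.05, 2.0, 0.0, 1.56),
            (1.46, 0.05, 0.0, 0.175, 1.635),  # one extra hour of exercise
            (1.46, 0.05, 0.704, 0.0, 1.4952),
        ],
    )
    def test_update_pal_linear_form(self, pal0, intent, disc, delta, expected):
        pal, n_floor = update_pal(pal0, intent, disc, delta)
        assert pal == pytest.approx(expected)
        assert n_floor == 0

    def test_update_pal_floor_counts(self):
        pal, n_floor = update_pal(1.46, 0.05, -20.0, 0.0, floor=1.0)
        assert pal == 1.0
        assert n_floor == 1

    @pytest.mark.parametrize(
        "tdei0, intent, disc, delta, expected",
        [
            (2000.0, -50.0, 0.0, -200.0, 1800.0),  # one less snack
            (2000.0, -50.0, 2.0, 0.0, 1900.0),
            (1792.82, -50.0, 0.704, 0.0, 1757.62),
        ],
    )
    def test_update_tdei_linear_form(self, tdei0, intent, disc, delta, expected):
        tdei, n_floor = update_tdei(tdei0, intent, disc, delta)
        assert tdei == pytest.approx(expected, abs=0.02)
        assert n_floor == 0

    def test_update_tdei_floor_counts(self):
        tdei, n_floor = update_tdei(600.0, -50.0, 10.0, 0.0, floor=500.0)
        assert tdei == 500.0
        assert n_floor == 1

    @pytest.mark.parametrize(
        "bmr, pal, expected",
        [(1000.0, 1.46, 1460.0), (1227.96, 1.4952, 1836.05), (1000.0, 1.0, 1000.0)],
    )
    def test_update_tdee_product(self, bmr, pal, expected):
        assert update_tdee(bmr, pal) == pytest.approx(expected, abs=0.01)

    def test_update_weight_energy_balance(self):
        p = ModelParams()
        assert float(update_weight(50.0, 2000.0, 2000.0, p)) == 50.0
        assert float(update_weight(50.0, 2100.0, 2000.0, p)) == pytest.approx(
            50.39502, abs=1e-5
        )

    def test_conversion_constant_identity(self):
        """The monthly kcal-to-kg factor is exactly 73/18480 = 365/92400;
        a 100 kcal/day surplus adds that many kg (to the last ulp) and the
        inverse surplus adds exactly one kg."""
        import math

        p = ModelParams()
        assert p.days_per_month / p.kcal_per_kg == 73.0 / 18480.0 == 365.0 / 92400.0
        inc = float(update_weight(0.0, 2100.0, 2000.0, p))
        target = 73.0 * 100.0 / 18480.0
        assert abs(inc - target) <= math.ulp(target)
        assert float(update_weight(50.0, 2000.0 + 18480.0 / 73.0, 2000.0, p)) == 51.0

    @pytest.mark.parametrize(
        "w, h, expected",
        [(40.0, 1.40, 20.4082), (1.5**2 * 25.0, 1.5, 25.0), (39.690, 1.40, 20.250)],
    )
    def test_bmi_from_weight(self, w, h, expected):
        assert bmi_from_weight(w, h) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize(
        "gender, age, w, expected",
        [
            ("boy", 12, 40.0, 1365.64),
            ("girl", 9, 30.0, 1095.35),
            ("boy", 9, 30.0, 1185.48),
            ("girl", 12, 40.0, 13.384 * 40 + 692.6),
        ],
    )
    def test_bmr_children_brackets(self, gender, age, w, expected):
        assert bmr_children(gender, age, w) == pytest.approx(expected, abs=0.01)

    def test_bmr_children_rejects_unsupported_age(self):
        with pytest.raises(UnsupportedAgeError):
            bmr_children("boy", 2, 20.0)
        with pytest.raises(UnsupportedAgeError):
            bmr_children(np.array(["girl"]), np.array([19]), np.array([50.0]))

    @pytest.mark.parametrize(
        "bmis, expected", [([18, 19, 20], 19.0), ([18, 20], 19.0), ([23.4], 23.4)]
    )
    def test_group_median_bmi(self, bmis, expected):
        assert group_median_bmi(bmis) == expected

    def test_group_median_bmi_empty_errors(self):
        with pytest.raises(ValueError):
            group_median_bmi([])

    @pytest.mark.parametrize(
        "median, scib, expected", [(20.0, 18.0, 19.0), (18.4, 18.1, 18.25), (22.2, 22.2, 22.2)]
    )
    def test_perceived_norm_mean(self, median, scib, expected):
        assert perceived_norm(median, scib) == pytest.approx(expected)


class TestSimulator:
    def test_zero_months_returns_baseline_only(self, oracle_pop, params):
        traj = simulate(oracle_pop, params, 0)
        assert traj.median_bmi.tolist() == [pytest.approx(40.0 / 1.96)]

    def test_single_child_first_step_matches_hand_values(self, oracle_pop):
        """Frozen hand-evaluated first step of the reference recurrence."""
        params = ModelParams(w_hb=0.0)
        traj = simulate(oracle_pop, params, 1, record_history=True)
        s = traj.history[1].state
        assert s.iib[0] == pytest.approx(19.7041, abs=1e-4)
        assert s.discrepancy[0] == pytest.approx(0.7041, abs=1e-4)
        assert s.pal[0] == pytest.approx(1.4952, abs=1e-4)
        assert s.tdei[0] == pytest.approx(1757.61, abs=0.01)
        assert s.tdee[0] == pytest.approx(1836.05, abs=0.01)
        assert s.weight[0] == pytest.approx(39.690, abs=1e-3)
        assert s.bmi[0] == pytest.approx(20.250, abs=1e-3)

    @pytest.mark.parametrize("months", [1, 2, 36])
    def test_oracle_equivalence(self, oracle_pop, months):
        """The simulator reproduces the independent scalar recurrence to
        1e-9 relative error at every month."""
        params = ModelParams(w_hb=0.0)
        traj = simulate(oracle_pop, params, months)
        expected = hand_recurrence(months, w_hb=0.0)
        np.testing.assert_allclose(traj.median_bmi, expected, rtol=1e-9)

    def test_fixed_point_is_invariant(self, homogeneous_pop):
        """D=0 everywhere and intake balancing expenditure: nothing moves,
        for any norm weight."""
        for w_hb in (0.0, 0.5, 1.0):
            traj = simulate(homogeneous_pop, ModelParams(w_hb=w_hb), 12, record_history=True)
            np.testing.assert_allclose(traj.median_bmi, 20.0, rtol=1e-12)
            final = traj.history[-1].state
            np.testing.assert_allclose(final.weight, 39.2, rtol=1e-12)
            np.testing.assert_allclose(final.norm, 20.0, rtol=1e-12)

    def test_child_order_does_not_matter(self, pooled_pop, params):
        """Synchronous updates: permuting the children leaves every
        trajectory value unchanged."""
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(pooled_pop))
        t1 = simulate(pooled_pop, params, 12)
        t2 = simulate(pooled_pop.take(perm), params, 12)
        np.testing.assert_array_equal(t1.median_bmi, t2.median_bmi)

    def test_median_norm_identity(self, pooled_pop, params):
        """median(norm) = (median BMI + median SCIB)/2 at every month
        (exact for odd group sizes)."""
        n = len(pooled_pop)
        pop = pooled_pop if n % 2 == 1 else pooled_pop.take(np.arange(n - 1))
        traj = simulate(pop, params, 6, record_history=True)
        med_scib = np.median(pop.scib)
        for g in traj.history:
            assert np.median(g.state.norm) == (g.median_bmi + med_scib) / 2.0

    def test_divergence_error_names_child_and_month(self, oracle_pop):
        params = ModelParams(
            intent_pab=5.0, tdei_floor=0.0, pal_floor=0.0, w_hb=1.0
        )
        pop = oracle_pop
        pop.healthy_bmi = np.array([10.0])
        with pytest.raises(SimulationDivergenceError, match="g1.*month"):
            simulate(pop, params, 120)

    def test_two_identical_children_stay_identical(self):
        one = single_girl_population()
        two = Population(
            ids=np.array(["a", "b"]),
            community=np.array(["test"] * 2),
            gender=np.array(["girl"] * 2),
            age0=np.full(2, 10),
            height0=np.full(2, 1.40),
            weight0=np.full(2, 40.0),
            pal0=np.full(2, 1.46),
            tdei0=np.full(2, (13.384 * 40 + 692.6) * 1.46),
            scib=np.full(2, 19.0),
            healthy_bmi=np.full(2, 17.0),
        )
        params = ModelParams(w_hb=0.0)
        t2 = simulate(two, params, 12, record_history=True)
        t1 = simulate(one, params, 12)
        np.testing.assert_allclose(t1.median_bmi, t2.median_bmi, rtol=1e-12)
        final = t2.history[-1].state
        assert final.weight[0] == final.weight[1]


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"w_hb": 1.5},
            {"w_hb": -0.1},
            {"intent_pab": -0.01},
            {"intent_eb": 1.0},
            {"kcal_per_kg": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ModelParams(**kwargs)
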