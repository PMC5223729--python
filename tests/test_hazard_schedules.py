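"""Per-cycle probability construction, life tables and schedule shapes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnpce.hazard_schedules import (
    SUBGROUPS,
    LifeTable,
    build_schedule,
    cycle_prob_from_monthly_hazard,
    hospitalisation_schedule,
    life_table_cycle_prob,
    mortality_schedule,
    rr_from_interval_survival,
    weibull_cycle_prob,
)
from bnpce.scenarios import build_scenario

PRIMARY = build_scenario("primary")


class TestCycleProb:
    @pytest.mark.parametrize(
        "hazard,expected",
        [
            (0.0, 0.0),
            (0.009, 1.0 - math.exp(-0.027)),
            (0.066, 1.0 - math.exp(-0.198)),
        ],
    )
    def test_closed_form(self, hazard, expected):
        assert cycle_prob_from_monthly_hazard(hazard) == pytest.approx(expected, rel=1e-12)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            cycle_prob_from_monthly_hazard(-0.1)


class TestWeibullCycleProb:
    def test_shape_one_is_exponential(self):
        expo = cycle_prob_from_monthly_hazard(0.009)
        for k in (0, 5, 31):
            assert weibull_cycle_prob(0.009, 1.0, k) == pytest.approx(expo, rel=1e-12)

    def test_first_cycle_and_decreasing_hazard(self):
        p0 = weibull_cycle_prob(0.017, 0.842, 0)
        assert p0 == pytest.approx(1.0 - math.exp(-0.017 * 3**0.842), rel=1e-12)
        probs = [weibull_cycle_prob(0.017, 0.842, k) for k in range(20)]
        assert all(a > b for a, b in zip(probs, probs[1:]))  # shape < 1

    def test_chained_conditionals_telescope_to_survival(self):
        scale, shape, n = 0.017, 0.842, 32
        surv = np.prod([1.0 - weibull_cycle_prob(scale, shape, k) for k in range(n)])
        assert surv == pytest.approx(math.exp(-scale * (3 * n) ** shape), rel=1e-10)


class TestRRConversion:
    def test_equal_groups_give_unity(self):
        assert rr_from_interval_survival(10, 100, 10, 100, 28) == pytest.approx(1.0)

    def test_hf_vs_population_seven_year(self):
        # 199/293 HF deaths vs 176/586 control deaths over 28 cycles
        rr = rr_from_interval_survival(199, 293, 176, 586, 28)
        assert rr == pytest.approx(3.14, abs=0.005)

    def test_hfpef_vs_hfref_one_year(self):
        rr = rr_from_interval_survival(766, 3631, 584, 2205, 4)
        assert rr == pytest.approx(0.78, abs=0.005)

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            rr_from_interval_survival(0, 100, 10, 100, 4)
        with pytest.raises(ValueError):
            rr_from_interval_survival(100, 100, 10, 100, 4)


class TestLifeTable:
    def test_cycle_prob_closed_form(self, life_table):
        lt = LifeTable(np.arange(60, 111), np.full(51, 0.1), np.full(51, 0.1))
        expected = (1.0 - 0.9**0.25) * 3.14
        assert life_table_cycle_prob(lt, 70, rr=3.14) == pytest.approx(expected, rel=1e-12)

    def test_pure_male_weighting(self):
        lt = LifeTable(np.arange(60, 111), np.full(51, 0.2), np.full(51, 0.05))
        got = life_table_cycle_prob(lt, 70, male_fraction=1.0, rr=1.0)
        assert got == pytest.approx(1.0 - 0.8**0.25, rel=1e-12)

    def test_large_rr_capped_at_one(self, life_table):
        assert life_table_cycle_prob(life_table, 100, rr=1e6) == 1.0

    def test_beyond_table_uses_terminal_q(self, life_table):
        assert life_table.annual_q(150, "male") == 1.0

    def test_csv_roundtrip(self, life_table, tmp_path):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        back = LifeTable.from_csv(path)
        np.testing.assert_allclose(back.q_male, life_table.q_male)
        np.testing.assert_allclose(back.q_female, life_table.q_female)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age,q_m\n60,0.1\n")
        with pytest.raises(ValueError):
            LifeTable.from_csv(path)


class TestMortalitySchedule:
    def test_clinical_hfref_u75_constant_early_phase(self, point_params, life_table):
        d = mortality_schedule(SUBGROUPS["hfref_u75"], "clinical", PRIMARY, point_params, life_table)
        expected = 1.0 - math.exp(-0.027)
        np.testing.assert_allclose(d[:32], expected, rtol=1e-12)

    def test_early_survival_matches_exponential_closed_form(self, point_params, life_table):
        d = mortality_schedule(SUBGROUPS["hfref_u75"], "clinical", PRIMARY, point_params, life_table)
        surv32 = np.prod(1.0 - d[:32])
        assert surv32 == pytest.approx(math.exp(-0.009 * 96), rel=1e-10)

    def test_hfpef_multiplies_by_subgroup_rr(self, point_params, life_table):
        d_ref = mortality_schedule(SUBGROUPS["hfref_u75"], "clinical", PRIMARY, point_params, life_table)
        d_pef = mortality_schedule(SUBGROUPS["hfpef_u75"], "clinical", PRIMARY, point_params, life_table)
        rr = rr_from_interval_survival(766, 3631, 584, 2205, 4)
        assert d_pef[0] == pytest.approx(d_ref[0] * rr, rel=1e-9)
        assert np.all(d_pef <= d_ref + 1e-15)  # pointwise below HFrEF

    def test_bnp_effect_window(self, point_params, life_table):
        sub = SUBGROUPS["hfref_u75"]
        d_c = mortality_schedule(sub, "clinical", PRIMARY, point_params, life_table)
        d_b = mortality_schedule(sub, "bnp", PRIMARY, point_params, life_table)
        np.testing.assert_allclose(d_b[:16], d_c[:16] * 0.68, rtol=1e-12)
        np.testing.assert_allclose(d_b[16:], d_c[16:], rtol=1e-12)
        assert d_b[0] == pytest.approx((1.0 - math.exp(-0.027)) * 0.68, rel=1e-9)

    def test_over75_age_hr_on_hazard_scale(self, point_params, life_table):
        d = mortality_schedule(SUBGROUPS["hfref_o75"], "clinical", PRIMARY, point_params, life_table)
        expected = 1.0 - math.exp(-0.009 * 2.801 * 3)
        assert d[0] == pytest.approx(expected, rel=1e-12)

    def test_life_table_phase_non_decreasing(self, point_params, life_table):
        d = mortality_schedule(SUBGROUPS["hfref_u75"], "clinical", PRIMARY, point_params, life_table)
        assert np.all(np.diff(d[32:]) >= -1e-15)

    def test_life_table_required_beyond_eight_years(self, point_params):
        with pytest.raises(ValueError):
            mortality_schedule(SUBGROUPS["hfref_u75"], "clinical", PRIMARY, point_params, None)

    def test_weibull_scenario_matches_weibull_cells(self, point_params, life_table):
        sa1 = build_scenario("SA1")
        d = mortality_schedule(SUBGROUPS["hfref_u75"], "clinical", sa1, point_params, life_table)
        for k in (0, 7, 31):
            assert d[k] == pytest.approx(weibull_cycle_prob(0.017, 0.842, k), rel=1e-12)
        # life-table phase unchanged by the survival form
        d_exp = mortality_schedule(SUBGROUPS["hfref_u75"], "clinical", PRIMARY, point_params, life_table)
        np.testing.assert_allclose(d[32:], d_exp[32:], rtol=1e-12)


class TestHospitalisationSchedule:
    def test_constant_under75(self, point_params):
        h = hospitalisation_schedule(SUBGROUPS["hfref_u75"], "clinical", PRIMARY, point_params)
        np.testing.assert_allclose(h, 1.0 - math.exp(-0.198), rtol=1e-12)

    def test_over75_age_hr_on_hazard_scale(self, point_params):
        h = hospitalisation_schedule(SUBGROUPS["hfref_o75"], "clinical", PRIMARY, point_params)
        assert h[0] == pytest.approx(1.0 - math.exp(-0.066 * 1.248 * 3), rel=1e-12)

    def test_bnp_window_effect(self, point_params):
        h = hospitalisation_schedule(SUBGROUPS["hfref_u75"], "bnp", PRIMARY, point_params)
        base = 1.0 - math.exp(-0.198)
        np.testing.assert_allclose(h[:16], base * 0.94, rtol=1e-12)
        np.testing.assert_allclose(h[16:], base, rtol=1e-12)

    def test_same_for_both_lvef_classes(self, point_params):
        h_ref = hospitalisation_schedule(SUBGROUPS["hfref_u75"], "clinical", PRIMARY, point_params)
        h_pef = hospitalisation_schedule(SUBGROUPS["hfpef_u75"], "clinical", PRIMARY, point_params)
        np.testing.assert_array_equal(h_ref, h_pef)


@given(seed=st.integers(0, 50))
@settings(derandomize=True, max_examples=15, deadline=None)
def test_bnp_pointwise_below_clinical_within_window(seed):
    """BNP schedules never exceed clinical ones; equal outside the window."""
    from bnpce.parameters import load_default_registry, sample_parameter_set
    from bnpce.synthetic_data import generate_life_table

    reg = load_default_registry()
    lt = generate_life_table()
    params = sample_parameter_set(reg, seed=seed, iteration=0)
    for key in SUBGROUPS:
        sched_c = build_schedule(SUBGROUPS[key], "clinical", PRIMARY, params, lt)
        sched_b = build_schedule(SUBGROUPS[key], "bnp", PRIMARY, params, lt)
        hr = params[SUBGROUPS[key].bnp_mortality_hr_name]
        if hr <= 1.0:
            assert np.all(sched_b.d <= sched_c.d + 1e-15)
        np.testing.assert_array_equal(sched_b.d[16:], sched_c.d[16:])
        np.testing.assert_array_equal(sched_b.h[16:], sched_c.h[16:])
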