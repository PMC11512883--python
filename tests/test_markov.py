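"""Markov engine: occupancy dynamics, accrual conventions, ICUR/INMB logic,
and equivalence with an independent path-enumeration oracle."""

import numpy as np
import pytest

from radecon.costing import derive_cycle_costs
from radecon.markov import (
    calibrate_discounting,
    discount_factors,
    discounted_totals,
    icur,
    inmb_trajectory,
    run_cea,
    run_cohort,
)
from radecon.parameters import LifeTable, Payer, Strategy


def flat_life_table(q_const, max_age=120):
    q = np.full(max_age + 1, q_const)
    q[-1] = 1.0
    return LifeTable(ages=np.arange(max_age + 1), q=q)


def enumerate_expected_qalys(q, u, d):
    """Independent oracle: enumerate every death-time path of one woman.

    A path dying in cycle k has probability prod_{j<k}(1-q_j) * q_k and
    accrues utility in cycles 0..k (alive at cycle start); a full survivor
    accrues every cycle.  The cohort expectation is the probability-weighted
    sum over paths.
    """
    n = len(q)
    total = 0.0
    for k in range(n):  # death during cycle k
        p_path = np.prod([1 - q[j] for j in range(k)]) * q[k]
        total += p_path * sum(d[t] * u[t] for t in range(k + 1))
    p_survive = np.prod([1 - q[j] for j in range(n)])
    total += p_survive * sum(d[t] * u[t] for t in range(n))
    return total


class TestDiscountFactors:
    def test_exponential_and_simple_forms(self):
        np.testing.assert_allclose(
            discount_factors(3, 0.03, "exponential"), [1, 1 / 1.03, 1 / 1.03**2]
        )
        np.testing.assert_allclose(
            discount_factors(3, 0.03, "simple"), [1, 1 / 1.03, 1 / 1.06]
        )

    def test_cycle0_discounted_shifts_by_one(self):
        np.testing.assert_allclose(
            discount_factors(2, 0.03, "exponential", cycle0_discounted=True),
            [1 / 1.03, 1 / 1.03**2],
        )

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            discount_factors(2, 0.03, "hyperbolic-ish")


class TestCohortDynamics:
    def test_deterministic_survival_accrues_full_lifeyears(self, cfg):
        """q=0, u=1, r=0 over 10 cycles -> exactly 10 QALYs, everyone in the
        following-years state from cycle 1 on."""
        cfg.econ.discount_rate = 0.0
        cfg.econ.discounting = "exponential"
        cfg.utilities.soc = 1.0
        tr = run_cohort(Strategy.SOC, cfg, None, flat_life_table(0.0), horizon=10)
        assert tr.qaly_disc.sum() == pytest.approx(10.0)
        assert np.all(tr.occupancy[1:, 0] == 0.0)
        assert np.all(tr.occupancy[1:, 1] == 1.0)

    def test_two_cycle_hand_computation(self, cfg):
        """q=0.1, u=0.5, r=3% exponential: 0.5 + 0.5*0.9/1.03 = 0.93689..."""
        cfg.econ.discount_rate = 0.03
        cfg.econ.discounting = "exponential"
        cfg.utilities.soc = 0.5
        tr = run_cohort(Strategy.SOC, cfg, None, flat_life_table(0.1), horizon=2)
        assert tr.qaly_disc.sum() == pytest.approx(0.5 + 0.5 * 0.9 / 1.03, rel=1e-12)

    def test_occupancy_conserved_and_death_monotone(self, cfg, lt):
        for s in Strategy:
            tr = run_cohort(s, cfg, None, lt)
            np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(tr.occupancy[:, 2]) >= -1e-15)
            assert np.all(tr.occupancy[1:, 0] == 0.0)

    def test_qaly_bounded_by_discounted_lifeyears(self, cfg, lt):
        tr = run_cohort(Strategy.SOC, cfg, None, lt)
        d = discount_factors(tr.n_cycles, cfg.econ.discount_rate, cfg.econ.discounting)
        disc_ly = float((tr.alive * d).sum())
        undisc_ly = float(tr.alive.sum())
        assert tr.qaly_disc.sum() <= disc_ly <= undisc_ly

    def test_life_table_must_cover_start_age(self, cfg):
        late = LifeTable(ages=np.arange(60, 111), q=np.r_[np.full(50, 0.01), 1.0])
        with pytest.raises(ValueError, match="start age"):
            run_cohort(Strategy.SOC, cfg, None, late)

    @pytest.mark.parametrize("horizon", [1, 2, 3, 5])
    @pytest.mark.parametrize("q_const", [0.0, 0.1, 0.35])
    def test_matches_path_enumeration_oracle(self, cfg, horizon, q_const):
        """For short horizons the engine's recursion must equal a brute-force
        enumeration over all individual death-time paths."""
        cfg.econ.discounting = "exponential"
        tr = run_cohort(Strategy.REPAIR, cfg, None, flat_life_table(q_const), horizon=horizon)
        q = [q_const] * horizon
        u = [cfg.utilities.repair_first_year] + [cfg.utilities.repair_following_years] * (horizon - 1)
        d = discount_factors(horizon, cfg.econ.discount_rate, "exponential")
        expected = enumerate_expected_qalys(q, u, d)
        assert tr.qaly_disc.sum() == pytest.approx(expected, rel=1e-12)

    def test_productivity_zeroed_from_retirement_age(self, cfg, lt, costs):
        tr = run_cohort(Strategy.SOC, cfg, costs, lt)
        retired = tr.ages >= cfg.econ.retirement_age_years
        assert np.all(tr.cost_undisc[Payer.PRODUCTIVITY][retired] == 0.0)
        assert np.all(tr.cost_undisc[Payer.PRODUCTIVITY][~retired] > 0.0)

    def test_half_cycle_correction_reduces_accruals(self, cfg, lt):
        full = run_cohort(Strategy.SOC, cfg, None, lt).qaly_disc.sum()
        cfg.econ.half_cycle_correction = True
        halved = run_cohort(Strategy.SOC, cfg, None, lt).qaly_disc.sum()
        assert halved < full


class TestPerspectivesAndIcur:
    def test_nhs_delta_cost_equals_first_cycle_bundle(self, cfg, lt, costs):
        """All NHS flows besides the repair first-cycle bundle are zero."""
        res = run_cea(cfg, lt)
        assert res.costs["nhs"][Strategy.SOC.value] == 0.0
        assert res.outcomes["nhs"].delta_cost_eur == pytest.approx(
            costs.one_off[Strategy.REPAIR][Payer.NHS], rel=1e-12
        )

    def test_zero_cost_config_still_accrues_qalys(self, cfg, lt):
        cfg.cost_items = [it.model_copy(update={"amount_eur": 0.0}) for it in cfg.cost_items]
        for t in cfg.nhs_tariffs.values():
            t.amount_eur = 0.0
        for c in cfg.complications.values():
            c.unit_cost_eur = 0.0
        tr = run_cohort(Strategy.SOC, cfg, derive_cycle_costs(cfg), lt)
        cost, qalys = discounted_totals(tr, "societal")
        assert cost == 0.0 and qalys > 0.0

    def test_societal_sums_all_payers(self, cfg, lt):
        tr = run_cohort(Strategy.REPAIR, cfg, None, lt)
        cost_nhs, _ = discounted_totals(tr, "nhs")
        cost_soc, _ = discounted_totals(tr, "societal")
        by_payer = sum(tr.cost_disc[p].sum() for p in Payer)
        assert cost_soc == pytest.approx(by_payer, rel=1e-12)
        assert cost_nhs <= cost_soc

    def test_icur_ratio_and_flags(self):
        out = icur((0.0, 19.55), (5104.0, 25.74))
        assert out.flag == "icur"
        assert out.icur_eur_per_qaly == pytest.approx(5104.0 / 6.19, rel=1e-3)
        assert icur((100.0, 10.0), (50.0, 12.0)).flag == "dominant"
        assert icur((100.0, 10.0), (150.0, 8.0)).flag == "dominated"

    def test_zero_delta_qalys_is_undefined_not_division(self):
        out = icur((0.0, 10.0), (1.0, 10.0))
        assert out.flag == "undefined"
        assert out.icur_eur_per_qaly is None

    def test_internal_consistency_icur_equals_ratio(self, cfg, lt):
        res = run_cea(cfg, lt)
        o = res.outcomes["nhs"]
        assert o.icur_eur_per_qaly == o.delta_cost_eur / o.delta_qalys

    def test_higher_utilities_imply_positive_delta_qalys(self, cfg, lt):
        """Mortality is strategy-independent, so a uniformly higher utility
        must yield dE > 0 for any life table."""
        res = run_cea(cfg, lt)
        assert res.outcomes["societal"].delta_qalys > 0
        other = run_cea(cfg, flat_life_table(0.05))
        assert other.outcomes["societal"].delta_qalys > 0


class TestInmb:
    def test_year0_negative_then_positive_at_reference_wtp(self, cfg, lt):
        """At 25,000 EUR/QALY the NHS INMB is negative in the intervention
        year and cumulatively positive from the year after."""
        res = run_cea(cfg, lt)
        series = res.inmb["nhs"]
        assert series[0] < 0
        assert np.all(series[1:] > 0)

    def test_zero_wtp_reduces_to_minus_cumulative_cost(self, cfg, lt, costs):
        tr_soc = run_cohort(Strategy.SOC, cfg, costs, lt)
        tr_rep = run_cohort(Strategy.REPAIR, cfg, costs, lt)
        series = inmb_trajectory(tr_soc, tr_rep, 0.0, "societal")
        d_cost = sum(tr_rep.cost_disc[p] - tr_soc.cost_disc[p] for p in Payer)
        np.testing.assert_allclose(series, -np.cumsum(d_cost))

    def test_identical_strategies_flat_zero(self, cfg, lt, costs):
        tr = run_cohort(Strategy.SOC, cfg, costs, lt)
        np.testing.assert_array_equal(inmb_trajectory(tr, tr, 25000.0, "nhs"), 0.0)

    def test_mismatched_horizons_rejected(self, cfg, lt, costs):
        tr_a = run_cohort(Strategy.SOC, cfg, costs, lt, horizon=5)
        tr_b = run_cohort(Strategy.SOC, cfg, costs, lt, horizon=6)
        with pytest.raises(ValueError, match="horizon"):
            inmb_trajectory(tr_a, tr_b, 25000.0, "nhs")


class TestConventionSearch:
    def test_search_covers_all_eight_conventions_sorted(self, cfg, lt):
        results = calibrate_discounting(cfg, lt)
        assert len(results) == 8
        errs = [r["max_rel_err"] for r in results]
        assert errs == sorted(errs)
        combos = {(r["discounting"], r["discount_cycle0"], r["half_cycle_correction"])
                  for r in results}
        assert len(combos) == 8

    def test_search_does_not_mutate_config(self, cfg, lt):
        before = cfg.model_copy(deep=True)
        calibrate_discounting(cfg, lt)
        assert cfg == before
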