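"""Cost derivation: complication expectation, NHS bundle, annualization,
human-capital productivity valuation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radecon.costing import (
    STATES,
    WageTable,
    annualize_cost_items,
    derive_cycle_costs,
    expected_complication_cost,
    nhs_repair_first_cycle_cost,
    productivity_value,
    uplift_cost,
)
from radecon.parameters import (
    Complication,
    CostItem,
    Payer,
    Recurrence,
    StateScope,
    Strategy,
    Tariff,
)


def _comp(rate, cost):
    return Complication(rate=rate, unit_cost_eur=cost)


class TestExpectedComplicationCost:
    def test_registry_profile_gives_174(self, base_cfg):
        """Weighting the literature unit costs by the registry frequencies
        yields the ~174 EUR per-patient expectation (173.9 before rounding)."""
        value = expected_complication_cost(base_cfg.complications)
        assert value == pytest.approx(173.873, abs=1e-9)
        assert round(value) == 174

    def test_sheath_disruption_priced_as_recurrence(self, base_cfg):
        comps = base_cfg.complications
        assert (
            comps["posterior_sheath_disruption"].unit_cost_eur
            == comps["recurrence"].unit_cost_eur
        )

    def test_zero_rates_give_zero(self):
        profile = {"a": _comp(0.0, 4058.0), "b": _comp(0.0, 109.0)}
        assert expected_complication_cost(profile) == 0.0

    def test_degenerate_certain_complication(self):
        assert expected_complication_cost({"x": _comp(1.0, 100.0)}) == 100.0


class TestNhsRepairFirstCycleCost:
    def test_baseline_bundle_is_5104(self, base_cfg):
        value = nhs_repair_first_cycle_cost(base_cfg.nhs_tariffs, base_cfg.complications)
        assert value == pytest.approx(22 + 16.20 + 4892 + 173.873)
        assert round(value) == 5104

    def test_uncomplicated_drg_variant(self, base_cfg):
        """Swapping in the without-complications DRG tariff (1,371 EUR)."""
        tariffs = dict(base_cfg.nhs_tariffs)
        tariffs["intervention_drg"] = Tariff(amount_eur=1371.0)
        value = nhs_repair_first_cycle_cost(tariffs, base_cfg.complications)
        assert value == pytest.approx(22 + 16.20 + 1371 + 173.873)  # ~1,583

    def test_all_zero_tariffs_and_rates(self):
        tariffs = {k: Tariff(amount_eur=0.0) for k in
                   ("pre_intervention_visit", "post_intervention_visit", "intervention_drg")}
        assert nhs_repair_first_cycle_cost(tariffs, {"a": _comp(0.0, 100.0)}) == 0.0

    def test_missing_tariff_key_is_config_error(self, base_cfg):
        with pytest.raises(KeyError, match="intervention_drg"):
            nhs_repair_first_cycle_cost(
                {"pre_intervention_visit": Tariff(amount_eur=22.0),
                 "post_intervention_visit": Tariff(amount_eur=16.2)},
                base_cfg.complications,
            )


def _item(amount, *, strategy=Strategy.SOC, payer=Payer.OUT_OF_POCKET,
          recurrence=Recurrence.MONTHLY_RECURRING, scope=StateScope.BOTH, uplift=1.0):
    return CostItem(label="x", strategy=strategy, payer=payer, recurrence=recurrence,
                    state_scope=scope, amount_eur=amount, uplift_factor=uplift)


class TestAnnualize:
    def test_monthly_item_contributes_twelvefold(self):
        recurring, one_off = annualize_cost_items([_item(10.0)], Strategy.SOC, "first_year")
        assert recurring[Payer.OUT_OF_POCKET] == 120.0
        assert sum(one_off.values()) == 0.0

    def test_repair_one_offs_sum_to_published_first_cycle_total(self, base_cfg):
        """<=1-year column one-offs: 148.53 + 11.14 + 198.10 + 8.09 = 365.86."""
        _, one_off = annualize_cost_items(base_cfg.cost_items, Strategy.REPAIR, "first_year")
        assert one_off[Payer.OUT_OF_POCKET] == pytest.approx(365.86)

    def test_empty_items_give_zero_entry(self):
        recurring, one_off = annualize_cost_items([], Strategy.SOC, "first_year")
        assert all(v == 0.0 for v in recurring.values())
        assert all(v == 0.0 for v in one_off.values())

    def test_one_off_not_charged_in_following_years(self):
        it = _item(50.0, recurrence=Recurrence.ONE_OFF_FIRST_CYCLE, scope=StateScope.FIRST_YEAR)
        _, one_off = annualize_cost_items([it], Strategy.SOC, "following_years")
        assert sum(one_off.values()) == 0.0

    def test_soc_nhs_component_is_zero(self, costs):
        for state in STATES:
            assert costs.cycle_cost(Strategy.SOC, state, Payer.NHS) == 0.0
        assert costs.one_off[Strategy.SOC][Payer.NHS] == 0.0

    def test_payer_additivity(self, costs):
        for (strategy, state), by_payer in costs.recurring.items():
            assert costs.societal_cycle_cost(strategy, state) == pytest.approx(
                by_payer[Payer.NHS] + by_payer[Payer.OUT_OF_POCKET] + by_payer[Payer.PRODUCTIVITY]
            )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        amount=st.floats(min_value=0.0, max_value=1e4),
        bump=st.floats(min_value=0.0, max_value=1e4),
    )
    def test_increasing_an_amount_never_decreases_components(self, amount, bump):
        lo, _ = annualize_cost_items([_item(amount)], Strategy.SOC, "first_year")
        hi, _ = annualize_cost_items([_item(amount + bump)], Strategy.SOC, "first_year")
        assert all(hi[p] >= lo[p] for p in Payer)


class TestDerivedCycleCosts:
    def test_published_annual_sums(self, costs):
        # no-intervention: 220.77 EUR/month across payers -> 2,649.24 EUR/year
        assert costs.societal_cycle_cost(Strategy.SOC, "following_years") == pytest.approx(2649.24)
        # repair, first year: 379.83 EUR/month -> 4,557.96 EUR/year
        assert costs.societal_cycle_cost(Strategy.REPAIR, "first_year") == pytest.approx(4557.96)
        # repair, following years: 132.02 EUR/month -> 1,584.24 EUR/year
        assert costs.societal_cycle_cost(Strategy.REPAIR, "following_years") == pytest.approx(1584.24)

    def test_export_records_cover_all_cells(self, costs):
        recs = costs.to_records()
        assert len(recs) == 2 * 2 * 3 + 2 * 3  # (strategy,state,payer) + one-offs


class TestUplift:
    def test_identity_and_scaling(self):
        assert uplift_cost(100.0, 1.0) == 100.0
        assert uplift_cost(100.0, 1.15) == pytest.approx(115.0)

    def test_non_positive_factor_rejected(self):
        with pytest.raises(ValueError):
            uplift_cost(100.0, 0.0)

    def test_bundled_unit_costs_need_no_uplift(self, base_cfg):
        """The configured unit costs reproduce the printed 174 EUR expectation
        with uplift 1, so they are already at the analysis price level."""
        assert all(c.uplift_factor == 1.0 for c in base_cfg.complications.values())
        assert round(expected_complication_cost(base_cfg.complications)) == 174


class TestProductivityValue:
    wages = WageTable(annual_wage_eur={"employee": 34400.0, "teacher": 25800.0})

    def test_zero_hours(self):
        assert productivity_value(0.0, "employee", self.wages) == 0.0

    def test_whole_day_counts_eight_hours(self):
        w = self.wages.hourly_wage("employee")
        assert productivity_value(8.0, "employee", self.wages) == pytest.approx(8 * w)

    def test_hours_times_rate(self):
        # 34,400 EUR / 1,720 h = 20 EUR/h; 3.5 h -> 70 EUR
        assert productivity_value(3.5, "employee", self.wages) == pytest.approx(70.0)

    def test_unknown_occupation_lists_known(self):
        with pytest.raises(KeyError, match="employee"):
            productivity_value(1.0, "astronaut", self.wages)
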