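import numpy as np
import pytest

from epicua import default_config, generate_inputs
from epicua.cohort_engine import CohortTrace, run_arm
from epicua.model_types import ModelSettings
from epicua.outcomes_costing import (
    COST_CATEGORIES,
    accrue_costs,
    accrue_qalys,
    child_fraction_curve,
    count_events,
    cycle_drug_cost,
    discount_factor,
    mean_weight_curve,
)


def _constant_trace(dist, n_cycles, arm="CBD", on=1.0, age0=30.0):
    occ = np.tile(np.asarray(dist, dtype=float), (n_cycles + 1, 1))
    return CohortTrace(
        arm=arm,
        occupancy=occ,
        on_cbd=np.full(n_cycles + 1, on),
        drug_frac=np.full(n_cycles + 1, on),
        age_years=age0 + 0.25 * np.arange(n_cycles + 1),
    )


def _adult_only_config(condition="LGS", **settings_kw):
    """All cohort mass in the adult band so dosing weight is constant."""
    cfg = default_config(condition)
    data = cfg.model_dump(mode="json")
    for i in range(4):
        data["age_bands"][i]["proportion"]["mean"] = 1.0 if i == 3 else 0.0
    data["baseline"]["mean_age_years"]["mean"] = 30.0
    cfg = type(cfg).model_validate(data)
    if settings_kw:
        cfg = cfg.model_copy(update={"settings": ModelSettings(**settings_kw)})
    return cfg


class TestDiscounting:
    @pytest.mark.parametrize("rate", [0.0, 0.015, 0.04])
    def test_unity_at_cycle_zero(self, rate):
        assert discount_factor(0, rate) == 1.0

    def test_zero_rate_always_one(self):
        np.testing.assert_array_equal(discount_factor(np.arange(100), 0.0), 1.0)

    def test_one_year_at_four_percent(self):
        assert discount_factor(4, 0.04) == pytest.approx(1 / 1.04, rel=1e-12)

    def test_monotone_nonincreasing(self):
        df = discount_factor(np.arange(361), 0.04)
        assert (np.diff(df) < 0).all()


class TestDrugCost:
    def test_zero_arguments(self):
        assert cycle_drug_cost(0.0, 12, 1.0, 91.3125) == 0.0
        assert cycle_drug_cost(28.7, 0.0, 1.0, 91.3125) == 0.0

    def test_published_weight_hand_multiplication(self):
        # 28.7 kg x 12 mg/kg/day x 91.3125 days at unit price
        assert cycle_drug_cost(28.7, 12, 1.0, 365.25 / 4) == pytest.approx(
            31_448.025, abs=1e-9
        )

    def test_linearity_in_dose(self):
        base = cycle_drug_cost(28.7, 12, 0.11, 91.3125)
        assert cycle_drug_cost(28.7, 24, 0.11, 91.3125) == pytest.approx(2 * base)


class TestWeightAndAgeCurves:
    def test_children_grow_into_adult_weight(self, lgs_config):
        curve = mean_weight_curve(lgs_config.age_bands, 360)
        adult = lgs_config.age_bands[3].mean_weight_kg.mean
        assert curve[0] < adult                 # mixed pediatric cohort at entry
        assert curve[-1] == pytest.approx(adult)  # everyone adult by the horizon
        assert (np.diff(curve) >= 0).all()

    def test_child_fraction_decays_to_zero(self, lgs_config):
        frac = child_fraction_curve(lgs_config.age_bands, 360)
        assert 0 < frac[0] <= 1
        assert frac[-1] == 0.0


class TestQalyAccrual:
    def test_full_health_annuity_identity(self):
        """A cohort pinned in a utility-1 state, undiscounted, accrues one
        QALY per four cycles."""
        cfg = _adult_only_config(qaly_discount_annual=0.0, horizon_years=1)
        cfg.utilities.state_utilities["SEIZURE_FREE"].mean = 1.0
        trace = _constant_trace([1, 0, 0, 0, 0, 0], 4)
        assert accrue_qalys(trace, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_dead_cohort_accrues_nothing(self, lgs_config):
        trace = _constant_trace([0, 0, 0, 0, 0, 1], 40)
        assert accrue_qalys(trace, lgs_config) == 0.0

    def test_geometric_annuity_closed_form(self, lgs_config):
        """Constant occupancy at utility u, rate r: total equals
        u/4 * sum_k (1+r)^(-k/4) to 1e-10."""
        n = 360
        r = lgs_config.settings.qaly_discount_annual
        u = lgs_config.utilities.state_utilities["SEIZURE_FREE"].mean
        trace = _constant_trace([1, 0, 0, 0, 0, 0], n)
        expected = u * 0.25 * sum((1 + r) ** (-k / 4) for k in range(1, n + 1))
        assert accrue_qalys(trace, lgs_config) == pytest.approx(expected, abs=1e-10)

    def test_negative_utility_accrues_negative_qalys(self, lgs_config):
        """The worst LGS state is valued below death (-0.037); a cohort pinned
        there accrues negative QALYs."""
        trace = _constant_trace([0, 0, 0, 1, 0, 0], 360)
        assert accrue_qalys(trace, lgs_config) < 0

    def test_sae_disutility_reduces_qalys(self, lgs_config):
        trace = _constant_trace([1, 0, 0, 0, 0, 0], 40)
        with_sae = accrue_qalys(trace, lgs_config, sae_prob=0.03)
        without = accrue_qalys(trace, lgs_config)
        # base case: one cycle of -0.12 weighted by probability and cycle length
        expected_loss = 0.03 * 0.12 * 0.25 * discount_factor(1, 0.015)
        assert without - with_sae == pytest.approx(expected_loss, rel=1e-9)

    def test_caregiver_scenario_decrement(self, lgs_config):
        cfg = lgs_config.model_copy(deep=True)
        cfg.utilities.n_caregivers = 2
        trace = _constant_trace([1, 0, 0, 0, 0, 0], 40)
        assert accrue_qalys(trace, cfg) < accrue_qalys(trace, lgs_config)


class TestCostAccrual:
    def test_zero_unit_costs_zero_total(self, lgs_config):
        data = lgs_config.model_dump(mode="json")
        for key in ("cbd_price_per_mg", "ed_visit_cost", "nurse_visit_cost",
                    "ward_day_cost", "icu_day_cost", "institution_cycle_cost",
                    "travel_cost_per_visit", "ae_cost", "sae_cost"):
            data["costs"][key]["mean"] = 0.0
        data["costs"]["family_care_rate_per_hour"] = 0.0
        data["costs"]["professional_care_rate_per_hour"] = 0.0
        for name in data["costs"]["asm_usage"]:
            data["costs"]["asm_usage"][name][1] = 0.0
        cfg = type(lgs_config).model_validate(data)
        trace = _constant_trace([0.2, 0.2, 0.2, 0.2, 0.2, 0], 40)
        assert accrue_costs(trace, cfg)["total"] == 0.0

    def test_family_care_hand_multiplication(self):
        """LGS seizure-free child: 34.0 h/week x 14.95 = 508.30 per week."""
        cfg = default_config("LGS")
        hours = cfg.care_hours["seizure_free"].family_child.mean
        rate = cfg.costs.family_care_rate_per_hour
        assert hours * rate == pytest.approx(508.30, abs=1e-9)

    def test_healthcare_perspective_strictly_cheaper(self, lgs_config):
        trace = _constant_trace([0.2, 0.2, 0.2, 0.2, 0.2, 0], 40)
        societal = accrue_costs(trace, lgs_config)
        cfg_h = lgs_config.model_copy(update={"perspective": "HEALTHCARE"})
        healthcare = accrue_costs(trace, cfg_h)
        assert healthcare["family_care"] == 0.0
        assert healthcare["travel"] == 0.0
        assert healthcare["total"] < societal["total"]
        # categories other than the excluded two are unchanged
        for k in ("drug", "asm", "professional_care", "hcru", "ae"):
            assert healthcare[k] == pytest.approx(societal[k])

    def test_category_decomposition_sums_to_total(self, lgs_result):
        for arm in (lgs_result.cbd, lgs_result.usual_care):
            total = sum(arm.costs[k] for k in COST_CATEGORIES)
            assert arm.costs["total"] == pytest.approx(total, rel=1e-6)

    def test_cost_annuity_closed_form(self):
        """Adult-only cohort, full persistence: the drug category equals the
        per-cycle drug cost times the discount annuity to 1e-10 relative."""
        cfg = _adult_only_config()
        n = cfg.settings.n_cycles
        trace = _constant_trace([1, 0, 0, 0, 0, 0], n)
        costs = accrue_costs(trace, cfg, arm="CBD")
        per_cycle = cycle_drug_cost(
            cfg.age_bands[3].mean_weight_kg.mean,
            cfg.settings.cbd_dose_mg_per_kg_day,
            cfg.costs.cbd_price_per_mg.mean,
            cfg.settings.cycle_length_days,
        )
        r = cfg.settings.cost_discount_annual
        annuity = sum((1 + r) ** (-k / 4) for k in range(1, n + 1))
        assert costs["drug"] == pytest.approx(per_cycle * annuity, rel=1e-10)

    def test_discounting_never_increases_costs(self, lgs_config):
        trace = _constant_trace([0.2, 0.2, 0.2, 0.2, 0.2, 0], 40)
        discounted = accrue_costs(trace, lgs_config)["total"]
        cfg0 = lgs_config.model_copy(
            update={"settings": ModelSettings(cost_discount_annual=0.0)}
        )
        undiscounted = accrue_costs(trace, cfg0)["total"]
        assert discounted < undiscounted

    def test_linearity_in_unit_price(self, lgs_config):
        trace = _constant_trace([0.2, 0.2, 0.2, 0.2, 0.2, 0], 40)
        base = accrue_costs(trace, lgs_config)
        cfg2 = lgs_config.model_copy(deep=True)
        cfg2.costs.cbd_price_per_mg.mean *= 2
        doubled = accrue_costs(trace, cfg2)
        assert doubled["drug"] == pytest.approx(2 * base["drug"], rel=1e-12)
        assert doubled["hcru"] == pytest.approx(base["hcru"], rel=1e-12)


class TestEventCounts:
    def test_zero_probabilities_zero_counts(self, lgs_config):
        cfg = lgs_config.model_copy(deep=True)
        for g in cfg.hcru.values():
            g.ed_visit.mean = 0.0
            g.nurse_visit.mean = 0.0
            g.hospitalization.mean = 0.0
            g.institutionalized.mean = 0.0
        trace = _constant_trace([0.2, 0.2, 0.2, 0.2, 0.2, 0], 40)
        assert all(v == 0.0 for v in count_events(trace, cfg).values())

    def test_single_state_closed_form(self, lgs_config):
        """Full survival in one state for N cycles: N x p events."""
        n = 40
        trace = _constant_trace([0, 0, 0, 0, 1, 0], n)
        counts = count_events(trace, lgs_config)
        p = lgs_config.hcru["high_freq"].ed_visit.mean
        assert counts["ed_visits"] == pytest.approx(n * p, rel=1e-12)

    def test_counts_match_microsimulation(self, lgs_config, lgs_bundle):
        from microsim import microsimulate

        n = 10_000
        trace = run_arm(lgs_config, "CBD", lgs_bundle)
        expected = count_events(trace, lgs_config)
        _f, _o, sampled = microsimulate(lgs_config, lgs_bundle, "CBD", n, seed=5)
        for kind in ("ed_visits", "nurse_visits", "hospitalizations",
                     "institutionalizations"):
            # per-patient lifetime counts; Poisson-binomial sampling error
            se = np.sqrt(expected[kind] / n)
            assert abs(sampled[kind] - expected[kind]) <= 4 * se + 0.01, kind
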