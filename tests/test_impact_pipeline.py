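"""Two-route impact model: margin conversion, Models 1/2, satellites."""

import numpy as np
import pytest

from ioimpact.cost_allocation import CostAllocation, ExpenseSectorMap, SectorMapEntry
from ioimpact.impact_pipeline import (
    PipelineConfig,
    compute_multipliers,
    decomposition_frame,
    employment_effect,
    public_expenditure_impact,
    purchaser_to_producer,
    run_model1,
    run_model2,
    to_usd,
)
from ioimpact.io_core import CoefficientSet
from ioimpact.sensitivity import PipelineScenario
from ioimpact.synthetic_data import ScenarioConfig, generate_scenario


class TestPurchaserToProducer:
    def test_three_way_split(self, toy_scenario):
        scenario, _ = toy_scenario
        smap = ExpenseSectorMap({"medicine": SectorMapEntry("Chemical products")})
        coeffs = CoefficientSet(
            A=scenario.coeffs.A, m=scenario.coeffs.m, v=scenario.coeffs.v,
            trade_margin_rate={"medicine": 0.2}, transport_rate={"medicine": 0.05},
        )
        out = purchaser_to_producer(
            {"medicine": 100.0}, coeffs, smap, scenario.table, "Commerce", "Transport"
        )
        i_own = scenario.table.sector_index("Chemical products")
        assert out.values[i_own] == pytest.approx(75.0)
        assert out.values[scenario.table.sector_index("Commerce")] == pytest.approx(20.0)
        assert out.values[scenario.table.sector_index("Transport")] == pytest.approx(5.0)

    def test_zero_margins_identity(self, toy_scenario):
        scenario, _ = toy_scenario
        smap = ExpenseSectorMap({"medicine": SectorMapEntry("Chemical products")})
        coeffs = CoefficientSet(A=scenario.coeffs.A, m=scenario.coeffs.m, v=scenario.coeffs.v)
        out = purchaser_to_producer(
            {"medicine": 42.0}, coeffs, smap, scenario.table, "Commerce", "Transport"
        )
        assert out.values[scenario.table.sector_index("Chemical products")] == pytest.approx(42.0)
        assert out.total == pytest.approx(42.0)

    def test_conserves_total_on_random_item_sets(self, toy_scenario):
        scenario, _ = toy_scenario
        rng = np.random.default_rng(3)
        items = list(scenario.sector_map.entries)
        interindustry = [
            i for i in items
            if not scenario.sector_map.entries[i].is_personnel
            and not scenario.sector_map.entries[i].is_depreciation
        ]
        for _ in range(200):
            values = {i: float(rng.uniform(0, 100)) for i in interindustry}
            out = purchaser_to_producer(
                values, scenario.coeffs, scenario.sector_map, scenario.table,
                "Commerce", "Transport",
            )
            assert out.total == pytest.approx(sum(values.values()), rel=1e-12)

    def test_personnel_must_be_excluded(self, toy_scenario):
        scenario, _ = toy_scenario
        with pytest.raises(ValueError, match="personnel"):
            purchaser_to_producer(
                {"personal_expenses": 10.0}, scenario.coeffs, scenario.sector_map,
                scenario.table, "Commerce", "Transport",
            )

    def test_missing_commerce_sector_is_config_error(self, toy_scenario):
        scenario, _ = toy_scenario
        with pytest.raises(ValueError, match="misconfigured"):
            purchaser_to_producer(
                {}, scenario.coeffs, scenario.sector_map, scenario.table,
                "No such sector", "Transport",
            )


def stepwise_oracle(scenario):
    """Re-execute the nine pipeline steps with plain numpy."""
    from ioimpact.cost_allocation import build_allocation

    table, coeffs, cfg = scenario.table, scenario.coeffs, scenario.config
    alloc = build_allocation(
        scenario.hospital_shares, scenario.clinic_shares,
        scenario.expenditure_hospitals, scenario.expenditure_clinics, scenario.sector_map,
    )
    n = table.n_sectors
    labels = table.sector_labels
    direct = np.zeros(n)
    direct[labels.index(cfg.medical_sector)] = alloc.medical_revenue
    y = np.zeros(n)
    for item, p in alloc.interindustry_items.items():
        e = scenario.sector_map.entries[item]
        t = coeffs.trade_margin_rate.get(item, 0.0)
        d = coeffs.transport_rate.get(item, 0.0)
        y[labels.index(e.sector)] += p * (1 - t - d)
        y[labels.index(cfg.commerce_sector)] += p * t
        y[labels.index(cfg.transport_sector)] += p * d
    keep = 1.0 - coeffs.m
    lhs = np.eye(n) - keep[:, None] * coeffs.A
    x1 = np.linalg.solve(lhs, keep * y)
    primary_vec = direct + x1
    income = float(primary_vec @ coeffs.v) + alloc.personnel_expenses
    pc = table.private_consumption
    cons = cfg.propensity * income * pc / pc.sum()
    x2 = np.linalg.solve(lhs, keep * cons)
    return {
        "direct": alloc.medical_revenue,
        "indirect": float(x1.sum()),
        "primary": alloc.medical_revenue + float(x1.sum()),
        "secondary": float(x2.sum()),
        "economic": alloc.medical_revenue + float(x1.sum()) + float(x2.sum()),
    }


class TestModel1:
    def test_matches_stepwise_oracle(self, toy_scenario):
        scenario, _ = toy_scenario
        result = scenario.evaluate()
        want = stepwise_oracle(scenario)
        assert result.direct_effect == pytest.approx(want["direct"])
        assert result.indirect_effect == pytest.approx(want["indirect"], rel=1e-10)
        assert result.primary_impact == pytest.approx(want["primary"], rel=1e-10)
        assert result.secondary_impact == pytest.approx(want["secondary"], rel=1e-10)
        assert result.economic_impact == pytest.approx(want["economic"], rel=1e-10)

    def test_degenerate_allocation_zero_cost(self, toy_scenario):
        scenario, _ = toy_scenario
        alloc = CostAllocation(
            medical_revenue=100.0, medical_cost_total=0.0, by_item={},
            by_sector={}, personnel_expenses=0.0, depreciation=0.0,
        )
        result = run_model1(alloc, scenario.coeffs, scenario.table, scenario.config)
        assert result.indirect_effect == pytest.approx(0.0)
        assert result.primary_impact == pytest.approx(100.0)
        assert result.secondary_impact > 0  # induced via medical-sector wages
        assert result.multipliers["total"] >= 1.0

    def test_additivity_identities(self, toy_scenario):
        scenario, _ = toy_scenario
        r = scenario.evaluate()
        assert r.primary_impact == pytest.approx(r.direct_effect + r.indirect_effect, rel=1e-9)
        assert r.economic_impact == pytest.approx(r.primary_impact + r.secondary_impact, rel=1e-9)
        for key, impact in [
            ("total", r.economic_impact), ("primary", r.primary_impact),
            ("indirect", r.indirect_effect), ("secondary", r.secondary_impact),
        ]:
            assert r.multipliers[key] * r.direct_effect == pytest.approx(impact, rel=1e-9)

    def test_secondary_increases_with_propensity(self, toy_scenario):
        scenario, _ = toy_scenario
        lo = scenario.evaluate(propensity=0.4)
        hi = scenario.evaluate(propensity=0.8)
        assert hi.secondary_impact > lo.secondary_impact
        assert hi.multipliers["total"] > lo.multipliers["total"]

    def test_scale_invariance_of_multipliers(self):
        cfg = ScenarioConfig(seed=21)
        s1, _ = generate_scenario(cfg)
        k = 3.7
        s2 = PipelineScenario(
            table=s1.table, coeffs=s1.coeffs,
            hospital_shares=s1.hospital_shares, clinic_shares=s1.clinic_shares,
            expenditure_hospitals=k * s1.expenditure_hospitals,
            expenditure_clinics=k * s1.expenditure_clinics,
            config=s1.config, sector_map=s1.sector_map, model=1,
        )
        r1, r2 = s1.evaluate(), s2.evaluate()
        assert r2.economic_impact == pytest.approx(k * r1.economic_impact, rel=1e-9)
        for key in r1.multipliers:
            assert r2.multipliers[key] == pytest.approx(r1.multipliers[key], rel=1e-9)

    def test_income_base_indirect_reduces_income(self, toy_scenario):
        scenario, _ = toy_scenario
        primary_base = scenario.evaluate()
        indirect_base = PipelineScenario(
            table=scenario.table, coeffs=scenario.coeffs,
            hospital_shares=scenario.hospital_shares, clinic_shares=scenario.clinic_shares,
            expenditure_hospitals=scenario.expenditure_hospitals,
            expenditure_clinics=scenario.expenditure_clinics,
            config=PipelineConfig(
                medical_sector=scenario.config.medical_sector,
                commerce_sector=scenario.config.commerce_sector,
                transport_sector=scenario.config.transport_sector,
                propensity=scenario.config.propensity,
                income_base="indirect",
            ),
            sector_map=scenario.sector_map, model=1,
        ).evaluate()
        assert indirect_base.total_employee_income < primary_base.total_employee_income
        assert indirect_base.secondary_impact < primary_base.secondary_impact


class TestModel2:
    def test_direct_effect_is_medical_cost(self, toy_scenario):
        scenario, _ = toy_scenario
        m1 = scenario.evaluate()
        m2 = PipelineScenario(**{**scenario.__dict__, "model": 2}).evaluate()
        assert m2.model_variant == "model2"
        assert m2.direct_effect < m1.direct_effect  # hospital-dominated: cost < revenue
        # shared pipeline: indirect and secondary routes identical
        assert m2.indirect_effect == pytest.approx(m1.indirect_effect, rel=1e-12)
        assert m2.economic_impact < m1.economic_impact

    def test_cost_equal_revenue_collapses_to_model1(self, toy_scenario):
        scenario, _ = toy_scenario
        from ioimpact.cost_allocation import build_allocation

        alloc = build_allocation(
            scenario.hospital_shares, scenario.clinic_shares,
            scenario.expenditure_hospitals, scenario.expenditure_clinics, scenario.sector_map,
        )
        alloc.medical_revenue = alloc.medical_cost_total
        r1 = run_model1(alloc, scenario.coeffs, scenario.table, scenario.config, scenario.sector_map)
        r2 = run_model2(alloc, scenario.coeffs, scenario.table, scenario.config, scenario.sector_map)
        assert r1.economic_impact == pytest.approx(r2.economic_impact, rel=1e-12)


class TestSatellites:
    def test_published_multiplier_arithmetic(self, paper_fixture):
        # 72107.4 / 25948.4 -> 2.78 ; 18474.3 / 25948.4 -> 0.71
        assert round(72107.4 / paper_fixture.medical_revenue, 2) == 2.78
        assert round(18474.3 / paper_fixture.medical_revenue, 2) == 0.71

    def test_multiplier_of_direct_equals_one(self, toy_scenario):
        scenario, _ = toy_scenario
        r = scenario.evaluate()
        r2 = r
        r2.economic_impact = r.direct_effect
        assert compute_multipliers(r2)["total"] == pytest.approx(1.0)

    def test_employment_effect_dot_product(self, toy_scenario):
        scenario, _ = toy_scenario
        r = scenario.evaluate()
        ell = np.linspace(0.01, 0.1, scenario.table.n_sectors)
        assert employment_effect(r, ell) == pytest.approx(float(r.economic_vector @ ell))
        assert employment_effect(r, np.zeros(scenario.table.n_sectors)) == 0.0

    @pytest.mark.parametrize("share, factor", [(0.0, 0.0), (1.0, 1.0), (0.36, 0.36)])
    def test_public_expenditure_share(self, toy_scenario, share, factor):
        scenario, _ = toy_scenario
        r = scenario.evaluate()
        assert public_expenditure_impact(r, share) == pytest.approx(factor * r.economic_impact)

    @pytest.mark.parametrize(
        "value, expected", [(25948.4, 238.1), (72107.4, 661.5), (0.0, 0.0)]
    )
    def test_usd_conversion(self, value, expected):
        assert to_usd(value, 109.0) == pytest.approx(expected)

    def test_usd_nonpositive_rate(self):
        with pytest.raises(ValueError):
            to_usd(1.0, 0.0)

    def test_decomposition_frame_rows(self, toy_scenario):
        scenario, _ = toy_scenario
        frame = decomposition_frame(scenario.evaluate())
        assert list(frame["category"]) == [
            "economic_impact", "primary_impact", "direct_effect",
            "indirect_effect", "secondary_impact",
        ]
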