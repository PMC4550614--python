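"""Synthetic, accounting-consistent inputs for the whole pipeline.

Real national I-O tables and the facility-level medical economics survey
are not redistributable, so every pipeline stage is exercised on a
generated "toy economy": a square I-O table built coefficient-first (draw
input coefficients, import coefficients and a value-added split, solve the
equilibrium for a consistent production vector, then back out the
transaction matrix, imports and balances — consistent by construction, no
rejection sampling), a multi-wave P/L survey whose item shares drift as a
bounded random walk, and per-item trade/transport margin rates.

The toy economy mirrors the structure the analysis needs: a medical-service
sector that sells only to final demand, explicit commerce and transport
sectors to receive margins, and goods sectors that carry them.  It makes no
attempt to replicate any actual economy; it validates mechanics and
statistical behaviour only.

:func:`build_paper_fixture` loads the packaged published sector-allocation
and impact-decomposition tables (billion yen) used by the arithmetic
acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cost_allocation import (
    EXPENSE_ITEMS,
    CostAllocation,
    ExpenseSectorMap,
    PLSurveyWave,
    clinic_shares,
    pooled_hospital_shares,
)
from .impact_pipeline import PipelineConfig
from .io_core import CoefficientSet, IOTable
from .sensitivity import PipelineScenario

__all__ = [
    "DEFAULT_SECTORS",
    "ScenarioConfig",
    "PaperFixture",
    "generate_io_table",
    "generate_pl_survey",
    "generate_margin_rates",
    "generate_scenario",
    "toy_sector_map",
    "build_paper_fixture",
]

DEFAULT_SECTORS = [
    "Agriculture and foods",
    "Chemical products",
    "Miscellaneous manufacturing products",
    "Commerce",
    "Transport",
    "Business services",
    "Medical service",
    "Other services",
]


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic economy; every artifact is a deterministic
    function of (config, seed)."""

    n_sectors: int = 8
    seed: int = 0
    medical_sector_index: int = 6
    commerce_sector_index: int = 3
    transport_sector_index: int = 4
    target_column_sum_range: tuple[float, float] = (0.3, 0.7)
    import_share_range: tuple[float, float] = (0.0, 0.3)
    expense_items: tuple[str, ...] = tuple(EXPENSE_ITEMS)
    n_waves: int = 5
    revenue_cost_ratio_hospitals: float = 0.95  # cost/revenue < 1
    revenue_cost_ratio_clinics: float = 1.05  # cost/revenue > 1
    sector_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_sectors < 1:
            raise ValueError("need at least one sector")
        idx = (self.medical_sector_index, self.commerce_sector_index, self.transport_sector_index)
        if any(i >= self.n_sectors or i < 0 for i in idx):
            raise ValueError("special sector indices must be < n_sectors")
        if self.n_sectors >= 3 and len(set(idx)) != 3:
            raise ValueError("medical, commerce and transport sectors must be distinct")
        lo, hi = self.target_column_sum_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("column-sum range must lie within (0, 1)")
        lo, hi = self.import_share_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("import-share range must lie within [0, 1)")
        if self.revenue_cost_ratio_hospitals <= 0 or self.revenue_cost_ratio_clinics <= 0:
            raise ValueError("cost/revenue ratios must be positive")
        if not self.expense_items:
            raise ValueError("expense-item vocabulary is empty")
        if self.sector_labels is None:
            if self.n_sectors == len(DEFAULT_SECTORS):
                self.sector_labels = list(DEFAULT_SECTORS)
            else:
                self.sector_labels = [f"Sector {i + 1:02d}" for i in range(self.n_sectors)]
                self.sector_labels[self.medical_sector_index] = "Medical service"
                if self.n_sectors >= 3:
                    self.sector_labels[self.commerce_sector_index] = "Commerce"
                    self.sector_labels[self.transport_sector_index] = "Transport"
        if len(self.sector_labels) != self.n_sectors:
            raise ValueError("sector_labels length must equal n_sectors")

    @property
    def medical_sector(self) -> str:
        return self.sector_labels[self.medical_sector_index]

    @property
    def commerce_sector(self) -> str:
        return self.sector_labels[self.commerce_sector_index]

    @property
    def transport_sector(self) -> str:
        return self.sector_labels[self.transport_sector_index]


#: Curated expense-item -> sector assignment for the named 8-sector toy
#: economy (personnel/depreciation flags come from the vocabulary).
_TOY_ITEM_SECTORS = {
    "medicine": "Chemical products",
    "food_material": "Agriculture and foods",
    "patient_meal_service": "Agriculture and foods",
    "medical_materials": "Miscellaneous manufacturing products",
    "utility_costs": "Other services",
    "land_and_building_rents": "Other services",
    "linen_and_gown_cleaning": "Other services",
    "medical_waste_disposal": "Other services",
    "equipment_rentals": "Business services",
    "consignment_laboratory_tests": "Business services",
    "others": "Business services",
}


def toy_sector_map(config: ScenarioConfig) -> ExpenseSectorMap:
    """Expense-item -> sector map valid for the synthetic economy.

    The canonical vocabulary maps items onto published-table sectors that
    a small toy economy does not carry, so interindustry items are
    re-homed: onto the curated assignment when the named 8-sector labels
    are in use, otherwise round-robin across the non-special sectors.
    Personnel and depreciation flags are preserved.
    """
    from .cost_allocation import SectorMapEntry

    labels = list(config.sector_labels)
    special = {
        config.medical_sector_index,
        config.commerce_sector_index,
        config.transport_sector_index,
    }
    ordinary = [s for i, s in enumerate(labels) if i not in special] or labels
    entries: dict[str, SectorMapEntry] = {}
    k = 0
    for item in config.expense_items:
        sector, pers, dep, _ = EXPENSE_ITEMS[item]
        if pers or dep:
            entries[item] = SectorMapEntry(sector, pers, dep)
            continue
        if labels == DEFAULT_SECTORS and item in _TOY_ITEM_SECTORS:
            entries[item] = SectorMapEntry(_TOY_ITEM_SECTORS[item])
        else:
            entries[item] = SectorMapEntry(ordinary[k % len(ordinary)])
            k += 1
    return ExpenseSectorMap(entries)


def generate_io_table(config: ScenarioConfig) -> IOTable:
    """Draw a balanced, viable I-O table.

    Column sums of the input-coefficient matrix are held inside the
    configured range, so the spectral radius of ``(I - M)A`` is below one
    and the equilibrium always has a nonnegative solution.  Employee
    income takes between 20% and 70% of each sector's value added.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sectors
    lo, hi = config.target_column_sum_range

    # input coefficients: random composition scaled to a target column sum;
    # the medical-service row is zeroed (it sells only to final demand)
    weights = rng.uniform(0.05, 1.0, size=(n, n))
    if n > 1:
        weights[config.medical_sector_index, :] = 0.0
    col_targets = rng.uniform(lo, hi, size=n)
    A = weights / weights.sum(axis=0, keepdims=True) * col_targets[np.newaxis, :]

    m = rng.uniform(*config.import_share_range, size=n)
    m[config.medical_sector_index] = 0.0  # medical services are not imported

    # final demand and exports
    pc = rng.uniform(50.0, 150.0, size=n)
    other_fd = rng.uniform(0.0, 50.0, size=n)
    E = rng.uniform(0.0, 30.0, size=n)
    E[config.medical_sector_index] = 0.0
    Y = pc + other_fd

    keep = 1.0 - m
    X = np.linalg.solve(np.eye(n) - keep[:, np.newaxis] * A, keep * Y + E)
    Z = A * X[np.newaxis, :]
    imports = m * (Z.sum(axis=1) + Y)

    value_added = (1.0 - A.sum(axis=0)) * X
    labor_frac = rng.uniform(0.2, 0.7, size=n)
    employee_income = labor_frac * value_added
    other_va = value_added - employee_income
    employees = rng.uniform(0.02, 0.12, size=n) * X

    return IOTable(
        sector_labels=list(config.sector_labels),
        Z=Z,
        final_demand=pd.DataFrame(
            {"private_consumption": pc, "other_final_demand": other_fd},
            index=config.sector_labels,
        ),
        exports=E,
        imports=imports,
        employee_income=employee_income,
        other_value_added=other_va,
        domestic_production=X,
        employees=employees,
    )


def generate_pl_survey(config: ScenarioConfig) -> list[PLSurveyWave]:
    """Draw multi-wave per-facility P/L records for all facility types.

    Item shares follow a bounded multiplicative random walk across waves
    (so triangular fits have non-degenerate supports); hospital revenue
    exceeds cost and clinic revenue falls short of it, per the configured
    cost/revenue ratios.
    """
    if config.n_waves < 1:
        raise ValueError("need at least one survey wave")
    items = list(config.expense_items)
    if not items:
        raise ValueError("expense-item vocabulary is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    specs = {
        "hospital": (200.0, (50, 200), config.revenue_cost_ratio_hospitals),
        "special_functioning_hospital": (400.0, (5, 30), config.revenue_cost_ratio_hospitals),
        "medical_clinic": (6.0, (100, 400), config.revenue_cost_ratio_clinics),
    }
    waves: list[PLSurveyWave] = []
    for ftype, (scale, n_range, cost_rev_ratio) in specs.items():
        shares = rng.dirichlet(np.full(len(items), 2.0))
        for w in range(config.n_waves):
            if w > 0:
                shares = shares * np.exp(rng.normal(0.0, 0.08, size=len(items)))
                shares = shares / shares.sum()
            cost_per_facility = scale * float(rng.uniform(0.9, 1.1))
            waves.append(
                PLSurveyWave(
                    wave_label=f"wave_{w + 1:02d}",
                    facility_type=ftype,
                    n_facilities=int(rng.integers(*n_range)),
                    per_facility_monthly={
                        it: cost_per_facility * s for it, s in zip(items, shares)
                    },
                    revenue_per_facility_monthly=cost_per_facility / cost_rev_ratio,
                )
            )
    return waves


def generate_margin_rates(config: ScenarioConfig) -> tuple[dict[str, float], dict[str, float]]:
    """Per-item trade and transport margin rates.

    Goods items carry a trade margin in [0.05, 0.35] and a transport
    charge in [0.01, 0.10]; service items carry none (their purchasers'
    and producers' prices coincide).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    trade: dict[str, float] = {}
    transport: dict[str, float] = {}
    for item in config.expense_items:
        is_goods = EXPENSE_ITEMS.get(item, ("", False, False, False))[3]
        if is_goods:
            trade[item] = float(rng.uniform(0.05, 0.35))
            transport[item] = float(rng.uniform(0.01, 0.10))
        else:
            trade[item] = 0.0
            transport[item] = 0.0
    return trade, transport


def generate_scenario(
    config: ScenarioConfig | None = None,
    model: int = 1,
    propensity: float = 0.62,
    income_base: str = "primary",
) -> tuple[PipelineScenario, list[PLSurveyWave]]:
    """Assemble a full end-to-end scenario from one config.

    Point-estimate expense shares come from the latest survey wave (the
    estimation survey); earlier waves feed the sensitivity layer's
    triangular fits.  National expenditure is set to the toy table's
    medical-sector final demand, split 70/30 between hospitals and
    clinics.
    """
    config = config or ScenarioConfig()
    table = generate_io_table(config)
    trade, transport = generate_margin_rates(config)
    coeffs = CoefficientSet.from_table(table, trade, transport)
    waves = generate_pl_survey(config)
    last = [w for w in waves if w.wave_label == f"wave_{config.n_waves:02d}"]
    hosp = pooled_hospital_shares(last)
    clin = clinic_shares(last)
    fd_med = float(table.final_demand_total[config.medical_sector_index])
    scenario = PipelineScenario(
        table=table,
        coeffs=coeffs,
        hospital_shares=hosp,
        clinic_shares=clin,
        expenditure_hospitals=0.7 * fd_med,
        expenditure_clinics=0.3 * fd_med,
        config=PipelineConfig(
            medical_sector=config.medical_sector,
            commerce_sector=config.commerce_sector,
            transport_sector=config.transport_sector,
            propensity=propensity,
            income_base=income_base,
        ),
        sector_map=toy_sector_map(config),
        model=model,
    )
    return scenario, waves


# ---------------------------------------------------------------------------
# Packaged published-table fixture
# ---------------------------------------------------------------------------


@dataclass
class PaperFixture:
    """The published sector allocation and impact decomposition.

    All currency values in billion yen.  ``allocation.medical_cost_total``
    is the printed total (24825.6); the printed per-item values sum to
    24825.5 — a 0.1 rounding discrepancy in the source table, kept as
    printed.
    """

    allocation: CostAllocation
    item_table: pd.DataFrame
    impact_table: pd.DataFrame
    medical_revenue: float = 25948.4
    medical_cost_total: float = 24825.6
    public_share: float = 0.36
    usd_rate: float = 109.0
    model2_impact: float = 34638.9
    model2_impact_ci: tuple[float, float] = (33475.3, 37227.6)
    model2_multiplier_ci: tuple[float, float] = (1.38, 1.46)
    employment_effect_thousand: float = 4946.0
    employment_ci_thousand: tuple[float, float] = (4876.0, 5119.0)

    @property
    def cost_excluding_depreciation(self) -> float:
        return self.medical_cost_total - self.allocation.depreciation


def _data_path(name: str) -> Path:
    return Path(resources.files("ioimpact").joinpath("data", name))


def build_paper_fixture() -> PaperFixture:
    """Load the packaged published tables into pipeline types."""
    items = pd.read_csv(_data_path("medical_cost_table.csv"))
    impact = pd.read_csv(_data_path("impact_decomposition_table.csv"))
    by_item = dict(zip(items["item"], items["value_billion_yen"].astype(float)))
    by_sector: dict[str, float] = {}
    personnel = 0.0
    depreciation = 0.0
    for row in items.itertuples(index=False):
        v = float(row.value_billion_yen)
        if row.is_personnel:
            personnel += v
        elif row.is_depreciation:
            depreciation += v
        else:
            by_sector[row.sector] = by_sector.get(row.sector, 0.0) + v
    allocation = CostAllocation(
        medical_revenue=25948.4,
        medical_cost_total=24825.6,
        by_item=by_item,
        by_sector=by_sector,
        personnel_expenses=personnel,
        depreciation=depreciation,
    )
    return PaperFixture(allocation=allocation, item_table=items, impact_table=impact)
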