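"""Two-route economic-impact model built on the equilibrium output solver.

Route 1 (raw-materials purchase): medical institutions' spending on goods
and services, converted from purchasers' to producers' prices, is injected
as domestic final demand; the induced domestic production is the *indirect
effect*.  Added to the *direct effect* — the demand injection itself,
medical revenue in Model 1 or medical cost in Model 2, placed in the
medical-service sector — it gives the *primary impact*.

Route 2 (consumption): the primary impact generates employee income via
per-sector employee-income rates; medical personnel expenses are added;
the consumption propensity turns total income into household consumption,
distributed across sectors and injected once more through the equilibrium
model to give the *secondary impact*.  The consumption loop runs exactly
once (no endogenized-household closure).

Economic impact = primary + secondary; each multiplier divides its impact
by the direct effect.  Employment and public-expenditure figures are
satellite computations on the economic impact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cost_allocation import CostAllocation, ExpenseSectorMap
from .io_core import CoefficientSet, IOTable
from .leontief import EquilibriumInputs, domestic_induced_production

__all__ = [
    "PipelineConfig",
    "FinalDemandVector",
    "ImpactResult",
    "purchaser_to_producer",
    "run_model1",
    "run_model2",
    "compute_multipliers",
    "employment_effect",
    "public_expenditure_impact",
    "to_usd",
    "decomposition_frame",
]


@dataclass
class PipelineConfig:
    """Run configuration: sector roles and behavioural parameters.

    ``consumption_shares`` distributes induced household consumption
    across sectors; when None, the I-O table's private-consumption
    final-demand column is used (normalized).  ``income_base`` selects
    whether employee-income rates apply to the full per-sector primary
    impact ("primary", the literal procedure, which arguably double
    counts medical-sector labor income because personnel expenses are
    added separately) or to the indirect effect only ("indirect").
    """

    medical_sector: str
    commerce_sector: str
    transport_sector: str
    propensity: float = 0.62
    consumption_shares: np.ndarray | None = None
    income_base: str = "primary"
    public_share: float = 0.36
    usd_rate: float = 109.0

    def __post_init__(self) -> None:
        if not 0.0 < self.propensity < 1.0:
            raise ValueError("consumption propensity must lie strictly in (0, 1)")
        if self.income_base not in ("primary", "indirect"):
            raise ValueError("income_base must be 'primary' or 'indirect'")
        if self.consumption_shares is not None:
            s = np.asarray(self.consumption_shares, dtype=float)
            if np.any(s < 0) or not np.isclose(s.sum(), 1.0):
                raise ValueError("consumption shares must be nonnegative and sum to 1")
            self.consumption_shares = s


@dataclass
class FinalDemandVector:
    """A per-sector final-demand injection at producers' prices."""

    values: np.ndarray
    sector_labels: list[str]
    provenance: str  # medical_cost_route | consumption_route | direct_effect

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sector_labels),):
            raise ValueError("final-demand vector does not match sector labels")
        if np.any(self.values < 0):
            raise ValueError("final demand must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class ImpactResult:
    """Impact decomposition, per-sector vectors, and multipliers."""

    model_variant: str
    direct_effect: float
    indirect_effect: float
    primary_impact: float
    employee_income_induced: float
    total_employee_income: float
    household_consumption: float
    secondary_impact: float
    economic_impact: float
    multipliers: dict[str, float]
    direct_vector: np.ndarray
    indirect_vector: np.ndarray
    secondary_vector: np.ndarray
    sector_labels: list[str]
    employment_effect: float | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def economic_vector(self) -> np.ndarray:
        return self.direct_vector + self.indirect_vector + self.secondary_vector


def purchaser_to_producer(
    items: Mapping[str, float],
    coeffs: CoefficientSet,
    sector_map: ExpenseSectorMap,
    table: IOTable,
    commerce_sector: str,
    transport_sector: str,
) -> FinalDemandVector:
    """Convert purchaser-price item values to a producer-price demand vector.

    Each item's purchaser value ``p`` splits into ``p*(1 - t - d)`` in its
    own sector, ``p*t`` in the commerce sector and ``p*d`` in the transport
    sector, where ``t``/``d`` are its trade-margin and transport-charge
    rates (looked up per item first, then per sector, else zero).  The
    split conserves the total exactly.
    """
    try:
        i_com = table.sector_index(commerce_sector)
        i_tra = table.sector_index(transport_sector)
    except KeyError as exc:
        raise ValueError(f"margin conversion misconfigured: {exc}") from exc
    y = np.zeros(table.n_sectors)
    for item, p in items.items():
        entry = sector_map.sector_of(item)
        if entry.is_personnel or entry.is_depreciation:
            raise ValueError(
                f"item {item!r} is personnel/depreciation and must be excluded "
                "before margin conversion"
            )
        t = coeffs.trade_margin_rate.get(item, coeffs.trade_margin_rate.get(entry.sector, 0.0))
        d = coeffs.transport_rate.get(item, coeffs.transport_rate.get(entry.sector, 0.0))
        if t < 0 or d < 0 or t + d > 1:
            raise ValueError(f"margin rates for {item!r} invalid: t={t}, d={d}")
        y[table.sector_index(entry.sector)] += p * (1.0 - t - d)
        y[i_com] += p * t
        y[i_tra] += p * d
    return FinalDemandVector(y, list(table.sector_labels), "medical_cost_route")


def _run_pipeline(
    direct_value: float,
    model_variant: str,
    allocation: CostAllocation,
    coeffs: CoefficientSet,
    table: IOTable,
    config: PipelineConfig,
    sector_map: ExpenseSectorMap | None = None,
) -> ImpactResult:
    sector_map = sector_map or ExpenseSectorMap.default()
    labels = list(table.sector_labels)
    n = table.n_sectors
    i_med = table.sector_index(config.medical_sector)

    # {1} direct effect in the medical-service sector (service revenue is
    # margin-free, so no purchaser->producer conversion applies to it)
    direct_vec = np.zeros(n)
    direct_vec[i_med] = direct_value

    # {2},{3} interindustry cost items to producers' prices
    demand = purchaser_to_producer(
        allocation.interindustry_items,
        coeffs,
        sector_map,
        table,
        config.commerce_sector,
        config.transport_sector,
    )

    # {4} indirect effect: induced production of the purchase route
    indirect = domestic_induced_production(
        EquilibriumInputs(A=coeffs.A, m=coeffs.m, Y=demand.values)
    )

    # {5} primary impact
    primary_vec = direct_vec + indirect.X
    primary = float(primary_vec.sum())

    # {6},{7} employee income
    base = primary_vec if config.income_base == "primary" else indirect.X
    income_induced = float(base @ coeffs.v)
    total_income = income_induced + allocation.personnel_expenses

    # {8} household consumption
    if config.consumption_shares is not None:
        shares = config.consumption_shares
    else:
        pc = table.private_consumption
        if pc.sum() <= 0:
            raise ValueError(
                "private-consumption column is zero; supply consumption_shares"
            )
        shares = pc / pc.sum()
    consumption_total = config.propensity * total_income
    consumption = FinalDemandVector(
        consumption_total * shares, labels, "consumption_route"
    )

    # {9} secondary impact and totals
    secondary = domestic_induced_production(
        EquilibriumInputs(A=coeffs.A, m=coeffs.m, Y=consumption.values)
    )
    economic = primary + secondary.total

    result = ImpactResult(
        model_variant=model_variant,
        direct_effect=direct_value,
        indirect_effect=indirect.total,
        primary_impact=primary,
        employee_income_induced=income_induced,
        total_employee_income=total_income,
        household_consumption=consumption_total,
        secondary_impact=secondary.total,
        economic_impact=economic,
        multipliers={},
        direct_vector=direct_vec,
        indirect_vector=indirect.X,
        secondary_vector=secondary.X,
        sector_labels=labels,
    )
    result.multipliers = compute_multipliers(result)
    if config.income_base == "primary":
        result.notes.append(
            "employee-income rates applied to the full primary impact while "
            "personnel expenses are also added; medical-sector labor income "
            "may be double counted (use income_base='indirect' to avoid)"
        )
    if coeffs.ell is not None:
        result.employment_effect = employment_effect(result, coeffs.ell)
    return result


def run_model1(
    allocation: CostAllocation,
    coeffs: CoefficientSet,
    table: IOTable,
    config: PipelineConfig,
    sector_map: ExpenseSectorMap | None = None,
) -> ImpactResult:
    """Model 1: direct effect = medical revenue (final-demand basis)."""
    if not np.isfinite(allocation.medical_revenue):
        raise ValueError("allocation carries no medical revenue")
    return _run_pipeline(
        allocation.medical_revenue, "model1", allocation, coeffs, table, config, sector_map
    )


def run_model2(
    allocation: CostAllocation,
    coeffs: CoefficientSet,
    table: IOTable,
    config: PipelineConfig,
    sector_map: ExpenseSectorMap | None = None,
) -> ImpactResult:
    """Model 2: direct effect = medical cost (intermediate-demand basis).

    Comparable to studies that shock the model with medical cost; its
    impact is a deducted value relative to Model 1 whenever cost is below
    revenue.
    """
    return _run_pipeline(
        allocation.medical_cost_total, "model2", allocation, coeffs, table, config, sector_map
    )


def compute_multipliers(result: ImpactResult, round_decimals: int | None = None) -> dict[str, float]:
    """Impacts divided by the direct effect (induced production coefficients)."""
    if result.direct_effect <= 0:
        raise ValueError("direct effect must be positive to form multipliers")
    mult = {
        "total": result.economic_impact / result.direct_effect,
        "primary": result.primary_impact / result.direct_effect,
        "indirect": result.indirect_effect / result.direct_effect,
        "secondary": result.secondary_impact / result.direct_effect,
    }
    if round_decimals is not None:
        mult = {k: round(v, round_decimals) for k, v in mult.items()}
    return mult


def employment_effect(result: ImpactResult, ell: np.ndarray) -> float:
    """Job creation: per-sector economic impact dotted with employment rates.

    Units follow ``ell`` (the published convention is thousands of
    persons per currency unit of production).
    """
    if ell is None:
        warnings.warn("employment rates unavailable; satellite skipped", stacklevel=2)
        return float("nan")
    ell = np.asarray(ell, dtype=float)
    if ell.shape != result.economic_vector.shape:
        warnings.warn("employment rates unavailable; satellite skipped", stacklevel=2)
        return float("nan")
    if np.any(ell < 0):
        raise ValueError("employment rates must be nonnegative")
    return float(result.economic_vector @ ell)


def public_expenditure_impact(result: ImpactResult, public_share: float = 0.36) -> float:
    """Share of the economic impact attributable to public expenditure."""
    if not 0.0 <= public_share <= 1.0:
        raise ValueError("public share must lie in [0, 1]")
    return result.economic_impact * public_share


def to_usd(value: float, rate: float = 109.0) -> float:
    """Convert billion-yen values to billion USD at ``rate`` yen per dollar."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return round(value / rate, 1)


def decomposition_frame(result: ImpactResult, usd_rate: float = 109.0) -> pd.DataFrame:
    """Impact decomposition as a report table (billions, 1 dp; multipliers 2 dp)."""
    rows = [
        ("economic_impact", result.economic_impact, result.multipliers["total"]),
        ("primary_impact", result.primary_impact, result.multipliers["primary"]),
        ("direct_effect", result.direct_effect, 1.0),
        ("indirect_effect", result.indirect_effect, result.multipliers["indirect"]),
        ("secondary_impact", result.secondary_impact, result.multipliers["secondary"]),
    ]
    return pd.DataFrame(
        {
            "category": [r[0] for r in rows],
            "value_billion": [round(r[1], 1) for r in rows],
            "value_usd_billion": [to_usd(r[1], usd_rate) for r in rows],
            "multiplier": [round(r[2], 2) for r in rows],
        }
    )
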