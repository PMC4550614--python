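"""Medical-cost estimation and allocation to I-O sectors.

National medical care expenditure (general medical care expenditure plus
hospitalization meal expenses) equals the medical revenue of all medical
institutions, but the *cost structure* behind it is only observed in
per-facility monthly profit-and-loss (P/L) survey data.  The procedure
implemented here:

1. pool per-facility P/L values over hospitals and special functioning
   hospitals, weighting each facility type by its count of valid replies,
   to obtain the share of total medical cost held by each expense item
   (and the cost-to-revenue ratio) for the hospital class;
2. do the same for medical clinics;
3. scale each class's national expenditure by its cost/revenue ratio to
   obtain national medical cost;
4. allocate that cost over expense items by the class's shares;
5. sum the two classes per item and map items onto I-O sectors.

Personnel expenses map to the employee-compensation row and depreciation
to fixed-capital depreciation; both are tracked but excluded from the
interindustry final-demand vector (investment-like and income flows do
not enter the intermediate-demand shock).

The cost/revenue ratio direction: the survey reports hospital revenue
above cost and clinic revenue below cost, so scaling expenditure (i.e.
revenue) by cost/revenue yields hospital cost below revenue, consistent
with the survey.  The inverse reading would contradict it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOSPITAL_TYPES",
    "EXPENSE_ITEMS",
    "PLSurveyWave",
    "ExpenseShareSet",
    "ExpenseSectorMap",
    "CostAllocation",
    "pooled_hospital_shares",
    "clinic_shares",
    "scale_expenditure_to_cost",
    "allocate_items",
    "combine_and_map",
    "build_allocation",
    "read_pl_survey",
    "write_pl_survey",
    "read_sector_map",
    "write_sector_map",
]

HOSPITAL_TYPES = ("hospital", "special_functioning_hospital")
_FACILITY_TYPES = HOSPITAL_TYPES + ("medical_clinic",)
REVENUE_ITEM = "medical_revenue"

#: Controlled vocabulary of expense items: key -> (I-O sector, is_personnel,
#: is_depreciation, is_goods).  ``is_goods`` marks items traded as physical
#: commodities, which carry trade and transport margins.
EXPENSE_ITEMS: dict[str, tuple[str, bool, bool, bool]] = {
    "personal_expenses": ("Compensation of employees", True, False, False),
    "medicine": ("Chemical products", False, False, True),
    "food_material": ("Foods", False, False, True),
    "medical_materials": ("Miscellaneous manufacturing products", False, False, True),
    "utility_costs": ("Electricity, gas and heat supply", False, False, False),
    "land_and_building_rents": ("Real estate", False, False, False),
    "equipment_rentals": ("Business services", False, False, False),
    "consignment_laboratory_tests": ("Business services", False, False, False),
    "patient_meal_service": ("Foods", False, False, True),
    "linen_and_gown_cleaning": ("Personal services", False, False, False),
    "medical_waste_disposal": ("Water supply and waste management services", False, False, False),
    "depreciation": ("Depreciation of fixed capital", False, True, False),
    "others": ("Business services", False, False, False),
}


@dataclass
class PLSurveyWave:
    """One facility type's P/L record from one survey wave.

    Values are per facility per month; they enter the model only through
    shares and cost/revenue ratios and are never annualized.
    """

    wave_label: str
    facility_type: str
    n_facilities: int
    per_facility_monthly: dict[str, float]
    revenue_per_facility_monthly: float

    def __post_init__(self) -> None:
        if self.facility_type not in _FACILITY_TYPES:
            raise ValueError(
                f"facility_type must be one of {_FACILITY_TYPES}, got {self.facility_type!r}"
            )
        if self.n_facilities <= 0:
            raise ValueError("n_facilities must be positive")
        if self.revenue_per_facility_monthly < 0 or any(
            v < 0 for v in self.per_facility_monthly.values()
        ):
            raise ValueError("P/L values must be nonnegative")


@dataclass
class ExpenseShareSet:
    """Expense-item shares of medical cost for one facility class."""

    facility_class: str  # "all_hospitals" or "medical_clinics"
    shares: dict[str, float]
    revenue_cost_ratio: float  # medical cost / medical revenue

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if any(s < 0 for s in self.shares.values()):
            raise ValueError("shares must be nonnegative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"shares must sum to 1, got {total!r}")
        if self.revenue_cost_ratio <= 0:
            raise ValueError("cost/revenue ratio must be positive")


@dataclass(frozen=True)
class SectorMapEntry:
    sector: str
    is_personnel: bool = False
    is_depreciation: bool = False


@dataclass
class ExpenseSectorMap:
    """Mapping from expense items to I-O sectors (with personnel and
    depreciation flags routing those items out of interindustry demand)."""

    entries: dict[str, SectorMapEntry]

    @classmethod
    def default(cls) -> "ExpenseSectorMap":
        return cls(
            {
                item: SectorMapEntry(sector, pers, dep)
                for item, (sector, pers, dep, _) in EXPENSE_ITEMS.items()
            }
        )

    def sector_of(self, item: str) -> SectorMapEntry:
        try:
            return self.entries[item]
        except KeyError:
            raise KeyError(f"expense item {item!r} has no sector mapping") from None


@dataclass
class CostAllocation:
    """National medical cost per expense item and per I-O sector.

    ``by_sector`` covers interindustry items only (purchaser prices, not
    yet converted to producers' prices); personnel and depreciation are
    carried separately.
    """

    medical_revenue: float
    medical_cost_total: float
    by_item: dict[str, float]
    by_sector: dict[str, float]
    personnel_expenses: float
    depreciation: float

    @property
    def interindustry_items(self) -> dict[str, float]:
        excluded = {
            item
            for item, (_, pers, dep, _) in EXPENSE_ITEMS.items()
            if pers or dep
        }
        return {k: v for k, v in self.by_item.items() if k not in excluded}

    @property
    def cost_excluding_depreciation(self) -> float:
        return self.medical_cost_total - self.depreciation


def _pool_waves(waves: Sequence[PLSurveyWave], facility_class: str) -> ExpenseShareSet:
    if not waves:
        raise ValueError("at least one survey wave is required")
    item_sets = [frozenset(w.per_facility_monthly) for w in waves]
    if len(set(item_sets)) > 1:
        union = set().union(*item_sets)
        inter = set(item_sets[0]).intersection(*item_sets[1:])
        raise ValueError(
            f"mismatched expense-item sets across facility types: {sorted(union - inter)}"
        )
    items = sorted(item_sets[0])
    totals = {i: 0.0 for i in items}
    revenue_total = 0.0
    n_total = 0
    for w in waves:
        for i in items:
            totals[i] += w.n_facilities * w.per_facility_monthly[i]
        revenue_total += w.n_facilities * w.revenue_per_facility_monthly
        n_total += w.n_facilities
    # per-facility averages; the division by facility count cancels in the
    # shares and the ratio but mirrors the survey's published statistic
    cost_total = sum(totals.values())
    if cost_total <= 0:
        raise ValueError("total medical cost is zero: shares undefined")
    if revenue_total <= 0:
        raise ValueError("total medical revenue is zero: cost/revenue ratio undefined")
    shares = {i: totals[i] / cost_total for i in items}
    return ExpenseShareSet(
        facility_class=facility_class,
        shares=shares,
        revenue_cost_ratio=cost_total / revenue_total,
    )


def pooled_hospital_shares(waves: Sequence[PLSurveyWave]) -> ExpenseShareSet:
    """Pool hospitals and special functioning hospitals into one class.

    Per-item national cost is the reply-count-weighted sum over the two
    facility types; shares and the cost/revenue ratio follow from the
    pooled totals.
    """
    hosp = [w for w in waves if w.facility_type in HOSPITAL_TYPES]
    if not hosp:
        raise ValueError("no hospital waves supplied")
    return _pool_waves(hosp, "all_hospitals")


def clinic_shares(waves: Sequence[PLSurveyWave]) -> ExpenseShareSet:
    """Expense-item shares for medical clinics."""
    clinics = [w for w in waves if w.facility_type == "medical_clinic"]
    if not clinics:
        raise ValueError("no medical-clinic waves supplied")
    return _pool_waves(clinics, "medical_clinics")


def scale_expenditure_to_cost(expenditure: float, share_set: ExpenseShareSet) -> float:
    """National medical cost = expenditure x (cost / revenue).

    ``expenditure`` is the facility class's general medical care
    expenditure plus hospitalization meal expenses, which equals its
    medical revenue.
    """
    if expenditure < 0:
        raise ValueError("expenditure must be nonnegative")
    return expenditure * share_set.revenue_cost_ratio


def allocate_items(
    cost_total: float,
    share_set: ExpenseShareSet,
    round_decimals: int | None = None,
) -> dict[str, float]:
    """Distribute a total over expense items by their shares.

    With ``round_decimals`` set, a largest-remainder correction makes the
    rounded values sum to the (equally rounded) total exactly.
    """
    raw = {i: cost_total * s for i, s in share_set.shares.items()}
    if round_decimals is None:
        return raw
    scale = 10 ** round_decimals
    target = round(cost_total * scale)
    floored = {i: np.floor(v * scale) for i, v in raw.items()}
    residual = int(target - sum(floored.values()))
    out = dict(floored)
    step = 1 if residual >= 0 else -1
    # add to the largest remainders (or, on over-count, remove from the smallest)
    order = sorted(raw, key=lambda i: (raw[i] * scale) - floored[i], reverse=residual >= 0)
    for i in order[: abs(residual)]:
        out[i] += step
    return {i: out[i] / scale for i in raw}


def combine_and_map(
    hospital_items: Mapping[str, float],
    clinic_items: Mapping[str, float],
    sector_map: ExpenseSectorMap | None = None,
) -> CostAllocation:
    """Sum the two facility classes per item and aggregate onto sectors.

    Items sharing a sector (e.g. equipment rentals, consignment
    laboratory tests and "others", all Business services) are summed.
    Medical revenue is not set here; callers fill it from expenditure
    totals (see :func:`build_allocation`).
    """
    sector_map = sector_map or ExpenseSectorMap.default()
    by_item: dict[str, float] = {}
    for src in (hospital_items, clinic_items):
        for item, value in src.items():
            by_item[item] = by_item.get(item, 0.0) + float(value)
    by_sector: dict[str, float] = {}
    personnel = 0.0
    depreciation = 0.0
    for item, value in by_item.items():
        entry = sector_map.sector_of(item)
        if entry.is_personnel:
            personnel += value
        elif entry.is_depreciation:
            depreciation += value
        else:
            by_sector[entry.sector] = by_sector.get(entry.sector, 0.0) + value
    return CostAllocation(
        medical_revenue=float("nan"),
        medical_cost_total=sum(by_item.values()),
        by_item=by_item,
        by_sector=by_sector,
        personnel_expenses=personnel,
        depreciation=depreciation,
    )


def build_allocation(
    hospital_shares: ExpenseShareSet,
    clinic_share_set: ExpenseShareSet,
    expenditure_hospitals: float,
    expenditure_clinics: float,
    sector_map: ExpenseSectorMap | None = None,
) -> CostAllocation:
    """Run the full estimation chain from shares and expenditure totals."""
    cost_h = scale_expenditure_to_cost(expenditure_hospitals, hospital_shares)
    cost_c = scale_expenditure_to_cost(expenditure_clinics, clinic_share_set)
    alloc = combine_and_map(
        allocate_items(cost_h, hospital_shares),
        allocate_items(cost_c, clinic_share_set),
        sector_map,
    )
    alloc.medical_revenue = expenditure_hospitals + expenditure_clinics
    return alloc


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def read_pl_survey(path: str | Path) -> list[PLSurveyWave]:
    """Read P/L survey rows: wave, facility_type, n_facilities, item, value.

    Revenue rows are flagged by ``item == "medical_revenue"``.
    """
    df = pd.read_csv(path)
    required = {"wave", "facility_type", "n_facilities", "item", "value_per_facility_month"}
    if not required.issubset(df.columns):
        raise ValueError(f"P/L survey file must have columns {sorted(required)}")
    waves: list[PLSurveyWave] = []
    for (wave, ftype), grp in df.groupby(["wave", "facility_type"], sort=False):
        n = int(grp["n_facilities"].iloc[0])
        values = dict(zip(grp["item"], grp["value_per_facility_month"].astype(float)))
        revenue = values.pop(REVENUE_ITEM, 0.0)
        waves.append(
            PLSurveyWave(
                wave_label=str(wave),
                facility_type=str(ftype),
                n_facilities=n,
                per_facility_monthly=values,
                revenue_per_facility_monthly=revenue,
            )
        )
    return waves


def write_pl_survey(waves: Iterable[PLSurveyWave], path: str | Path) -> None:
    rows = []
    for w in waves:
        items = dict(w.per_facility_monthly)
        items[REVENUE_ITEM] = w.revenue_per_facility_monthly
        for item, value in items.items():
            rows.append(
                {
                    "wave": w.wave_label,
                    "facility_type": w.facility_type,
                    "n_facilities": w.n_facilities,
                    "item": item,
                    "value_per_facility_month": value,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sector_map(path: str | Path) -> ExpenseSectorMap:
    """Read a sector map CSV: item, sector, is_personnel, is_depreciation."""
    df = pd.read_csv(path)
    entries = {}
    for row in df.itertuples(index=False):
        entries[str(row.item)] = SectorMapEntry(
            sector=str(row.sector),
            is_personnel=bool(row.is_personnel),
            is_depreciation=bool(row.is_depreciation),
        )
    return ExpenseSectorMap(entries)


def write_sector_map(sector_map: ExpenseSectorMap, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "item": item,
                "sector": e.sector,
                "is_personnel": e.is_personnel,
                "is_depreciation": e.is_depreciation,
            }
            for item, e in sector_map.entries.items()
        ]
    ).to_csv(path, index=False)
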