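"""Input-output table container and coefficient derivation.

The national input-output (I-O) table records, for one accounting year, the
flow of goods and services between producing sectors (the intermediate
transaction matrix ``Z``, valued at producers' prices), the components of
final demand, exports, imports, value added and domestic production.  From
it we derive the dimensionless coefficients that the equilibrium output
model consumes:

* input coefficients ``A[i, j] = Z[i, j] / X0[j]`` — intermediate input from
  sector *i* per unit of sector *j* output;
* import coefficients ``m[i]`` — imports over total domestic demand
  (intermediate plus domestic final demand) of sector *i*;
* employee-income rates ``v[i]`` — employee compensation per unit of
  domestic production;
* employment rates ``ell[i]`` — persons engaged per unit of domestic
  production (the employment satellite).

Conventions: imports are stored as nonnegative magnitudes and subtracted in
the row balance; sector order is taken from the input file as authoritative
and every vector must share it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IOTable",
    "CoefficientSet",
    "BalanceViolation",
    "InvalidTableError",
    "compute_input_coefficients",
    "compute_import_coefficients",
    "compute_employee_income_rates",
    "compute_employment_rates",
    "compute_margin_rates",
    "validate_io_table",
    "read_io_table",
    "write_io_table",
    "read_margin_rates",
    "write_margin_rates",
]

#: Reserved row labels in the delimited-text table layout.
_VALUE_ADDED_ROWS = ("employee_income", "other_value_added", "domestic_production", "employees")
#: Reserved column labels (everything else right of the Z block is a
#: final-demand sub-column).
_SPECIAL_COLS = ("exports", "imports")


class InvalidTableError(ValueError):
    """Raised when an I-O table violates a structural precondition."""


def _as_vector(x, n: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (n,):
        raise InvalidTableError(f"{name} must have shape ({n},), got {v.shape}")
    return v


@dataclass
class IOTable:
    """A square symmetric I-O table at producers' prices.

    ``final_demand`` is a DataFrame (index = sectors) whose columns are
    named domestic final-demand categories; at minimum it carries
    ``private_consumption``, which the impact pipeline uses to distribute
    induced household consumption across sectors.
    """

    sector_labels: list[str]
    Z: np.ndarray
    final_demand: pd.DataFrame
    exports: np.ndarray
    imports: np.ndarray
    employee_income: np.ndarray
    other_value_added: np.ndarray
    domestic_production: np.ndarray
    employees: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sector_labels)
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (n, n):
            raise InvalidTableError(f"Z must be {n}x{n}, got {self.Z.shape}")
        if not isinstance(self.final_demand, pd.DataFrame):
            # accept a bare vector: treat it as a single private-consumption column
            vec = _as_vector(self.final_demand, n, "final_demand")
            self.final_demand = pd.DataFrame(
                {"private_consumption": vec}, index=self.sector_labels
            )
        if list(self.final_demand.index) != list(self.sector_labels):
            raise InvalidTableError("final_demand index does not match sector_labels")
        if "private_consumption" not in self.final_demand.columns:
            raise InvalidTableError("final_demand must carry a 'private_consumption' column")
        for name in ("exports", "imports", "employee_income", "other_value_added", "domestic_production"):
            setattr(self, name, _as_vector(getattr(self, name), n, name))
        if self.employees is not None:
            self.employees = _as_vector(self.employees, n, "employees")
        for name in ("Z", "exports", "imports", "domestic_production"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise InvalidTableError(f"{name} must be nonnegative")
        if np.any(self.final_demand.to_numpy() < 0):
            raise InvalidTableError("final demand must be nonnegative")

    @property
    def n_sectors(self) -> int:
        return len(self.sector_labels)

    @property
    def final_demand_total(self) -> np.ndarray:
        """Total domestic final demand per sector (sum of sub-columns)."""
        return self.final_demand.to_numpy().sum(axis=1)

    @property
    def private_consumption(self) -> np.ndarray:
        return self.final_demand["private_consumption"].to_numpy(dtype=float)

    def sector_index(self, label: str) -> int:
        try:
            return self.sector_labels.index(label)
        except ValueError:
            raise KeyError(f"sector {label!r} not in table") from None


@dataclass
class CoefficientSet:
    """Derived coefficients for the equilibrium output model.

    All members are dimensionless except ``ell`` (persons per currency
    unit).  Margin rates may be keyed per expense item or per sector;
    per-item rates take precedence in the purchasers'-to-producers'
    conversion.
    """

    A: np.ndarray
    m: np.ndarray
    v: np.ndarray
    ell: np.ndarray | None = None
    trade_margin_rate: dict[str, float] = field(default_factory=dict)
    transport_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.m.shape != (n,) or self.v.shape != (n,):
            raise InvalidTableError("coefficient dimensions do not agree")
        if np.any(self.A < 0):
            raise InvalidTableError("input coefficients must be nonnegative")
        if np.any((self.m < 0) | (self.m > 1)):
            raise InvalidTableError("import coefficients must lie in [0, 1]")
        colsums = self.A.sum(axis=0)
        if np.any(colsums >= 1):
            warnings.warn(
                "input-coefficient column sums >= 1 for some sector; "
                "the table may not be viable",
                stacklevel=2,
            )
        if np.any((self.v < 0) | (self.v > 1)):
            warnings.warn("employee-income rates outside [0, 1]", stacklevel=2)
        for item in self.trade_margin_rate:
            t = self.trade_margin_rate[item]
            d = self.transport_rate.get(item, 0.0)
            if t + d > 1 + 1e-12:
                raise InvalidTableError(
                    f"trade + transport margin rates exceed 1 for {item!r}"
                )

    @classmethod
    def from_table(
        cls,
        table: IOTable,
        trade_margin_rate: dict[str, float] | None = None,
        transport_rate: dict[str, float] | None = None,
    ) -> "CoefficientSet":
        """Derive every coefficient the pipeline needs from one table."""
        ell = None
        if table.employees is not None:
            ell = compute_employment_rates(table)
        return cls(
            A=compute_input_coefficients(table),
            m=compute_import_coefficients(table),
            v=compute_employee_income_rates(table),
            ell=ell,
            trade_margin_rate=dict(trade_margin_rate or {}),
            transport_rate=dict(transport_rate or {}),
        )


def _require_positive_production(table: IOTable) -> np.ndarray:
    X0 = table.domestic_production
    bad = np.flatnonzero(X0 <= 0)
    if bad.size:
        names = ", ".join(table.sector_labels[i] for i in bad)
        raise InvalidTableError(f"nonpositive domestic production for sector(s): {names}")
    return X0


def compute_input_coefficients(table: IOTable) -> np.ndarray:
    """Input-coefficient matrix ``A[i, j] = Z[i, j] / X0[j]``."""
    X0 = _require_positive_production(table)
    return table.Z / X0[np.newaxis, :]


def compute_import_coefficients(table: IOTable) -> np.ndarray:
    """Import coefficients: imports over total domestic demand per sector.

    Domestic demand of sector *i* is its intermediate sales (row sum of
    ``Z``) plus domestic final demand; exports are excluded because they
    are not satisfied by imports in the competitive-import convention.
    """
    demand = table.Z.sum(axis=1) + table.final_demand_total
    m = np.zeros(table.n_sectors)
    pos = demand > 0
    m[pos] = table.imports[pos] / demand[pos]
    bad = np.flatnonzero((table.imports > 0) & ~pos)
    if bad.size:
        names = ", ".join(table.sector_labels[i] for i in bad)
        raise InvalidTableError(f"imports with zero domestic demand for sector(s): {names}")
    out = np.flatnonzero((m < 0) | (m > 1))
    if out.size:
        names = ", ".join(table.sector_labels[i] for i in out)
        raise InvalidTableError(
            f"import coefficient outside [0, 1] (imports exceed domestic demand) "
            f"for sector(s): {names}"
        )
    return m


def compute_employee_income_rates(table: IOTable) -> np.ndarray:
    """Employee income divided by domestic production, per sector."""
    X0 = _require_positive_production(table)
    v = table.employee_income / X0
    if np.any((v < 0) | (v > 1)):
        warnings.warn("employee-income rate outside [0, 1] for some sector", stacklevel=2)
    return v


def compute_employment_rates(table: IOTable) -> np.ndarray:
    """Employees per unit of domestic production (persons / currency)."""
    if table.employees is None:
        raise InvalidTableError(
            "employment vector missing: employment satellite unavailable"
        )
    X0 = _require_positive_production(table)
    return table.employees / X0


def compute_margin_rates(purchaser_value: float, margin_value: float) -> float:
    """Margin rate = margin over purchasers' price, in [0, 1]."""
    if purchaser_value <= 0:
        raise ValueError("purchaser value must be positive")
    if margin_value < 0 or margin_value > purchaser_value:
        raise ValueError("margin must lie between 0 and the purchasers' price")
    return margin_value / purchaser_value


@dataclass(frozen=True)
class BalanceViolation:
    kind: str  # "row" or "column"
    sector: str
    expected: float
    actual: float

    @property
    def discrepancy(self) -> float:
        return self.actual - self.expected


def validate_io_table(table: IOTable, tolerance: float = 1e-6) -> list[BalanceViolation]:
    """Check the accounting identities of the table.

    Row balance (supply = demand): row sum of Z + final demand + exports
    - imports = domestic production.  Column balance (cost = output):
    column sum of Z + employee income + other value added = domestic
    production.  ``tolerance`` is relative to domestic production (real
    published tables carry rounding error).  Returns the list of
    violations; an empty list means the table is consistent.
    """
    X0 = table.domestic_production
    scale = np.maximum(np.abs(X0), 1.0)
    report: list[BalanceViolation] = []
    row = table.Z.sum(axis=1) + table.final_demand_total + table.exports - table.imports
    col = table.Z.sum(axis=0) + table.employee_income + table.other_value_added
    for i, label in enumerate(table.sector_labels):
        if abs(row[i] - X0[i]) > tolerance * scale[i]:
            report.append(BalanceViolation("row", label, X0[i], row[i]))
        if abs(col[i] - X0[i]) > tolerance * scale[i]:
            report.append(BalanceViolation("column", label, X0[i], col[i]))
    return report


# ---------------------------------------------------------------------------
# Delimited-text reader / writer
#
# One CSV holds the whole table.  Layout: the index column carries sector
# labels followed by the reserved value-added rows; the header carries
# sector labels, then final-demand sub-columns (any names not reserved;
# "private_consumption" required), then "exports" and "imports".  The Z
# block is the sector-rows x sector-columns corner.  Value-added rows have
# entries only under sector columns.  The "employees" row is optional.
# ---------------------------------------------------------------------------


def read_io_table(path: str | Path) -> IOTable:
    """Read an I-O table from the documented single-file CSV layout."""
    df = pd.read_csv(path, index_col=0)
    rows = [str(r) for r in df.index]
    sectors = [r for r in rows if r not in _VALUE_ADDED_ROWS]
    missing = [r for r in ("employee_income", "other_value_added", "domestic_production") if r not in rows]
    if missing:
        raise InvalidTableError(f"table file missing required rows: {missing}")
    cols = [str(c) for c in df.columns]
    if set(sectors) - set(cols):
        raise InvalidTableError("sector rows and sector columns do not match")
    fd_cols = [c for c in cols if c not in sectors and c not in _SPECIAL_COLS]
    for c in _SPECIAL_COLS:
        if c not in cols:
            raise InvalidTableError(f"table file missing required column {c!r}")
    sec = df.loc[sectors]
    employees = None
    if "employees" in rows:
        employees = df.loc["employees", sectors].to_numpy(dtype=float)
    return IOTable(
        sector_labels=sectors,
        Z=sec[sectors].to_numpy(dtype=float),
        final_demand=sec[fd_cols].astype(float).set_axis(sectors, axis=0),
        exports=sec["exports"].to_numpy(dtype=float),
        imports=sec["imports"].to_numpy(dtype=float),
        employee_income=df.loc["employee_income", sectors].to_numpy(dtype=float),
        other_value_added=df.loc["other_value_added", sectors].to_numpy(dtype=float),
        domestic_production=df.loc["domestic_production", sectors].to_numpy(dtype=float),
        employees=employees,
    )


def write_io_table(table: IOTable, path: str | Path) -> None:
    """Write a table in the layout :func:`read_io_table` reads."""
    sectors = table.sector_labels
    body = pd.DataFrame(table.Z, index=sectors, columns=sectors)
    for c in table.final_demand.columns:
        body[c] = table.final_demand[c].to_numpy()
    body["exports"] = table.exports
    body["imports"] = table.imports
    va = pd.DataFrame(
        [table.employee_income, table.other_value_added, table.domestic_production],
        index=["employee_income", "other_value_added", "domestic_production"],
        columns=sectors,
    )
    if table.employees is not None:
        va.loc["employees"] = table.employees
    out = pd.concat([body, va])
    out.index.name = "sector"
    out.to_csv(path)


def read_margin_rates(path: str | Path) -> tuple[dict[str, float], dict[str, float]]:
    """Read a margin-rate CSV: item_or_sector, trade_margin_rate, transport_rate."""
    df = pd.read_csv(path)
    required = {"item_or_sector", "trade_margin_rate", "transport_rate"}
    if not required.issubset(df.columns):
        raise InvalidTableError(f"margin-rate file must have columns {sorted(required)}")
    trade = dict(zip(df["item_or_sector"], df["trade_margin_rate"].astype(float)))
    transport = dict(zip(df["item_or_sector"], df["transport_rate"].astype(float)))
    return trade, transport


def write_margin_rates(
    trade: dict[str, float], transport: dict[str, float], path: str | Path
) -> None:
    keys = list(trade)
    pd.DataFrame(
        {
            "item_or_sector": keys,
            "trade_margin_rate": [trade[k] for k in keys],
            "transport_rate": [transport.get(k, 0.0) for k in keys],
        }
    ).to_csv(path, index=False)
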