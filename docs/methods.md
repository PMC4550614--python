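# Methods

## Equilibrium output model

The core solver computes domestic induced production under competitive
imports,

    X = [I − (I − M)A]⁻¹ [(I − M)Y + E],

where `A` is the input-coefficient matrix derived as `Z[i,j]/X₀[j]` from
the transaction matrix and domestic production, `m` the per-sector import
coefficients (imports over intermediate plus domestic final demand;
exports excluded from the denominator since imports do not serve them),
`Y` domestic final demand and `E` exports. Although the import
coefficients form a column vector, they enter the equation as `diag(m)` —
the only dimensionally consistent reading: each sector's demand leaks to
imports at its own rate.

Assumptions inherited from I–O analysis: inputs proportional to outputs
(no economies of scale), fixed coefficients over the accounting year, and
no supply constraints. Investment is excluded from the demand shock
(depreciation items never enter final demand) because its timing and
location cannot be attributed.

Numerical choices: the system is solved with a dense LU solve
(`scipy.linalg.solve`), never by materializing the inverse (exposed only
as a diagnostic). Viability is checked first via the spectral radius of
`(I − M)A`; ρ ≥ 1 raises an error citing ρ. Round-off negatives in `X`
above −1e-9 are clamped to zero and logged; anything larger raises.

## Table model and validation

`IOTable` stores the intermediate matrix at producers' prices, final
demand as named sub-columns (at minimum private consumption), exports,
imports (nonnegative magnitudes, subtracted in the row balance), employee
income, other value added, domestic production and an optional employment
row. Sector order comes from the input file and is authoritative;
mismatched label sets are an error, never silently reordered. Validation
checks row balance (intermediate sales + final demand + exports − imports
= production) and column balance (intermediate purchases + value added =
production) at a relative tolerance defaulting to 1e-6 — published tables
carry rounding, so the tolerance is configurable rather than exact.

## Cost estimation from P/L surveys

Expense-item shares for the hospital class pool hospitals and special
functioning hospitals, weighting each type's per-facility monthly P/L
values by its count of valid survey replies; clinic shares come from the
clinic records alone. Monthly values enter only through shares and the
cost/revenue ratio — they are never annualized, since national annual
expenditure supplies the scale.

The scaling ratio is implemented as **cost/revenue** (expenditure × ratio
= cost). The survey itself reports hospital revenue above cost and clinic
revenue below cost; the inverse reading would inflate hospital cost above
revenue and contradict that. This direction is therefore fixed, and the
class-specific ratios in the synthetic generator default to 0.95
(hospitals) and 1.05 (clinics) to straddle one the same way.

Expense items form a controlled vocabulary of 13 items keyed by exact
strings; each maps to exactly one I–O sector, with personnel routed to the
employee-compensation row and depreciation to fixed-capital depreciation —
both tracked for reporting but excluded from interindustry demand.
Dentistry, pharmacy and home-nursing expenses are outside the model's
scope and never appear in the vocabulary. When totals are rounded for
reports, a largest-remainder correction keeps item values summing to the
rounded total exactly.

## Impact pipeline

Purchasers'-to-producers' conversion splits each item's value `p` into
`p(1−t−d)` in its own sector, `pt` to commerce and `pd` to transport;
totals are conserved exactly. Margin rates may be keyed per expense item
(taking precedence, since final-demand-specific rates differ from
all-transaction averages) or per sector. The direct effect itself is
service revenue and carries no margins.

Design choices where the procedure is genuinely open:

- **Income base.** Employee-income rates are applied to the full
  per-sector primary impact (direct effect included) and personnel
  expenses are then added — the literal reading of the procedure. This
  plausibly double counts medical-sector labor income, so the result
  carries a note and `income_base="indirect"` restricts the rates to the
  indirect effect.
- **Consumption split.** The sectoral composition of induced household
  consumption is unstated; it defaults to the I–O table's
  private-consumption final-demand column (normalized), overridable by a
  user-supplied share vector.
- **One consumption round.** The household loop runs exactly once; there
  is no endogenized-household (closed Leontief) variant.
- **Model 2** places medical cost in the medical-service sector exactly as
  Model 1 places revenue; only the magnitude of the direct effect (and
  hence the multiplier denominators) changes.

Reports round billions to 1 decimal and multipliers to 2, as in the
published tables; internal arithmetic is full precision. The identities
primary = direct + indirect, total = primary + secondary, and
multiplier × direct = impact hold to 1e-9 relative on every run.

## Sensitivity analysis

Uncertain inputs: the consumption propensity — truncated normal with mean
0.62, sd 0.01, support [0.57, 0.67] (two decades of household survey data
are well summarized this way) — and the expense-item cost shares.
Truncated-normal sampling is exact rejection from the untruncated normal;
with bounds 5 sd out, rejections are rare.

Share distributions are fitted per item from multi-wave survey shares:
triangular with mode = mean of the two most recent waves and support =
observation range symmetrically widened by 10% of the range (floored at
zero). The original fitting software's support estimates are not
recoverable, so the widening factor is configuration, not fixed truth;
consequently published CI endpoints are not exact reproduction targets.
Items with fewer than three observations fall back to a uniform on the
observed values ±10% (a triangular fit needs at least three points; the
threshold is likewise configurable).

Each draw samples one propensity (shared by both routes) and independent
hospital and clinic share vectors, in a fixed documented order from a
single seeded generator (propensity, then hospital items in vocabulary
order, then clinic items). Sampled share vectors are renormalized to sum
to one — shares are compositional, and unnormalized draws would break the
cost-conservation identities — with a flag to disable for replication
experiments. CIs default to the 2.5th/97.5th percentiles of the draws; a
normal approximation (mean ± 1.96 sd) is available because summarizing
output distributions as normal is a common spreadsheet convention. Draws
failing viability are recorded as failed; more than 1% failures aborts.

Default 1000 draws. The percentile interval between the empirical 2.5/97.5
quantiles of n draws covers a fresh realization with probability about
0.95·n/(n+1), so coverage is effectively nominal at n = 1000 but visibly
below it for small n — the coverage test uses 1000 draws per repetition
for this reason.

## Synthetic data

The generator builds tables coefficient-first: draw `A` column-wise with
target column sums in [0.3, 0.7] (hence spectral radius < 1 and viability
guaranteed), draw import coefficients in [0, 0.3), draw final demand and
exports, solve the equilibrium for production, and back out transactions,
imports and the value-added split (employee income takes 20–70% of value
added). Balance holds by construction — no rejection sampling. The toy
economy has a medical-service sector selling only to final demand, and
explicit commerce and transport sectors to receive margins; goods items
carry trade margins in [0.05, 0.35] and transport charges in [0.01, 0.10],
service items none. P/L surveys are generated for five waves by default
(matching the survey cadence the share distributions are fitted from),
with item shares following a bounded multiplicative random walk so
triangular fits have non-degenerate supports. Default size is 8 sectors —
large enough to exercise every role distinctly while keeping the test
suite fast — with 32 available by configuration.

Everything is a deterministic function of (config, seed). What passing
tests on synthetic data do show: the accounting, conversion and solver
machinery, the statistical contracts of the sampling layer, and the
qualitative orderings (total > primary multiplier > 1, Model 2 below
Model 1 when cost < revenue). What they do not show: any statistical
resemblance to an actual national economy — the generator makes no such
attempt, and headline magnitudes from synthetic runs carry no empirical
meaning.

## Limitations

- Square symmetric tables only; no supply–use (commodity × industry)
  support, no price deflation or RAS updating, no regional tables.
- The published headline values depend on a proprietary national table and
  survey microdata; the package reproduces their arithmetic identities
  from the printed tables and validates the pipeline mechanics on
  synthetic data, but cannot re-derive the headline point estimates from
  raw inputs.
- No noncompetitive-import variant; no variance-based (Sobol) sensitivity
  indices; no correlated sampling between expense items beyond
  renormalization.
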