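# Methods

## Scope and perspective

`ecdeval` evaluates two delivery models of a group-based parenting
intervention (group-only: 16 group sessions; mixed: 12 group sessions plus
4 home-visit review sessions) against a control, from a societal costing
perspective. Estimation of the child-level intention-to-treat impacts
themselves is out of scope: the package takes effect sizes with 95% CIs as
input and carries them, with their uncertainty, through costing,
cost-effectiveness, benefit–cost and sensitivity analysis.

## Cost accounting

Costs are 2020 USD (local currency converted at 101.8 KSh/USD). The ledger
is data-driven: each `CostLine` carries a category, a perspective
(`provider_direct`, `provider_indirect`, `societal`) and an arm
(`group_only`, `mixed`, or `both` for shared items), with an amount either
computed as unit cost × quantity or carried directly for items whose
published decomposition is incomplete (e.g. venue totals). `aggregate`
sums lines into a `CostBreakdown` using exactly-rounded summation
(`math.fsum`), so totals are bit-for-bit independent of line order.

Opportunity-cost primitives (`price_time`, `mother_session_hours`,
`mother_opportunity_cost`) implement the economic-costing side: session
attendance and travel hours priced at an imputed mother wage of
US$0.19/h, CHV time at US$0.58/h, and one additional weekly hour of home
stimulation practice over three years. The packaged ledger's
mother-opportunity lines carry the published aggregate amounts rather than
this bottom-up construction, because the published aggregates are not
exactly reconstructible from the published attendance, duration and wage
parameters; the bottom-up path (with an attendance-scaling switch for the
behavioural time) is provided for fully specified ledgers.

One reconciliation: the published group-arm direct line items sum to one
dollar more than the published subtotal (whole-dollar rounding in the
source accounts). The fixture carries the travel-and-accommodation line at
US$19,719 so that line items, subtotals (42,693 / 4,730 / 8,748) and the
total (56,171) are mutually consistent.

## Cost-effectiveness

ICERs are expressed as SD improvement per US$100 invested:
`effect / (per-child cost / 100)`, under provider-only or full societal
per-child costs. Costs are treated as fixed, so the SE is the impact SE
under the same linear map. Impact SEs are recovered from the 95% CI width
divided by twice the exact normal quantile (1.959964, not 1.96); reported
tables round half-up to 2 decimals (points) and 3 decimals (SEs), matching
conventional presentation. Known caveat: in the source tables, the
mixed-arm receptive-language SEs are not consistent with that arm's
printed CI under this transformation (the CI implies 0.132/0.072-scale
discrepancy); the package follows the stated transformation.

## Lifetime projection

`pdv_lifetime_earnings` computes `Σ_a S(a) · w(a) / (1+r)^(a − a₀)` over
working ages 16–64 (the "at-least-halftime workers" convention), where
`S(a)` is survival conditional on being alive at the anchor age. Life
tables are stored anchored (S(anchor) = 1); a reader converts standard
`qx` columns by cumulative product and re-anchoring.

Choices the source material leaves open, made here once:

- **Anchor age** defaults to 2 — approximately the children's age at the
  end of the intervention — and is configurable. Because the synthetic
  wage profile is calibrated to the published PDV (below), downstream
  benefit–cost results do not depend on this choice.
- **Schooling-cost discounting.** The public cost of one extra school
  year is `schooling_cost_share` (15%) of the low-skilled basic annual
  wage, discounted from the midpoint of the schooling window (entry 6,
  exit 18 → midpoint 12) back to the anchor; an undiscounted mode exists.
  The exact basic wage behind the published US$35-per-0.93-years figure is
  not recoverable, so `benchmark_assumptions()` calibrates the low-skilled
  wage (≈ US$408/year) such that 0.93 extra years cost exactly US$35; the
  mixed arm's US$23 then follows by linearity.

## Returns to cognition

`estimate_returns` runs two multivariate OLS regressions (statsmodels) on
panel data: years of schooling, and log annual wage, each on
age-standardised cognition plus covariates (parental education, a female
indicator, survey wave, interview month, baseline grade fixed effects as
dummies). SEs are conventional homoskedastic OLS SEs by default — the
benchmark estimates (1.79 y/SD, SE 0.12; 0.397/SD, SE 0.058) are carried
as `ReturnsModel` defaults — with a cluster-robust option. Rank-deficient
designs raise an error naming the collinear columns (QR with column
pivoting).

## Benefit–cost and ROI

`evaluate_arm` composes the chain: gains `G = PDV · β·ρ_w`; long-term cost
`C = c + schooling_cost(β·ρ_s)`; `BCR = G/C`; `ROI = τ·BCR − 1` with
τ = 14.6%. Monte Carlo SEs draw ρ_w ~ N(0.397, 0.058²) and
ρ_s ~ N(1.79, 0.12²) independently (1,000 draws by default; ITT impacts
and present costs fixed), recompute BCR/ROI per draw, and report sample
SDs. Negative draws are not truncated — a negative wage-return draw
produces negative gains — and the ROI identity holds draw-by-draw.
Under this literal scheme the group-arm BCR SE is ≈ 2.25; the much smaller
SEs printed alongside the source benchmark (0.21 / 3.00 points) cannot be
produced by the scheme as described there, so the package reports its own
simulated SEs and makes no claim to match those two numbers.

## Threshold sensitivity

`solve_threshold` varies one parameter (discount rate, provider cost per
child, tax rate, wage return, schooling cost share, or long-run cognition
effect) over a generous physical range, first scanning the criterion
(BCR − 1 or ROI) on a coarse grid to verify monotonicity and a sign
change, then locating the root with Brent's method (tolerance 1e−6).
Parameters the criterion cannot respond to (tax rate × BCR) return an
explicit no-threshold marker, as do non-monotone responses — nothing is
silently bisected. When the cognition effect is varied, future schooling
costs rescale with it by default (fade-out affects both pathways); the
alternative convention is exposed and moves the break-even effect by less
than 0.005 SD. Closed forms exist for two cells — tax threshold `C/G` and
wage-return threshold `C/(PDV·β)` — and the root-finder agrees with both
to 1e−6 relative; every solved cell is also cross-checked against a
10,000-point grid scan in the test suite. The provider-cost row is
computed but, like the published version of that row, depends on
under-documented conventions and is not used as a reference value.

## Synthetic data

`ecdeval.synthetic` emulates the three external data sources, all pure
functions of a config and seed:

- **Wage profile**: worker-level lognormal wages around a Mincer-style
  quadratic-experience log-wage curve (peak around age 45), averaged by
  age over ages 16–64. A calibration mode rescales the level so the
  survival-adjusted PDV at r = 5% and anchor age 2 equals the published
  US$13,219 per child; every downstream benefit–cost quantity depends on
  the profile only through this calibrated PDV, not its shape.
- **Life table**: piecewise-constant hazards by age band (infant 3.5%,
  child, adult 0.4%/y, older-adult 1.5%/y rising 9%/y past 65), a stylised
  high-mortality-decline setting.
- **Returns panel** (default n = 5,000): cognition ~ N(0,1); schooling
  and log-wage equations embed the true returns (1.79, 0.397) plus
  covariate effects and noise (SDs 2.0 and 0.65). Parental education is
  deliberately correlated with cognition so that covariate adjustment is
  load-bearing: unadjusted estimates are visibly biased, adjusted ones
  recover the truth (coverage ≈ 95% across replicates).

What the synthetic data do **not** emulate: real labour-market features
(informal/formal sector mix, participation, migration), schooling-quality
heterogeneity, or the sampling design of the original surveys. Passing
tests therefore demonstrate that the evaluation machinery is correct and
calibrated, not that the stand-ins are statistically exchangeable with the
original microdata.

## Problem sizes and numerics

Default analysis sizes — 1,000 Monte Carlo draws, 5,000-person panels, 200
replicate panels for coverage checks, 10,000-point grid scans — run in
seconds and match the sizes used in the benchmark analyses where stated.
Money is held in floats (all fixture amounts are integral dollars, exactly
representable); half-up rounding via `decimal` is applied only when
formatting reports. Degenerate inputs (zero effects, zero-width CIs, empty
ledgers, zero mortality) are defined and tested; invalid ones (negative
costs, inverted CIs, rank-deficient designs, out-of-domain parameter
values) raise typed errors naming the offending input.

## Limitations

Benefits are wages only — no health, crime or prosociality channels — so
BCR/ROI are lower bounds under sustained impacts, and conversely assume no
long-run fade-out beyond what the sensitivity analysis explores. Costs and
ITT impacts enter the Monte Carlo as fixed. The schooling-cost and
anchor-age conventions are calibrated choices, flagged above, not
estimates.
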