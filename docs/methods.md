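# Methods

`neocea` implements a retrospective cost-effectiveness analysis of a
hospital systems-strengthening program, with the 2012–2016 maternal and
newborn program at a regional referral hospital in Accra, Ghana as the
packaged reference dataset. This note records the model, the
conventions the implementation commits to, and what the tests do and do
not demonstrate.

## Counterfactual deaths averted

The evaluation is quasi-experimental: no concurrent control exists, so
the no-intervention counterfactual is constructed from the baseline
(pre-program) year. Under the **steady-state assumption** the baseline
neonatal mortality rate (NMR) and intrapartum stillbirth rate (SBR)
would have persisted unchanged, so expected deaths in program year *t*
are

    E_t = p0 × n_t,        p0 = d0 / n0,

with `n_t` the year's deliveries and `(d0, n0)` the baseline deaths and
deliveries. Deaths averted are `E_t − O_t` (observed), summed over
post-baseline years; the baseline year contributes zero by
construction. Per-year averted values may be negative and are never
censored — the estimator is a subtraction, and censoring would bias
totals.

Two conventions matter and both are deliberate:

* **Rates are per total delivery**, not per live birth, even though
  registry rates are conventionally labelled "per 1,000 live births".
  Only the per-delivery convention reproduces the reference program's
  published expected-death series cell for cell (baseline NMR 3.11%,
  expected neonatal deaths 235/301/274/253).
* **Expected deaths are rounded half away from zero** to the nearest
  integer for display and deterministic reporting — the unique rule
  consistent with all eight published cells (e.g. 89.9 → 90,
  104.87 → 105). Inside the Monte Carlo engine expected deaths stay
  fractional (`rounded=False`): rounding inside draws would inject
  spurious discreteness into the intervals.

A generic declining-rate counterfactual (`trend_expected`) compounds
the baseline rate down by a configurable annual decline (e.g. the
1.26%/year national NMR trend) before applying it to deliveries. It
quantifies how much a secular trend erodes the steady-state estimate;
no attempt is made to reproduce any particular published
trend-attribution percentage, whose derivation is not stated in the
source material.

## Years of life lost

DALYs are computed from YLL only. YLD is excluded: long-term
disability after neonatal events cannot be estimated credibly from a
delivery registry, and the analysis follows the common practice for
neonatal cost-effectiveness work in low- and middle-income settings.

One death at age `a` with residual standard life expectancy `L` loses

    YLL = ∫₀ᴸ [ K·C·(a+x)·e^{−β(a+x)} + (1−K) ] · e^{−r·x} dx

with discount rate `r`, age-weighting modulation `K ∈ [0,1]` and the
standard age-weight `C·x·e^{−βx}`. Defaults: `r = 0.03`, `K = 1`,
`β = 0.04`, `C = 0.1658`; demography `a = 0.0192` y (early neonatal
deaths dominate), `L = 62.5` y (Ghana life expectancy at birth,
male/female average). Stillbirths use the same formula with `a = 0`
and are restricted to fresh intrapartum stillbirths (fetal heartbeat
on arrival, born dead); no value is assigned to life lost in utero
before labor.

Numerical choices:

* The closed form is evaluated with analytic limits, not epsilon
  substitution: the unweighted term uses `(1−e^{−rL})/r → L` as
  `r → 0`, and the age-weighted bracket collapses to
  `K·C·((L+a)²−a²)/2` as `r+β → 0`, so the undiscounted/unweighted
  column is exactly `L`.
* The bracket is computed as a difference of
  `G(x) = 1 −(1+x)e^{−x}`, with a series expansion below `x = 10⁻³`
  and limit branches below `x = 10⁻⁸`, keeping the closed form within
  10⁻⁶ relative of numerical quadrature over the whole valid parameter
  range (property-tested).
* Reporting rounds YLL to two decimals and DALY totals to the nearest
  integer. **Aggregation multiplies deaths averted by the two-decimal
  YLL** (e.g. 307 × 31.57 = 9,691.99 → 9,692) — the convention of the
  reference analysis; `yll_decimals=None` gives full-precision
  products (307 × 31.5679… = 9,691.4), which is what the Monte Carlo
  engine uses internally. The two conventions differ by ~0.05% and
  published tables mix them; the package exposes both.

## Cost standardization

Costs enter as a component ledger (funder, participant travel, valued
volunteer time, local-partner contributions, donated equipment) in
nominal US$ and are standardized to reference-year US$ by one
multiplicative factor per component: CPI all-items for program costs,
CPI physician-services for valued professional time, CPI medical
commodities for donated equipment, and a PPP step folded into the same
factor for local-currency items. CPI time series are not shipped; the
packaged defaults are the per-component standardization ratios of the
reference ledger, which reproduce it to the cent. Factors are looked up
by component first, then by adjustment class — components sharing a CPI
class still standardize differently when their spending profiles span
different years. Volunteer time is valued at occupational day rates
($1,100/day physicians and QI specialists, $500/day midwives/nurse
practitioners, 10-hour days); the reference program's 484 volunteer
days split 292/192 across the two rates (the unique non-negative split
matching its reported total). A small omitted NICU-renovation line
(US$4,980.28, ~0.3% of costs) can be switched back in. The analysis is
from the implementing organization's perspective and excludes
care-delivery costs.

## ICER and thresholds

ICER = (Cost_program − Cost_null)/(DALY_program − DALY_null) against a
zero-cost, zero-effect null. Non-positive incremental DALYs raise a
typed error rather than returning a signed ratio — signed ICERs are
uninterpretable without a full cost-effectiveness plane, which is out
of scope. Two decision rules: the GDP ceiling ratio (below 1× per-capita
GDP "highly cost-effective", below 3× "cost-effective"; default basis
US$1,649, Ghana's 2012–2016 average) and World Bank league-table
cutoffs (middle income: $100 "highly attractive", $500 "attractive";
low income: $25/$150). Thresholds are strict upper bounds; a value
exactly at a cutoff takes the less favourable label.

## Probabilistic sensitivity analysis

All assumptions vary simultaneously over 10,000 draws (configurable;
seeded, bit-reproducible): uniform ±10% on age at death and both life
expectancies, uniform ±25% on the standardized professional-time
value, and truncated-at-zero normals on the per-year observed neonatal
deaths, observed stillbirths, and expected (counterfactual) neonatal
deaths. Expected stillbirths are carried as fixed parameters — the
standard specification for this analysis does not vary them. Per draw
the whole pipeline is recomputed; draws with non-positive DALYs
averted are flagged undefined-ICER and excluded from ICER percentiles
with their frequency reported. Intervals are central 95% percentile
intervals whose endpoints are order statistics of the draw vector.

The standard error of a count parameter is a modelling choice, and the
package implements three conventions:

* `sample` (default): the between-year sample SD (ddof = 1) of the four
  post-baseline yearly values of the same series. This treats the
  year-to-year scatter as the relevant uncertainty and is the
  convention that reproduces the reference analysis's published
  interval bounds.
* `poisson`: SE = √count, the rare-event convention; it reproduces the
  reference analysis's abstract-style ± half-widths. The two published
  figure sets are mutually inconsistent and correspond to these two
  conventions; both are first-class here.
* `binomial`: SE = √(n·p·(1−p)) with the year's deliveries as
  denominator; narrower than Poisson by the factor √(1−p), negligible
  at these rates.

The base case attached to a PSA result is the deterministic pipeline
under the engine's own conventions (fractional expected deaths,
full-precision YLL), so a fully degenerate specification collapses to
it exactly.

## Tornado analysis

Bar ends come from one-at-a-time sweeps: each parameter set to its
marginal 5th/95th percentile with all others central. The ranking
metric is contribution to variance from the *joint* draws: squared
Spearman rank correlation between parameter and output, normalized to
sum to one over parameters (invariant to monotone rescaling of any
parameter). Both are emitted so either convention can be inspected;
reports suppress entries under 4% by default. Under the `sample`
convention all four expected-neonatal years share one SE, so their
contributions are equal in expectation (~14% each) and their relative
order in any single run is Monte Carlo noise.

## Synthetic data and what the tests show

The generator emulates the statistical structure the steady-state
analysis assumes: year-*t* deaths are Binomial(deliveries_t, rate_t)
with `rate_t = baseline × (1 − secular_decline)^t × effect_t`,
independently for neonatal deaths and stillbirths. Binomial rather
than Poisson because deliveries are a known finite denominator,
making deaths ≤ deliveries hold by construction. The generating
scenario travels with the data, so recovery experiments compare the
pipeline against the generator's own expectations. Default scenario
scale (~10,000 deliveries/year, NMR ~3%, four program years) mirrors a
large referral maternity unit; recovery experiments use 300–400
replicates, enough to resolve biases of a few deaths against a
replicate SE of ~3.

What passing tests demonstrate: the estimator is unbiased when the
steady-state assumption is true; injected multiplicative effects are
recovered within binomial sampling error; and a pure secular decline
produces a strictly positive "averted" total — quantifying the
steady-state counterfactual's documented optimism. What they do not
demonstrate: anything about real registries, where referral-mix and
case-severity shifts, demand-side change, reporting artefacts and
non-multiplicative dynamics are all outside the generator. The
synthetic null is a calibration of the arithmetic, not evidence of
causal attribution.

## Known limitations

* Causal attribution is assumed, not identified: the steady-state
  counterfactual absorbs every secular improvement into the program's
  effect, and conversely a rising referral acuity would bias it the
  other way. The trend counterfactual and the recovery experiments
  bound, but do not resolve, this.
* Parameters are sampled independently; correlated uncertainty (e.g.
  between yearly counts) is not modelled.
* Single scalar life expectancy; no country life table, no YLD, no
  disability weights.
* Cost-effectiveness acceptability curves, net monetary benefit and
  multi-comparator frontiers are out of scope.
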