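# Methods

## The decision problem

Two strategies for replacing one missing molar are compared from the
patient's perspective over a 30-year horizon: starting with an
implant-supported single crown (ISC) or with a three-unit fixed dental
prosthesis (FDP). Each strategy is a small state-transition model in which
the current prosthesis eventually fails and is replaced by the clinically
indicated successor, ending in the absorbing missing-tooth (MT) state:

- ISC arm: ISC1 → ISC2 → FDP → MT, with a failed second crown going to a
  bridge with probability 0.998 and directly to MT with 0.002;
- FDP arm: FDP1 → FDP2 → DIB → MT, with a failed second bridge going to a
  double implant-supported bridge (DIB) with probability 0.846 and to MT
  with 0.154.

The outcome unit is the quality-adjusted prosthesis year (QAPY): one year
weighted by the quality weight of the state occupied (ISC 74.75, FDP 71.47,
DIB 59.19, MT 0 on a 0–100 scale, divided by 100 at accrual). Costs are in
CZK; a USD figure appears in reports only through a fixed display constant
(0.048 USD/CZK).

## Survival of prostheses

Longevity enters as a parametric survivor function per prosthesis type.
The supported workflow mirrors how published curves are actually used:

1. **Kaplan–Meier estimation** (`km_estimator`, via lifelines) from raw
   censored event times, or a digitized curve read from CSV.
2. **Pseudo-individual reconstruction**: each drop of the curve becomes a
   weighted event placed at the midpoint of the interval over which the
   drop occurred (events are only known to lie between successive curve
   points; midpoint placement makes the fit unbiased on noiseless gridded
   curves, recovering generating Weibull parameters to ~1e−4 relative).
   Residual survival at the last point becomes a censored observation.
   At-risk counts are unavailable from a digitized curve, so weights are
   the unconditional drop fractions.
3. **Weighted maximum likelihood** per candidate family (exponential,
   Weibull, log-normal, log-logistic; lifelines fitters), with a
   least-squares fallback on the log(−log S) scale for degenerate Weibull
   inputs. **Selection** keeps the highest log-likelihood; candidates
   within a tolerance (default 1e−6) are tied and the tie goes to the
   family with fewer parameters.
4. **Per-cycle failure**: the engine consumes the conditional probability
   1 − S(a)/S(a−1) that a prosthesis in its a-th year of service fails
   during it. Extrapolation beyond observed follow-up is the parametric
   S(t), which is what makes a 30-year horizon usable.

### Calibrated parameters

No per-prosthesis Weibull parameters are published numerically, so the
packaged configuration ships **calibrated** values — chosen once to give
the expected qualitative longevity ordering (ISC longest-lived, DIB
intermediate, FDP shortest at long horizons) at magnitudes typical of
published prosthesis survival — and labels them as calibrated in the file:

| prosthesis | shape k | scale λ (years) | S(10) | S(30) |
|---|---|---|---|---|
| ISC | 1.6 | 48 | 0.92 | 0.62 |
| FDP | 1.8 | 28 | 0.86 | 0.32 |
| DIB | 1.7 | 35 | 0.89 | 0.46 |

Every absolute cumulative result (costs, QAPY, break-even utilities)
depends on these values; the qualitative verdict — the ISC arm cheaper and
more effective, hence dominant at 30 years — is what the package asserts,
and it is robust across the deterministic sensitivity suite except for
±30% utility variation, where dominance gives way to a trade-off exactly as
a one-way utility sweep should show.

## Cohort engine

- **Tunnel states.** Occupancy is a map (state, residence age) → fraction;
  tunnel depth equals the horizon (exact, at most horizon × |states|
  strata, trivially cheap at 1-year cycles). Residence age, not model
  time, drives both the failure probability and the annual cost band (a
  replacement restarts in band "years 1–2"); a configuration switch
  (`cost_band_keying: model_time`) keys bands to model time instead.
- **Cycle order.** During cycle t the cohort occupying strata at the start
  of the cycle accrues utility/annual costs, discounted; failures are then
  resolved at the cycle boundary and redistributed per the failure rules.
  A replacement's entry cost and its first annual-band cost are charged in
  its entry cycle (t + 1), with that cycle's discount factor. Fractions
  redistributed at the final boundary have no cycle left inside the
  horizon and are therefore not charged an entry cost.
- **Discounting.** Default convention leaves the first year undiscounted
  (factor (1+r)^−(t−1); "discounted beyond one year") at r = 3%. Because
  published cumulative values could not be reproduced without knowing the
  original tool's timing convention, two alternatives are exposed:
  discounting from the first cycle ((1+r)^−t) and an additional
  undiscounted cycle-0 state reward. A half-cycle correction (averaging
  start- and end-of-cycle occupancy in the accrual) is available and off
  by default, since the study describes none.
- The cohort is deterministic; the engine uses no random numbers.
  Occupancy conservation holds to < 1e−12 at every cycle, and on
  constant-hazard toy models the engine equals the closed-form geometric
  cohort to < 1e−12 per cycle.

## Costs

- Initial costs are the arithmetic mean of three clinical treatment
  variants per strategy, rounded to whole CZK as the base case uses them
  (ISC (35,485 + 36,918 + 48,454)/3 → 40,286; FDP → 40,161). The exact
  mean is available through `mean_initial_cost`.
- The DIB composite rule (one third of the bridge variant-A cost plus
  twice the crown variant-B cost) yields 84,620.00 on the printed variant
  costs, which does not equal the tabulated 83,072.82; the tabulated value
  is the packaged default and the rule is exposed for what-if use.
- MT entry cost depends on the source state: 1,600 CZK from a bridge
  (extraction of abutment teeth), 14,358 CZK from a crown or DIB
  (explantation).
- The indirect-cost helpers implement lost earnings
  ((1 − unemployment) × hourly × hours, with hourly earnings
  36,144/(40 × 4.348) = 207.82 CZK/h) and transport as a *return* journey
  per visit (2 × 32 CZK); treatment hours and visit counts are inputs, not
  constants, because the tabulated totals already include them.

## Sensitivity analysis

All analyses perturb numeric leaves of the configuration document by dotted
path, rebuild and re-run, so a shared parameter such as `utilities.FDP`
consistently moves every bridge state in both arms. Utilities are varied
multiplicatively on the stored 0–100 scale (the −30% crown-utility point is
0.52325 on the 0–1 scale). Sweeps default to 13 grid points over ±30% (5%
steps) so the base case lies on the grid and is reproduced bit-for-bit
there. The tornado evaluates each parameter at ±30% and sorts by the ICUR
swing. The break-even search bisects on the dominance margin
min(−ΔC, ΔE) — positive exactly when the evaluated arm dominates, crossing
zero where either increment changes sign — to the requested parameter
tolerance (default 1e−6). Discount scenarios are 0%, 3%, 5%; horizons run
5–55 years in 5-year steps.

## Synthetic data

`simulate_survival_data` emulates the assumed data structure: event times
from the specified family, independent exponential censoring whose rate is
solved (via the Laplace transform of the event distribution and bracketed
root finding) so the expected censored fraction equals the requested rate,
plus administrative censoring at end of follow-up. It reproduces the
marginal censoring pattern only — no covariates, no clustering of failures
within patients, no informative censoring — so passing recovery tests show
the fitting pipeline is correct under its own assumptions, not that real
clinic data satisfy them. `make_toy_geometric_model` builds the two-state
constant-hazard arm whose closed forms serve as the engine oracle, and
`reference_fixture_bundle` writes a byte-reproducible fixture directory (base
configuration plus one simulated dataset per prosthesis from the calibrated
parameters; default n = 500 per curve, 20% random censoring, 40-year
administrative cut-off).

## Problem sizes and numerical choices

- Base case: deterministic, 30 cycles, two arms of 4 states — milliseconds.
- Parameter-recovery study: 20 replicates of n = 500 with 20% censoring;
  median relative error of Weibull shape and scale ≈ 2–3%, within the 5%
  design target.
- Model selection tolerance 1e−6 on total weighted log-likelihood;
  threshold-search tolerance 1e−6 on the parameter axis; conservation and
  oracle checks at 1e−12.
- Degenerate inputs: fitting needs ≥ 3 curve points and at least one
  observed event; conditional failure is undefined once S(a−1) underflows
  to 0 (the engine never reaches this with the packaged parameters);
  ICUR is reported as undefined (not ±∞) when ΔE = 0 and the verdict then
  rests on cost alone.

## Known limitations

- Background mortality is not modelled: the cohort ages 30 years with no
  competing death risk, so late-cycle costs and utilities are upper bounds.
- Utilities and transition probabilities are time-invariant; only
  prosthesis failure is age-dependent.
- Published cumulative headline values are not exactly reproducible from
  printed inputs alone (they depend on unpublished survival parameters and
  the original tool's discount-timing convention; the source text itself
  carries two inconsistent cumulative-utility pairs), which is why the
  test suite asserts structural properties and the qualitative dominance
  verdict rather than those absolute numbers.
- One-year cycles only; no probabilistic sensitivity analysis (none was
  performed in the underlying evaluation).
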