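# dentalcua

A Markov cohort cost-utility model for single-tooth prosthetic treatment,
built for health economists and dental researchers comparing an
**implant-supported single crown (ISC)** against the conventional
**three-unit fixed dental prosthesis (FDP)** from the patient's perspective.

When a molar is lost, the patient chooses between an implant crown and a
bridge anchored on the two ground-down neighbouring (abutment) teeth. Either
prosthesis eventually fails and is replaced — a failed crown by a second
crown and later a bridge, a failed bridge by a second bridge and later a
double implant-supported bridge (DIB) — until the tooth is left missing (MT,
the absorbing state). The model follows a cohort through these states over a
30-year horizon in one-year cycles and asks which initial strategy buys more
prosthesis-quality per koruna.

## Model

- **States and transitions.** Each arm has four health states
  (ISC arm: ISC1 → ISC2 → FDP → MT; FDP arm: FDP1 → FDP2 → DIB → MT) with
  fixed failure-destination probabilities (e.g. a failed second crown goes
  to a bridge with probability 0.998 and straight to MT with 0.002).
- **Time-dependent failure.** Prosthesis longevity is a parametric survival
  function S(t) (Weibull by default, S(t) = exp(−(t/λ)^k)); the chance that
  a prosthesis in its *a*-th year of service fails during that year is the
  conditional probability 1 − S(a)/S(a−1). Because this depends on
  prosthesis age rather than model time, the cohort is tracked over
  (state, residence-age) tunnel strata.
- **Survival workflow.** Digitized Kaplan–Meier points (or raw censored
  event times) are fitted by weighted maximum likelihood over
  pseudo-individual event data reconstructed from the curve steps;
  candidate families (exponential, Weibull, log-normal, log-logistic) are
  compared by log-likelihood, ties broken toward parsimony. The packaged
  Weibull parameters are *calibrated* to the expected longevity ordering of
  the three prosthesis types, not extracted from any clinical dataset.
- **Costs and utilities.** Costs (CZK, patient perspective) comprise a
  one-off initial/entry cost per prosthesis (the mean of three clinical
  treatment variants), banded annual maintenance costs keyed to prosthesis
  age, and source-dependent entry costs into MT. Utilities are quality
  weights on a 0–100 scale (ISC 74.75, FDP 71.47, DIB 59.19, MT 0),
  accrued per cycle as quality-adjusted prosthesis years (QAPY). Costs and
  utilities are discounted at 3%/year beyond the first year.
- **Comparison.** Per-arm cost-effectiveness ratios C/E, incremental cost
  ΔC and outcome ΔE, the incremental cost-utility ratio ICUR = ΔC/ΔE, and a
  dominance verdict located on the cost-utility plane (ΔC < 0 with ΔE > 0 —
  the lower-right quadrant — means the evaluated arm dominates).
- **Sensitivity.** One-way ±30% sweeps, a tornado diagram over the six main
  cost/utility parameters, bisection for break-even parameter values,
  0%/5% discount scenarios and 5–55-year horizon sweeps.

## Worked example

```python
import dentalcua as d

model = d.make_reference_config()      # the packaged base case
outcome = d.run_cua(model)
cea = outcome.cea
usd = model.environment.czk_to_usd
print(f"{cea.evaluated_name}: {cea.evaluated_cost:,.2f} CZK, "
      f"{cea.evaluated_utility:.2f} QAPY, CE {cea.evaluated_ce:,.2f} CZK/QAPY")
print(f"{cea.comparator_name}: {cea.comparator_cost:,.2f} CZK, "
      f"{cea.comparator_utility:.2f} QAPY, CE {cea.comparator_ce:,.2f} CZK/QAPY")
print(f"incremental: {cea.incremental_cost:,.2f} CZK, "
      f"{cea.incremental_utility:.2f} QAPY")
print(f"ICUR: {cea.icur:,.2f} CZK/QAPY ({cea.icur * usd:,.0f} USD/QAPY)")
print(f"verdict: {cea.dominance.value} ({cea.plane_quadrant.value} quadrant)")
```

prints

```
ISC: 130,285.97 CZK, 15.08 QAPY, CE 8,640.67 CZK/QAPY
FDP: 144,908.56 CZK, 14.30 QAPY, CE 10,133.60 CZK/QAPY
incremental: -14,622.60 CZK, 0.78 QAPY
ICUR: -18,785.14 CZK/QAPY (-902 USD/QAPY)
verdict: evaluated_dominant (se quadrant)
```

Over 30 years the implant-crown strategy costs about 14,600 CZK less and
yields 0.78 more quality-adjusted prosthesis years than the bridge
strategy, so it *dominates*: the negative ICUR with positive ΔE places the
comparison in the lower-right quadrant of the cost-utility plane, where no
willingness-to-pay threshold is needed to call the evaluated arm
cost-effective. The absolute cumulative values depend on the calibrated
survival parameters shipped with the package (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
dentalcua run --config model.yaml --out results/
dentalcua sensitivity --config model.yaml --out results/ --mode tornado \
    --param costs.FDP.initial --param utilities.ISC
dentalcua simulate --family weibull --shape 1.5 --scale 20 --n 500 --out sim.csv
dentalcua fit --data sim.csv --out fit.csv
```

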