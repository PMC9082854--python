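# vphi-demand

Price and income elasticity of **voluntary private health insurance (VPHI)
take-up**, estimated from household expenditure survey microdata.

In countries with near-universal mandatory health coverage (the motivating
case is Colombia's contributory system and its supplementary "prepaid
medicine" plans), a small share of households buys private insurance on top
of the public scheme. Expenditure surveys record what those households pay —
but only for buyers, and the premium is endogenous to the purchase decision.
This package implements the estimator chain that deals with both problems,
for analysts who want to run it on survey extracts or study its behaviour
on synthetic data:

1. **Reduced-form participation probit** on controls, log income and
   household size;
2. **Heckman-corrected premium equation** — OLS of the log premium on the
   same design plus the inverse Mills ratio λ = φ(q)/Φ(q) at the fitted
   selection index, over purchasers only, with *household size* as the
   instrument (family plans charge per covered member; size moves the bill
   but not the taste for insurance);
3. **Fitted-value instrumented probit**: participation on the *predicted*
   log premium Z'δ̂, log income and controls,

       vphi = 1  iff  β₀ + β₁·ln p̂ + β₂·ln y + X'γ + ε > 0;

4. **Semi-elasticities and elasticities** from probit average marginal
   effects: AME(v) = mean φ(x'β̂)·β̂ᵥ, and ε_p = AME(p)/E[vphi],
   ε_y = AME(y)/E[vphi];
5. **Bootstrap inference** (the second stage feeds a generated regressor
   into the third, so analytic SEs are invalid): household resampling,
   all stages re-run per replicate.

Around the estimator: the 30 USD/month truncation rule that discards
misreported low-value "premiums", reporting-sample restrictions
(non-informal heads, middle-income-and-up), heterogeneity by age group /
elderly member / young children with group-equality tests, a truncation
sensitivity sweep, and a synthetic survey generator with correlated
selection errors, instrument relevance, and low-value contamination — plus
the latent ground truth real data never has.

## Worked example

```python
import vphi_demand as v

params = v.StructuralParams()                      # documented default calibration
survey = v.generate(params, n=50_000, seed=1)      # synthetic households + latent truth

sample = v.derive_vphi_indicator(survey.records, threshold=30.0)
result = v.estimate_sample(sample)                 # probit -> Mills -> price eq -> IV probit

for key in ("beta1", "ame_price", "participation_share",
            "elasticity_price", "elasticity_income"):
    print(f"{key:22s} {result.stats[key]: .4f}")
```

prints

```
beta1                  -1.3946
ame_price              -0.0926
participation_share     0.0369
elasticity_price       -2.5089
elasticity_income       1.8075
```

Reading: on this draw the instrumented probit recovers a price coefficient
near the true β₁ = −1 (up to the fitted-value scale factor and sampling
noise; see `docs/methods.md`), the purchase probability falls by about
0.093 per unit increase of the log premium, and — dividing by the 3.7%
take-up share — demand is elastic: a 1% premium increase reduces VPHI
participation by about 2.5%. Income pushes the other way (elasticity +1.8):
VPHI behaves like a luxury good.

The same chain runs from the shell, end to end:

```bash
vphi-demand simulate -n 50000 --seed 1 --out scratch/sim
vphi-demand report --input-csv scratch/sim/records.csv --threshold 30 \
    --seed 1 --out scratch/report
```

which writes `descriptives.csv` (three-group summary statistics),
`estimates.csv` (AMEs, shares, elasticities, bootstrap SEs and p-values per
restriction column), `coefficients.csv` (all three stages),
`heterogeneity_*.csv`, `sweep.csv`, a premium histogram and a JSON manifest
that makes the run replayable. Real survey extracts work the same way; a
YAML config can remap column names and set a COP→USD conversion rate.

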