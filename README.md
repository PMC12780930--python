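# agemix

Donor–recipient **age-mismatch** analysis for liver-transplant
registries, with a counterfactual **broader-sharing** simulation for
adolescent donor grafts.

In US liver allocation, pediatric donor livers are offered to pediatric
candidates within 500 nautical miles (NM) of the donor hospital; when no
candidate accepts, adolescent grafts frequently go to adults, and
adolescent recipients — often the sickest ones — accept grafts from
donors 10 or more years older than themselves. `agemix` packages the
full analytic chain needed to study the long-term consequences of this
practice and of policy alternatives:

1. **Synthetic registry generation** — national transplant-outcome files
   (OPTN/UNOS STAR) are access-restricted, so the package ships a seeded
   generator that emulates their statistical structure: a latent acuity
   score confounding mismatched-graft acceptance with MELD / status 1 /
   ICU admission, piecewise-constant graft-failure hazards with a
   *late-emerging* exposure effect, right censoring, an adult-recipient
   stream of adolescent-donor grafts, and hospital geography.
2. **Cohort derivation** — inclusion rules (recipients aged 12–17,
   brain-dead donors, liver-only), Du Bois body-surface-area index and
   graft size classes, center-volume tertiles, era and policy flags,
   and 10-year-censored graft/patient survival outcomes.
3. **Propensity-score matching** — logistic exposure model, greedy 1:1
   nearest-neighbor matching without replacement within a caliper
   (default 0.1 on the score scale), and standardized-mean-difference
   balance tables.
4. **Survival analysis** — Kaplan–Meier curves, log-rank tests, Cox
   proportional-hazards models (Efron ties, Wald CIs), and **landmark
   analyses** that reset time 0 at 1 and 5 years post-transplant to
   separate early and late risk.
5. **Counterfactual reallocation** — for each age-mismatched index
   transplant under the current policy, scan the observed stream of
   adolescent-donor grafts given to adults on days 1–90, keep those
   within ±20 kg of the index recipient's weight and within a
   travel-distance ceiling (500 / 1000 / 1500 NM / unlimited), and
   report the **p90 wait**: the smallest day by which ≥90% of index
   recipients would have received an age-matched offer.

## The model in brief

Exposure is *age mismatch*: donor age − recipient age ≥ 10 years
(signed; a much younger donor is not exposure). Graft survival runs
from transplant to retransplant or death, censored at 10 years, last
follow-up, or the administrative cutoff. The landmark Cox hazard ratio
at landmark L keeps only subjects event-free and under follow-up at L,
resets the clock, and fits

&nbsp;&nbsp;λ(t | x, z) = λ₀(t) · exp(β·x + γᵀz),&nbsp;&nbsp; t > L,

with x the exposure flag and z the adjustment covariates (graft
type/size, donor and recipient sex and mismatch, recipient BSA,
diagnosis, cold ischemia ≥ 8 h, MELD, status 1, admission status,
center volume). The synthetic generator plants a null hazard ratio on
years (0, 5] and exp(β_late) = 1.67 on years (5, 10], so the pipeline's
ability to recover a late-emerging effect is testable.

## Worked example

```python
import agemix

cfg = agemix.RunConfig(registry=agemix.RegistryConfig(),  # default study conditions
                       out_dir="out", seed=1)
summary = agemix.run_pipeline(cfg)
print(summary["cohort"], summary["matching"]["n_pairs"])
print(summary["survival_unmatched"]["graft"]["arms"])
print([ (r["ceiling_nm"], r["p90_wait_days"]) for r in summary["reallocation"] ])
```

With seed 1 this prints (numbers produced by the run above):

```
{'n_input': 2020, 'n_retained': 2020, 'n_mismatched': 614, 'mismatched_pct': 30.4} 528
{'mismatched': {'km_survival_at_horizon_pct': 61.3, 'n': 614, 'events': 185},
 'matched':    {'km_survival_at_horizon_pct': 75.9, 'n': 1406, 'events': 266}}
[(500.0, 28), (1000.0, 11), (1500.0, 8), (None, 5)]
```

Reading: 30.4% of the 2020 synthetic adolescent transplants are
age-mismatched; matching yields 528 pairs with all post-matching
|SMD| < 0.1; 10-year Kaplan–Meier graft survival is 61.3% in the
mismatched arm vs 75.9% in the matched arm (the planted late hazard
deficit); and raising the distance ceiling shortens the p90 wait for an
age-matched offer from 28 days at 500 NM to 5 days with no limit.

The same stages are available from a shell:

```bash
agemix simulate --seed 1 --out registry/
agemix run --seed 1 --out results/
```

## Layout

```
src/agemix/
  synthetic_registry.py   seeded registry generator + CSV/YAML I/O
  cohort.py               inclusion rules and derived covariates
  psm.py                  propensity model, 1:1 caliper matching, SMDs
  survival.py             KM / log-rank / Cox / landmark (lifelines-backed)
  reallocation.py         great-circle distances and wait-time simulation
  pipeline.py             end-to-end orchestration and trend tables
  cli.py                  click CLI (`agemix`)
docs/methods.md           model, assumptions, parameter choices, limits
```
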