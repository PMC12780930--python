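# Methods

This note documents the models, assumptions, parameter defaults, and
design choices behind `agemix`. It states no empirical claim that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Study design being emulated

The package implements the analytic chain of a registry case-control
study of adolescent (12–17 y) liver-transplant recipients: exposure is
receipt of a graft from a donor at least 10 years older than the
recipient; the primary outcome is 10-year graft survival (transplant to
retransplant or death); confounding arises because sicker candidates
(higher MELD, status 1, ICU admission) are more likely to accept an
age-mismatched offer; and a counterfactual simulation asks how long
age-mismatched recipients would have waited for an age-matched graft
had adolescent donor livers been shared over wider distances.

The real data for such a study (the national OPTN/UNOS STAR file) are
restricted. Everything here therefore runs against a synthetic
registry; what passing tests demonstrate is that the *estimators and
the pipeline* behave correctly under a known generative model, not that
any real-world effect has a particular size.

## 2. The synthetic registry generator

All distributional choices are stand-ins chosen for plausibility and
for exercising the downstream analysis; none are estimates from the
restricted data.

**Latent acuity.** Each adolescent recipient carries one standard
normal latent score A. Admission category (ICU / ward / home) and
status 1 are fixed-threshold indicators of A (thresholds set to give
roughly 27% ICU, 14% ward, 32% status 1 marginally); MELD is the linear
map `round(17 + 7.5·A)` clipped to the registry's 6–40 range; acute
liver failure probability rises with A. A single latent is the simplest
structure that makes all acuity covariates jointly imbalanced between
exposure groups, the pattern the analysis must remove.

**Exposure assignment.** P(mismatched | A) = logistic(α + c·A) with
`confounding_strength` c = 0.9 log-odds per SD by default; α is solved
by Gauss–Hermite quadrature so the marginal prevalence equals
`frac_mismatched_target` (default 0.303). c = 0.9 was chosen so the
implied pre-matching standardized mean differences on the acuity
covariates land near 0.7, the magnitude reported for MELD, status 1
and ICU admission in the national cohort this generator emulates.

**Donor ages.** Mismatched donors: recipient age + 10 + Gamma(1.8, 7)
years (median gap ≈ 20 y). Matched donors: recipient age + N(1, 4²)
truncated above at +9. Ages are whole years, as registries report them.

**Survival.** Graft-failure times are drawn from a piecewise-constant
yearly hazard. The baseline (per-year rates 0.08, 0.03, 0.025 ×3,
0.02 ×5, extended beyond year 10) gives ≈75% 10-year baseline graft
survival with a front-loaded first year. The exposure multiplies the
hazard by `exp(exposure_log_hr_early)` on (0, 1] years, 1 on (1, 5],
and `exp(exposure_log_hr_late)` on (5, 10] and beyond; defaults are
early = 0 and late = ln 1.67, i.e. a purely late-emerging deficit.
Acuity multiplies the hazard by `exp(0.30·A)` (`acuity_log_hr`); this
confounder→outcome link is required for the exposure–outcome
association to be genuinely confounded, which the matching and
adjustment tests rely on. Because the hazard is multiplicative in
(exposure, A) with no unobserved frailty, the conditional hazard ratio
within any landmark window equals the planted one, making parameter
recovery a well-defined check. Event type: a generated failure is a
death with probability 0.64, otherwise a retransplant (graft loss
without death). Censoring: independent exponential loss to follow-up
(0.02/yr) plus administrative censoring at `admin_censor_date`
(default 2025-04-04); transplant dates are uniform over the window
(default 2002-03-01 to 2024-12-31).

**Geography and supply.** Hospitals are uniform in a continental-US
bounding box (103 of them by default, matching the national center
count); center volumes follow a log-normal weight distribution so the
volume tertiles are populated. The adult-recipient stream of
adolescent-donor grafts (default n = 5401 over the window) is generated
independently of adolescent outcomes — the reallocation module treats
it as exogenous supply, mirroring the retrospective design.

**What the generator does not emulate:** waiting-list dynamics before
transplant, DCD and living-donor streams, real US hospital locations
(uniform geography makes distance ceilings bind less sharply than in
reality, so simulated p90 waits are shorter at 500 NM than published
real-data waits), center-level practice variation beyond volume, and
secular trends in acceptance behavior. Passing tests therefore say
nothing about real-data effect sizes; they validate estimator behavior.

## 3. Cohort rules and derived covariates

Inclusion: recipient age 12–17, donor type DBD, not multiorgan, within
the date window. The criteria are independent boolean masks, so filter
composition is order-free (tested). Rows missing a required field are
dropped with a row-level log entry; rows missing height/weight keep NaN
size covariates and are excluded from matching (complete case).

BSA uses the Du Bois formula 0.007184·h^0.725·w^0.425 (h cm, w kg).
The BSA index (donor/recipient) classifies grafts as small (< 0.78),
normal (0.78–1.24, closed), large (> 1.24); it is undefined for
split/reduced grafts, which form their own size class. Center volume
uses fixed tertile cutoffs (high ≥ 57, middle 28–56, low < 28 cases
over the period). The exposure difference is signed: donor ≥ 10 years
*older*. Survival times are censored at min(last follow-up,
administrative date) and then truncated at the 10-year horizon
(configurable; `horizon_years=None` disables truncation).

## 4. Matching

The propensity model is a maximum-likelihood logistic regression of
exposure on graft size class, donor sex, sex mismatch, center volume,
recipient age/sex/BSA, diagnosis, MELD, status 1, and admission status,
with one-hot encoding against documented reference levels; constant
columns are dropped with a warning, and perfect separation raises with
advice to use the ridge (`fit_regularized`) fallback.

Matching is greedy 1:1 nearest-neighbor without replacement. Design
choices the source design left open, fixed here: the caliper default is
0.1 **on the propensity-score scale** (the most literal reading of
"caliper 0.1"), with `caliper_scale="logit"` giving the common
0.1 × SD-of-logit alternative; exposed rows are processed in a seeded
random permutation (avoids sort-order artifacts); ties between
equidistant controls break to the lowest row id. Balance is the SMD
with unbiased variances (continuous), the proportion-based formula
(binary), and the maximum absolute indicator SMD (multi-level
categoricals); zero pooled variance with equal means is defined as 0.

## 5. Survival analysis

Kaplan–Meier, log-rank, and Cox PH are delegated to lifelines behind
the module surface; the test suite checks them against hand-computed
product limits, an independently coded O−E/hypergeometric-variance
score statistic (the log-rank statistic equals the Cox score test at
β = 0 for a binary group), exponential closed forms at n = 20 000, and
a 1000-replicate type-I-error calibration. Ties use Efron's method
(lifelines' default; lower bias than Breslow), CIs are Wald on the
log-HR scale — both conventional choices where the source design is
silent.

Landmark restriction at L with horizon H: subjects whose follow-up ends
at or before L (including censoring exactly at L, who are not "under
follow-up" beyond it — a documented boundary choice) are excluded,
remaining times are shifted by −L, and follow-up is truncated at H − L.
The 1-to-5-year window hazard ratio is obtained as landmark 1 with
horizon 5.

## 6. Reallocation simulation

Distances are haversine great circles on a sphere of radius
6371.0088 km, converted at 1 NM = 1852 m, between the index recipient's
hospital and the candidate donor's hospital. A candidate graft for an
index case must be: from an adolescent (12–17 y) DBD donor, a whole
graft (splits excluded), transplanted into an adult on days 1–90 after
the index date, with donor weight within ±20 kg of the index
recipient's weight, and within the scenario's distance ceiling. Marked
size mismatch is operationalized solely by the ±20 kg rule — no
additional BSA screen. Records with unknown hospital coordinates are
skipped with a log entry.

By default index cases do **not** compete for grafts: each keeps the
full candidate stream, consistent with a per-candidate offer-list
reading of the design; `consume=True` provides a
first-come-first-served sensitivity mode (index cases in date order,
each removing its first-arriving graft). The p90 wait is the smallest
day d at which the empirical fraction of index cases with a candidate
on days 1..d reaches 0.90, reported as undefined (`None`) if 90% is
never reached within the window; the standard empirical percentile is
used even though a complementary "no arrivals in the remaining 10%"
phrasing exists, which is not a standard percentile.

## 7. Pipeline, problem sizes, and numerics

`run_pipeline` executes simulate → cohort → match → survival →
reallocate → trends, writes every stage CSV plus `summary.json`, and is
deterministic for a fixed config and seed (all randomness flows from
one integer through `numpy.random.default_rng`). The default registry
size is the emulated cohort's: 2020 adolescent transplants and 5401
adult-stream grafts. Parameter-recovery checks use 20 000 transplants
per replicate — large enough that the 5-year-landmark Cox SE on the log
hazard ratio is ≈ 0.07, so replicate means isolate bias from noise —
with 20 replicates in the test suite and 10 in the acceptance script.
Calibration tolerances are stated in sampling units (3 SE) rather than
absolute numbers wherever a closed form exists.

Degenerate inputs are errors, not silent defaults: empty samples for
KM, empty risk sets at a landmark, no events or constant covariates in
Cox, zero pooled variance with unequal means in the SMD, non-positive
heights/weights in the BSA, out-of-range coordinates in the distance.

## 8. Known limitations

- Uniform hospital geography compresses the spread between distance
  ceilings; only the ordering of p90 waits, not their values, is
  meaningful.
- The single-latent acuity model makes admission, status 1 and MELD
  deterministic functions of one score; real acuity is
  multidimensional, so matching here is easier than in real data.
- The generator's diagnosis, anthropometric and waiting-time
  distributions are plausibility stand-ins, not fitted quantities.
- No modeling of offer refusal, cold-ischemia feasibility, competing
  risks, or allocation-sequence mechanics in the reallocation
  counterfactual.
- Retransplant is encoded as graft loss without death; re-entries onto
  the waiting list are not modeled.
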