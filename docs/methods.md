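# Methods

`bpgrs` implements a gene–environment interaction analysis for urothelial
carcinoma (UC) in men: a weighted genetic risk score (wGRS) for bladder
cancer, cause-specific Cox models of blood pressure (BP) and the score on
the attained-age time scale, additive and multiplicative interaction
inference, and competing-risk absolute risk. Because individual-level
cohort data of this kind are not openly distributable, the package ships a
synthetic-cohort generator that reproduces the statistical structure of
such a study and lets every stage be tested against known truths.

## Weighted genetic risk score

For individual *i* with genotype dosages `d_ix ∈ [0, 2]` (expected count of
effect alleles at variant *x*) and GWAS log odds ratios `β_x = ln(OR_x)`,

```
wGRS_i = ( Σ_x β_x · d_ix ) / n_SNPs .
```

The division by the number of SNPs is a pure rescaling retained for
fidelity with the published equation; z-scored versions of the score are
invariant to it. The packaged panel holds 18 bladder-cancer variants with
their effect/other alleles, effect-allele frequencies (EAF) and odds
ratios. The loader always recomputes `ln(OR)` at full floating precision
and only validates a supplied `ln_or` column against it at 1e-6 (the
published 6-decimal precision), so printed rounding is never compounded.

Missing genotypes exclude the individual by default, mirroring how such
cohorts drop unglenotyped participants; an optional policy imputes the
population expectation `2·EAF`. Quantile groups (quartiles, median split)
use sample percentiles with boundary ties assigned to the lower group —
deterministic and order-independent. Z-scores use the n−1 sample SD and
are computed on the analysis sample after exclusions.

VCF input uses the `DS` FORMAT field when present, otherwise 0/1/2 hard
calls; a site whose REF/ALT orientation is reversed relative to the panel
is flipped (`d → 2 − d`) so dosages always count effect alleles.

## Synthetic cohorts

The generator emulates a male population-based cohort (default n = 10,576,
baseline ages 45–73 from a truncated normal with mean 59, SD 7) followed
up to 27 years with staggered entry (a 5-year recruitment window shortens
the administrative horizon uniformly). Components:

- **Genotypes** — independent SNPs under Hardy–Weinberg equilibrium,
  dosage ~ Binomial(2, EAF). Linkage disequilibrium between panel SNPs is
  deliberately not simulated.
- **Blood pressure** — bivariate normal, SBP 144 (19) and DBP 88 (10)
  mmHg with correlation 0.7 (only the marginals are constrained by the
  emulated study; 0.7 is a typical SBP–DBP correlation and configurable).
- **Covariates** — smoking in 5 categories (never 28.2%, ex 42.9%,
  current split 16.9/12.0/71.1% across pack-year groups), BMI quartile,
  activity tertile (uniform), education in 5 categories (45.9/19.6/11.9/
  9.3/13.3%); independent of genotype by design.
- **Events** — three competing causes (non-aggressive UC, aggressive UC,
  death) with Gompertz-shaped cause-specific hazards evaluated on 1-year
  bands of attained age: `h(age) = rate60 · exp(slope · (age − 60))`.
  Default rates at 60 are 6.0e-4, 2.9e-4 and 7.0e-3 per person-year with
  slopes 0.06, 0.06 and 0.085, calibrated so a default cohort produces
  ≈250 non-aggressive and ≈128 aggressive UC events and a 20-year mean
  follow-up. Event times are drawn by inverting the piecewise-linear
  cumulative hazard at an Exp(1) draw; the cause is sampled from the
  band's cause-specific rates. Age enters as left truncation: people
  enter the risk set at their baseline age.

Effects are injected either as per-covariate log hazard ratios or as joint
exposure-group relative risks (RR10, RR01, RR11) applied directly to one
cause. The latter makes the true additive interaction known in closed
form, `RERI = RR11 − RR10 − RR01 + 1`, which anchors the coverage and
calibration studies.

What the generator does **not** emulate: LD, genotype–covariate
confounding (available as a hook but off by default), antihypertensive
treatment dynamics, calendar-period effects, and emigration as a distinct
censoring cause. Passing tests therefore certify the estimators under the
model's assumptions, not robustness to those real-data complications.

## Cause-specific Cox models

All models use attained age as the time scale with delayed entry and
treat competing events as censoring (cause-specific hazards). The partial
likelihood uses Efron's tie correction and is maximized by Newton–Raphson
(step-halving, tolerance 1e-9 on the coefficient change, max 100
iterations; |log HR| > 20 raises a separation error). The engine is
vectorized through the counting-process identity
`Σ_{i∈R(t)} f_i = Σ_{exit≥t} f_i − Σ_{entry≥t} f_i`, giving O(n·p²) per
iteration; it reproduces lifelines' estimates to ~1e-5 and brute-force
risk-set enumeration to 1e-10 on left-truncated fixtures.

Exposure forms follow the emulated study: SBP categories <140, 140–149,
150–159, ≥160 mmHg; DBP <90, 90–94, 95–99, ≥100; wGRS quartiles; and
per-SD (z-score) forms standardized on each model's complete-case sample.
Adjustment covariates (smoking 5, BMI quartiles, activity tertiles,
education 5) enter as indicators against the lowest/never category.
The trend test codes categories 1..k as one continuous term and reports
its Wald p.

Proportional hazards are checked with the Grambsch–Therneau scaled
Schoenfeld residual score test (per-term and global, with identity, rank
or Kaplan–Meier time transforms). It tracks R `survival::cox.zph` closely
but not exactly — the per-event variance is approximated by the average
information, and residual expectations use the Breslow form — which is
immaterial for a diagnostic: the test holds its nominal size under
proportional hazards and detects strong violations in the power study.
Violations are reported, not fatal.

## Interaction

**Additive.** Binary exposures: high BP (SBP ≥140 or DBP ≥90, with 130
and 150 mmHg sensitivity cuts for SBP) crossed with the median wGRS split
gives four joint groups; three indicators (reference = normal BP, lower
half) enter the adjusted cause-specific model and

```
RERI = exp(b11) − exp(b10) − exp(b01) + 1 .
```

The variance follows the Hosmer–Lemeshow delta method on the RR scale:
`Var = gᵀΣg` with `g = (−RR10, −RR01, RR11)` over the joint-coefficient
covariance block; the 95% CI is `RERI ± 1.96·SE` and the additive p-value
is the corresponding Wald test. A nonparametric bootstrap (resampling
individuals, re-estimating the median split per replicate) is provided as
a cross-check and agrees with the delta SE within sampling error.

Continuous scale: both exposures are z-scored, the sample is restricted
to |z| ≤ 2 on both exposures jointly, and with coefficients (b1, b2, b3)
for z1, z2 and their product, `RERI(δ1, δ2) = exp(b1δ1 + b2δ2 + b3δ1δ2) −
exp(b1δ1) − exp(b2δ2) + 1`, evaluated by default at +1 SD on each
exposure (the increment is a configuration knob; there is no canonical
choice, so results at other increments are not comparable across reports).

**Multiplicative.** A likelihood-ratio test of the product term: the
main-effects model is nested in the model adding the product (for binary
exposures the joint-indicator model is the same model reparametrized),
`stat = 2(ℓ_full − ℓ_restricted) ~ χ²_df`.

## Absolute risk

Cause-specific hazards are estimated nonparametrically as occurrence/
exposure rates on 1-year bands of attained age within each joint exposure
group, then combined by the piecewise-exponential competing-risk integral

```
risk = Σ_j h1_j · exp(−Σ_{k<j}(h1_k+h2_k)·w_k) · (1−exp(−(h1_j+h2_j)·w_j)) / (h1_j+h2_j)
```

with the outcome hazard h1 and the competing death hazard h2; the
integral is exact for piecewise-constant hazards and the two-cause
decomposition `risk(outcome) + risk(death) + P(event-free) = 1` closes to
1e-12. Default report: risk from age 60 over 20 years. Each group keeps
its own death hazard (hypertension raises mortality; sharing the death
hazard would flatter the exposed groups), with a switch for a shared
competing hazard. Rates are crude (no covariate adjustment) since the
group-wise absolute risks are descriptive. An event at an exact band
boundary is attributed to the band below, consistent with the half-open
risk intervals. No confidence intervals are reported for absolute risks.

## Validation studies and their sizes

`bpgrs.calibration` packages the replicate studies; the test suite and
`scripts/acceptance.py` run them at these sizes, chosen to give tight
Monte-Carlo error at interactive runtimes:

- **Type-I error** — 1,000 null cohorts (n = 2,000, raised event rates:
  aggressive-UC rate 6e-3/py); both the RERI Wald test and the LR product
  test must land in 0.05 ± 0.02.
- **Coverage** — 500 cohorts of n = 6,000 with injected RERs
  (1.2, 1.3, 2.0), truth RERI = 0.5; the delta-method 95% CI must cover
  in ≥93% of replicates.
- **Delta vs bootstrap** — one n = 20,000 cohort, 400 bootstrap
  replicates; agreement within 10% (bootstrap-SD Monte-Carlo error ≈3.5%
  at 400 replicates).
- **Parameter recovery** — n = 50,000, injected 0.25 log HR per SD of
  SBP, recovered within 3 SE.

## Known limitations

- The Cox engine supports time-fixed covariates only; time-varying
  effects appear solely in the diagnostic.
- The wGRS panel is fixed at the packaged 18 variants; re-weighting or
  SNP discovery is out of scope, as are imputation and array QC.
- RERI magnitudes from rate ratios are interpretable only against the
  background risk; the package reports the components (RRs, absolute
  risks) alongside RERI for that reason.
- Fine–Gray subdistribution modelling is intentionally absent: the
  analysis pairs cause-specific hazards with the crude-risk integral.
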