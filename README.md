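# bpgrs

Gene–environment interaction analysis of **blood pressure** and a
**weighted bladder-cancer genetic risk score (wGRS)** against
**urothelial carcinoma (UC)** risk in men — packaged as a tested,
reusable pipeline with a synthetic-cohort generator so every stage can
be validated against known truths.

## The science

Bladder cancer has a substantial polygenic component, and systolic blood
pressure (SBP) has been associated with aggressive (muscle-invasive) UC
in men. Whether genetics and blood pressure interact — whether their
joint effect exceeds the sum of their separate effects — matters for
prevention: a positive *additive* interaction identifies the subgroup
that gains most from treating hypertension.

The package implements the full analysis chain:

1. **wGRS** — for 18 GWAS bladder-cancer variants with weights
   `β_x = ln(OR_x)`, the score is
   `wGRS_i = Σ_x β_x · d_ix / 18` over genotype dosages `d_ix ∈ [0, 2]`,
   then z-scored and split into quartiles / median halves.
2. **Cause-specific Cox models** on the attained-age time scale with
   delayed entry at baseline age, Efron tie handling, categorical and
   per-SD exposure forms, trend tests and Schoenfeld-residual
   proportional-hazards diagnostics. Outcomes: total, non-aggressive and
   aggressive UC, with death as a competing event.
3. **Additive interaction** — the relative excess risk due to interaction
   over four joint exposure groups (BP cut × median wGRS split),
   `RERI = RR11 − RR10 − RR01 + 1`, with delta-method (Hosmer–Lemeshow)
   confidence intervals, a continuous (z-score) variant restricted to
   ±2 SD, and sensitivity analyses at alternative SBP cuts.
   **Multiplicative interaction** via the likelihood-ratio test of the
   product term.
4. **Absolute risk** — 20-year crude risk from age 60 per joint group,
   integrating nonparametric cause-specific hazards with death as the
   competing cause.
5. **Synthetic cohorts** — Hardy–Weinberg genotypes at the panel's
   allele frequencies, correlated BP, categorical covariates, and
   piecewise-exponential competing event times with *injectable, known*
   effects (per-SD log HRs or joint-group relative risks, making the
   true RERI available in closed form).

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a cohort of 20,000 men with a known super-additive effect on
aggressive UC (joint-group relative risks 1.2, 1.3 and 2.0, so the true
RERI is 2.0 − 1.2 − 1.3 + 1 = 0.5), then estimate the interaction:

```python
from bpgrs.simulate import SimConfig, JointEffect, GompertzHazard, simulate_cohort
from bpgrs.interaction import reri_analysis

cfg = SimConfig(
    n=20_000, seed=7,
    hazards={"uc_aggressive": GompertzHazard(4e-3, 0.0),
             "death": GompertzHazard(8e-3, 0.05)},
    joint_effect=JointEffect(rr10=1.2, rr01=1.3, rr11=2.0, cause="uc_aggressive"),
)
cohort, dosages = simulate_cohort(cfg)
est, fit = reri_analysis(cohort, "uc_aggressive", adjustment=())
print(f"RR10 {est.rr10:.2f}  RR01 {est.rr01:.2f}  RR11 {est.rr11:.2f}")
print(f"RERI {est.reri:.3f} (SE {est.se:.3f}, 95% CI {est.ci95[0]:.3f} to {est.ci95[1]:.3f})")
print(f"p_additive {est.p_additive:.4f}   p_multiplicative {est.p_multiplicative:.3f}")
```

prints

```
RR10 1.19  RR01 1.39  RR11 2.02
RERI 0.437 (SE 0.113, 95% CI 0.215 to 0.659)
p_additive 0.0001   p_multiplicative 0.033
```

The three hazard ratios recover the injected 1.2 / 1.3 / 2.0 within
sampling error, the RERI estimate 0.437 sits within one standard error
of the true 0.5, and the additive interaction is clearly detected. The
matching 20-year absolute risks from age 60 show the same pattern on the
probability scale:

```python
from bpgrs.absrisk import group_absolute_risks
from bpgrs.interaction import assign_joint_groups

print(group_absolute_risks(assign_joint_groups(cohort), "uc_aggressive")
      [["n", "absolute_risk_percent"]].round(2))
```

```
          n  absolute_risk_percent
group
ref    4192                   6.38
10     5808                   7.91
01     4111                   8.68
11     5889                  12.57
```

The doubly-exposed group's risk exceeds what the two single exposures
would add (6.38 + (7.91−6.38) + (8.68−6.38) = 10.2 < 12.57) — the
absolute-scale footprint of the positive RERI.

A command-line interface wraps the same stages
(`bpgrs simulate | score | fit | interact | absrisk | run-all`), driven
by a YAML config and a `--seed`; `run-all` writes score, hazard-ratio,
interaction, sensitivity-cut and absolute-risk CSVs plus a manifest with
exclusion bookkeeping.

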