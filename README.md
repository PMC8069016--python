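# rutinpk

Population pharmacokinetics of rutin and its quercetin conjugates in rats,
comparing the pure flavonoid with *Physalis peruviana* calyx extract.

Rutin given intravenously is cleared within hours; given orally it is not
absorbed intact — the circulating species are quercetin conjugates
(quercetin-3-O-glucuronide and -sulfate, measured together as quercetin),
whose plasma profiles show a characteristic **double peak** caused by a
second, delayed absorption site (enteric recirculation).  The calyx
extract's plant matrix changes both disposition (IV) and absorption
(oral), and this package implements the full quantitative analysis of
that comparison:

* **Structural models** — two-compartment IV bolus
  (`dX1/dt = k21·X2 − (k12+k)·X1`, `dX2/dt = k12·X1 − k21·X2`, `C = X1/V`)
  and a two-site first-order absorption model in which a fraction `F1` of
  the dose is absorbed at rate `ka1` from t = 0 and the rest at rate `ka2`
  only after a delay `Tlag2`; exact closed-form simulators with stiff-ODE
  cross-checks.
* **Population layer** — `h(P_i) = h(P_pop) + β_level + η_i` with log or
  logit transforms, categorical covariates (extract source; dose group),
  correlated lognormal random effects, and combined residual error
  `sd(f) = a + b·f`.
* **Synthetic studies** — the exact 10-group × 5-rat design (IV 1.45–14.8
  and oral 75–100 mg/kg rutin-equivalent doses, extract groups dosed as
  rutin equivalents), published sampling schedules, and LLOQ censoring at
  100 ng/mL.
* **NCA** — trapezoidal AUC, terminal-slope regression, AUC/AUMC
  extrapolation, MRT, clearances and volumes, group summaries and relative
  bioavailability (`Frel = (AUC_test/AUC_ref)·(D_ref/D_test)`).
* **SAEM estimation** — statsmodels-style `PopPKModel.fit()` →
  `PopPKResults` with estimates, SEs/RSEs (empirical Fisher), AIC, Wald
  tests, IWRES and VPC; multistart from deterministic pooled pre-fits,
  Laplace-ranked chains, direct marginal-likelihood refinement and a
  profile polish over the weakly identified oral absorption rate.

## Worked example

```python
from rutinpk import (default_design, simulate_study, nca_subject,
                     nca_group_summary, PopPKModel,
                     iv_reference_model, oral_reference_model)
from rutinpk.structural import ROUTE_IV

# simulate the IV arm of the rat study from the published final model
design = default_design().subset(routes=(ROUTE_IV,))
data = simulate_study(design, iv_reference_model(), None, seed=42)

# non-compartmental analysis of group 2 (pure rutin, 2.9 mg/kg)
print(nca_group_summary([nca_subject(s) for s in data if s.group == 2])
      .loc[["auc0_inf", "cl", "mrt"], ["mean", "sd"]])

# refit the population model by SAEM and inspect the estimates
res = PopPKModel.from_study(data, "iv").fit(seed=7, multistart=2, prefit=True)
print(res.summary().loc[["V_pop", "k_pop", "beta_V_GEXT"],
                        ["value", "se", "rse_pct"]])
print(res.wald_test("beta_V_GEXT"))
```

Output (seeds 42/7):

```
                   mean           sd
parameter
auc0_inf   32289.959287  4972.420027
cl             0.091567     0.014312
mrt            0.799943     0.085413
                value        se    rse_pct
quantity
V_pop        0.062929  0.012806  20.350114
k_pop        1.485083  0.151970  10.233096
beta_V_GEXT  0.537547  0.260917  48.538428
(2.0602232808128713, 0.03937720027132108)
```

Reading: the simulated 2.9 mg/kg group's exposure (AUC ≈ 32,300 ng·h/mL)
and clearance (≈0.09 L/h/kg) match the study's scale; the refit recovers
the generating population values (V_pop 0.0646 L/kg, k_pop 1.47 1/h)
within a few percent, and the extract effect on the central volume is
significant by the Wald test (z = 2.06, p = 0.039).

A command-line interface mirrors the library: `rutinpk simulate`,
`rutinpk nca`, `rutinpk fit`, `rutinpk vpc`, `rutinpk reproduce`
(see `rutinpk --help`).

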