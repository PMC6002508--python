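# pbpkgsa

Global sensitivity analysis (GSA) driven Bayesian calibration of a
physiologically-based pharmacokinetic (PBPK) model for acetaminophen (APAP)
and its two primary conjugates, APAP-glucuronide (AG) and APAP-sulfate (AS).

PBPK models carry dozens of parameters, most of which are traditionally fixed
by expert judgment before the remainder are calibrated against plasma
concentration data — a practice that can silently bias both parameter
estimates and predictions. This package implements the alternative: decide
*objectively* which parameters can be fixed, by computing global sensitivity
indices of every model output with respect to every parameter, and calibrate
only the influential subset. It is written for PK/PBPK modellers and for
anyone studying parameter-fixing strategies in mechanistic models.

## What is in the box

| module | contents |
| --- | --- |
| `pbpkgsa.priors` | the 58-parameter prior table (21 "original" metabolism/elimination parameters with uniform or truncated-lognormal priors, 37 "additional" physiological parameters), unit-hypercube rescaling, seeded sampling |
| `pbpkgsa.pbpk` | the APAP PBPK ODE system: nine blood-flow-limited compartments per compound, saturable CYP/SULT/UGT metabolism with cofactor depletion, saturable hepatic conjugate export, renal clearance; stiff integration via LSODA with a numba-compiled right-hand side |
| `pbpkgsa.gsa` | Morris elementary-effects screening (Campolongo trajectory selection) and three variance-based Sobol estimators: eFAST (spectral), Jansen (two-matrix), Owen (three-matrix), plus a double-loop brute-force oracle for testing |
| `pbpkgsa.convergence` | Sarrazin-style convergence index: width of 95% CIs of the indices across bootstrap / random-phase resamples |
| `pbpkgsa.classify` | per-parameter index maxima, Morris normalisation, influential/non-influential cut-off classification, method-agreement correlations, set overlap reports |
| `pbpkgsa.bayes` | Metropolis-within-Gibbs MCMC with a lognormal likelihood, Gelman-Rubin diagnostics, posterior fit reports |
| `pbpkgsa.synthetic` | synthetic PK datasets with the structure of the single-oral-dose clinical studies (325 mg – 80 mg/kg, three compounds, lognormal noise) |
| `pbpkgsa.workflow` | the five-stage prior-check → GSA → classify → calibrate pipeline with artifact manifests; `pbpkgsa.cli` wraps it for the shell |

## The statistics in brief

For a model output `Y = f(X₁,…,Xₚ)` the Sobol **main effect**
`Sᵢ = V[E(Y|Xᵢ)]/V(Y)` is the share of output variance removed by fixing
`Xᵢ`; the **total effect** `STᵢ` adds every interaction involving `Xᵢ`, and
`STᵢ − Sᵢ` is the interaction share. Outputs here are log plasma
concentrations of APAP/AG/AS at 0.5, 1, 1.5, 2, 4, 6, 8 and 12 h post dose;
each parameter is summarised by its *maximum* index over all 24 outputs and
called **influential** when that maximum main effect *or* interaction exceeds
a cut-off (0.05 or 0.01 for Sobol indices; 0.1 for per-output-normalised
Morris μ\*, σ). Model-evaluation budgets at base sample size `n` are
`n(p+1)` (Morris), `np` (eFAST), `n(p+2)` (Jansen) and `n(3p+2)` (Owen).

Calibration maximises the lognormal log-likelihood

```
LL = Σᵢ [ −(yᵢ − ŷᵢ)² / (2·s²_{j[i]}) − ½·ln(2π·s²_{j[i]}) ]
```

with `y = ln(conc)`, one error variance `s²ⱼ` per compound, sampled one
component at a time by random-walk Metropolis on the log scale across four
independent chains, convergence judged by the Gelman-Rubin potential scale
reduction factor.

## Worked example

```python
import numpy as np
import pbpkgsa as pg

table = pg.load_prior_table()
params = pg.build_default_parameters(table)
res = pg.simulate(params, pg.DoseSpec(1000.0), np.asarray(pg.GSA_TIMES))
print(res.plasma.round(3))
```

```
       APAP     AG      AS
0.5   8.339  3.651  47.122
1.0   5.081  4.307  60.221
1.5   3.175  4.532  64.662
2.0   1.997  4.588  65.769
4.0   0.313  4.212  58.459
6.0   0.049  3.634  47.648
8.0   0.008  3.101  38.226
12.0  0.000  2.250  24.438
```

APAP is absorbed and conjugated within hours; the sulfate dominates at the
nominal parameter values while both conjugates are cleared renally.
Ranking an eight-parameter subset by eFAST
(`examples/03_pbpk_sensitivity.py`, 16,400 model evaluations at n=1025)
and classifying at the 0.05 cut-off prints:

```
   parameter  max_main  max_interaction           label
          Tg     0.565            0.072     influential
          Tp     0.013            0.080     influential
   CYP_VmaxC     0.000            0.024 non-influential
  SULT_VmaxC     0.509            0.061     influential
SULT_Km_apap     0.232            0.035     influential
      CLC_AS     0.875            0.064     influential
       Km_AS     0.001            0.028 non-influential
    CLC_APAP     0.249            0.037     influential
```

i.e. two parameters can be fixed at nominal values. Calibrating only the
influential subset against synthetic data (`examples/05_calibration.py`)
recovers the true values — e.g. `SULT_VmaxC` true 1805.5, posterior median
1856.4, 95% CI [1765.1, 1984.1] — with all PSRF below 1.03 and per-study
R² ≥ 0.997 on log predictions.

Each script in `examples/` is a short narrative: priors and simulation,
benchmark validation of the estimators, PBPK sensitivity ranking,
convergence checking, calibration, and the full workflow.

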