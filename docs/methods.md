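# Methods

This note records the scientific and numerical choices behind `pbpkgsa`:
what is modelled, which settings matter, where the design was genuinely open
and what was decided, and what the synthetic-data experiments do and do not
demonstrate.

## The PBPK model

The model tracks molar amounts of APAP, APAP-glucuronide (AG) and
APAP-sulfate (AS) in nine compartments per compound — arterial blood, venous
blood, fat, gut tissue, kidney, liver, muscle, and lumped rapidly/slowly
perfused tissue — connected by fractional cardiac-output flows under the
blood-flow-limited (perfusion-limited) assumption: each tissue's venous
outflow leaves at `C_tissue / P`, with `P` the tissue:blood partition
coefficient. The published lineage of this model describes its structure but
defers the equation set to earlier work, so the ODE system here is a
reconstruction built to give every parameter in the prior table a mechanistic
role:

* **Absorption.** A stomach → GI-lumen chain with first-order rates `1/Tg`
  (gastric emptying) and `1/Tp` (GI perfusion); the lumen empties into the
  liver via the portal inflow. The oral dose is fully absorbed.
* **Metabolism** (liver only, driven by the venous-equilibrated free liver
  concentration `C_L/P_L`): a CYP pathway with plain Michaelis–Menten loss
  (products not tracked), and SULT/UGT conjugation with substrate inhibition,
  `v = Vmax·C / (Km + C·(1 + C/Ki))`, each multiplied by a cofactor occupancy
  factor `P_c/(Km_c + P_c)`. The PAPS and UDPGA pools are normalised to 1,
  resynthesised at `k_syn·(1 − P_c)` and depleted stoichiometrically with
  conjugation; converting molar conjugation flux into fractional pool
  depletion requires a nominal pool size, set to 100 µmol (configurable).
  Because the occupancy factor vanishes linearly as a pool empties, the pools
  remain positive.
* **Conjugate disposition.** Conjugates formed in the liver leave to venous
  blood through saturable transporters (`Vmax_AG/Km_AG`, `Vmax_AS/Km_AS`)
  and also exchange with the circulation by perfusion using their own
  partition coefficients, so the circulating conjugate re-distributes into
  tissues.
* **Elimination.** Renal clearance `CLC_x · BW^0.75 × C_arterial` for each
  compound, accumulated as urinary amount.
* **Observation model.** Plasma concentration = venous blood concentration /
  blood:plasma ratio. Only `BP_APAP` is tabulated; by default the same ratio
  is applied to the conjugates (configurable), since the data the workflow
  targets are plasma measurements of all three compounds.

Molecular masses 151.16 (APAP), 327.29 (AG) and 231.23 (AS) g/mol convert
µmol to mg. Default body mass is 70 kg; mg/kg doses scale with it.
Fractional flows and volumes are sampled independently, so the lumped
rapidly-perfused flow and volume are computed as one minus the sum of the
named fractions, floored at 10⁻³ to stay physical for extreme prior draws.

**Numerics.** LSODA with `rtol 1e-6`, `atol 1e-9` (both configurable); the
right-hand side is numba-compiled. Halving the tolerances moves plasma
outputs by < 0.1 % (tested). Solver-level negative noise in plasma outputs is
clipped at zero, and log-transformed outputs are floored at 10⁻¹².
Mass balance (parent + conjugates + urinary + cumulative CYP loss = dose)
holds to the solver tolerance and is asserted in the tests.

## Priors

21 "original" metabolism/elimination parameters and 37 "additional"
physiological parameters, each uniform (min, max in natural units) or
truncated-lognormal. The tabulated "mean" of a lognormal prior is read as
the *geometric* mean, because its spread (sdlog) and truncation (±z) are
given on the log scale; support is `loc·exp(±z·sdlog)`. Sampling uses
inverse-CDF restricted to the truncated range — exact, and deterministic
under seeding. The partition-coefficient rows carry no tabulated spread;
they are assigned sdlog 0.3 with ±2 truncation (configurable), a moderate
uncertainty that keeps them sampleable in full-parameter analyses.

Sensitivity designs live on the unit hypercube: uniform parameters map
linearly, lognormal parameters map linearly in log space between their
truncation bounds, so `u = 0.5` returns the geometric mean exactly.

Nominal values (used for fixing parameters and as the simulation default)
are the geometric mean for lognormal priors and the geometric mean of
(min, max) for uniform priors, whose ranges span up to six decades; the
original fixed point values are not recoverable, and the geometric midpoint
is the natural unbiased choice on the sampling (log) scale. One consequence,
visible in the prior-predictive check: for the uniform Vmax priors the
geometric midpoint sits far below the *arithmetic* bulk of the prior, so
most prior draws metabolise APAP much faster than the nominal parameter set,
and data generated at the nominal values sit in the upper tail of the prior
predictive band for APAP. Coverage reports should therefore be read
per-compound, and self-consistency checks in the tests generate data from a
prior draw rather than the nominal point.

## Sensitivity engines

All engines evaluate the model over the active parameter subset with every
other parameter at its nominal value, at a single 1,000 mg dose
(configurable), and operate on log plasma concentrations of the three
compounds at 0.5–12 h (24 outputs), computing indices for every output at
once.

* **Morris.** Even-level grids (default 8 levels, step Δ = L/(2(L−1))),
  trajectories built from Latin-Hypercube base points with random move order
  and direction. A candidate pool (default 100·r for r ≤ 20 trajectories;
  at larger r the LHS pool is used directly, since spread-maximising
  selection costs O(pool²)) is thinned by the Campolongo criterion —
  maximise the root of summed squared pairwise trajectory distances —
  exhaustively when the subset count is small, greedily otherwise.
  Outputs: μ, μ\* (mean absolute) and σ of the elementary effects.
* **eFAST.** Each parameter in turn is driven along a search curve at the
  maximum admissible frequency `ω_max = ⌊(n−1)/(2M)⌋` (interference factor
  M = 4) with a random phase; the complementary parameters get low
  frequencies spread over `1…⌊ω_max/(2M)⌋` (spreading, rather than packing
  them at 1, 2, …, avoids phase-locked low-frequency pairs distorting the
  curve variance). `S` is the spectral power at the focal frequency's first
  M harmonics over total variance; `ST` is one minus the power below
  `ω_max/2`. The minimum admissible n is `4M² + 1 = 65`; requests below it
  raise an error stating that bound. Nr = 5 random-phase resamples by
  default; their spread feeds the convergence index.
* **Jansen.** Two base matrices A, B and the radial blocks `AB_i`:
  `ST_i = E[(f(A) − f(AB_i))²]/(2V)`, `S_i = 1 − E[(f(B) − f(AB_i))²]/(2V)`,
  V estimated from the pooled base evaluations.
* **Owen.** Three base matrices; the main effect uses the correlated
  difference identity `2V_i = E[(f(C_{i←A}) − f(C_{i←B}))·(f(B_{i←A}) −
  f(B))]`, which is accurate for small indices, and the total effect is
  Jansen on the pair (B, B_{i←A}). Budget n(3p+2).
* **Clipping.** Estimated indices are clipped to [0, 1] and ST floored at S;
  negative estimates are estimator noise and would otherwise break the
  cut-off logic.
* A **double-loop conditional-variance oracle** (with the inner-mean noise
  debiased) exists purely as an independent cross-check in tests.

Failed ODE integrations at design points abort the analysis by default; an
opt-in policy instead imputes the nearest successful evaluation and logs it.
The prior truncation keeps the sampled space integrable in practice.

## Convergence

An index estimate has converged when resampling barely moves it: the
convergence index is the maximum, over parameters, outputs and metrics, of
the width of the 95 % percentile interval across replicates — random-phase
resamples for eFAST, B = 100 bootstrap resamples of evaluation rows (matrix
pairing preserved) for Jansen/Owen, whole-trajectory bootstrap for Morris.
Sobol widths are taken on the raw index scale with threshold 0.1; Morris
μ\*/σ replicates are first normalised so the per-output maximum is 1, making
the same threshold a "10 % of the largest index" rule (both μ\* and σ enter,
and the maximum is taken). Percentile rather than BCa intervals keep the
procedure deterministic and match the "range of the 95 % interval" reading.
Replicate values at floating-noise level (< 10⁻¹⁰) are zeroed before
normalising so an exactly degenerate slice cannot amplify round-off.

## Classification

Each parameter is summarised by the maximum of its main-type and
interaction-type indices over all 24 outputs; it is influential when either
maximum is *strictly* greater than the cut-off (a tie counts as
non-influential). Default metric pair is (S, ST − S) — the pair the
influential-set construction uses — with (ST, ST − S) available behind a
switch. Morris classification uses normalised μ\* and σ at 0.1; Sobol
cut-offs of 0.05 and 0.01 are both supported, and lowering the cut-off can
only grow the influential set (tested property). Method agreement is
quantified by Pearson and Spearman correlations of per-parameter maxima.

## Bayesian calibration

Pooled (non-hierarchical) calibration of a chosen subset; everything else
stays at nominal values. The likelihood is lognormal with one log-scale
error variance per compound. Sampling is Metropolis-within-Gibbs: each
parameter is a component on the log scale (truncated-lognormal priors become
truncated normals; uniform priors keep their natural-scale density via the
Jacobian), and each error variance is a component with a log-uniform prior
on [10⁻³, 10]. Per-component Gaussian steps adapt geometrically toward a
20–40 % acceptance window during burn-in only and are frozen afterwards, so
the retained chain has a fixed kernel. A failed model evaluation maps to
log-posterior −∞ and simply rejects the proposal. Four chains by default
(tests use two), started from prior draws shrunk halfway toward the prior
centre — overdispersed enough for the Gelman-Rubin diagnostic, close enough
to keep burn-in short at test scale. Defaults are test-scale (10,000
iterations, thin 10); production-scale analyses of this model family use
hundreds of thousands of iterations.

The fit report evaluates the model at the posterior medians: log10 residuals
(median = accuracy, IQR = precision), per-study R² on log10 predictions
versus observations, 95 % prediction intervals from posterior-predictive
draws (parameter draw + lognormal noise at the drawn variance), and the
LnData (data log-likelihood per kept iteration) distribution used to compare
calibrations.

## Synthetic data

The generator emulates the structure of the single-oral-dose clinical
studies the workflow targets: eight studies — two each at 325 mg, 1,000 mg,
20 mg/kg and 80 mg/kg (the high-dose group is configurable) — sampled at
0.5–12 h, all three compounds measured, and multiplicative lognormal noise
with compound-specific sdlog, default 0.2 (a typical PK assay spread). One
representative 70 kg subject per study; no inter-individual variability, no
dropout, no censoring at a limit of detection. Passing tests on these data
therefore demonstrate the *workflow logic* — that the GSA-selected subset
suffices to calibrate the model that generated the data — not clinical
fidelity of the reconstructed model.

## Experiment scales

The test suite and the acceptance script size their simulations for a single
CPU: benchmark estimator checks run at n ≤ 8192 on analytic functions; PBPK
sensitivity runs use 4–8 parameter subsets at n = 65–1025 (the full
21/58-parameter analyses run through exactly the same code path and are
exercised at small n); calibrations use 1–2 synthetic studies, two chains
and 300–500 iterations. The parameter-recovery check uses 10 replicate
datasets; the reduced-versus-full comparison uses 5 replicate seeds. The
key claims — credible-interval coverage of true values, and
indistinguishable residual/LnData distributions between reduced and full
calibrations alongside a clear LnData drop when an influential parameter is
fixed 8-fold off its true value — are asserted at these scales.

## Known limitations

* The ODE system is a faithful-by-role reconstruction, not a coefficient-
  level reproduction of the original publication's model; absolute
  trajectories should not be compared against clinical data.
* Independent priors throughout; correlated-input GSA is out of scope.
* Component-wise Metropolis mixes slowly for strongly correlated posteriors
  (e.g. Vmax/Km pairs); production runs need long chains or a reduced,
  less collinear subset.
* The eFAST total effect inherits the usual spectral truncation bias
  (visible as interaction estimates of a few percent for truly additive
  parameters at moderate n); classification at the 0.05 cut-off should use
  n ≥ ~1000 for stable labels on this model.
* Urinary excretion data, multiple-dose regimens and non-oral routes are not
  modelled.
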