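# Methods

## Structural model and scaling

Unbound piperacillin disposition is described by a linear mammillary
three-compartment model: a central compartment (volume `Vc`) exchanging
with a slow (`Q1`, `Vp1`) and a rapid (`Q2`, `Vp2`) peripheral compartment,
with first-order elimination (`CL`) from the central compartment. Amounts
obey `dA/dt = K A + u(t)` with infusion input `u` into the central
compartment only; concentration is the central amount divided by `Vc`.

All six typical parameters refer to a 70 kg individual and are scaled to
body weight with fixed allometric exponents — 0.75 for the three clearances
and 1.0 for the three volumes. Body weight is the only covariate; age and
sex are carried through the virtual population for reporting but do not
enter the model.

Defaults (embedded, overridable from a flat YAML/JSON file):

| parameter | value | units | meaning |
|---|---|---|---|
| `cl_70` | 14.24 | L/h | elimination clearance |
| `vc_70` | 5.953 | L | central volume |
| `q1_70` | 0.1943 | L/h | slow inter-compartmental clearance |
| `vp1_70` | 3.537 | L | slow peripheral volume |
| `q2_70` | 27.45 | L/h | rapid inter-compartmental clearance |
| `vp2_70` | 7.329 | L | rapid peripheral volume |
| `omega_cl_ia` | 0.180 | log-SD | between-episode CL variability, IA cohort |
| `omega_cl_ci` | 0.481 | log-SD | between-episode CL variability, CI cohort |
| `omega_err` | 0.307 | log-SD | inter-individual residual-error magnitude |
| `sigma_ia` | 0.275 | – | proportional residual SD, IA cohort |
| `sigma_ci` | 0.500 | – | proportional residual SD, CI cohort |

Percent-style variability estimates are interpreted as `100·ω` with ω the
SD on the log scale (not as a CV converted via `sqrt(ln(1+CV²))`). The
package-level justification: with ω = 0.481 the closed-form dose-finding
results reproduce the published weight-dependent dose requirements to
better than 1%, while the CV conversion (ω ≈ 0.456) misses them by ~4%.

Only clearance carries a random effect in simulation
(`CL = CL_typ·e^η`, `η ~ N(0, ω²)`); volumes and inter-compartmental
clearances stay at their scaled typical values. Inter-individual and
between-episode variability collapse to a single log-normal deviation per
simulated child (one occasion per child). Regimen-matched ω is the
default: 0.481 (continuous-infusion cohort estimate) for continuous
infusion, 0.180 (intermittent cohort) for intermittent and extended
regimens. All concentrations are unbound; no protein-binding conversion is
applied anywhere.

## Exact profile solver

The rate matrix of a mammillary model is symmetrizable by the diagonal
transform `D = diag(1/sqrt(V))`, so its spectrum is real and each
constant-rate segment propagates exactly through `eigh`:

    w(t0 + h) = e^{Λh} w(t0) + φ1(Λ, h) w_u,   φ1(λ, h) = (e^{λh} − 1)/λ

with `w` the state in eigencoordinates and `w_u` the transformed input.
The `φ1` limit at λ→0 is handled explicitly, which keeps the solver exact
for degenerate cases (zero clearance, used by the mass-balance property
test). The implementation is batched over individuals (stacked 3×3
eigendecompositions), so a 10,000-child population profile evaluation is a
few seconds of numpy work. Agreement with an adaptive-ODE oracle (per
segment LSODA at rtol 1e-11) is at machine-precision level (~1e-11
relative; the test suite asserts 1e-6 on 100 random parameter sets).

Bolus and loading doses are modeled as 5-minute (1/12 h) infusions
(configurable). The default profile evaluation grid is 1-minute resolution
over the evaluation window; crossing times between grid points are located
by linear interpolation when computing time-above-threshold.

## Regimens

Five families, all dosed per kg/day with the total piperacillin amount
capped at 16 g/day (the cap binds above 53.3 kg at 300 mg/kg/day and above
40 kg at 400 mg/kg/day):

* `IA_q8h` / `IA_q6h`: capped daily dose split into 3 / 4 infusions of
  5 min (duration configurable; the trial did not state the simulated
  infusion duration, so the loading-bolus duration is reused).
* `EI_q8h` / `EI_q6h`: same split, each infusion lasting half the dosing
  interval (4 h / 3 h).
* `CI`: constant rate over 24 h, optionally preceded by a 100 mg/kg
  loading bolus that is *not* subtracted from the daily dose. Simulated
  IA/EI regimens carry no loading dose.

## Virtual population

10,000 children aged 2–18 years, sexes exactly balanced, ages uniform.
Body weight is drawn from a two-piece log-normal: log-weight normal with a
common median and separate lower/upper SDs chosen so the 2.5th/50th/97.5th
percentiles equal 12.6/42.7/94.2 kg exactly. An externally supplied
(id, age, sex, weight) CSV is accepted as an alternative source. Weight
groups <25, 25–50, 50–75, ≥75 kg are attached for stratified reporting.

What this emulates — and what it does not. The three printed quantiles are
matched exactly, and every result that depends mainly on them (PTA at the
16 mg/L breakpoint under 100% fT>MIC, dose finding, the spread of the Css
distribution) is insensitive to the rest of the distribution. But the
two-piece model says nothing about the *shape between* those quantiles and
it generates weight independently of age. A real growth-curve population
of uniformly distributed ages puts less mass in the 40–55 kg range, which
is exactly where the steady-state concentration for capped per-kg dosing
peaks. Quantities driven by the middle of the weight distribution —
mid-range PTA values (roughly 10–90%) and Css medians — are therefore
biased a few percent high relative to a growth-curve-based population with
the same printed quantiles. A constrained-fit feasibility analysis showed
a quantile-consistent weight distribution exists that removes the bias
entirely, but pinning it down requires population data that is not
published; passing tests on this generator consequently validate the PK
and attainment machinery, not the demographic shape.

## PTA, CFR and dose finding

Attainment of target (f, m) at a MIC: the unbound concentration exceeds
`m·MIC` for at least fraction `f` of one steady-state dosing interval
(default: the interval starting at 48 h; attainment uses noise-free model
predictions — residual error reflects assay and process noise, not
exposure). For continuous infusion the profile is flat at `Css = rate/CL`,
so attainment for any `f ∈ (0, 1]` reduces to `Css > m·MIC` (this is why
50% and 100% fT>4×MIC coincide for CI) and the closed form is used
directly. PTA is reported with its binomial Monte-Carlo SE, overall and by
weight group. CFR is `Σ PTA(MIC_i)·p_i` over a MIC distribution whose
values are snapped to the doubling grid with a warning. Success may be
read against either the strict 95% criterion or the conventional 90%.

Required dose for a weight, Css threshold and attainment level `a` solves
`P(rate/CL ≥ threshold) ≥ a` under the log-normal clearance law; the
closed form is `24·CL_typ·thr·e^{z_a ω}/WT` and the default bisection on
the attainment probability reproduces it to 1e-6 (a Monte-Carlo mode is
available as a cross-check). No dose cap is applied — required doses
exceed the cap by construction.

## Synthetic study generator

Emulates the two-cohort clinical design: 43 children / 89 episodes on
q8h intermittent dosing and 38 children / 68 episodes on loading +
continuous infusion, episodes per child between 1 and 4 (one each, the
remainder spread at random). CI episodes contribute 3 samples with
probability 0.4, else 2 (windows dropped uniformly at random), drawn
uniformly from the protocol windows: post-load peak (2–30 min),
distribution phase (0.5–1.5 h), steady state (12–24 h). IA episodes
contribute end-of-infusion, mid-interval and trough samples of the dosing
interval starting at 24 h (fast distribution phases are fully equilibrated
there; the slow compartment, with Q1 two orders of magnitude below Q2,
contributes negligibly to the central profile). Observations are
`pred·(1+ε)` with `ε ~ N(0, (σ_cohort·e^κ)²)` and `κ ~ N(0, ω_err²)` per
child; values below the 0.5 mg/L quantification limit are truncated at the
limit and flagged. An optional continuous-infusion interruption (>30 min,
probability configurable; 13% was observed clinically) splits the infusion
and re-administers the loading dose.

## Estimation

`map_estimate` maximizes the log-normal prior on η plus the
proportional-error likelihood in fixed-weight (IWRES) form — the
prediction-dependent Gaussian normalization term is dropped, so a
noise-free observation at the typical prediction gives η = 0 exactly and
shrinkage behaves as expected at sparse sampling. Bounded scalar
optimization at 1e-8 tolerance; below-LOQ observations are excluded by
default (M1). `recover_population` alternates MAP per episode with moment
updates: the typical clearance absorbs the mean η, the cohort ω² is
updated as the mean of `η̂² + posterior variance` (Laplace curvature —
an EM-type correction for shrinkage), and σ from squared weighted
residuals at the MAP. Volumes and inter-compartmental clearances are held
fixed (not identifiable at 2–3 samples/episode), ω_err is simulated but
not estimated, and episodes whose samples are all below the LOQ are
dropped with a warning. Non-convergence after `max_iter` is reported in
the result, not raised.

Known limitations: σ is recovered with a downward bias of roughly 25% at
the trial's sampling density (MAP η absorbs part of the residual noise;
the ω update is corrected for shrinkage, the σ update is not), and from a
starting point far from the truth the alternating scheme can settle at a
different fixed point — it is a simplified two-stage method, not a full
marginal-likelihood fit. Parameter-recovery tests therefore assert the
typical clearance (within 10%) and ω (within 30%), not σ.

`vpc` re-simulates each episode under the full error model (n_sim
replicates, clearance effect + error-magnitude factor + proportional
noise), bins observations by time quantiles per cohort (empty or
degenerate bins merged with a warning) and reports observed 5th/50th/95th
percentiles against the simulation band (2.5–97.5% across replicates) per
bin. `observed_attainment` takes each episode's latest steady-state-window
sample and reports the fraction above a threshold. `lrt` is the chi-square
upper tail of a −2Δlog-likelihood.

## Numerical and design choices

* Time-above-threshold uses strict exceedance; a profile exactly at the
  threshold does not count (a constant profile at the MIC fails 100%
  fT>MIC).
* The MIC grid is the doubling series 0.125–128 mg/L; PTA is monotone
  non-increasing along it by construction of the attainment rule.
* Attainment evaluation starts at 48 h rather than at the exact periodic
  steady state; residual non-stationarity of the slow compartment at 48 h
  changes troughs by well under 1%.
* Seeds: every stochastic entry point takes a seed or numpy Generator;
  the CLI and acceptance script derive all stage seeds from one master
  seed via `SeedSequence.spawn`.
* Monte-Carlo problem sizes: 10,000 children for PTA/Css summaries
  (binomial SE ≤ 0.5 pp near 95%), 157-episode studies for recovery
  checks, 20 replicates for the recovery distribution, 10 for VPC
  calibration — chosen to keep each quantity's Monte-Carlo error well
  below the tolerance it is compared at.
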