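# pippk — pediatric piperacillin population PK and target attainment

`pippk` is a simulation and estimation toolkit for piperacillin dosing in
children with cancer and febrile neutropenia — a population whose augmented
renal clearance routinely drives β-lactam concentrations below effective
levels. It answers the dosing question with Monte-Carlo simulation from a
population pharmacokinetic model: *which regimen (intermittent, extended or
continuous infusion, 300 or 400 mg/kg/day) keeps the unbound piperacillin
concentration above the pathogen's MIC for the required fraction of the
dosing interval, and in what fraction of children?*

It is written for pharmacometricians and pediatric-infectious-disease
researchers who want a scriptable, reproducible PTA engine rather than a
closed simulation product.

## Model

Disposition is a linear mammillary three-compartment model with first-order
elimination. Typical values refer to a 70 kg individual and scale with body
weight by fixed allometric exponents:

    CL_i = CL_70 · (WT_i / 70)^0.75        (all clearances)
    V_i  = V_70  · (WT_i / 70)^1.0         (all volumes)

Between-episode variability acts on clearance as a log-normal random effect,
`CL = CL_typ · e^η`, `η ~ N(0, ω²)`, with cohort-specific ω (0.180 for the
intermittent-administration cohort, 0.481 for the continuous-infusion
cohort). Residual error is proportional with a cohort-specific SD (0.275 /
0.500) and a log-normal inter-individual error-magnitude factor
(`ω_err = 0.307`). Defaults for all typical values (CL 14.24 L/h, Vc 5.953 L,
Q1 0.1943 L/h, Vp1 3.537 L, Q2 27.45 L/h, Vp2 7.329 L at 70 kg) are embedded
and can be overridden from a YAML/JSON file.

Profiles for arbitrary piecewise-constant infusion schedules are solved
exactly (eigendecomposition of the symmetrizable rate matrix — no ODE
integration error), vectorized across a whole virtual population.

PK/PD targets are of the form *f*T > m·MIC ≥ f: the package ships the two
standard neutropenia targets, 100% *f*T>MIC and 50% *f*T>4×MIC. PTA is the
fraction of a 10,000-child virtual population (ages 2–18, weights from a
two-piece log-normal matched to median 42.7 kg and a 12.6–94.2 kg 95%
interval) attaining the target at each MIC on the doubling-dilution grid
0.125–128 mg/L; CFR weights PTA by a MIC distribution. Daily doses are
capped at 16 g of piperacillin. For continuous infusion, attainment uses
the closed form Css = rate/CL; dose finding inverts it.

A synthetic-study generator reproduces the two-cohort clinical sampling
design (89 intermittent + 68 continuous-infusion fever episodes, 2–3
samples each), and an estimation module provides empirical-Bayes (MAP)
individual clearance estimates, an iterative two-stage population recovery,
visual-predictive-check bands and a likelihood-ratio helper.

## Worked example

```python
import numpy as np
from pippk import (PopulationParameters, generate_population, compute_pta,
                   css_distribution, required_dose, TARGET_100_FT_MIC)

children = generate_population(10_000, seed=42)
pta = compute_pta(children, "CI", 300, TARGET_100_FT_MIC, mic_grid=[2, 4, 16], seed=42)
for mic, p, se in zip(pta.mic_grid, pta.pta_overall, pta.pta_se):
    print(f"MIC {mic:5.1f} mg/L  PTA {100 * p:5.1f}%  (MC SE {100 * se:.2f} pp)")

css = css_distribution(children, 300, seed=42)
print(f"Css median {np.median(css):.1f} mg/L "
      f"(95% interval {np.percentile(css, 2.5):.1f}-{np.percentile(css, 97.5):.1f})")
print(f"dose for 95% attainment of 64 mg/L at 15 kg: "
      f"{required_dose(15, 64, 0.95):.0f} mg/kg/day")
```

prints

```
MIC   2.0 mg/L  PTA 100.0%  (MC SE 0.00 pp)
MIC   4.0 mg/L  PTA 100.0%  (MC SE 0.00 pp)
MIC  16.0 mg/L  PTA  98.7%  (MC SE 0.11 pp)
Css median 49.5 mg/L (95% interval 18.3-130.4)
dose for 95% attainment of 64 mg/L at 15 kg: 1013 mg/kg/day
```

Read: continuous infusion of 300 mg/kg/day keeps essentially every
simulated child above MICs up to 4 mg/L for the whole interval and 98.7%
above the *P. aeruginosa* breakpoint of 16 mg/L; holding the much stricter
64 mg/L level in 95% of small children would need a far-beyond-label daily
dose around 1 g/kg.

The same pipeline is scriptable from the shell:

```bash
pippk simulate-pta --out results/          # PTA curves + regimen table + Css summary
pippk dose-find --weight 15 --weight 40 --weight 65 --out results/
pippk generate-data --out results/         # synthetic two-cohort study (NONMEM-like CSV)
pippk fit  --data results/study.csv --out results/
pippk vpc  --data results/study.csv --out results/
```

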