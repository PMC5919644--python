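# dosepaint

In-silico **dose painting by numbers (DPBN)** on virtual hypoxic
head-and-neck tumors.  The package grows voxelized virtual tumors with a
multiscale tumor response model, redistributes the 2 Gy fraction dose
according to each voxel's microscopic oxygenation and cell density,
simulates adaptively re-optimized fractionated treatments, and quantifies
the benefit as tumor control probability (TCP), D50 and treatment gain.

It is aimed at radiotherapy modellers and computational radiobiologists who
want a reproducible, tested implementation of the full DPBN analysis chain:
oxygen microenvironment → oxygen-dependent cell survival → constrained dose
optimization → adaptive schedules → outcome statistics.

## The model in brief

Cell survival follows the linear-quadratic model with oxygen enhancement
ratios (Wouters–Brown form),

    SF(d, p) = exp[ −α_h·OER_α(p)·d − β_h·(OER_β(p)·d)² ],
    OER(p)   = (k + p·OER_max)/(p + k),

with α = 0.35 Gy⁻¹, β = 0.035 Gy⁻², OER_α,max = 2.5, OER_β,max = 3,
k = 3.28 mmHg, and α_h = α/OER_α,max, β_h = β/OER_β,max².  Each 1.124 mm
voxel carries a 16-bin microscopic pO₂ histogram computed by a
reaction–diffusion oxygenation model (parallel random vessels, Michaelis–
Menten consumption scaled by the viable fraction of the voxel's tumor
cells), so the expected survivors of a treatment fraction are

    C_surv = Σ_i Σ_j c_ij · SF(d_i, p_j).

Fraction doses are redistributed under hard constraints — tumor-mean dose
2 Gy, per-voxel box 1.5–2.5 Gy — minimizing either `C_surv` (OF_surv, a
convex separable problem solved by a KKT multiplier bisection) or the
spatial standard deviation of surviving cells (OF_std, multi-start
projected gradient).  Adaptive schemes (1F, 2F, 3F, FBF3W, FBF4W) decide
when plans are re-optimized on the evolving tumor; TCP populations draw
per-patient radiosensitivity α ~ N(0.35, 0.05) Gy⁻¹, kill cells
binomially when voxel counts are small, fit a logistic dose–response and
report D50 = −b₀/b₁ with bootstrap uncertainties (k = 2).

Four virtual tumors probe which heterogeneity matters: T1 (grown reference:
non-uniform density and vasculature with a ~1 cm hypoxic core), T2 (uniform
density and 6% vascular fraction), T3 (uniform density, grown vasculature),
T4 (grown density, uniform vasculature) — all with the same cell burden.

See `docs/methods.md` for the complete model description, parameter tables
and design decisions.

## Worked example

```python
import numpy as np
from dosepaint import (LQParams, OERParams, survival_fraction, optimize,
                       DoseConstraints)

lq, oer = LQParams(), OERParams()
print("SF(2 Gy, oxic)   =", round(survival_fraction(2.0, 1e6, lq, oer), 4))
print("SF(2 Gy, anoxic) =", round(survival_fraction(2.0, 0.0, lq, oer), 4))

viable = np.array([8.0e5, 2.0e5])                 # cells per voxel
weights = np.array([[1.0, 0.0], [0.0, 1.0]])      # anoxic vs oxic bin
centers = np.array([0.0, 1.0e6])                  # bin pO2, mmHg
plan = optimize(viable, weights, centers, lq, oer, objective="surv",
                constraints=DoseConstraints())
print("optimized doses  =", np.round(plan.doses, 3), "Gy")
print("expected survivors:", round(plan.solver_report["objective_value"]),
      "vs uniform:", round(plan.solver_report["uniform_value"]))
```

prints

```
SF(2 Gy, oxic)   = 0.4317
SF(2 Gy, anoxic) = 0.7441
optimized doses  = [2.5 1.5] Gy
expected survivors: 659565 vs uniform: 681637
```

A 2 Gy fraction kills 57% of well-oxygenated cells but only 26% of anoxic
ones.  When the anoxic voxel holds most of the surviving cells, minimizing
total survival boosts it to the 2.5 Gy box limit and compensates at the
oxic voxel, lowering the expected survivors of the fraction by ~3%; over an
adaptively re-optimized course these per-fraction advantages compound into
a D50 gain of a few Gy for tumors whose hypoxia resolves during treatment.

The same pipeline is scriptable from the shell:

```
dosepaint generate-tumors --out-dir tumors/
dosepaint optimize-dose --tumor T1 --objective surv --out plan.csv
dosepaint run-tcp --tumor T1 --scheme FBF4W --objective surv --out tcp.csv
dosepaint run-experiment --config experiment.yaml
```

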