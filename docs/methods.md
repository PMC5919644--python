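# Methods

`dosepaint` simulates dose painting by numbers (DPBN) on virtual hypoxic
head-and-neck tumors: a voxel-based tumor response model is grown into four
reference tumors, fractionated 2 Gy treatments are delivered with uniform or
adaptively re-optimized non-uniform dose distributions, and outcome is
quantified as tumor control probability (TCP), D50 and treatment gain.  This
note records the model, its free constants, and the design decisions taken
where the problem was genuinely open.

## Cell survival

Radiation response follows the linear-quadratic model with oxygen
enhancement ratios (OER) in the Wouters–Brown form:

    SF(d, p) = exp[ −α_h·OER_α(p)·d − β_h·(OER_β(p)·d)² ]
    OER(p)   = (k + p·OER_max) / (p + k)

with α_h = α/OER_α,max and β_h = β/OER_β,max².  Defaults: α = 0.35 Gy⁻¹,
β = 0.035 Gy⁻², OER_α,max = 2.5, OER_β,max = 3, k = 3.28 mmHg; inter-patient
radiosensitivity variation is α ~ Normal(0.35, 0.05) Gy⁻¹ truncated at
0.05 Gy⁻¹.  "Fully oxic" evaluations use p = 10⁶ mmHg, which is within 10⁻³
of the asymptote for this k.

The expected survivors of a voxel are the sum over its 16-bin microscopic
pO₂ histogram, `Σ_j viable·w_j·SF(d, p_j)`, and the tumor-level survival
`C_surv` sums this over all voxels.

## Microscopic oxygenation

A tumor voxel (1.124 mm) is much larger than the oxygen diffusion range, so
response is governed by the sub-voxel pO₂ distribution.  Capillaries are
modelled as parallel, randomly placed, non-overlapping straight vessels;
the steady-state reaction–diffusion equation

    D ∇²p = M_max · χ · p/(p + k_m),     p = p₀ inside vessels

is solved on a periodic 2-D cross section with a Shortley–Weller
finite-difference scheme (stencil arms shortened to the exact vessel-circle
intersections; second-order at the circular Dirichlet boundaries; Newton
iteration for the Michaelis–Menten sink).  χ ∈ [0, 1] is the consumption
scale of the voxel: the viable fraction of its tumor cells,
viable/(viable+dead) — dead cells occupy space but do not consume.

The resulting fields are condensed into 16-bin histograms (one explicit
anoxic bin [0, 0.01) mmHg plus 15 log-spaced bins up to p₀, resolving the
radiobiologically critical 0–10 mmHg range), averaged over 10 vessel
placements per node, pre-tabulated on a (vascular fraction, consumption)
grid and interpolated bilinearly at every simulated day.  A pre-computed
default table ships with the package and is regenerated by the acceptance
pipeline.

Free constants (none are printed in the source literature for this model
family; all are exposed in the configuration): vessel radius 10 µm,
D = 2000 µm²/s, k_m = 2.5 mmHg, domain side 1124 µm, 96 grid points per
side.  The intravascular pO₂ is 60 mmHg — the arterial end of the
physiological capillary range; with the OER slope k = 3.28 mmHg, the
per-fraction log cell kill of a well-oxygenated tumor at 2 Gy is then
≈ 0.79–0.80, the dose–response scale this model family exhibits (a 40 mmHg
source would cap the kill visibly below it).  The single calibrated scalar
M_max = 35 mmHg/s is set so that a 6% vascular fraction at full consumption
is well oxygenated (median ≈ 41 mmHg) while a 1% vascular fraction stays
hypoxic (median < 5 mmHg) until about half of its tumor cells are dead.
Doubling the grid resolution changes the extravascular mean pO₂ by < 1%;
resolutions below ~80 points per side under-resolve the 10 µm vessels and
are outside the solver's validity range.

## Tumor response model

Each voxel of a 23³ lattice (side 1.124 mm) holds viable tumor cells, dead
tumor cells, capillary cells and normal host cells, all of equal volume;
capacity is μ = 10⁶ cells/mm³.  Intact host tissue occupies 80% of that
packing capacity with a 6% vascular fraction.  The vascular fraction seen
by the oxygenation model is capillary/(occupied tissue), so loss of tumor
mass itself reoxygenates a voxel (shrinkage-driven reoxygenation); the
reported Fig-style trajectories additionally record capillary content per
voxel capacity.

Six processes iterate once per simulated day, in this order on treatment
days: irradiation → proliferation → angiogenesis → dead-cell resorption →
spatial exchange → oxygenation update.

* **Irradiation.** Oxygen-dependent LQ kill per histogram bin; killed cells
  move to the dead compartment.  Voxels with fewer than 10⁴ viable cells
  realize survivors stochastically (the integer count is partitioned over
  the bins multinomially and killed binomially per bin); larger voxels use
  the expected value — cell-killing stochasticity only matters when counts
  are small, and the hybrid keeps population runs fast.  Tumor cells that
  migrated outside the planned target volume receive the uniform margin
  dose (the plan mean).
* **Proliferation.** viable ← viable·2^(Δt/t_p) with t_p = 1200 h switching
  to 120 h two weeks after treatment start (accelerated repopulation);
  growth of untreated virtual tumors uses t_p = 120 h.  Voxels at capacity
  do not grow; their confined proliferation pressure instead crushes
  capillaries at 0.25 of the suppressed growth rate (never below a 1%
  vascular-fraction floor) and atrophies resident normal cells (halving
  time 96 h at full tumor occupancy).  The crush/atrophy channel is what
  dilutes the vasculature of a growing tumor core into a hypoxic core.
* **Angiogenesis.** Capillaries double with t_a = 612 h in voxels whose
  histogram median pO₂ is below 5 mmHg.  The trigger is evaluated through a
  pre-computed critical-vf curve (the median is monotone in both lookup
  coordinates), which makes it cheap on large batches.
* **Resorption.** dead ← dead·2^(−Δt/t_r), t_r = 168 h.
* **Exchange.** Two conservative transport mechanisms move all four
  compartments in proportion to the source voxel's composition:
  above-capacity voxels push their excess into neighbor headroom
  (receivers tolerate 5% overfill so a growth front can invade still-full
  host tissue), and a diffusive flux of 0.3/6 · capacity per unit occupancy
  difference per day flows across every face from fuller to emptier voxel,
  limited by receiver headroom.  This single mechanism produces outward
  tumor growth, inward consolidation of shrinking tumors, and host-tissue
  influx into cleared regions.
* **Oxygenation update.** Histograms are re-derived from the lookup at the
  current (vf, consumption); no persistent per-voxel histogram state is
  kept, which is also how intra-voxel selection is handled: survivors are
  redistributed over the (new) histogram each day.

The daily ordering is fixed as listed; at a 24 h step the outcome is
insensitive to reasonable reorderings because each step changes its
compartment by a small factor per day.

## Virtual tumors

T1 grows from a single seeded cell until the 3888-voxel sphere (≈ 2 cm
diameter) around the lattice center has its outermost shell at half the
packing density; that sphere becomes the fixed planned target volume, which
makes the border cell density ≈ 5·10⁵ cells/mm³ by construction while the
center sits at ≈ 10⁶.  The emergent vasculature is ≈ 1% vf in the ≈ 1 cm
hypoxic core (median pO₂ < 5 mmHg) rising to ≈ 5% at the rim.  Growth is
deterministic: the same parameters reproduce T1 bit for bit.

Variants redistribute the same total cell burden: T2 (uniform density,
uniform 6% vf), T3 (uniform density, grown vasculature), T4 (grown density,
uniform 6% vf).  Uniform density concentrates the entire T1 burden evenly
over the mask voxels; uniform vf sets capillaries to 6% of the occupied
tissue.

## Dose optimization

Each fraction's voxel doses satisfy mean(d) = 2 Gy over the planned target
volume and 1.5 ≤ d_i ≤ 2.5 Gy (±25%).  Two objectives:

* `surv` minimizes total expected survivors.  The objective is strictly
  convex and separable, so the constrained optimum equalizes the marginal
  kill per Gy across voxels not pinned at a box bound; the solver bisects
  the mean-dose multiplier with warm-started Newton updates per voxel.
  Voxels with (near-)zero survivors fall to d_min, releasing their dose
  budget to the surviving voxels — this is what concentrates dose on the
  residual disease late in an adaptive course.  A generic SLSQP path and a
  brute-force grid search serve as independent cross-checks in the tests.
  Note the equal-count two-voxel intuition: minimizing survivors boosts the
  voxel with the larger *marginal kill*, which for equal counts is the oxic
  one; hypoxic voxels attract dose only once their survivors dominate.
* `std` minimizes the standard deviation of per-voxel survivors.  The
  objective is non-convex; it is minimized by projected gradient descent
  (exact Euclidean projection onto the mean+box set by bisection) from five
  starts — uniform, an equalize-survivors heuristic (bisection on a common
  survivor target), and seeded perturbations — keeping the best feasible
  result.  Ties resolve toward the plan closest to uniform.

Failed solves fall back to the uniform plan with a warning in the solver
report; a returned plan is always feasible and never worse than uniform.

## Schedules and outcome statistics

One fraction per weekday from a Monday; adaptive schemes re-optimize before
fraction 1 (1F), fractions 1 and 11 (2F), 1/11/16 (3F), every fraction of
the first three (FBF3W) or four (FBF4W) weeks.  Plans persist until
replaced; beyond the scheme's window treatment continues with uniform 2 Gy.
Re-optimization always uses the population-mean-α deterministic trajectory,
and the same plan sequence is replayed on every TCP patient.

Dose levels extend the fraction count (default 26–42 fractions ≈ 52–84 Gy);
each level simulates 30 patients with stochastic killing and per-patient α
draws.  A patient is controlled when total viable < 1 after the course.
TCP(D) is a maximum-likelihood logistic fit on total mean dose (perfectly
separated outcomes raise an explicit error rather than fitting a divergent
slope), D50 = −b0/b1, uncertainty is a 1000-replicate patient-level
bootstrap reported as 2 SD (k = 2), and gain = D50(uniform) − D50(painted).

## What the generator does and does not emulate

The virtual tumors emulate the published study conditions: equal cell
burden, ≈ 2 cm spheres, the four density/vasculature combinations, an
emergent hypoxic core, and reoxygenation during treatment through falling
consumption, angiogenesis and shrinkage.  They do not emulate patient
anatomy, non-spherical shapes, tumor stem-cell subpopulations, LET/RBE or
repair kinetics, intervessel pO₂ gradients along vessels, or
image-acquisition noise in the adaptive loop — conclusions from passing
tests transfer to real tumors only insofar as those simplifications are
acceptable.

## Numerical and scale choices

Population simulations are batched (all 30 patients advance as one array
program; the hot per-day loops are numba kernels cross-checked against the
histogram-explicit numpy implementations).  The test suite and the
reproduction script run TCP populations at 30 patients per level with 6–11
dose levels and a few hundred bootstrap replicates; these sizes put
Monte-Carlo error on an individual D50 near the 1–1.5 Gy scale, the same
order as the 2 SD uncertainties of the quantities they estimate.
Comparative claims (treatment gains, scheme and objective orderings) are
therefore evaluated as *paired* comparisons: every treatment arm uses the
same population seed and dose levels, so each virtual patient receives the
same radiosensitivity draw under every treatment and the patient-sampling
term cancels from gain differences.

## Known limitations

* The exchange, vascular-crush and host-atrophy laws are reconstructions:
  the published model family states the six processes but not their update
  equations.  All their constants are configuration-exposed, and the
  generator was calibrated once against the published radial profiles and
  hypoxic-core geometry, not against outcome dose–response values.
* With α = 0.35 Gy⁻¹, β = 0.035 Gy⁻², μ = 10⁶ cells/mm³ and the
  repopulation switch, the per-fraction log-kill at a 2 Gy mean is bounded
  by ≈ 0.85 even for a fully oxic tumor under the most favorable ±25%
  redistribution, so no plan sequence can reach control below ≈ 30
  fractions (≈ 60 Gy).  Painted-treatment control points below that bound
  are outside what this parameterization can produce; the package reports
  what its model computes.
* The mean-dose constraint weights voxels equally (the plain voxel
  average), not by cell count.
* D50 estimates at 30 patients/level carry ≈ 1 Gy Monte-Carlo error;
  orderings of nearby D50s (differences ≲ 1 Gy) are not stable claims at
  this population size.
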