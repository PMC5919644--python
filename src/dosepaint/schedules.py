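"""Fractionation calendars and adaptive dose-painting schemes.

Treatment follows conventional fractionation: one fraction per weekday,
starting on a Monday, with weekend breaks.  The adaptive schemes differ only
in *when* the dose distribution is re-optimized on the evolving tumor:

========  ====================================================
uniform   never (2 Gy everywhere, the conventional reference)
1F        before fraction 1 only
2F        before fractions 1 and 11 (start of week 3)
3F        before fractions 1, 11 and 16 (start of weeks 3, 4)
FBF3W     before every fraction of the first 3 weeks (1-15)
FBF4W     before every fraction of the first 4 weeks (1-20)
========  ====================================================

A plan stays in effect until replaced.  Beyond the scheme's adaptation
window the treatment continues with the uniform 2 Gy distribution (after
week 3 for FBF3W, after week 4 for all the others), reflecting that dose
painting is abandoned once cell numbers are low and imaging/optimization
would chase stochastic noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_optimization import DoseConstraints, DosePlan, optimize, uniform_plan
from .oxygenation import OxygenLookup
from .radiobiology import LQParams, OERParams
from .tumor_model import BioParams, TumorGrid, step_day
from .virtual_tumors import core_mask

SCHEMES = ("uniform", "1F", "2F", "3F", "FBF3W", "FBF4W")
FRACTIONS_PER_WEEK = 5


def build_calendar(n_fractions: int) -> np.ndarray:
    """Calendar-day index of each fraction (day 0 = first Monday).

    Five fractions per seven-day week: fraction f (1-based) falls on day
    ``7*((f-1)//5) + (f-1)%5``, skipping weekends.
    """
    if n_fractions < 1:
        raise ValueError("need at least one fraction")
    f = np.arange(n_fractions)
    return 7 * (f // FRACTIONS_PER_WEEK) + f % FRACTIONS_PER_WEEK


def optimization_fractions(scheme: str, n_fractions: int) -> set[int]:
    """1-based fraction indices before which a new plan is computed."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    windows = {
        "uniform": set(),
        "1F": {1},
        "2F": {1, 11},
        "3F": {1, 11, 16},
        "FBF3W": set(range(1, 16)),
        "FBF4W": set(range(1, 21)),
    }
    return {f for f in windows[scheme] if f <= n_fractions}


def painting_window(scheme: str) -> int:
    """Last fraction at which a painted (non-uniform) plan may be delivered."""
    return {"uniform": 0, "FBF3W": 15}.get(scheme, 20)


@dataclass(frozen=True)
class TreatmentSchedule:
    """A fractionation calendar plus adaptation scheme."""

    scheme: str
    n_fractions: int

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def fraction_days(self) -> np.ndarray:
        return build_calendar(self.n_fractions)

    @property
    def optimization_set(self) -> set[int]:
        return optimization_fractions(self.scheme, self.n_fractions)

    @property
    def total_dose(self) -> float:
        return 2.0 * self.n_fractions


@dataclass
class TreatmentResult:
    """Outcome of one treatment simulation."""

    schedule: TreatmentSchedule
    plans: list[DosePlan]              # plan delivered at each fraction (1-based order)
    trajectory: pd.DataFrame           # per-day summaries
    grid: TumorGrid                    # final state
    controlled: np.ndarray = field(default=None)  # (B,) viable < 1 at end
    first_control_fraction: int | None = None     # planning runs: earliest control

    @property
    def n_optimizations(self) -> int:
        """Distinct optimization events (a plan persists across fractions)."""
        return len({id(p) for p in self.plans if p.solver_report.get("fresh", False)})


def run_treatment(grid: TumorGrid, schedule: TreatmentSchedule,
                  objective: str, constraints: DoseConstraints | None,
                  lq: LQParams, oer: OERParams, lookup: OxygenLookup,
                  bio: BioParams | None = None,
                  rng: np.random.Generator | None = None,
                  alpha: np.ndarray | None = None,
                  plans: list[DosePlan] | None = None,
                  stop_when_controlled: bool = False) -> TreatmentResult:
    """Simulate a full treatment course on (a batch of) tumors.

    Two modes:

    * planning mode (``plans=None``): re-optimizes the dose distribution at
      the scheme's adaptation fractions using the *current* simulated state
      (run this with the population-mean radiosensitivity and ``rng=None``
      for the deterministic planning trajectory);
    * delivery mode (``plans`` given): replays precomputed plans on a
      (batched) population, e.g. with per-patient alphas and stochastic
      cell killing.

    Returns the per-day trajectory (total viable/dead cells, core mean
    vascular fraction), the plans actually delivered, the final state, and
    per-batch-member control (total viable < 1 at course end).
    """
    bio = bio or BioParams()
    constraints = constraints or DoseConstraints()
    n_mask = int(grid.tumor_mask.sum())
    calendar = schedule.fraction_days
    opt_set = schedule.optimization_set if plans is None else set()
    window = painting_window(schedule.scheme)
    core = core_mask(grid)
    uni = uniform_plan(n_mask, constraints)
    current = uni
    delivered: list[DosePlan] = []
    rows = []
    controlled_at = None
    day_to_fraction = {int(d): f + 1 for f, d in enumerate(calendar)}
    for day in range(int(calendar[-1]) + 1):
        fraction = day_to_fraction.get(day)
        doses = None
        if fraction is not None:
            if plans is not None:
                current = plans[fraction - 1]
            elif fraction in opt_set and objective != "uniform":
                plan = optimize(grid.mask_view(grid.viable)[0],
                                grid.histogram_weights(lookup)[0],
                                lookup.bin_centers, lq, oer,
                                objective=objective, constraints=constraints)
                plan.solver_report["fresh"] = True
                current = plan
            if fraction > window and current.objective != "uniform":
                current = uni
            delivered.append(current)
            doses = current.doses
        step_day(grid, doses, bio, lq, oer, lookup, rng=rng, alpha=alpha)
        total_v = grid.total_viable()
        v_c = grid.viable[:, core]
        d_c = grid.dead[:, core]
        c_c = grid.capillary[:, core]
        n_c = grid.normal[:, core]
        tr_c = v_c + d_c + c_c + n_c
        with np.errstate(invalid="ignore", divide="ignore"):
            vf_c = np.where(tr_c > 0, c_c / tr_c, 0.0)
        rows.append({
            "day": day,
            "fraction": fraction if fraction is not None else 0,
            "total_viable": float(total_v.mean()),
            "total_dead": float(grid.dead.sum(axis=(1, 2, 3)).mean()),
            "core_vf": float(vf_c.mean()),
            "core_vf_capacity": float(c_c.mean() / grid.capacity),
            "plan": current.objective if fraction is not None else "",
        })
        if fraction is not None and controlled_at is None and np.all(total_v < 1.0):
            controlled_at = fraction
            if stop_when_controlled:
                break
    trajectory = pd.DataFrame(rows)
    return TreatmentResult(
        schedule=schedule,
        plans=delivered,
        trajectory=trajectory,
        grid=grid,
        controlled=grid.total_viable() < 1.0,
        first_control_fraction=controlled_at,
    )


def plan_treatment(grid: TumorGrid, schedule: TreatmentSchedule, objective: str,
                   constraints: DoseConstraints | None, lq: LQParams,
                   oer: OERParams, lookup: OxygenLookup,
                   bio: BioParams | None = None) -> TreatmentResult:
    """Deterministic planning run with the population-mean radiosensitivity.

    Returns the treatment result whose ``plans`` list is replayed verbatim
    on TCP populations; fractions beyond ``schedule.n_fractions`` of longer
    courses are uniform by construction (extend with ``extend_plans``).
    """
    return run_treatment(grid.copy(), schedule, objective, constraints,
                         lq, oer, lookup, bio=bio, rng=None)


def extend_plans(plans: list[DosePlan], n_fractions: int,
                 constraints: DoseConstraints | None = None) -> list[DosePlan]:
    """Pad a delivered-plan list with uniform plans up to ``n_fractions``."""
    constraints = constraints or DoseConstraints()
    if not plans:
        raise ValueError("empty plan list")
    n_mask = plans[0].doses.size
    out = list(plans[:n_fractions])
    while len(out) < n_fractions:
        out.append(uniform_plan(n_mask, constraints))
    return out
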