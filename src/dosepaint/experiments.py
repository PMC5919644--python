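"""Prepackaged study workflows: the simulation experiments of the analysis.

These functions wire the pipeline stages together for the standard
experiments run on the virtual tumor set: uniform-dose TCP curves,
adaptively painted treatments with their TCP curves and treatment gains,
reoxygenation trajectories under uniform irradiation, and the
planning/stochastic/population decomposition of response variability for a
single tumor-scheme combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_optimization import DoseConstraints
from .oxygenation import OxygenLookup
from .outcome_stats import (PopulationSpec, TCPResult, simulate_population,
                            tcp_result, treatment_gain)
from .radiobiology import LQParams, OERParams
from .schedules import TreatmentSchedule, plan_treatment
from .tumor_model import BioParams, TumorGrid


def tcp_for(grid: TumorGrid, scheme: str, objective: str, pop: PopulationSpec,
            lq: LQParams, oer: OERParams, lookup: OxygenLookup,
            bio: BioParams | None = None,
            constraints: DoseConstraints | None = None,
            fixed_alpha: bool = False, n_boot: int = 500):
    """Plan (mean alpha) and simulate the TCP population for one combination.

    Returns (planning TreatmentResult, per-patient outcomes, TCPResult).
    """
    bio = bio or BioParams()
    constraints = constraints or DoseConstraints()
    n_max = int(max(pop.dose_levels))
    planning = plan_treatment(grid, TreatmentSchedule(scheme, n_max), objective,
                              constraints, lq, oer, lookup, bio=bio)
    outcomes = simulate_population(grid, scheme, planning.plans, pop, lq, oer,
                                   lookup, bio=bio, constraints=constraints,
                                   fixed_alpha=fixed_alpha)
    result = tcp_result(outcomes, scheme=scheme, objective=objective,
                        n_boot=n_boot, seed=pop.seed)
    return planning, outcomes, result


def uniform_tcp_study(tumors: dict, pop: PopulationSpec, lq, oer, lookup,
                      bio=None, constraints=None) -> dict[str, TCPResult]:
    """Conventional 2 Gy uniform treatment TCP for every tumor."""
    out = {}
    for name, grid in tumors.items():
        _, _, res = tcp_for(grid, "uniform", "uniform", pop, lq, oer, lookup,
                            bio=bio, constraints=constraints)
        out[name] = res
    return out


def gain_study(tumors: dict, schemes, objectives, pop: PopulationSpec,
               uniform_results: dict, lq, oer, lookup, bio=None,
               constraints=None) -> pd.DataFrame:
    """Treatment gains D50_conv - D50_painted for tumor x scheme x objective."""
    rows = []
    for name, grid in tumors.items():
        d50_conv = uniform_results[name].d50
        for scheme in schemes:
            for objective in objectives:
                _, _, res = tcp_for(grid, scheme, objective, pop, lq, oer,
                                    lookup, bio=bio, constraints=constraints)
                rows.append({
                    "tumor": name, "scheme": scheme, "objective": objective,
                    "d50": res.d50, "d50_uncertainty": res.d50_uncertainty,
                    "gain": treatment_gain(d50_conv, res.d50),
                })
    return pd.DataFrame(rows)


def reoxygenation_study(tumors: dict, n_fractions: int, lq, oer, lookup,
                        bio=None, constraints=None) -> pd.DataFrame:
    """Core vascular-fraction trajectories under uniform irradiation.

    The reoxygenation measure of a tumor is the rise of its core-averaged
    vascular fraction (capillary cells / voxel capacity) from treatment
    start to the end of the course.
    """
    rows = []
    for name, grid in tumors.items():
        planning = plan_treatment(grid, TreatmentSchedule("uniform", n_fractions),
                                  "uniform", constraints, lq, oer, lookup, bio=bio)
        tr = planning.trajectory
        rows.append({
            "tumor": name,
            "vf_start": tr["core_vf_capacity"].iloc[0],
            "vf_end": tr["core_vf_capacity"].iloc[-1],
            "reox": tr["core_vf_capacity"].iloc[-1] - tr["core_vf_capacity"].iloc[0],
            "trajectory": tr[["day", "core_vf", "core_vf_capacity"]],
        })
    return pd.DataFrame(rows)


@dataclass
class ResponseDecomposition:
    """Fig 6-style variability decomposition for one tumor and scheme."""

    control_dose_mean_alpha: float      # Gy; deterministic planning run
    d50_fixed_alpha: float              # Gy; stochastic kill only
    d50_normal_alpha: float             # Gy; + population radiosensitivity
    planning: object
    fixed_result: TCPResult
    normal_result: TCPResult


def response_decomposition(grid: TumorGrid, scheme: str, objective: str,
                           pop: PopulationSpec, lq, oer, lookup, bio=None,
                           constraints=None, n_boot: int = 500) -> ResponseDecomposition:
    """Separate the sources of response variability for one treatment.

    (i) the deterministic mean-radiosensitivity planning run and its control
    dose; (ii) the TCP of replicate tumors with the population-mean alpha,
    where only cell-killing stochasticity varies; (iii) the TCP with
    per-patient alpha ~ Normal(mean, sigma).
    """
    bio = bio or BioParams()
    constraints = constraints or DoseConstraints()
    n_max = int(max(pop.dose_levels))
    planning = plan_treatment(grid, TreatmentSchedule(scheme, n_max), objective,
                              constraints, lq, oer, lookup, bio=bio)
    if planning.first_control_fraction is None:
        control_dose = float("nan")
    else:
        control_dose = 2.0 * planning.first_control_fraction
    fixed = simulate_population(grid, scheme, planning.plans, pop, lq, oer,
                                lookup, bio=bio, constraints=constraints,
                                fixed_alpha=True)
    fixed_res = tcp_result(fixed, scheme=scheme, objective=objective,
                           n_boot=n_boot, seed=pop.seed)
    normal = simulate_population(grid, scheme, planning.plans, pop, lq, oer,
                                 lookup, bio=bio, constraints=constraints)
    normal_res = tcp_result(normal, scheme=scheme, objective=objective,
                            n_boot=n_boot, seed=pop.seed + 1)
    return ResponseDecomposition(
        control_dose_mean_alpha=control_dose,
        d50_fixed_alpha=fixed_res.d50,
        d50_normal_alpha=normal_res.d50,
        planning=planning,
        fixed_result=fixed_res,
        normal_result=normal_res,
    )
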