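"""Tumor control probability curves, D50 and treatment gain.

Dose levels are realized by extending the number of 2 Gy fractions (not by
raising the fraction size).  At each level a population of virtual patients
(default 30) is simulated with stochastic cell killing; patient-to-patient
radiosensitivity variation enters as alpha ~ Normal(alpha_mean, sigma_alpha)
truncated at a small positive floor.  A patient is controlled when no viable
tumor cell survives the course (total viable < 1 after integerized killing).

Control outcomes are fitted with a univariate logistic regression on the
total mean dose, TCP(D) = 1 / (1 + exp(-(b0 + b1 D))), characterized by
D50 = -b0/b1, the dose at 50% control.  Uncertainty on D50 comes from a
patient-level bootstrap (resampling outcomes within each dose level) and is
reported as two standard deviations (coverage factor k = 2).  The treatment
gain of a painted treatment is D50(conventional uniform) - D50(painted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dose_optimization import DoseConstraints, DosePlan
from .oxygenation import OxygenLookup
from .radiobiology import LQParams, OERParams
from .schedules import TreatmentSchedule, extend_plans, run_treatment
from .tumor_model import BioParams, TumorGrid

ALPHA_FLOOR = 0.05  # Gy^-1; truncation of the population alpha draw


class SeparationError(RuntimeError):
    """Logistic fit is non-identifiable (perfectly separated outcomes)."""


@dataclass(frozen=True)
class PopulationSpec:
    """TCP population design."""

    n_per_dose: int = 30
    alpha_mean: float = 0.35
    alpha_sd: float = 0.05
    dose_levels: tuple = (20, 23, 26, 29, 32, 35, 38, 41)  # fraction counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_dose < 2:
            raise ValueError("n_per_dose must be >= 2")
        if np.any(np.diff(self.dose_levels) <= 0):
            raise ValueError("dose_levels must be strictly increasing")


@dataclass
class TCPResult:
    """Fitted dose-response of one (tumor, scheme, objective) combination."""

    table: pd.DataFrame          # per level: total_dose, controlled, n
    coefficients: tuple          # (b0, b1)
    d50: float                   # Gy
    d50_uncertainty: float       # Gy, 2 SD (k = 2)
    scheme: str = ""
    objective: str = ""

    def tcp(self, dose) -> np.ndarray:
        b0, b1 = self.coefficients
        return 1.0 / (1.0 + np.exp(-(b0 + b1 * np.asarray(dose, dtype=float))))


def draw_alphas(spec: PopulationSpec, rng: np.random.Generator,
                fixed: bool = False) -> np.ndarray:
    """Per-patient radiosensitivities, truncated at the positive floor."""
    if fixed or spec.alpha_sd == 0:
        return np.full(spec.n_per_dose, spec.alpha_mean)
    return np.maximum(rng.normal(spec.alpha_mean, spec.alpha_sd, spec.n_per_dose),
                      ALPHA_FLOOR)


def simulate_population(grid: TumorGrid, scheme: str, plans: list[DosePlan],
                        pop: PopulationSpec, lq: LQParams, oer: OERParams,
                        lookup: OxygenLookup, bio: BioParams | None = None,
                        constraints: DoseConstraints | None = None,
                        fixed_alpha: bool = False) -> pd.DataFrame:
    """Simulate the TCP population over all dose levels.

    ``plans`` are the precomputed fraction plans from the population-mean
    planning run; they are padded with uniform plans for the longer courses.
    Returns a tidy DataFrame with one row per patient: dose level (total
    Gy), alpha, controlled.
    """
    if grid.batch != 1:
        raise ValueError("pass a single-batch tumor; the population is tiled here")
    bio = bio or BioParams()
    rows = []
    for level_idx, n_frac in enumerate(pop.dose_levels):
        rng = np.random.default_rng([pop.seed, level_idx])
        alphas = draw_alphas(pop, rng, fixed=fixed_alpha)
        batch = grid.tile(pop.n_per_dose)
        schedule = TreatmentSchedule(scheme, int(n_frac))
        level_plans = extend_plans(plans, int(n_frac), constraints)
        res = run_treatment(batch, schedule, objective="replay",
                            constraints=constraints, lq=lq, oer=oer,
                            lookup=lookup, bio=bio, rng=rng, alpha=alphas,
                            plans=level_plans)
        for alpha, ctrl in zip(alphas, res.controlled):
            rows.append({"n_fractions": int(n_frac),
                         "total_dose": 2.0 * n_frac,
                         "alpha": float(alpha),
                         "controlled": bool(ctrl)})
    return pd.DataFrame(rows)


def control_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-patient outcomes into per-level control counts."""
    agg = (outcomes.groupby("total_dose")["controlled"]
           .agg(controlled="sum", n="size").reset_index())
    agg["rate"] = agg["controlled"] / agg["n"]
    return agg


def fit_tcp(outcomes: pd.DataFrame) -> tuple[float, float]:
    """Maximum-likelihood logistic fit of control vs total mean dose.

    Raises :class:`SeparationError` when the outcomes are perfectly
    separated in dose (the slope diverges and D50 is not identifiable).
    """
    y = outcomes["controlled"].to_numpy(dtype=float)
    d = outcomes["total_dose"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise SeparationError("all outcomes identical; logistic fit undefined")
    lo = d[y == 0].max()
    hi = d[y == 1].min()
    if hi > lo:
        raise SeparationError("outcomes perfectly separated in dose")
    X = sm.add_constant(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    b0, b1 = fit.params
    if not np.all(np.isfinite([b0, b1])) or b1 <= 0:
        raise SeparationError("logistic fit did not converge to a rising curve")
    return float(b0), float(b1)


def d50(coefficients: tuple[float, float]) -> float:
    """Dose at 50% control: the (negated) ratio of the logistic coefficients."""
    b0, b1 = coefficients
    if b1 == 0:
        raise ValueError("zero slope; D50 undefined")
    return -b0 / b1


def bootstrap_d50(outcomes: pd.DataFrame, n_boot: int = 1000,
                  seed: int = 0) -> float:
    """2-SD bootstrap uncertainty of D50 (patients resampled within levels)."""
    rng = np.random.default_rng(seed)
    groups = [g.reset_index(drop=True) for _, g in outcomes.groupby("total_dose")]
    values = []
    for _ in range(n_boot):
        parts = [g.iloc[rng.integers(0, len(g), len(g))] for g in groups]
        sample = pd.concat(parts, ignore_index=True)
        try:
            values.append(d50(fit_tcp(sample)))
        except SeparationError:
            continue  # degenerate resample; skip
    if len(values) < max(10, n_boot // 10):
        return float("nan")
    return 2.0 * float(np.std(values))


def tcp_result(outcomes: pd.DataFrame, scheme: str = "", objective: str = "",
               n_boot: int = 1000, seed: int = 0) -> TCPResult:
    """Fit, D50 and bootstrap uncertainty in one call."""
    coeff = fit_tcp(outcomes)
    return TCPResult(
        table=control_table(outcomes),
        coefficients=coeff,
        d50=d50(coeff),
        d50_uncertainty=bootstrap_d50(outcomes, n_boot=n_boot, seed=seed),
        scheme=scheme,
        objective=objective,
    )


def treatment_gain(d50_conv: float, d50_dpbn: float) -> float:
    """Gain of a painted treatment over the conventional uniform one (Gy)."""
    return d50_conv - d50_dpbn
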