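"""Run configuration: validation, serialization and the experiment driver.

A single YAML (or dict) configuration fully specifies an experiment:
biological parameters, LQ/OER radiosensitivity, oxygenation-model numerics,
tumor selection, adaptive scheme, optimization objective, dose constraints,
TCP population design and seeds.  Defaults reproduce the head-and-neck
parameter set used throughout the package.  Unknown keys are rejected (a
typo must not silently fall back to a default).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dose_optimization import DoseConstraints
from .oxygenation import (OxygenLookup, TOMParams, build_lookup,
                          default_lookup)
from .outcome_stats import PopulationSpec, tcp_result, simulate_population, treatment_gain
from .radiobiology import LQParams, OERParams
from .schedules import SCHEMES, TreatmentSchedule, plan_treatment
from .tumor_model import BioParams
from .virtual_tumors import TUMOR_SPECS, make_tumor_set

log = logging.getLogger("dosepaint")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated experiment configuration (defaults = study conditions)."""

    bio: BioParams = field(default_factory=BioParams)
    lq: LQParams = field(default_factory=LQParams)
    oer: OERParams = field(default_factory=OERParams)
    tom: TOMParams = field(default_factory=TOMParams)
    constraints: DoseConstraints = field(default_factory=DoseConstraints)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    tumors: tuple = ("T1", "T2", "T3", "T4")
    schemes: tuple = ("uniform", "1F", "2F", "3F", "FBF3W", "FBF4W")
    objectives: tuple = ("surv", "std")
    seed: int = 0
    lookup_path: str | None = None   # None -> packaged default lookup
    output_dir: str = "results"

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(to_dict(self), sort_keys=True).encode()).hexdigest()[:12]


_SECTIONS = {
    "bio": BioParams,
    "lq": LQParams,
    "oer": OERParams,
    "tom": TOMParams,
    "constraints": DoseConstraints,
    "population": PopulationSpec,
}
_SCALARS = ("tumors", "schemes", "objectives", "seed", "lookup_path", "output_dir")


def validate_config(raw: dict | None) -> RunConfig:
    """Build a :class:`RunConfig` from a (possibly partial) plain dict.

    Every section accepts only its dataclass's field names; ranges are
    enforced by the dataclasses themselves.  Missing entries take the
    defaults above.
    """
    raw = dict(raw or {})
    kwargs = {}
    for section, cls in _SECTIONS.items():
        entries = raw.pop(section, {})
        if not isinstance(entries, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(entries) - valid
        if unknown:
            raise ConfigError(f"unknown keys in {section!r}: {sorted(unknown)}")
        if section == "population" and "dose_levels" in entries:
            entries["dose_levels"] = tuple(entries["dose_levels"])
        try:
            kwargs[section] = cls(**entries)
        except ValueError as err:
            raise ConfigError(f"invalid {section!r}: {err}") from err
    for key in _SCALARS:
        if key in raw:
            value = raw.pop(key)
            if key in ("tumors", "schemes", "objectives"):
                value = tuple(value)
            kwargs[key] = value
    if raw:
        raise ConfigError(f"unknown configuration keys: {sorted(raw)}")
    cfg = RunConfig(**kwargs)
    for t in cfg.tumors:
        if t not in TUMOR_SPECS:
            raise ConfigError(f"unknown tumor {t!r}")
    for s in cfg.schemes:
        if s not in SCHEMES:
            raise ConfigError(f"unknown scheme {s!r}")
    for o in cfg.objectives:
        if o not in ("surv", "std"):
            raise ConfigError(f"unknown objective {o!r}")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def to_dict(cfg: RunConfig) -> dict:
    out = {}
    for section, _ in _SECTIONS.items():
        out[section] = dataclasses.asdict(getattr(cfg, section))
    out["population"]["dose_levels"] = list(out["population"]["dose_levels"])
    for key in _SCALARS:
        value = getattr(cfg, key)
        out[key] = list(value) if isinstance(value, tuple) else value
    return out


def get_lookup(cfg: RunConfig) -> OxygenLookup:
    """Load the configured oxygen lookup, rebuilding transparently if absent."""
    if cfg.lookup_path is None:
        return default_lookup()
    path = Path(cfg.lookup_path)
    if not path.exists():
        log.warning("oxygen lookup %s missing; rebuilding (this takes minutes)", path)
        lookup = build_lookup(params=cfg.tom, seed=cfg.seed)
        path.parent.mkdir(parents=True, exist_ok=True)
        lookup.to_json(path)
        return lookup
    return OxygenLookup.from_json(path)


def run_experiment(cfg: RunConfig) -> dict:
    """Execute the configured pipeline end to end.

    Stages: oxygen lookup -> virtual tumors -> per (tumor, scheme,
    objective) planning run and TCP population -> D50s and treatment gains.
    Writes trajectory CSVs, a TCP summary JSON and a copy of the config
    under ``cfg.output_dir``; returns the summary dict.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log.info("experiment %s starting", chash)

    try:
        lookup = get_lookup(cfg)
    except Exception as err:
        raise RuntimeError(f"stage build-oxygen-lookup failed: {err}") from err
    try:
        tumors = make_tumor_set(cfg.bio, lookup)
    except Exception as err:
        raise RuntimeError(f"stage generate-tumors failed: {err}") from err

    summary = {"config_hash": chash, "results": []}
    n_max = int(max(cfg.population.dose_levels))
    for tumor_name in cfg.tumors:
        grid = tumors[tumor_name]
        combos = [("uniform", "uniform")]
        combos += [(s, o) for s in cfg.schemes if s != "uniform"
                   for o in cfg.objectives]
        d50_conv = None
        for scheme, objective in combos:
            label = f"{tumor_name}_{scheme}_{objective}"
            try:
                planning = plan_treatment(grid, TreatmentSchedule(scheme, n_max),
                                          objective, cfg.constraints, cfg.lq,
                                          cfg.oer, lookup, bio=cfg.bio)
                outcomes = simulate_population(
                    grid, scheme, planning.plans, cfg.population, cfg.lq,
                    cfg.oer, lookup, bio=cfg.bio, constraints=cfg.constraints)
                res = tcp_result(outcomes, scheme=scheme, objective=objective,
                                 seed=cfg.seed)
            except Exception as err:
                raise RuntimeError(f"stage run-tcp[{label}] failed: {err}") from err
            planning.trajectory.assign(config_hash=chash).to_csv(
                out_dir / f"trajectory_{label}.csv", index=False)
            entry = {
                "tumor": tumor_name, "scheme": scheme, "objective": objective,
                "d50": res.d50, "d50_uncertainty": res.d50_uncertainty,
                "control_dose_mean_alpha":
                    (2.0 * planning.first_control_fraction
                     if planning.first_control_fraction else None),
            }
            if scheme == "uniform":
                d50_conv = res.d50
            elif d50_conv is not None:
                entry["gain"] = treatment_gain(d50_conv, res.d50)
            summary["results"].append(entry)
            log.info("%s: D50 = %.1f Gy", label, res.d50)
    with open(out_dir / "tcp_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh)
    return summary
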