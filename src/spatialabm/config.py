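"""YAML configuration loading for simulations and experiments.

One canonical dialect (YAML). The schema mirrors the dataclasses:

.. code-block:: yaml

    run:
      replicates: 3
      seeds: [1, 2, 3]
      duration_days: 5
      save_interval_min: 60
    types:
      cancer: {division_rate: 0.03, apoptosis_rate: 0.004, radius: 8,
               max_neighbors_for_division: 6}
      healthy: {radius: 8}
      CD8: {motility_speed: 2.0, persistence_time: 10, radius: 8}
    attack: {attack_rate: 0.1, attack_duration: 30, kill_probability: 0.8,
             contact_scale: 1.25}
    mechanics: {repulsion_strength: 10, dt_mech: 0.5, dt_phen: 6}
    domain: [-800, -800, 800, 800]
    analysis: {bin_width: 10, bin_max: 200, contact_scale: 1.25}
    scenarios:
      - {name: wellmixed, strategy: wellmixed,
         counts: {cancer: 1500, healthy: 800, CD8: 600}, disc_radius: 450}
      - {name: structured, strategy: structured, inner_radius: 400,
         ring_outer_radius: 600}
      - {name: spatial, strategy: spatial}   # synthetic sample by default

Every key is optional; omissions fall back to the shipped defaults.
"""
from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .errors import ConfigError
from .experiment import (
    AnalysisParams,
    DEFAULT_COUNTS,
    ExperimentConfig,
    ScenarioSpec,
    default_experiment_config,
)
from .geometry import Rectangle
from .model import (
    AttackParams,
    CellTypeParams,
    MechanicsParams,
    SimulationConfig,
    default_config,
)
from .synth import SampleSpec


def simulation_config_from_dict(data: Mapping[str, Any]) -> SimulationConfig:
    """Build a SimulationConfig from a (possibly partial) mapping."""
    base = default_config()
    types = base.types
    if "types" in data:
        types = {
            name: CellTypeParams(**params)
            for name, params in data["types"].items()
        }
    attack = AttackParams(**data["attack"]) if "attack" in data else base.attack
    mech = (
        MechanicsParams(**data["mechanics"])
        if "mechanics" in data
        else base.mechanics
    )
    domain = (
        Rectangle(*map(float, data["domain"])) if "domain" in data else base.domain
    )
    run = data.get("run", {})
    cfg = SimulationConfig(
        types=types,
        attack=attack,
        mechanics=mech,
        domain=domain,
        duration_min=float(run.get("duration_days", 5.0)) * 24.0 * 60.0,
        save_interval_min=float(run.get("save_interval_min", 60.0)),
        attacker_type=data.get("attacker_type", "CD8"),
        target_type=data.get("target_type", "cancer"),
    )
    cfg.validate()
    return cfg


def _scenario_from_dict(data: Mapping[str, Any]) -> ScenarioSpec:
    for key in ("name", "strategy"):
        if key not in data:
            raise ConfigError(f"scenario entry missing {key!r}: {dict(data)}")
    kwargs: dict[str, Any] = {
        "name": data["name"],
        "strategy": data["strategy"],
        "counts": dict(data.get("counts", DEFAULT_COUNTS)),
    }
    for key in ("disc_radius", "inner_radius", "ring_outer_radius"):
        if key in data:
            kwargs[key] = float(data[key])
    if "epithelial_types" in data:
        kwargs["epithelial_types"] = frozenset(data["epithelial_types"])
    if "immune_types" in data:
        kwargs["immune_types"] = frozenset(data["immune_types"])
    if "cell_table" in data:
        kwargs["cell_table_path"] = str(data["cell_table"])
    if "sample" in data:
        kwargs["sample_spec"] = SampleSpec(**data["sample"])
    return ScenarioSpec(**kwargs)


def experiment_config_from_dict(data: Mapping[str, Any]) -> ExperimentConfig:
    """Build an ExperimentConfig from a (possibly partial) mapping."""
    sim = simulation_config_from_dict(data)
    run = data.get("run", {})
    base = default_experiment_config()
    scenarios = (
        [_scenario_from_dict(s) for s in data["scenarios"]]
        if "scenarios" in data
        else base.scenarios
    )
    analysis = (
        AnalysisParams(**data["analysis"]) if "analysis" in data else base.analysis
    )
    cfg = ExperimentConfig(
        scenarios=scenarios,
        replicates=int(run.get("replicates", 3)),
        seeds=[int(s) for s in run.get("seeds", (1, 2, 3))],
        duration_days=float(run.get("duration_days", 5.0)),
        sim=sim,
        analysis=analysis,
    )
    cfg.validate()
    return cfg


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Load an experiment config from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return experiment_config_from_dict(data)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load just the simulation sections from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return simulation_config_from_dict(data)


def default_config_yaml() -> str:
    """The shipped defaults rendered as a YAML document (a config template)."""
    exp = default_experiment_config()
    sim = exp.sim
    doc = {
        "run": {
            "replicates": exp.replicates,
            "seeds": list(exp.seeds),
            "duration_days": exp.duration_days,
            "save_interval_min": sim.save_interval_min,
        },
        "types": {name: asdict(tp) for name, tp in sim.types.items()},
        "attack": asdict(sim.attack),
        "mechanics": asdict(sim.mechanics),
        "domain": [sim.domain.x_min, sim.domain.y_min,
                   sim.domain.x_max, sim.domain.y_max],
        "analysis": asdict(exp.analysis),
        "scenarios": [
            {
                "name": s.name,
                "strategy": s.strategy,
                "counts": dict(s.counts),
                "disc_radius": s.disc_radius,
                "inner_radius": s.inner_radius,
                "ring_outer_radius": s.ring_outer_radius,
            }
            for s in exp.scenarios
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)
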