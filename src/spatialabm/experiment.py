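"""End-to-end experiment driver: three initializations x replicates x readouts.

The default experiment mirrors the study design: well-mixed, structured and
spatial-informed initializations, each simulated three times over five
simulated days (nine runs), followed by replicate-aggregated readouts —
cancer-count and ongoing-attack series (mean ± 1 SD), per-replicate
cross-PCF time series, and the endpoint component-size CDF.

Placement seeding follows the study conditions: the synthetic placements
(well-mixed, structured) redraw positions per replicate, whereas the
spatial-informed scenario reuses one placement across replicates so that
stochasticity enters only through the dynamics.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .geometry import Annulus, Disc, Rectangle
from .initialize import (
    InitialState,
    init_spatial_informed,
    init_structured,
    init_well_mixed,
)
from .io import (
    read_cell_table_csv,
    write_snapshot_csv,
    write_timeseries_csv,
)
from .model import SimulationConfig, Trajectory, default_config, simulate
from .spatial import (
    aggregate_component_cdfs,
    aggregate_replicates,
    cancer_components,
    component_cdf,
    cross_pcf_timeseries,
    neighbor_graph,
)
from .synth import SampleSpec, generate_pdac_like_sample

#: Default per-type cell counts for the synthetic placements.
DEFAULT_COUNTS = {"cancer": 1500, "healthy": 800, "CD8": 600}


@dataclass
class AnalysisParams:
    """Readout settings shared by all scenarios."""

    bin_width: float = 10.0  # µm, cross-PCF bin width
    bin_max: float = 200.0  # µm, outermost cross-PCF edge
    contact_scale: float = 1.25  # neighbor-graph contact threshold multiplier

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(0.0, self.bin_max + self.bin_width / 2, self.bin_width)


@dataclass
class ScenarioSpec:
    """One initialization strategy plus its geometry/source parameters."""

    name: str
    strategy: str  # "wellmixed" | "structured" | "spatial"
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    disc_radius: float = 420.0  # wellmixed
    inner_radius: float = 460.0  # structured epithelial disc
    ring_outer_radius: float = 660.0  # structured immune annulus outer edge
    epithelial_types: frozenset = frozenset({"cancer", "healthy"})
    immune_types: frozenset = frozenset({"CD8"})
    cell_table_path: Optional[str] = None  # spatial: a real measured table
    sample_spec: SampleSpec = field(default_factory=SampleSpec)  # spatial default


@dataclass
class ExperimentConfig:
    """The full experiment: scenarios, replication, model and analysis."""

    scenarios: list[ScenarioSpec]
    replicates: int = 3
    seeds: Sequence[int] = (1, 2, 3)
    duration_days: float = 5.0
    sim: SimulationConfig = field(default_factory=default_config)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def validate(self) -> None:
        if not self.scenarios:
            raise ConfigError("experiment needs at least one scenario")
        if len(self.seeds) != self.replicates:
            raise ConfigError(
                f"{self.replicates} replicates need {self.replicates} seeds, "
                f"got {len(self.seeds)}"
            )
        if self.duration_days <= 0:
            raise ConfigError("duration_days must be > 0")
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ConfigError("scenario names must be unique")


def default_experiment_config(**overrides) -> ExperimentConfig:
    """The shipped 3-scenario x 3-replicate x 5-day design."""
    cfg = ExperimentConfig(
        scenarios=[
            ScenarioSpec(name="wellmixed", strategy="wellmixed"),
            ScenarioSpec(name="structured", strategy="structured"),
            ScenarioSpec(name="spatial", strategy="spatial"),
        ]
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def build_initial_state(
    scenario: ScenarioSpec, sim: SimulationConfig, seed: int
) -> InitialState:
    """Materialize one scenario's placement.

    ``seed`` drives the synthetic placements; the spatial strategy ignores
    it (its table is fixed), so replicates share the placement.
    """
    if scenario.strategy == "wellmixed":
        rng = np.random.default_rng([seed, 101])
        return init_well_mixed(
            scenario.counts,
            Disc((0.0, 0.0), scenario.disc_radius),
            rng,
            domain=sim.domain,
        )
    if scenario.strategy == "structured":
        rng = np.random.default_rng([seed, 101])
        return init_structured(
            scenario.counts,
            Disc((0.0, 0.0), scenario.inner_radius),
            Annulus((0.0, 0.0), scenario.inner_radius, scenario.ring_outer_radius),
            set(scenario.epithelial_types),
            set(scenario.immune_types),
            rng,
            domain=sim.domain,
        )
    if scenario.strategy == "spatial":
        if scenario.cell_table_path is not None:
            table = read_cell_table_csv(
                scenario.cell_table_path,
                {"id": "cell_id", "x": "x", "y": "y", "type": "cell_type"},
            )
        else:
            table = generate_pdac_like_sample(scenario.sample_spec)
        return init_spatial_informed(table)
    raise ConfigError(f"unknown initialization strategy {scenario.strategy!r}")


def _scenario_sim_config(
    scenario: ScenarioSpec, config: ExperimentConfig, init: InitialState
) -> SimulationConfig:
    domain = init.domain if scenario.strategy == "spatial" else config.sim.domain
    return SimulationConfig(
        types=config.sim.types,
        attack=config.sim.attack,
        mechanics=config.sim.mechanics,
        domain=domain,
        duration_min=config.duration_days * 24.0 * 60.0,
        save_interval_min=config.sim.save_interval_min,
        attacker_type=config.sim.attacker_type,
        target_type=config.sim.target_type,
    )


def _pcf_tidy(series) -> pd.DataFrame:
    rows = []
    edges = series.bin_edges
    for t, g_row in zip(series.times, series.G):
        rows.append(
            pd.DataFrame(
                {
                    "time_min": t,
                    "r_lo": edges[:-1],
                    "r_hi": edges[1:],
                    "g": g_row,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def run_experiment(config: ExperimentConfig, output_dir: str | Path) -> dict:
    """Run every scenario x replicate, write all artifacts, return the manifest.

    The manifest (also written as ``manifest.json``) lists every artifact
    with the seed that produced it; artifact paths are relative to
    ``output_dir``. A replicate failure aborts the experiment with the
    offending seed named.
    """
    config.validate()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "replicates": config.replicates,
        "seeds": list(map(int, config.seeds)),
        "duration_days": config.duration_days,
        "scenarios": {},
    }
    for scenario in config.scenarios:
        scn_dir = out / scenario.name
        scn_dir.mkdir(exist_ok=True)
        entry: dict = {"strategy": scenario.strategy, "replicates": []}
        trajectories: list[Trajectory] = []
        fixed_init = (
            build_initial_state(scenario, config.sim, int(config.seeds[0]))
            if scenario.strategy == "spatial"
            else None
        )
        for rep, seed in enumerate(config.seeds):
            seed = int(seed)
            init = (
                fixed_init
                if fixed_init is not None
                else build_initial_state(scenario, config.sim, seed)
            )
            sim_cfg = _scenario_sim_config(scenario, config, init)
            try:
                traj = simulate(init, sim_cfg, seed)
            except Exception as exc:
                raise RuntimeError(
                    f"scenario {scenario.name!r} replicate {rep} "
                    f"(seed {seed}) failed: {exc}"
                ) from exc
            trajectories.append(traj)
            rep_dir = scn_dir / f"rep{rep}_seed{seed}"
            rep_dir.mkdir(exist_ok=True)
            traj.summary.to_csv(rep_dir / "summary.csv", index=False)
            write_snapshot_csv(traj.snapshots, rep_dir / "snapshots.csv")
            traj.events.to_csv(rep_dir / "events.csv", index=False)
            pcf = cross_pcf_timeseries(
                traj,
                config.sim.target_type,
                config.sim.attacker_type,
                config.analysis.bin_edges,
            )
            _pcf_tidy(pcf).to_csv(rep_dir / "pcf.csv", index=False)
            entry["replicates"].append(
                {
                    "seed": seed,
                    "summary": str(rep_dir.relative_to(out) / "summary.csv"),
                    "snapshots": str(rep_dir.relative_to(out) / "snapshots.csv"),
                    "events": str(rep_dir.relative_to(out) / "events.csv"),
                    "pcf": str(rep_dir.relative_to(out) / "pcf.csv"),
                }
            )

        # replicate aggregation
        write_timeseries_csv(
            [t.summary for t in trajectories], scn_dir / "timeseries.csv"
        )
        times = trajectories[0].summary["time_min"].to_numpy()
        cancer_mean, cancer_sd = aggregate_replicates(
            [t.summary[f"count_{config.sim.target_type}"].to_numpy()
             for t in trajectories]
        )
        att_mean, att_sd = aggregate_replicates(
            [t.summary["ongoing_attacks"].to_numpy() for t in trajectories]
        )
        pd.DataFrame(
            {
                "time_min": times,
                "cancer_mean": cancer_mean,
                "cancer_sd": cancer_sd,
                "attacks_mean": att_mean,
                "attacks_sd": att_sd,
            }
        ).to_csv(scn_dir / "aggregates.csv", index=False)

        cdfs = []
        for traj in trajectories:
            endpoint = traj.snapshots[-1]
            graph = neighbor_graph(endpoint, config.analysis.contact_scale)
            cdfs.append(
                component_cdf(
                    cancer_components(graph, endpoint, config.sim.target_type)
                )
            )
        ens = aggregate_component_cdfs(cdfs)
        cdf_df = pd.DataFrame(
            {"size": ens.sizes, "F_mean": ens.F_mean, "F_sd": ens.F_sd}
        )
        for rep in range(len(cdfs)):
            cdf_df[f"F_rep{rep}"] = ens.F_per_replicate[rep]
        cdf_df.to_csv(scn_dir / "component_cdf.csv", index=False)

        entry["aggregates"] = {
            "timeseries": str((scn_dir / "timeseries.csv").relative_to(out)),
            "counts_attacks": str((scn_dir / "aggregates.csv").relative_to(out)),
            "component_cdf": str((scn_dir / "component_cdf.csv").relative_to(out)),
        }
        manifest["scenarios"][scenario.name] = entry

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest


def report(
    manifest: dict | str | Path, output_dir: Optional[str | Path] = None
) -> list[Path]:
    """Render the four readout figures from a finished experiment.

    Returns the figure paths: one endpoint scatter per scenario, a combined
    count/attack time-series panel (mean line, ±1 SD band), one cross-PCF
    heatmap per scenario (replicate mean), and the component CDF plot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        manifest = json.loads(Path(manifest).read_text())
    else:
        base = Path(output_dir) if output_dir is not None else Path(".")
    out = Path(output_dir) if output_dir is not None else base
    out.mkdir(parents=True, exist_ok=True)
    scenarios = manifest["scenarios"]
    if not scenarios:
        raise ValidationError("manifest lists no scenarios")

    def _load(rel: str) -> pd.DataFrame:
        path = base / rel
        if not path.exists():
            raise ValidationError(f"missing artifact: {path}")
        return pd.read_csv(path)

    figures: list[Path] = []
    palette = {"cancer": "tab:red", "healthy": "tab:blue", "CD8": "tab:green"}

    for name, entry in scenarios.items():
        snaps = _load(entry["replicates"][0]["snapshots"])
        endpoint = snaps[snaps["time"] == snaps["time"].max()]
        fig, ax = plt.subplots(figsize=(5, 5))
        for typ, grp in endpoint.groupby("type"):
            ax.scatter(grp["x"], grp["y"], s=3, label=typ,
                       color=palette.get(typ))
        ax.set_aspect("equal")
        ax.set_title(f"{name}: endpoint snapshot")
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        ax.legend(markerscale=3, fontsize=8)
        path = out / f"scatter_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(path)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for name, entry in scenarios.items():
        agg = _load(entry["aggregates"]["counts_attacks"])
        t_h = agg["time_min"] / 60.0
        ax1.plot(t_h, agg["cancer_mean"], label=name)
        ax1.fill_between(
            t_h,
            agg["cancer_mean"] - agg["cancer_sd"],
            agg["cancer_mean"] + agg["cancer_sd"],
            alpha=0.3,
        )
        ax2.plot(t_h, agg["attacks_mean"], label=name)
        ax2.fill_between(
            t_h,
            agg["attacks_mean"] - agg["attacks_sd"],
            agg["attacks_mean"] + agg["attacks_sd"],
            alpha=0.3,
        )
    ax1.set_xlabel("time (h)")
    ax1.set_ylabel("cancer cells")
    ax2.set_xlabel("time (h)")
    ax2.set_ylabel("ongoing attacks")
    ax1.legend()
    fig.tight_layout()
    path = out / "timeseries.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(path)

    for name, entry in scenarios.items():
        mats = []
        for rep in entry["replicates"]:
            tidy = _load(rep["pcf"])
            mat = tidy.pivot(index="time_min", columns="r_lo", values="g")
            mats.append(mat.to_numpy())
        mean_g = np.nanmean(np.stack(mats), axis=0)
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(
            mean_g.T,
            origin="lower",
            aspect="auto",
            extent=(
                0,
                mat.index.max() / 60.0,
                mat.columns.min(),
                tidy["r_hi"].max(),
            ),
            vmin=0,
            vmax=2,
            cmap="coolwarm",
        )
        fig.colorbar(im, ax=ax, label="g(r)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("distance (µm)")
        ax.set_title(f"{name}: cancer→CD8 cross-PCF")
        path = out / f"pcf_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(path)

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, entry in scenarios.items():
        cdf = _load(entry["aggregates"]["component_cdf"])
        ax.step(cdf["size"], cdf["F_mean"], where="post", label=name)
        ax.fill_between(
            cdf["size"],
            np.clip(cdf["F_mean"] - cdf["F_sd"], 0, 1),
            np.clip(cdf["F_mean"] + cdf["F_sd"], 0, 1),
            step="post",
            alpha=0.3,
        )
    ax.set_xscale("log")
    ax.set_xlabel("component size (cancer cells)")
    ax.set_ylabel("cumulative cancer-cell fraction")
    ax.legend()
    fig.tight_layout()
    path = out / "component_cdf.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(path)
    return figures
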