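"""Off-lattice 2D tumor-immune agent-based model.

Three cell types with asymmetric rules: cancer cells divide (contact
inhibited) and apoptose; CD8+ T cells migrate by a persistent random walk
and execute timed one-to-one attacks that probabilistically kill cancer
cells; healthy epithelial cells neither divide nor die. All cells repel on
overlap through overdamped mechanics with reflecting domain walls.

Time advances in *phenotype epochs* of ``dt_phen`` minutes, each containing
``dt_phen / dt_mech`` mechanics sub-steps followed by migration,
division/death and attack updates, in that fixed order. All stochastic
events are Bernoulli draws with probability rate x dt from one shared
per-replicate random stream, agents visited in id order, so a seed fully
determines a trajectory.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, ValidationError
from .geometry import Rectangle, reflect_into
from .initialize import InitialState

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class CellTypeParams:
    """Per-type behavioral parameters.

    Rates are per hour (they multiply ``dt_phen`` after conversion to
    minutes); speeds are µm/min; the persistence time is the mean time a
    migrating cell keeps its heading.
    """

    division_rate: float = 0.0  # 1/h
    apoptosis_rate: float = 0.0  # 1/h
    motility_speed: float = 0.0  # µm/min
    persistence_time: float = 10.0  # min
    radius: float = 8.0  # µm
    max_neighbors_for_division: int = 6

    def __post_init__(self) -> None:
        if self.division_rate < 0 or self.apoptosis_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.radius <= 0:
            raise ValidationError("radius must be > 0")
        if self.motility_speed > 0 and self.persistence_time <= 0:
            raise ValidationError(
                "motile cells need a positive persistence_time"
            )


@dataclass(frozen=True)
class AttackParams:
    """CD8 -> cancer attack state machine parameters."""

    attack_rate: float = 0.005  # 1/min, chance per unit time to engage a target in reach
    attack_duration: float = 30.0  # min, fixed engagement length
    kill_probability: float = 0.425  # chance the target dies when the attack ends
    contact_scale: float = 1.25  # reach, as multiple of summed radii

    def __post_init__(self) -> None:
        if self.attack_rate < 0:
            raise ValidationError("attack_rate must be >= 0")
        if self.attack_duration <= 0:
            raise ValidationError("attack_duration must be > 0")
        if not 0 <= self.kill_probability <= 1:
            raise ValidationError("kill_probability must be in [0, 1]")
        if self.contact_scale < 1:
            raise ValidationError("contact_scale must be >= 1")


@dataclass(frozen=True)
class MechanicsParams:
    """Overdamped pairwise repulsion; boundary handling is reflecting."""

    repulsion_strength: float = 10.0  # µm/min displacement at full overlap
    dt_mech: float = 0.5  # min
    dt_phen: float = 6.0  # min
    boundary: str = "reflecting"

    def __post_init__(self) -> None:
        if self.dt_mech <= 0 or self.dt_phen <= 0:
            raise ValidationError("time steps must be > 0")
        if self.dt_mech > self.dt_phen:
            raise ValidationError("dt_mech must be <= dt_phen")
        sub = self.dt_phen / self.dt_mech
        if abs(sub - round(sub)) > 1e-9:
            raise ValidationError("dt_phen must be divisible by dt_mech")
        if self.boundary != "reflecting":
            raise ValidationError("only reflecting boundaries are supported")

    @property
    def substeps(self) -> int:
        return int(round(self.dt_phen / self.dt_mech))


@dataclass
class SimulationConfig:
    """Everything that defines a run except the initial state and seed."""

    types: dict[str, CellTypeParams]
    attack: AttackParams = field(default_factory=AttackParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    domain: Rectangle = field(
        default_factory=lambda: Rectangle(-800.0, -800.0, 800.0, 800.0)
    )
    duration_min: float = 5 * 24 * 60.0
    save_interval_min: float = 60.0
    attacker_type: str = "CD8"
    target_type: str = "cancer"

    def validate(self) -> None:
        """Reject probability overflow and grid mismatches before a run starts."""
        dt = self.mechanics.dt_phen
        for name, tp in self.types.items():
            for label, rate_per_h in (
                ("division", tp.division_rate),
                ("apoptosis", tp.apoptosis_rate),
            ):
                p = rate_per_h / 60.0 * dt
                if p > 1.0:
                    raise ConfigError(
                        f"probability overflow: {label} rate of {name!r} gives "
                        f"rate*dt_phen = {p:.3f} > 1"
                    )
        p_att = self.attack.attack_rate * dt
        if p_att > 1.0:
            raise ConfigError(
                f"probability overflow: attack_rate*dt_phen = {p_att:.3f} > 1"
            )
        n_saves = self.duration_min / self.save_interval_min
        if abs(n_saves - round(n_saves)) > 1e-9:
            raise ConfigError("duration_min must be divisible by save_interval_min")
        per_save = self.save_interval_min / dt
        if abs(per_save - round(per_save)) > 1e-9:
            raise ConfigError("save_interval_min must be divisible by dt_phen")
        for role, name in (
            ("attacker", self.attacker_type),
            ("target", self.target_type),
        ):
            if name not in self.types:
                raise ConfigError(f"{role} type {name!r} not among configured types")


def default_config(**overrides) -> SimulationConfig:
    """The shipped three-type parameterization (see docs/methods.md).

    Cancer divides and apoptoses; CD8 migrates and attacks; healthy is inert.
    """
    cfg = SimulationConfig(
        types={
            "cancer": CellTypeParams(
                division_rate=0.02,
                apoptosis_rate=0.001,
                radius=8.0,
                max_neighbors_for_division=4,
            ),
            "healthy": CellTypeParams(radius=8.0),
            "CD8": CellTypeParams(
                motility_speed=8.0, persistence_time=10.0, radius=8.0
            ),
        },
        attack=AttackParams(
            attack_rate=0.005,
            attack_duration=30.0,
            kill_probability=0.425,
            contact_scale=1.25,
        ),
        mechanics=MechanicsParams(
            repulsion_strength=10.0, dt_mech=0.5, dt_phen=6.0
        ),
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@dataclass
class Snapshot:
    """State of every agent at one saved time point."""

    time: float  # min
    ids: np.ndarray  # (n,) int64
    types: np.ndarray  # (n,) str
    xy: np.ndarray  # (n, 2) float µm
    partner: np.ndarray  # (n,) int64 partner agent id, -1 if free
    timer: np.ndarray  # (n,) float min into the current attack
    radii: np.ndarray  # (n,) float µm
    domain: Rectangle

    @property
    def counts(self) -> dict[str, int]:
        names, counts = np.unique(self.types.astype(str), return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))

    @property
    def ongoing_attacks(self) -> int:
        return count_ongoing_attacks(self)


def count_ongoing_attacks(snapshot: Snapshot, attack_duration: float | None = None) -> int:
    """Number of attacker-target pairs active in a snapshot.

    Pairs whose timer already reached ``attack_duration`` (only possible in
    hand-built states; the stepper resolves them) are excluded when a
    duration is given.
    """
    engaged = snapshot.partner != -1
    if attack_duration is not None:
        engaged &= snapshot.timer < attack_duration
    total = int(engaged.sum())
    if total % 2:
        raise ValidationError("attack pairing is not symmetric")
    return total // 2


@dataclass
class Trajectory:
    """Saved snapshots plus the per-save summary and per-epoch event log."""

    snapshots: list[Snapshot]
    summary: pd.DataFrame  # time_min, count_<type>..., ongoing_attacks
    events: pd.DataFrame  # per-epoch divisions/deaths/kills/attacks_started

    @property
    def times(self) -> np.ndarray:
        return self.summary["time_min"].to_numpy()


class SpatialIndex:
    """Fixed-radius neighbor queries over a set of agent positions.

    ``bin_size`` is accepted as a spatial-resolution hint (it should be at
    least twice the largest interaction radius); a k-d tree serves as the
    engine, and queries return index arrays into the position set.
    """

    def __init__(self, xy: np.ndarray, bin_size: float = 32.0):
        self.xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        self.bin_size = float(bin_size)
        self._tree = cKDTree(self.xy) if len(self.xy) else None

    def query(self, point, r: float) -> np.ndarray:
        """Indices of all agents within distance ``r`` of ``point``."""
        if self._tree is None:
            return np.empty(0, dtype=np.intp)
        idx = self._tree.query_ball_point(np.asarray(point, dtype=float), r)
        return np.sort(np.asarray(idx, dtype=np.intp))

    def pairs(self, r: float) -> np.ndarray:
        """All index pairs (i < j) within distance ``r``."""
        if self._tree is None:
            return np.empty((0, 2), dtype=np.intp)
        return self._tree.query_pairs(r, output_type="ndarray")


def build_spatial_index(xy: np.ndarray, bin_size: float = 32.0) -> SpatialIndex:
    """Build a neighbor-query structure over agent positions."""
    return SpatialIndex(xy, bin_size)


class SimulationState:
    """Mutable array-of-struct agent state; stepped in place."""

    __slots__ = (
        "config",
        "type_names",
        "type_radii",
        "ids",
        "code",
        "xy",
        "angle",
        "partner",
        "timer",
        "next_id",
        "time",
    )

    def __init__(self, config: SimulationConfig, ids, code, xy, angle,
                 partner=None, timer=None, time=0.0):
        self.config = config
        self.type_names = tuple(sorted(config.types))
        self.type_radii = np.array(
            [config.types[n].radius for n in self.type_names]
        )
        self.ids = np.asarray(ids, dtype=np.int64)
        self.code = np.asarray(code, dtype=np.int16)
        self.xy = np.asarray(xy, dtype=float).reshape(-1, 2).copy()
        self.angle = np.asarray(angle, dtype=float)
        n = len(self.ids)
        self.partner = (
            np.full(n, -1, dtype=np.int64) if partner is None
            else np.asarray(partner, dtype=np.int64)
        )
        self.timer = (
            np.zeros(n) if timer is None else np.asarray(timer, dtype=float)
        )
        self.next_id = int(self.ids.max()) + 1 if n else 0
        self.time = float(time)

    @classmethod
    def from_initial_state(
        cls,
        init: InitialState,
        config: SimulationConfig,
        rng: np.random.Generator,
    ) -> "SimulationState":
        names = tuple(sorted(config.types))
        lookup = {n: k for k, n in enumerate(names)}
        try:
            code = np.array([lookup[t] for t in init.types], dtype=np.int16)
        except KeyError as exc:
            raise ConfigError(
                f"initial state contains unconfigured type {exc.args[0]!r}"
            ) from None
        n = len(init)
        return cls(
            config,
            ids=np.arange(n, dtype=np.int64),
            code=code,
            xy=init.xy,
            angle=rng.random(n) * TWO_PI,
        )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def radii(self) -> np.ndarray:
        return self.type_radii[self.code]

    def index_of(self, agent_ids: np.ndarray) -> np.ndarray:
        """Indices of agent ids (ids are kept sorted ascending)."""
        return np.searchsorted(self.ids, agent_ids)

    def type_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.code == self.type_names.index(name))

    def snapshot(self) -> Snapshot:
        return Snapshot(
            time=self.time,
            ids=self.ids.copy(),
            types=np.array([self.type_names[c] for c in self.code], dtype=object),
            xy=self.xy.copy(),
            partner=self.partner.copy(),
            timer=self.timer.copy(),
            radii=self.radii.copy(),
            domain=self.config.domain,
        )

    def _compact(self, keep: np.ndarray) -> None:
        self.ids = self.ids[keep]
        self.code = self.code[keep]
        self.xy = self.xy[keep]
        self.angle = self.angle[keep]
        self.partner = self.partner[keep]
        self.timer = self.timer[keep]

    def _append(self, code, xy, angle) -> None:
        n_new = len(code)
        if n_new == 0:
            return
        new_ids = np.arange(self.next_id, self.next_id + n_new, dtype=np.int64)
        self.next_id += n_new
        self.ids = np.concatenate([self.ids, new_ids])
        self.code = np.concatenate([self.code, np.asarray(code, dtype=np.int16)])
        self.xy = np.vstack([self.xy, xy])
        self.angle = np.concatenate([self.angle, angle])
        self.partner = np.concatenate(
            [self.partner, np.full(n_new, -1, dtype=np.int64)]
        )
        self.timer = np.concatenate([self.timer, np.zeros(n_new)])


def _coincident_axis(id_i: np.ndarray, id_j: np.ndarray) -> np.ndarray:
    """Deterministic pseudo-random separation angle for coincident pairs."""
    h = (id_i.astype(np.uint64) * np.uint64(2654435761)
         + id_j.astype(np.uint64) * np.uint64(40503)) % np.uint64(2**32)
    return h.astype(float) / float(2**32) * TWO_PI


def _apply_repulsion(
    state: SimulationState,
    i: np.ndarray,
    j: np.ndarray,
    rij: np.ndarray,
    mech: MechanicsParams,
) -> float:
    """Push candidate pairs (i, j) apart where they overlap; returns the
    largest per-agent displacement magnitude of this sub-step."""
    n = len(state)
    dvec = state.xy[j] - state.xy[i]
    d = np.hypot(dvec[:, 0], dvec[:, 1])
    overlap = d < rij
    if not overlap.any():
        return 0.0
    oi, oj, od, orij = i[overlap], j[overlap], d[overlap], rij[overlap]
    odvec = dvec[overlap]
    unit = np.empty_like(odvec)
    touching = od > 1e-12
    unit[touching] = odvec[touching] / od[touching, None]
    if (~touching).any():
        theta = _coincident_axis(state.ids[oi[~touching]], state.ids[oj[~touching]])
        unit[~touching, 0] = np.cos(theta)
        unit[~touching, 1] = np.sin(theta)
    mag = mech.dt_mech * mech.repulsion_strength * (1.0 - od / orij) ** 2
    fx = unit[:, 0] * mag
    fy = unit[:, 1] * mag
    disp_x = np.bincount(oj, weights=fx, minlength=n) - np.bincount(
        oi, weights=fx, minlength=n
    )
    disp_y = np.bincount(oj, weights=fy, minlength=n) - np.bincount(
        oi, weights=fy, minlength=n
    )
    locked = state.partner != -1
    if locked.any():
        disp_x[locked] = 0.0
        disp_y[locked] = 0.0
    moved = (disp_x != 0.0) | (disp_y != 0.0)
    if not moved.any():
        return 0.0
    state.xy[moved, 0] += disp_x[moved]
    state.xy[moved, 1] += disp_y[moved]
    sub = state.xy[moved]
    reflect_into(sub, state.config.domain)
    state.xy[moved] = sub
    return float(np.sqrt(np.max(disp_x[moved] ** 2 + disp_y[moved] ** 2)))


#: Extra candidate-pair search radius (µm) reused across mechanics sub-steps.
_PAIR_CACHE_MARGIN = 8.0


def run_mechanics_substeps(
    state: SimulationState, substeps: int, mech: Optional[MechanicsParams] = None
) -> SimulationState:
    """Run consecutive repulsion sub-steps with a cached candidate-pair list.

    Candidate pairs are found within ``2 r_max + margin``; the cache is
    rebuilt once accumulated motion could bring an unseen pair into overlap,
    so the result is identical to rebuilding the neighbor structure every
    sub-step. The agent set and attack locks must not change between the
    sub-steps (they only change at phenotype updates).
    """
    mech = mech or state.config.mechanics
    n = len(state)
    if n < 2:
        return state
    rad = state.radii
    r_cut = 2.0 * rad.max() + _PAIR_CACHE_MARGIN
    i = j = rij = None
    slack = -1.0  # remaining safe travel before a rebuild is needed
    for _ in range(substeps):
        if slack <= 0.0:
            tree = cKDTree(state.xy)
            pairs = tree.query_pairs(r_cut, output_type="ndarray")
            i, j = pairs[:, 0], pairs[:, 1]
            rij = rad[i] + rad[j]
            slack = _PAIR_CACHE_MARGIN / 2.0
        step_max = _apply_repulsion(state, i, j, rij, mech)
        slack -= 2.0 * step_max  # two agents can close a gap from both sides
    return state


def step_mechanics(
    state: SimulationState, mech: Optional[MechanicsParams] = None
) -> SimulationState:
    """One overdamped repulsion sub-step.

    Each overlapping pair (center distance d below summed radii R) pushes
    both members apart along the separation axis by
    ``dt_mech * repulsion_strength * (1 - d/R)^2``; agents locked in an
    attack do not move; walls reflect.
    """
    return run_mechanics_substeps(state, 1, mech)


def step_migration(
    state: SimulationState,
    rng: np.random.Generator,
    dt_phen: Optional[float] = None,
) -> SimulationState:
    """Persistent random walk for motile, non-attacking agents.

    A cell redraws its heading uniformly on the circle with probability
    ``dt / persistence_time``, then advances ``motility_speed * dt`` along
    it; walls reflect. Non-motile types and attack-locked cells stay put.
    """
    dt = dt_phen if dt_phen is not None else state.config.mechanics.dt_phen
    for k, name in enumerate(state.type_names):
        tp = state.config.types[name]
        if tp.motility_speed <= 0:
            continue
        idx = np.flatnonzero((state.code == k) & (state.partner == -1))
        if len(idx) == 0:
            continue
        p_turn = min(dt / tp.persistence_time, 1.0)
        redraw = rng.random(len(idx)) < p_turn
        if redraw.any():
            state.angle[idx[redraw]] = rng.random(int(redraw.sum())) * TWO_PI
        ang = state.angle[idx]
        step = tp.motility_speed * dt
        state.xy[idx, 0] += step * np.cos(ang)
        state.xy[idx, 1] += step * np.sin(ang)
        sub = state.xy[idx]
        reflect_into(sub, state.config.domain)
        state.xy[idx] = sub
    return state


def step_division_death(
    state: SimulationState,
    rng: np.random.Generator,
    dt_phen: Optional[float] = None,
) -> dict[str, int]:
    """Stochastic division (contact inhibited) and apoptosis.

    Division requires at most ``max_neighbors_for_division`` other agents
    within ``contact_scale * 2r``; the daughter lands one radius away at a
    uniform angle. Death removes the cell and frees any attacker locked on
    it. Returns event counts for bookkeeping.
    """
    dt = dt_phen if dt_phen is not None else state.config.mechanics.dt_phen
    contact_scale = state.config.attack.contact_scale
    tree = None
    death_mask = np.zeros(len(state), dtype=bool)
    new_code: list[np.ndarray] = []
    new_xy: list[np.ndarray] = []
    new_angle: list[np.ndarray] = []
    n_div = 0
    for k, name in enumerate(state.type_names):
        tp = state.config.types[name]
        p_div = tp.division_rate / 60.0 * dt
        p_die = tp.apoptosis_rate / 60.0 * dt
        if p_div <= 0 and p_die <= 0:
            continue
        idx = np.flatnonzero(state.code == k)
        if len(idx) == 0:
            continue
        if p_div > 0:
            if tree is None:
                tree = cKDTree(state.xy)
            thresh = contact_scale * 2.0 * tp.radius
            nb = tree.query_ball_point(
                state.xy[idx], thresh, return_length=True
            ) - 1
            divide = (rng.random(len(idx)) < p_div) & (
                nb <= tp.max_neighbors_for_division
            )
            parents = idx[divide]
            if len(parents):
                phi = rng.random(len(parents)) * TWO_PI
                offset = tp.radius * np.column_stack((np.cos(phi), np.sin(phi)))
                daughters = state.xy[parents] + offset
                reflect_into(daughters, state.config.domain)
                new_code.append(np.full(len(parents), k, dtype=np.int16))
                new_xy.append(daughters)
                new_angle.append(state.angle[parents].copy())
                n_div += len(parents)
        if p_die > 0:
            die = rng.random(len(idx)) < p_die
            death_mask[idx[die]] = True
    n_death = int(death_mask.sum())
    if n_death:
        # free attackers locked on dying cells, and drop the dying side
        dying_partners = state.partner[death_mask]
        engaged = dying_partners != -1
        if engaged.any():
            att_idx = state.index_of(dying_partners[engaged])
            state.partner[att_idx] = -1
            state.timer[att_idx] = 0.0
        state._compact(~death_mask)
    if new_code:
        state._append(
            np.concatenate(new_code), np.vstack(new_xy), np.concatenate(new_angle)
        )
    return {"divisions": n_div, "deaths": n_death}


def step_attack(
    state: SimulationState,
    rng: np.random.Generator,
    dt_phen: Optional[float] = None,
) -> dict[str, int]:
    """Attack engagement, progression, and resolution for one epoch.

    Free attackers (visited in id order) with an untargeted cancer cell in
    reach engage the nearest one (ties to the lowest id) with probability
    ``attack_rate * dt``; both members of a pair are immobilized; timers
    then advance by ``dt`` and pairs reaching ``attack_duration`` resolve —
    the target dies with ``kill_probability`` and the pair dissolves either
    way. Pairing is exclusively one-to-one.
    """
    dt = dt_phen if dt_phen is not None else state.config.mechanics.dt_phen
    ap = state.config.attack
    atk_code = state.type_names.index(state.config.attacker_type)
    tgt_code = state.type_names.index(state.config.target_type)
    started = 0

    p_start = ap.attack_rate * dt
    free_att = np.flatnonzero((state.code == atk_code) & (state.partner == -1))
    tgt_idx = np.flatnonzero(state.code == tgt_code)
    if p_start > 0 and len(free_att) and len(tgt_idx):
        reach = ap.contact_scale * (
            state.config.types[state.config.attacker_type].radius
            + state.config.types[state.config.target_type].radius
        )
        u = rng.random(len(free_att))
        trying = free_att[u < p_start]
        if len(trying):
            tgt_tree = cKDTree(state.xy[tgt_idx])
            tgt_open = state.partner[tgt_idx] == -1
            tgt_ids = state.ids[tgt_idx]
            cand_lists = tgt_tree.query_ball_point(state.xy[trying], reach)
            for ai, cands in zip(trying, cand_lists):
                if not cands:
                    continue
                cands = np.asarray(cands, dtype=np.intp)
                cands = cands[tgt_open[cands]]
                if len(cands) == 0:
                    continue
                dv = state.xy[tgt_idx[cands]] - state.xy[ai]
                d2 = dv[:, 0] ** 2 + dv[:, 1] ** 2
                pick = cands[np.lexsort((tgt_ids[cands], d2))[0]]
                tj = tgt_idx[pick]
                state.partner[ai] = state.ids[tj]
                state.partner[tj] = state.ids[ai]
                state.timer[ai] = 0.0
                state.timer[tj] = 0.0
                tgt_open[pick] = False
                started += 1

    engaged = state.partner != -1
    state.timer[engaged] += dt

    kills = 0
    done_att = np.flatnonzero(
        (state.code == atk_code)
        & engaged
        & (state.timer >= ap.attack_duration - 1e-9)
    )
    if len(done_att):
        target_ids = state.partner[done_att]
        tgt_at = state.index_of(target_ids)
        u = rng.random(len(done_att))
        killed = u < ap.kill_probability
        state.partner[done_att] = -1
        state.timer[done_att] = 0.0
        state.partner[tgt_at] = -1
        state.timer[tgt_at] = 0.0
        if killed.any():
            keep = np.ones(len(state), dtype=bool)
            keep[tgt_at[killed]] = False
            kills = int(killed.sum())
            state._compact(keep)
    return {"attacks_started": started, "kills": kills}


def simulate(
    init: InitialState, config: SimulationConfig, seed: int
) -> Trajectory:
    """Run the model from an initial state; one seed, one trajectory.

    Snapshots (the first of which is the untouched initial state at t=0)
    are recorded every ``save_interval_min``; the event log records
    divisions, deaths, kills and attack starts per phenotype epoch along
    with the post-epoch cancer count, supporting exact bookkeeping checks.
    """
    config.validate()
    if len(init) and not config.domain.contains(init.xy).all():
        raise ConfigError("initial state extends outside the simulation domain")
    rng = np.random.default_rng(seed)
    state = SimulationState.from_initial_state(init, config, rng)

    mech = config.mechanics
    n_epochs = int(round(config.duration_min / mech.dt_phen))
    save_every = int(round(config.save_interval_min / mech.dt_phen))
    substeps = mech.substeps

    snapshots = [state.snapshot()]
    events = []
    tgt_code = state.type_names.index(config.target_type)
    for epoch in range(1, n_epochs + 1):
        run_mechanics_substeps(state, substeps)
        step_migration(state, rng)
        dd = step_division_death(state, rng)
        at = step_attack(state, rng)
        state.time = epoch * mech.dt_phen
        events.append(
            {
                "time_min": state.time,
                "divisions": dd["divisions"],
                "deaths": dd["deaths"],
                "kills": at["kills"],
                "attacks_started": at["attacks_started"],
                "cancer_count": int((state.code == tgt_code).sum()),
            }
        )
        if epoch % save_every == 0:
            snapshots.append(state.snapshot())

    rows = []
    for snap in snapshots:
        row = {"time_min": snap.time}
        counts = snap.counts
        for name in state.type_names:
            row[f"count_{name}"] = counts.get(name, 0)
        row["ongoing_attacks"] = snap.ongoing_attacks
        rows.append(row)
    summary = pd.DataFrame(rows)
    return Trajectory(
        snapshots=snapshots, summary=summary, events=pd.DataFrame(events)
    )
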