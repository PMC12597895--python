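"""ABM stepping rules: mechanics, migration, division/death, attacks."""
import numpy as np
import pandas as pd
import pytest

import spatialabm as sa
from spatialabm.errors import ConfigError

from conftest import make_config, single_type_state


class TestSpatialIndex:
    def test_empty(self):
        idx = sa.build_spatial_index(np.empty((0, 2)))
        assert len(idx.query((0, 0), 100)) == 0

    def test_two_agents_within_range(self):
        idx = sa.build_spatial_index(np.array([[0.0, 0.0], [5.0, 0.0]]))
        assert list(idx.query((0, 0), 10)) == [0, 1]

    def test_matches_all_pairs_oracle(self, rng):
        xy = rng.uniform(-200, 200, (500, 2))
        idx = sa.build_spatial_index(xy)
        for _ in range(50):
            p = rng.uniform(-200, 200, 2)
            r = rng.uniform(5, 80)
            brute = np.flatnonzero(np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1]) <= r)
            np.testing.assert_array_equal(idx.query(p, r), brute)


class TestMechanics:
    def test_separated_cells_do_not_move(self):
        state = single_type_state([[0, 0], [20, 0]])  # distance 20 > 16
        before = state.xy.copy()
        sa.step_mechanics(state)
        np.testing.assert_array_equal(state.xy, before)

    def test_touching_cells_do_not_move(self):
        state = single_type_state([[0, 0], [16.0, 0]])  # exactly summed radii
        before = state.xy.copy()
        sa.step_mechanics(state)
        np.testing.assert_array_equal(state.xy, before)

    def test_symmetric_overlap_displaces_equally(self):
        state = single_type_state([[0, 0], [8.0, 0]])
        sa.step_mechanics(state)
        # midpoint unchanged, displacements equal and opposite along x
        assert state.xy[0, 0] < 0 < state.xy[1, 0] - 8.0 + 1e-12
        np.testing.assert_allclose(state.xy.mean(axis=0), [4.0, 0.0], atol=1e-12)
        np.testing.assert_array_equal(state.xy[:, 1], [0.0, 0.0])

    def test_displacement_magnitude_follows_overlap_law(self):
        d = 8.0
        state = single_type_state([[0, 0], [d, 0]])
        mech = state.config.mechanics
        sa.step_mechanics(state)
        expected = mech.dt_mech * mech.repulsion_strength * (1 - d / 16.0) ** 2
        np.testing.assert_allclose(state.xy[1, 0] - d, expected, rtol=1e-12)

    def test_coincident_cells_separate(self):
        state = single_type_state([[3.0, 3.0], [3.0, 3.0]])
        sa.step_mechanics(state)
        assert np.hypot(*(state.xy[1] - state.xy[0])) > 0

    def test_attack_locked_cells_do_not_move(self):
        state = single_type_state([[0, 0], [8.0, 0]], partner=[1, 0])
        before = state.xy.copy()
        sa.step_mechanics(state)
        np.testing.assert_array_equal(state.xy, before)

    def test_overlap_energy_non_increasing(self, rng):
        # frozen phenotype: repeated mechanics steps relax total overlap
        from scipy.spatial.distance import pdist

        state = single_type_state(rng.uniform(-30, 30, (40, 2)))

        def energy():
            d = pdist(state.xy)
            o = np.clip(16.0 - d, 0, None)
            return (o**3).sum()  # potential whose gradient is the (1-d/R)^2 push

        e = [energy()]
        for _ in range(50):
            sa.step_mechanics(state)
            e.append(energy())
        assert all(b <= a + 1e-9 for a, b in zip(e, e[1:]))

    def test_positions_stay_in_domain(self, rng):
        cfg = make_config(domain=sa.Rectangle(-40, -40, 40, 40))
        state = single_type_state(rng.uniform(-39, 39, (60, 2)), config=cfg)
        for _ in range(30):
            sa.step_mechanics(state)
        assert cfg.domain.contains(state.xy).all()


class TestMigration:
    def test_zero_speed_is_frozen(self, rng):
        state = single_type_state([[0, 0], [100, 100]], type_name="healthy")
        before = state.xy.copy()
        sa.step_migration(state, rng)
        np.testing.assert_array_equal(state.xy, before)

    def test_persistent_straight_line_step(self):
        cfg = make_config()
        cfg.types = dict(cfg.types)
        cfg.types["CD8"] = sa.CellTypeParams(
            motility_speed=2.0, persistence_time=1e18, radius=8.0
        )
        state = single_type_state([[0.0, 0.0]], type_name="CD8", config=cfg)
        state.angle[:] = 0.0  # heading +x
        sa.step_migration(state, np.random.default_rng(0), dt_phen=6.0)
        np.testing.assert_allclose(state.xy, [[12.0, 0.0]], atol=1e-12)

    def test_msd_matches_discrete_prw_formula(self):
        # independent walkers; E|X_n|^2 = (v dt)^2 [n + 2 sum_k (n-k) a^k],
        # a = 1 - dt/tau (heading correlation per step)
        rng = np.random.default_rng(99)
        n_agents, n_steps = 4000, 300
        cfg = make_config(domain=sa.Rectangle(-1e7, -1e7, 1e7, 1e7))
        cd8 = cfg.types["CD8"]
        v, dt, tau = cd8.motility_speed, 6.0, cd8.persistence_time
        state = single_type_state(
            np.zeros((n_agents, 2)), type_name="CD8", config=cfg, seed=99
        )
        start = state.xy.copy()
        for _ in range(n_steps):
            sa.step_migration(state, rng, dt_phen=dt)
        disp = state.xy - start
        sq = (disp**2).sum(axis=1)
        a = 1 - dt / tau
        k = np.arange(1, n_steps)
        msd_expected = (v * dt) ** 2 * (
            n_steps + 2 * ((n_steps - k) * a**k).sum()
        )
        se = sq.std(ddof=1) / np.sqrt(n_agents)
        assert abs(sq.mean() - msd_expected) < 3 * se
        # isotropy: mean displacement ~ 0
        assert np.all(np.abs(disp.mean(axis=0)) < 3 * disp.std(axis=0, ddof=1) / np.sqrt(n_agents))

    def test_attacking_cd8_does_not_move(self):
        state = single_type_state([[0.0, 0.0]], type_name="CD8", partner=[5])
        sa.step_migration(state, np.random.default_rng(0))
        np.testing.assert_array_equal(state.xy, [[0.0, 0.0]])


class TestDivisionDeath:
    def test_all_rates_zero_no_change(self, rng):
        state = single_type_state([[0, 0], [50, 50]], type_name="healthy")
        stats = sa.step_division_death(state, rng)
        assert len(state) == 2 and stats == {"divisions": 0, "deaths": 0}

    def test_certain_division_adds_daughter_at_radius(self):
        cfg = make_config()
        cfg.types = dict(cfg.types)
        cfg.types["cancer"] = sa.CellTypeParams(
            division_rate=10.0, radius=8.0, max_neighbors_for_division=6
        )  # 10/h * 6 min = p = 1
        state = single_type_state([[0.0, 0.0]], config=cfg)
        sa.step_division_death(state, np.random.default_rng(1))
        assert len(state) == 2
        np.testing.assert_allclose(
            np.hypot(*(state.xy[1] - state.xy[0])), 8.0, rtol=1e-12
        )

    def test_contact_inhibition_blocks_division(self):
        cfg = make_config()
        cfg.types = dict(cfg.types)
        cfg.types["cancer"] = sa.CellTypeParams(
            division_rate=10.0, radius=8.0, max_neighbors_for_division=2
        )
        # each cell has 3 neighbours within 20 µm > max 2 -> no divisions
        xy = [[0, 0], [10, 0], [0, 10], [10, 10]]
        state = single_type_state(xy, config=cfg)
        stats = sa.step_division_death(state, np.random.default_rng(1))
        assert stats["divisions"] == 0 and len(state) == 4

    def test_death_releases_attacker(self):
        cfg = make_config()
        cfg.types = dict(cfg.types)
        cfg.types["cancer"] = sa.CellTypeParams(apoptosis_rate=10.0, radius=8.0)
        init = sa.InitialState(
            xy=np.array([[0.0, 0.0], [10.0, 0.0]]),
            types=np.array(["cancer", "CD8"], dtype=object),
            domain=cfg.domain,
        )
        state = sa.SimulationState.from_initial_state(
            init, cfg, np.random.default_rng(0)
        )
        state.partner[:] = [1, 0]
        state.timer[:] = 12.0
        sa.step_division_death(state, np.random.default_rng(0))
        assert len(state) == 1  # cancer cell died with certainty
        assert state.partner[0] == -1 and state.timer[0] == 0.0

    def test_pure_death_matches_exponential_decay(self):
        # N0 cells, apoptosis rate lam: E[N(t)] = N0 * (1 - p)^epochs
        lam, n0, hours = 0.05, 2000, 12.0
        cfg = make_config(domain=sa.Rectangle(-1000, -1000, 1000, 1000))
        cfg.types = {"cancer": sa.CellTypeParams(apoptosis_rate=lam, radius=8.0)}
        cfg.attacker_type = "cancer"
        cfg.target_type = "cancer"
        p = lam / 60 * 6.0
        epochs = int(hours * 60 / 6)
        rng = np.random.default_rng(5)
        counts = []
        for _ in range(10):
            state = single_type_state(
                np.random.default_rng(1).uniform(-900, 900, (n0, 2)),
                config=cfg,
            )
            for _ in range(epochs):
                sa.step_division_death(state, rng)
            counts.append(len(state))
        expected = n0 * (1 - p) ** epochs
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se


class TestAttack:
    def attack_config(self, **attack_kw):
        cfg = make_config()
        kw = dict(attack_rate=1 / 6.0, attack_duration=30.0,
                  kill_probability=1.0, contact_scale=1.25)
        kw.update(attack_kw)
        cfg.attack = sa.AttackParams(**kw)
        return cfg

    def pair_state(self, cfg, cancer_xy, cd8_xy):
        types = ["cancer"] * len(cancer_xy) + ["CD8"] * len(cd8_xy)
        init = sa.InitialState(
            xy=np.array(cancer_xy + cd8_xy, dtype=float),
            types=np.array(types, dtype=object),
            domain=cfg.domain,
        )
        return sa.SimulationState.from_initial_state(
            init, cfg, np.random.default_rng(0)
        )

    def test_no_attackers_no_attacks(self, rng):
        state = single_type_state([[0, 0], [10, 0]])
        stats = sa.step_attack(state, rng)
        assert stats == {"attacks_started": 0, "kills": 0}

    def test_forced_attack_kills_after_duration(self):
        # p_start = 1, kill certain: engagement this epoch, death after
        # ceil(30/6) = 5 epochs
        cfg = self.attack_config()
        state = self.pair_state(cfg, [[0.0, 0.0]], [[10.0, 0.0]])
        rng = np.random.default_rng(0)
        sa.step_attack(state, rng)
        assert sa.count_ongoing_attacks(state.snapshot()) == 1
        for _ in range(3):
            sa.step_attack(state, rng)
            assert sa.count_ongoing_attacks(state.snapshot()) == 1
        stats = sa.step_attack(state, rng)  # 5th epoch: timer reaches 30
        assert stats["kills"] == 1
        assert len(state) == 1 and state.partner[0] == -1

    def test_equidistant_tie_broken_by_lower_id(self):
        cfg = self.attack_config()
        state = self.pair_state(cfg, [[10.0, 0.0], [-10.0, 0.0]], [[0.0, 0.0]])
        sa.step_attack(state, np.random.default_rng(0))
        # ids 0,1 are the cancer cells; the CD8 (id 2) must target id 0
        assert state.partner[2] == 0 and state.partner[0] == 2
        assert state.partner[1] == -1

    def test_one_to_one_pairing(self):
        cfg = self.attack_config()
        state = self.pair_state(
            cfg, [[0.0, 0.0]], [[10.0, 0.0], [-10.0, 0.0], [0.0, 10.0]]
        )
        stats = sa.step_attack(state, np.random.default_rng(0))
        assert stats["attacks_started"] == 1  # single target claims one attacker
        snap = state.snapshot()
        assert sa.count_ongoing_attacks(snap) == 1
        assert snap.ongoing_attacks <= min(3, 1)

    def test_out_of_reach_no_attack(self):
        cfg = self.attack_config()
        state = self.pair_state(cfg, [[0.0, 0.0]], [[25.0, 0.0]])  # reach is 20
        stats = sa.step_attack(state, np.random.default_rng(0))
        assert stats["attacks_started"] == 0

    def test_partner_relation_is_involution(self):
        cfg = self.attack_config(kill_probability=0.5)
        rng = np.random.default_rng(8)
        cancer = rng.uniform(-50, 50, (30, 2)).tolist()
        cd8 = rng.uniform(-50, 50, (20, 2)).tolist()
        state = self.pair_state(cfg, cancer, cd8)
        for _ in range(20):
            sa.step_attack(state, rng)
            engaged = np.flatnonzero(state.partner != -1)
            for i in engaged:
                j = state.index_of(np.array([state.partner[i]]))[0]
                assert state.partner[j] == state.ids[i]
            assert len(engaged) % 2 == 0


class TestSimulate:
    def test_frozen_system_all_snapshots_identical(self):
        cfg = make_config(duration_min=24 * 60.0, save_interval_min=240.0)
        cfg.types = {
            "cancer": sa.CellTypeParams(radius=8.0),
            "healthy": sa.CellTypeParams(radius=8.0),
            "CD8": sa.CellTypeParams(motility_speed=0.0, radius=8.0),
        }
        cfg.attack = sa.AttackParams(attack_rate=0.0)
        rng = np.random.default_rng(4)
        init = sa.init_well_mixed(
            {"cancer": 30, "healthy": 20, "CD8": 10},
            sa.Disc((0, 0), 400), rng, domain=cfg.domain,
        )
        # place cells apart enough that mechanics is silent too? overlaps may
        # exist; only checks phenotype freeze -> instead assert counts frozen
        traj = sa.simulate(init, cfg, seed=1)
        for snap in traj.snapshots:
            assert snap.counts == traj.snapshots[0].counts
            assert snap.ongoing_attacks == 0

    def test_frozen_positions_without_overlap(self):
        cfg = make_config(duration_min=120.0, save_interval_min=60.0)
        cfg.types = {"cancer": sa.CellTypeParams(radius=8.0)}
        cfg.attacker_type = cfg.target_type = "cancer"
        cfg.attack = sa.AttackParams(attack_rate=0.0)
        xy = np.array([[0.0, 0.0], [40.0, 0.0], [0.0, 40.0]])
        init = sa.InitialState(
            xy=xy, types=np.array(["cancer"] * 3, dtype=object), domain=cfg.domain
        )
        traj = sa.simulate(init, cfg, seed=1)
        for snap in traj.snapshots:
            np.testing.assert_array_equal(snap.xy, xy)

    def test_first_snapshot_equals_initial_state(self, rng):
        cfg = make_config(duration_min=60.0)
        init = sa.init_well_mixed(
            {"cancer": 50, "healthy": 20, "CD8": 20},
            sa.Disc((0, 0), 100), rng, domain=cfg.domain,
        )
        traj = sa.simulate(init, cfg, seed=3)
        first = traj.snapshots[0]
        assert first.time == 0.0
        # initial state is type-grouped; snapshot preserves insertion order
        np.testing.assert_array_equal(first.xy, init.xy)
        assert list(first.types) == list(init.types)

    def test_same_seed_byte_identical_summaries(self, tmp_path, rng):
        cfg = make_config(duration_min=6 * 60.0)
        init = sa.init_well_mixed(
            {"cancer": 80, "healthy": 30, "CD8": 40},
            sa.Disc((0, 0), 150), rng, domain=cfg.domain,
        )
        paths = []
        for k in range(2):
            traj = sa.simulate(init, cfg, seed=11)
            p = tmp_path / f"s{k}.csv"
            traj.summary.to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_healthy_count_constant(self, rng):
        cfg = make_config(duration_min=12 * 60.0)
        init = sa.init_well_mixed(
            {"cancer": 150, "healthy": 60, "CD8": 60},
            sa.Disc((0, 0), 200), rng, domain=cfg.domain,
        )
        traj = sa.simulate(init, cfg, seed=2)
        assert (traj.summary["count_healthy"] == 60).all()

    def test_bookkeeping_identity_per_epoch(self, rng):
        # cancer count change per epoch == divisions - deaths - kills
        cfg = make_config(duration_min=12 * 60.0)
        init = sa.init_well_mixed(
            {"cancer": 200, "healthy": 50, "CD8": 80},
            sa.Disc((0, 0), 200), rng, domain=cfg.domain,
        )
        traj = sa.simulate(init, cfg, seed=7)
        ev = traj.events
        n0 = traj.summary["count_cancer"].iloc[0]
        expected = n0 + (ev["divisions"] - ev["deaths"] - ev["kills"]).cumsum()
        np.testing.assert_array_equal(ev["cancer_count"].to_numpy(),
                                      expected.to_numpy())

    def test_containment_all_snapshots(self, rng):
        cfg = make_config(duration_min=6 * 60.0,
                          domain=sa.Rectangle(-220, -220, 220, 220))
        init = sa.init_well_mixed(
            {"cancer": 100, "healthy": 40, "CD8": 60},
            sa.Disc((0, 0), 200), rng, domain=cfg.domain,
        )
        traj = sa.simulate(init, cfg, seed=9)
        for snap in traj.snapshots:
            assert cfg.domain.contains(snap.xy).all()

    def test_probability_overflow_rejected_up_front(self):
        cfg = make_config()
        cfg.attack = sa.AttackParams(attack_rate=0.2)  # 0.2 * 6 = 1.2 > 1
        init = sa.InitialState(
            xy=np.array([[0.0, 0.0]]), types=np.array(["cancer"], dtype=object),
            domain=cfg.domain,
        )
        with pytest.raises(ConfigError, match="overflow"):
            sa.simulate(init, cfg, seed=1)
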