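"""Cluster initialization, the relax/protrude loop, and its invariants."""

import numpy as np
import pytest

from cohesim import experiments, run_simulation, simulate_ensemble
from cohesim.core import (
    ClusterConfig,
    SimulationConfig,
    SimulationError,
    _Engine,
    bond_stiffnesses,
    initialize_cluster,
)
from cohesim.protrusion import ProtrusionConfig
from cohesim.rheology import RheologyParams


class TestInitializeCluster:
    def test_just_touching_lattice_at_rest(self):
        agents, bonds = initialize_cluster(ClusterConfig(N=5))
        assert [a.x for a in agents] == [0.0, 2.0, 4.0, 6.0, 8.0]
        assert all(a.v == 0.0 and a.a == 0.0 for a in agents)
        assert [a.index for a in agents] == [1, 2, 3, 4, 5]

    def test_bond_stiffnesses_linear_in_bond_index(self):
        cfg = ClusterConfig(N=5, gradient_strength=10.0, K_min=1.0)
        np.testing.assert_allclose(bond_stiffnesses(cfg), [1.0, 4.0, 7.0, 10.0])
        # arithmetic progression for any N
        ks = bond_stiffnesses(ClusterConfig(N=9, gradient_strength=5.0, K_min=2.0))
        np.testing.assert_allclose(np.diff(ks), np.diff(ks)[0])
        assert ks[0] == 2.0 and ks[-1] == 10.0

    def test_degenerate_gradient_gives_equal_stiffness(self):
        ks = bond_stiffnesses(ClusterConfig(N=6, gradient_strength=1.0, K_min=0.5))
        np.testing.assert_allclose(ks, 0.5)

    def test_per_agent_assignment_uses_leading_member(self):
        cfg = ClusterConfig(
            N=5, gradient_strength=10.0, K_min=1.0, stiffness_assignment="agent"
        )
        # agent stiffnesses 1, 3.25, 5.5, 7.75, 10 -> bonds take the leader's
        np.testing.assert_allclose(bond_stiffnesses(cfg), [3.25, 5.5, 7.75, 10.0])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"N": 1},
            {"gradient_strength": 0.5},
            {"K_min": 0.0},
            {"Kr": -1.0},
            {"zone_max": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClusterConfig(**kwargs)


def _quiet_config(**kwargs):
    """Config with protrusions effectively disabled (pure relaxation)."""
    defaults = dict(
        cluster=ClusterConfig(),
        protrusion=ProtrusionConfig(period=10**6),
        n_steps=50,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestRelaxationDynamics:
    @pytest.mark.parametrize("model", ["kv", "sls"])
    def test_rest_state_is_fixed_point(self, model):
        cfg = _quiet_config(rheology=RheologyParams(model=model))
        with pytest.warns(UserWarning):
            traj = run_simulation(cfg)
        np.testing.assert_array_equal(traj.positions[0], traj.positions[-1])

    def test_stretched_pair_gap_decays_monotonically(self):
        cfg = _quiet_config(cluster=ClusterConfig(N=2, gradient_strength=1.0, K_min=0.05))
        eng = _Engine(cfg, 1)
        eng.x[0, 1] += 0.5
        gaps = []
        for k in range(1, 60):
            eng.relax(k)
            gaps.append(eng.x[0, 1] - eng.x[0, 0] - 2.0)
        gaps = np.asarray(gaps)
        assert np.all(np.diff(gaps) < 0)
        assert np.all(gaps > 0)  # no overshoot through the rest state

    @pytest.mark.parametrize("model", ["kv", "sls"])
    def test_symmetric_stretch_keeps_com_fixed(self, model):
        cfg = _quiet_config(
            cluster=ClusterConfig(N=3, gradient_strength=1.0, K_min=0.05),
            rheology=RheologyParams(model=model),
        )
        eng = _Engine(cfg, 1)
        eng.x[0, 0] -= 0.7
        eng.x[0, 2] += 0.7
        com0 = eng.x.mean()
        for k in range(1, 200):
            eng.relax(k)
            assert abs(eng.x.mean() - com0) < 1e-12

    @pytest.mark.parametrize("model", ["kv", "sls"])
    def test_bond_forces_conserve_momentum(self, model):
        # asymmetric stretch, eta_env=1 so damping does not mask the bookkeeping
        cfg = _quiet_config(
            cluster=ClusterConfig(N=4, gradient_strength=10.0, K_min=0.01),
            rheology=RheologyParams(model=model),
            eta_env=1.0,
        )
        eng = _Engine(cfg, 1)
        eng.x[0] += np.array([-0.4, 0.0, 0.1, 0.8])
        for k in range(1, 100):
            p_before = eng.v.sum()
            eng.relax(k)
            assert abs(eng.v.sum() - p_before) < 1e-10

    def test_numerical_blowup_raises_with_timestep(self):
        # undamped stiff chain, stiff in BOTH tension and compression so the
        # modulus switching cannot bound the oscillation; the detachment
        # cutoff is lifted so nothing rescues it
        cfg = SimulationConfig(
            cluster=ClusterConfig(
                N=5, gradient_strength=10.0, K_min=3.0, Kr=30.0, zone_max=1e9
            ),
            rheology=RheologyParams(model="kv", eta_i=0.0),
            protrusion=ProtrusionConfig(amplitude=1.0, period=600),
            eta_env=1.0,
            n_steps=2000,
            seed=0,
        )
        with pytest.raises(SimulationError, match="timestep"):
            simulate_ensemble(cfg, 1)


class TestRunSimulation:
    def test_same_seed_is_bit_identical(self):
        cfg = experiments.make_config(model="sls", amplitude=1.0, period=5, n_steps=300, seed=7)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert a.events.equals(b.events)

    def test_ensemble_row_matches_single_run(self):
        cfg = experiments.make_config(model="sls", amplitude=1.0, period=5, n_steps=300, seed=7)
        ens = simulate_ensemble(cfg, 4)
        single = run_simulation(cfg)
        assert np.array_equal(ens.positions[0], single.positions)

    def test_replicates_use_distinct_seeds(self):
        cfg = experiments.make_config(model="kv", amplitude=1.0, period=5, n_steps=200, seed=11)
        ens = simulate_ensemble(cfg, 3)
        assert ens.seeds == [11, 12, 13]
        assert not np.array_equal(ens.positions[0], ens.positions[1])

    def test_period_not_shorter_than_run_warns(self):
        cfg = experiments.make_config(n_steps=10, period=15)
        with pytest.warns(UserWarning, match="period"):
            traj = run_simulation(cfg)
        assert len(traj.events) == 0

    def test_com_is_mean_of_positions(self, short_kv_ensemble):
        traj = short_kv_ensemble.replicate(0)
        np.testing.assert_allclose(traj.com, traj.positions.mean(axis=1), atol=1e-14)

    def test_kv_trajectories_never_overlap(self, short_kv_ensemble):
        gaps = np.diff(short_kv_ensemble.positions, axis=2) - 2.0
        assert gaps.min() >= -1e-9

    def test_sls_compressions_are_small_transients(self, short_sls_ensemble):
        # velocity retention can overshoot into contact; the repulsive modulus
        # keeps the excursion well under a tenth of a radius
        gaps = np.diff(short_sls_ensemble.positions, axis=2) - 2.0
        assert gaps.min() >= -0.1

    def test_event_log_schema(self, short_kv_ensemble):
        ev = short_kv_ensemble.events
        assert list(ev.columns) == ["replicate", "timestep", "agent_index", "proposal", "accepted"]
        assert set(ev["agent_index"]) == {1, 5}  # ends_only
        assert (ev["timestep"] % 5 == 0).all()

    def test_accepted_events_move_only_that_agent(self):
        cfg = experiments.make_config(model="kv", amplitude=1.0, period=5, n_steps=40, seed=3)
        traj = run_simulation(cfg)
        ev = traj.events
        first = ev[ev["accepted"]].iloc[0]
        t, idx = int(first["timestep"]), int(first["agent_index"])
        jump = traj.positions[t] - traj.positions[t - 1]
        # the protruding agent's displacement includes the proposal
        assert abs(jump[idx - 1]) > 0
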