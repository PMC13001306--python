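"""Packing, box expansion, and integrator physics."""

import math
from dataclasses import replace

import numpy as np
import pytest

from condgram.constants import KB
from condgram.forcefield import InteractionParams
from condgram.model_core import (
    SequenceSpec,
    SystemComposition,
    build_system,
    concatenate_chains,
    parameterize,
)
from condgram.simulator import (
    Configuration,
    ProtocolSpec,
    SimulationError,
    expand_box,
    pack_random,
    repulsive_preequilibrate,
    run_langevin,
    unwrap_chains,
)


def _bond_lengths(positions, box, topo):
    d = positions[topo.bond_i] - positions[topo.bond_j]
    d -= box * np.round(d / box)
    return np.sqrt((d**2).sum(axis=1))


@pytest.fixture(scope="module")
def small_topo():
    comp = SystemComposition(SequenceSpec("R", 5, "N3G2", 1), 5, 5, 20.0)
    return build_system(comp)


class TestPacking:
    def test_single_chain_bonds_exact(self, table):
        topo = concatenate_chains([parameterize("R" * 30, table=table)])
        config = pack_random(topo, 100.0, 0.6, seed=0)
        assert np.all(np.abs(_bond_lengths(config.positions, 100.0, topo) - 0.38) < 1e-6)

    def test_deterministic_given_seed(self, small_topo):
        a = pack_random(small_topo, 20.0, 0.6, seed=42)
        b = pack_random(small_topo, 20.0, 0.6, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_min_distance_contract(self, small_topo):
        """Brute-force scan: no pair beyond the 1-3 neighbors is closer
        than min_dist, and 1-3 pairs respect their size-aware floor."""
        min_dist = 0.6
        config = pack_random(small_topo, 20.0, min_dist, seed=7)
        pos, box = config.positions, config.box_edge
        n = len(pos)
        chain = small_topo.chain_id
        sigma = small_topo.sigma
        for i in range(n):
            d = pos[i + 1:] - pos[i]
            d -= box * np.round(d / box)
            dist = np.sqrt((d**2).sum(axis=1))
            for off, r in enumerate(dist, start=1):
                j = i + off
                same = chain[i] == chain[j]
                if same and off == 1:
                    continue
                if same and off == 2:
                    floor = min(0.8 * sigma[j], 0.85 * 2 * 0.38)
                else:
                    floor = min_dist
                assert r >= floor - 1e-9, (i, j, r)

    def test_infeasible_packing_raises(self, small_topo):
        from condgram.simulator import PackingError

        with pytest.raises(PackingError):
            pack_random(small_topo, 3.0, 1.2, seed=0, max_chain_restarts=2)


class TestExpandBox:
    def test_zero_delta_is_identity(self, small_topo):
        config = pack_random(small_topo, 20.0, 0.6, seed=1)
        out = expand_box(config, 0.0, small_topo)
        assert out.box_edge == 20.0
        np.testing.assert_array_equal(out.positions, config.positions)

    def test_protocol_expansion(self, small_topo):
        config = pack_random(small_topo, 20.0, 0.6, seed=1)
        assert expand_box(config, 25.0, small_topo).box_edge == 45.0

    def test_bond_lengths_preserved_across_reimaging(self, small_topo):
        config = pack_random(small_topo, 20.0, 0.6, seed=2)
        before = _bond_lengths(config.positions, 20.0, small_topo)
        out = expand_box(config, 7.0, small_topo)
        after = _bond_lengths(out.positions, out.box_edge, small_topo)
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_chains_whole_after_expansion(self, small_topo):
        config = pack_random(small_topo, 20.0, 0.6, seed=3)
        out = expand_box(config, 10.0, small_topo)
        unwrapped = unwrap_chains(out.positions, out.box_edge, small_topo)
        # a whole molecule needs no re-imaging: unwrap is a no-op
        np.testing.assert_allclose(unwrapped, out.positions, atol=1e-9)


class TestIntegrator:
    def test_frame_count(self, small_topo, params300):
        config = pack_random(small_topo, 20.0, 0.6, seed=1)
        traj = run_langevin(
            config, small_topo, params300,
            ProtocolSpec(n_steps=1000, stride=250, seed=1),
        )
        assert traj.n_frames == 1000 // 250 + 1

    def test_deterministic_trajectories(self, small_topo, params300):
        config = pack_random(small_topo, 20.0, 0.6, seed=1)
        proto = ProtocolSpec(n_steps=500, stride=100, seed=9)
        a = run_langevin(config, small_topo, params300, proto)
        b = run_langevin(config, small_topo, params300, proto)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.positions, fb.positions)

    def test_harmonic_dimer_frequency(self, table, params300):
        """Zero-temperature, zero-friction stretched bond oscillates at
        omega = sqrt(k/mu)."""
        topo = concatenate_chains([parameterize("RG", table=table)])
        mu = topo.mass[0] * topo.mass[1] / topo.mass.sum()
        omega = math.sqrt(1000.0 / mu)
        config = Configuration(
            np.array([[10.0, 10.0, 10.0], [10.0 + 0.38 + 0.05, 10.0, 10.0]]), 50.0
        )
        proto = ProtocolSpec(dt=1.0, n_steps=8000, stride=1, friction=0.0,
                             temperature=0.0, seed=0)
        traj = run_langevin(config, topo, params300, proto,
                            velocities=np.zeros((2, 3)))
        r = np.array([
            np.linalg.norm(f.positions[1] - f.positions[0]) for f in traj.frames
        ])
        x = r - 0.38 - 0.05 / 2.0  # oscillates about equilibrium offset
        crossings = np.flatnonzero(np.diff(np.sign(r - r.mean())) != 0)
        # average half-period from successive zero crossings
        half_periods = np.diff(traj.times[crossings])
        measured = math.pi / half_periods.mean()
        assert measured == pytest.approx(omega, rel=0.01)

    def test_nve_energy_conservation(self, params300):
        """Velocity-Verlet (zero friction) drifts < 1e-4 relative over 1e4
        steps at dt = 1 fs on a 50-bead system."""
        comp = SystemComposition(SequenceSpec("R", 3, "N2", 1), 5, 5, 12.0)
        topo = build_system(comp)
        config = pack_random(topo, 12.0, 0.6, seed=4)
        rng = np.random.default_rng(0)
        v0 = rng.normal(size=(topo.n_beads, 3)) * np.sqrt(
            KB * 300.0 / topo.mass
        )[:, None]
        proto = ProtocolSpec(dt=1.0, n_steps=10_000, stride=500, friction=0.0,
                             temperature=0.0, seed=0)
        traj = run_langevin(config, topo, params300, proto, velocities=v0)
        total = traj.energies.sum(axis=1)
        assert np.abs(total - total[0]).max() / abs(total[0]) < 1e-4

    def test_langevin_thermostat_temperature(self, table, params300):
        """Kinetic temperature of a dilute gas converges to the target."""
        beads = [parameterize("G", table=table)] * 216
        topo = concatenate_chains(beads)
        config = pack_random(topo, 40.0, 2.0, seed=2)
        proto = ProtocolSpec(dt=10.0, n_steps=20_000, stride=100, friction=0.5,
                             temperature=300.0, seed=3)
        traj = run_langevin(config, topo, params300, proto)
        temps = traj.temperatures
        mean_t = temps[len(temps) // 4:].mean()
        assert mean_t == pytest.approx(300.0, rel=0.02)

    def test_divergence_is_detected(self, table, params300):
        """Overlapping beads at a huge time step raise, not silently corrupt."""
        topo = concatenate_chains([parameterize("R", table=table)] * 4)
        pos = np.full((4, 3), 10.0) + 1e-3 * np.arange(12).reshape(4, 3)
        proto = ProtocolSpec(dt=100.0, n_steps=2000, stride=10, friction=0.1,
                             temperature=300.0, seed=0)
        with pytest.raises(SimulationError):
            run_langevin(Configuration(pos, 20.0), topo, params300, proto)


class TestPreEquilibration:
    def test_disperses_to_singleton_chains(self, params300):
        from condgram.analysis import find_clusters

        comp = SystemComposition(SequenceSpec("R", 8, "N3G2", 1), 6, 6, 16.0)
        topo = build_system(comp)
        config = pack_random(topo, 16.0, 0.6, seed=0)
        proto = ProtocolSpec(n_steps=2000, stride=2000, seed=0, preequil_steps=1500)
        state = repulsive_preequilibrate(config, topo, params300, proto)
        labels = find_clusters(state.positions, state.box_edge, 1.1,
                               chain_id=topo.chain_id, level="chain")
        assert labels.max() + 1 == topo.n_chains

    def test_output_temperature_near_target(self, params300):
        comp = SystemComposition(SequenceSpec("R", 8, "N3G2", 1), 6, 6, 16.0)
        topo = build_system(comp)
        config = pack_random(topo, 16.0, 0.6, seed=1)
        proto = ProtocolSpec(n_steps=2000, stride=2000, seed=1,
                             preequil_steps=4000, friction=0.5)
        from condgram.simulator import replace_nonbonded, kinetic_temperature

        wca = replace_nonbonded(topo, lam=0.0, charge=0.0)
        traj, vel = run_langevin(config, wca, params300,
                                 replace(proto, n_steps=4000, stride=200),
                                 return_velocities=True)
        temps = traj.temperatures
        assert temps[len(temps) // 2:].mean() == pytest.approx(300.0, rel=0.05)
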