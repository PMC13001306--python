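"""System construction and Langevin dynamics: the assembly protocol.

The protocol mirrors the one used for lipid-vesicle style self-assembly:
chains are first packed uniformly into the box as self-avoiding random
walks, briefly relaxed under purely repulsive interactions (WCA, charges
off, plus an explicit soft chain-chain repulsion that prevents premature
clustering), the box is then expanded, and production Langevin dynamics is
run until condensates form.

Integration is BAOAB Langevin; zero friction reduces it exactly to velocity
Verlet (NVE).  Positions are stored wrapped; analyses unwrap as needed.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _kernels
from .constants import KB
from .forcefield import InteractionParams, build_pair_list
from .model_core import (
    ParameterTable,
    SystemComposition,
    SystemTopology,
    build_system,
)

__all__ = [
    "Configuration",
    "Trajectory",
    "ProtocolSpec",
    "PackingError",
    "SimulationError",
    "pack_random",
    "repulsive_preequilibrate",
    "expand_box",
    "run_langevin",
    "assembly_pipeline",
    "kinetic_temperature",
    "unwrap_chains",
]

NEIGHBOR_SKIN = 0.4  # nm added to rc_dh for the Verlet list


class PackingError(RuntimeError):
    pass


class SimulationError(RuntimeError):
    pass


@dataclass
class Configuration:
    """Bead positions (N x 3, nm, wrapped) in a cubic box."""

    positions: np.ndarray
    box_edge: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.box_edge)


@dataclass
class Trajectory:
    """Ordered frames with times (ps) and the save stride in steps.

    ``energies`` (optional) holds per-frame (potential, kinetic) in kJ/mol;
    ``temperatures`` derives the instantaneous kinetic temperature from it.
    """

    frames: List[Configuration]
    times: np.ndarray
    stride: int
    energies: Optional[np.ndarray] = None
    n_beads_for_temperature: Optional[int] = None

    @property
    def temperatures(self) -> Optional[np.ndarray]:
        if self.energies is None or not self.n_beads_for_temperature:
            return None
        from .constants import KB

        return 2.0 * self.energies[:, 1] / (3.0 * self.n_beads_for_temperature * KB)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != self.times.shape[0]:
            raise ValueError("frame/time count mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must increase monotonically")
        n = {f.n_beads for f in self.frames}
        if len(n) > 1:
            raise ValueError("bead count must be constant across frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def positions_array(self) -> np.ndarray:
        return np.stack([f.positions for f in self.frames])


@dataclass(frozen=True)
class ProtocolSpec:
    """Integration protocol.

    dt is in femtoseconds (default 10 fs); friction in ps^-1; expansion is
    the box-edge increase applied after pre-equilibration, nm.
    """

    dt: float = 10.0
    n_steps: int = 50_000
    friction: float = 0.01
    temperature: float = 300.0
    seed: int = 0
    expansion: float = 25.0
    stride: int = 2500
    preequil_steps: int = 2000
    pack_min_dist: float = 0.6

    @property
    def dt_ps(self) -> float:
        return self.dt * 1e-3


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

def _chain_slices(topo: SystemTopology) -> List[np.ndarray]:
    return [np.flatnonzero(topo.chain_id == c) for c in range(topo.n_chains)]


def pack_random(
    topo: SystemTopology,
    box_edge: float,
    min_dist: float = 0.6,
    seed: int = 0,
    max_chain_restarts: int = 50,
    max_bead_tries: int = 60,
) -> Configuration:
    """Place chains as self-avoiding random walks, uniformly over the box.

    Bond lengths are exactly r0.  No pair of beads separated by more than
    two bonds (or belonging to different chains) comes closer than
    ``min_dist``.  The 1-3 pair, whose span is capped by its two fixed
    bonds, gets a size-aware floor (0.8 sigma of the placed bead, capped by
    the reachable span) that keeps it off the steep repulsive core; the
    bonded 1-2 pair is unconstrained.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    n = topo.n_beads
    positions = np.zeros((n, 3))
    ncell = max(1, int(box_edge // min_dist))
    cell = box_edge / ncell
    grid: Dict[Tuple[int, int, int], List[int]] = {}

    def cell_of(p):
        return (
            int(p[0] // cell) % ncell,
            int(p[1] // cell) % ncell,
            int(p[2] // cell) % ncell,
        )

    sigma = topo.sigma

    def floor_13(bead):
        # next-nearest beads sit on two fixed bonds; keep them off the steep
        # repulsive core (0.8 sigma) without demanding an unreachable span
        b = r0_next.get(int(bead) - 1, 0.4) + r0_next.get(int(bead) - 2, 0.4)
        return min(0.8 * sigma[bead], 0.85 * b)

    def clashes(p, trial, bead):
        # previously committed chains, via the cell grid
        cx, cy, cz = cell_of(p)
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    key = ((cx + ox) % ncell, (cy + oy) % ncell, (cz + oz) % ncell)
                    for idx in grid.get(key, ()):
                        d = positions[idx] - p
                        d -= box_edge * np.round(d / box_edge)
                        if float(d @ d) < min_dist * min_dist:
                            return True
        # the growing chain: full min_dist beyond the 1-3 neighbor, a smaller
        # floor for the 1-3 pair itself (two fixed bonds limit its reach),
        # and no constraint on the bonded 1-2 neighbor
        for q in trial[:max(0, len(trial) - 2)]:
            d = q - p
            d -= box_edge * np.round(d / box_edge)
            if float(d @ d) < min_dist * min_dist:
                return True
        if len(trial) >= 2:
            d = trial[-2] - p
            d -= box_edge * np.round(d / box_edge)
            f13 = floor_13(bead)
            if float(d @ d) < f13 * f13:
                return True
        return False

    # map bead -> bond length to its successor
    r0_next = {}
    for bi, bj, r0 in zip(topo.bond_i, topo.bond_j, topo.bond_r0):
        r0_next[int(bi)] = float(r0)

    for chain in _chain_slices(topo):
        for restart in range(max_chain_restarts):
            trial: List[np.ndarray] = []
            ok = True
            for local, bead in enumerate(chain):
                for _ in range(max_bead_tries):
                    if local == 0:
                        p = rng.random(3) * box_edge
                    else:
                        v = rng.normal(size=3)
                        v /= np.linalg.norm(v)
                        p = np.mod(
                            trial[-1] + v * r0_next[int(chain[local - 1])], box_edge
                        )
                    if not clashes(p, trial, bead):
                        break
                else:
                    ok = False
                    break
                trial.append(p)
            if ok:
                for bead, p in zip(chain, trial):
                    positions[bead] = p
                    grid.setdefault(cell_of(p), []).append(int(bead))
                break
        else:
            raise PackingError(
                f"failed to place chain after {max_chain_restarts} restarts; "
                "try a larger box or smaller min_dist"
            )
    return Configuration(np.mod(positions, box_edge), box_edge)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature from equipartition, K."""
    n = velocities.shape[0]
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2))
    return 2.0 * ke / (3.0 * n * KB)


def _maxwell_boltzmann(rng, masses, temperature):
    if temperature <= 0:
        return np.zeros((masses.shape[0], 3))
    sd = np.sqrt(KB * temperature / masses)[:, None]
    return rng.normal(size=(masses.shape[0], 3)) * sd


@dataclass
class _ForceField:
    topo: SystemTopology
    params: InteractionParams
    chain_repulsion: Optional[Tuple[float, float]] = None  # (d0 nm, k kJ/mol/nm^2)

    def __call__(self, positions, box, pair_list):
        f = np.zeros_like(positions)
        e_bond = _kernels.bond_forces(
            positions, box, self.topo.bond_i, self.topo.bond_j,
            self.topo.bond_r0, self.topo.bond_k, f,
        )
        pi, pj = pair_list
        from .constants import COULOMB
        from .forcefield import OVERLAP_FLOOR

        e_ah, e_dh, _ = _kernels.pair_forces(
            positions, box, pi, pj,
            self.topo.sigma, self.topo.lam, self.topo.charge,
            self.topo.bonded_next,
            self.params.eps_ah, self.params.rc_ah, self.params.rc_dh,
            self.params.kappa, COULOMB / self.params.eps_r, OVERLAP_FLOOR, f,
        )
        e_extra = 0.0
        if self.chain_repulsion is not None:
            d0, k_rep = self.chain_repulsion
            e_extra = _kernels.chain_com_repulsion(
                positions, box, self.topo.chain_id, self.topo.mass,
                self.topo.n_chains, d0, k_rep, f,
            )
        return f, e_bond + e_ah + e_dh + e_extra


def run_langevin(
    config: Configuration,
    topo: SystemTopology,
    params: InteractionParams,
    protocol: ProtocolSpec,
    velocities: Optional[np.ndarray] = None,
    chain_repulsion: Optional[Tuple[float, float]] = None,
    return_velocities: bool = False,
):
    """BAOAB Langevin dynamics; zero friction gives velocity-Verlet NVE.

    Frames (wrapped positions) are saved every ``protocol.stride`` steps,
    including the initial one; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(protocol.seed)
    dt = protocol.dt_ps
    gamma = protocol.friction
    box = config.box_edge
    masses = topo.mass
    x = np.mod(config.positions.copy(), box)
    v = velocities.copy() if velocities is not None else _maxwell_boltzmann(
        rng, masses, protocol.temperature
    )
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sd = np.sqrt(KB * protocol.temperature / masses)[:, None]
    inv_m = 1.0 / masses[:, None]

    ff = _ForceField(topo, params, chain_repulsion)
    rlist = params.rc_dh + NEIGHBOR_SKIN
    pair_list = build_pair_list(x, box, rlist)
    x_ref = x.copy()
    f, e_pot = ff(x, box, pair_list)
    if not np.all(np.isfinite(f)):
        raise SimulationError("non-finite forces in the starting configuration")

    def e_kin():
        return 0.5 * float(np.sum(masses[:, None] * v**2))

    frames = [Configuration(x.copy(), box)]
    times = [0.0]
    energies = [(float(e_pot), e_kin())]
    half = 0.5 * dt
    for step in range(1, protocol.n_steps + 1):
        v += half * f * inv_m
        x += half * v
        if gamma > 0.0 and protocol.temperature > 0.0:
            v = c1 * v + c2 * sd * rng.normal(size=v.shape)
        elif gamma > 0.0:
            v = c1 * v
        x += half * v
        x = np.mod(x, box)
        if _kernels.max_displacement(x, x_ref, box) > NEIGHBOR_SKIN / 2.0:
            if not np.all(np.isfinite(x)):
                raise SimulationError(f"NaN positions at step {step}")
            pair_list = build_pair_list(x, box, rlist)
            x_ref = x.copy()
        f, e_pot = ff(x, box, pair_list)
        v += half * f * inv_m
        if step % protocol.stride == 0:
            if not np.all(np.isfinite(x)):
                raise SimulationError(f"NaN positions at step {step}")
            if gamma > 0.0 and protocol.temperature > 0.0:
                t_kin = kinetic_temperature(v, masses)
                if t_kin > 50.0 * protocol.temperature:
                    raise SimulationError(
                        f"diverging dynamics at step {step}: "
                        f"kinetic temperature {t_kin:.3g} K"
                    )
            frames.append(Configuration(x.copy(), box))
            times.append(step * dt)
            energies.append((float(e_pot), e_kin()))
    traj = Trajectory(
        frames=frames, times=np.asarray(times), stride=protocol.stride,
        energies=np.asarray(energies), n_beads_for_temperature=topo.n_beads,
    )
    if return_velocities:
        return traj, v
    return traj


# ---------------------------------------------------------------------------
# protocol stages
# ---------------------------------------------------------------------------

def repulsive_preequilibrate(
    config: Configuration,
    topo: SystemTopology,
    params: InteractionParams,
    protocol: ProtocolSpec,
    cluster_cutoff: float = 1.1,
    max_bursts: int = 12,
    chain_repulsion: Optional[Tuple[float, float]] = None,
) -> Configuration:
    """Relax under purely repulsive interactions until chains are dispersed.

    All hydrophobicities are set to zero (pure WCA) and charges are switched
    off; a soft chain-chain center-of-mass repulsion actively separates
    chains.  The run is extended in bursts until the chain-level cluster
    count equals the chain count at the analysis cutoff; failing that within
    ``max_bursts`` bursts is an error.
    """
    from .analysis import find_clusters  # local import to avoid a cycle

    wca_topo = replace_nonbonded(topo, lam=0.0, charge=0.0)
    if chain_repulsion is None:
        spacing = config.box_edge / max(1.0, topo.n_chains ** (1.0 / 3.0))
        chain_repulsion = (spacing, 50.0)
    burst = replace(protocol, n_steps=protocol.preequil_steps,
                    stride=protocol.preequil_steps)
    # gentle start: relax packing contacts at a reduced time step first
    soft = replace(burst, dt=protocol.dt / 10.0, n_steps=1000, stride=1000,
                   seed=protocol.seed + 7919)
    state, velocities = run_langevin(
        config, wca_topo, params, soft, chain_repulsion=chain_repulsion,
        return_velocities=True,
    )
    state = state.frames[-1]
    for i in range(max_bursts):
        traj, velocities = run_langevin(
            state, wca_topo, params, replace(burst, seed=protocol.seed + i),
            velocities=velocities, chain_repulsion=chain_repulsion,
            return_velocities=True,
        )
        state = traj.frames[-1]
        labels = find_clusters(
            state.positions, state.box_edge, cluster_cutoff,
            chain_id=topo.chain_id, level="chain",
        )
        if labels.max() + 1 == topo.n_chains:
            return state
    raise SimulationError(
        "pre-equilibration failed to disperse chains; "
        "consider a larger box or more bursts"
    )


def replace_nonbonded(topo: SystemTopology, lam=None, charge=None) -> SystemTopology:
    """Copy of a topology with lambda and/or charge arrays replaced."""
    import copy

    new = copy.copy(topo)
    if lam is not None:
        new.lam = np.full_like(topo.lam, float(lam))
    if charge is not None:
        new.charge = np.full_like(topo.charge, float(charge))
    return new


def unwrap_chains(positions: np.ndarray, box: float, topo: SystemTopology) -> np.ndarray:
    """Unwrap each chain by walking its bonds so molecules are whole.

    Successive minimum-image bond vectors are accumulated from the first
    bead; valid because every bond is far shorter than half the box, even
    when the chain contour is not.
    """
    out = positions.copy()
    for chain in _chain_slices(topo):
        steps = out[chain[1:]] - out[chain[:-1]]
        steps -= box * np.round(steps / box)
        out[chain[1:]] = out[chain[0]] + np.cumsum(steps, axis=0)
    return out


def expand_box(
    config: Configuration, delta: float, topo: Optional[SystemTopology] = None
) -> Configuration:
    """Grow the box edge by delta, keeping coordinates (no rescaling).

    Chains are re-imaged whole: each chain is unwrapped under the old box,
    then translated so its geometric center lies inside the new box.  Bond
    lengths are unchanged.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    new_box = config.box_edge + delta
    if delta == 0:
        return config.copy()
    pos = config.positions.copy()
    if topo is not None:
        pos = unwrap_chains(pos, config.box_edge, topo)
        for chain in _chain_slices(topo):
            center = pos[chain].mean(axis=0)
            shift = np.mod(center, new_box) - center
            pos[chain] += shift
    else:
        pos = np.mod(pos, new_box)
    return Configuration(pos, new_box)


def assembly_pipeline(
    comp: SystemComposition,
    protocol: ProtocolSpec,
    table: Optional[ParameterTable] = None,
    params: Optional[InteractionParams] = None,
) -> Tuple[Trajectory, SystemTopology, List[Dict]]:
    """pack -> repulsive pre-equilibration -> box expansion -> production.

    Returns the production trajectory, the system topology, and a provenance
    log recording each stage in order with its parameters.
    """
    topo = build_system(comp, table)
    if params is None:
        params = InteractionParams.from_conditions(
            comp.temperature, comp.ionic_strength
        )
    log: List[Dict] = []

    def record(stage, **info):
        log.append({"stage": stage, "wallclock_s": _time.time(), **info})

    config = pack_random(topo, comp.box_edge, protocol.pack_min_dist, protocol.seed)
    record("pack_random", box_edge=comp.box_edge,
           min_dist=protocol.pack_min_dist, seed=protocol.seed)

    config = repulsive_preequilibrate(config, topo, params, protocol)
    record("repulsive_preequilibrate", steps=protocol.preequil_steps)

    config = expand_box(config, protocol.expansion, topo)
    record("expand_box", delta=protocol.expansion, box_edge=config.box_edge)

    traj = run_langevin(config, topo, params, protocol)
    record("run_langevin", n_steps=protocol.n_steps, dt_fs=protocol.dt,
           friction=protocol.friction, temperature=protocol.temperature,
           seed=protocol.seed)
    return traj, topo, log
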