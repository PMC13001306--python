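"""Synthetic fixtures and scaled-down demo systems.

Two jobs: (1) geometric bead arrangements with known ground-truth
morphology (idealized vesicles, multilayers, biphasic droplets, micelle
fields, tadpoles, dilute gases) so every analysis stage is testable without
running dynamics; (2) desk-scale presets of the simulated systems — tens of
chains of 40-60 beads instead of hundreds of 200-residue chains — that keep
the interaction hierarchy (Domain H-RNA strongest) while running in
minutes.  The presets are qualitative analogues of the full-scale systems,
not reproductions of them.

Shell fixtures place beads at uniform random directions with Gaussian
radial jitter (sigma = the stated width), so radial peak shapes are
reproducible from the spec alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model_core import SequenceSpec, SystemComposition
from .simulator import Configuration, ProtocolSpec

__all__ = [
    "Shell",
    "FixtureSpec",
    "Fixture",
    "generate_fixture",
    "default_fixture_spec",
    "ARCHETYPES",
    "demo_system",
    "DEMO_PRESETS",
]

ARCHETYPES = (
    "uniform_gas",
    "vesicle",
    "multilayer",
    "biphasic",
    "micelle_field",
    "tadpole",
    "no_condensate",
)

#: ground-truth morphology label per archetype
TRUTH = {
    "uniform_gas": "homogeneous",
    "vesicle": "vesicle",
    "multilayer": "multilayer",
    "biphasic": "biphasic",
    "micelle_field": "micelles",
    "tadpole": "partial_vesicle",
    "no_condensate": "no_condensate",
}


@dataclass(frozen=True)
class Shell:
    """One radial component: group name, mean radius (nm), Gaussian width
    (nm; a radius of 0 with nonzero width means a filled ball of that
    radius taken from the width field), bead count."""

    group: str
    radius: float
    width: float
    count: int


@dataclass(frozen=True)
class FixtureSpec:
    archetype: str
    shells: Tuple[Shell, ...] = ()
    box_edge: float = 48.0
    seed: int = 0
    n_beads: int = 5000  # used by uniform_gas / no_condensate

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; choose from {ARCHETYPES}"
            )
        for s in self.shells:
            if s.radius >= self.box_edge / 2.0:
                raise ValueError("shell radius must be < box_edge/2")
            if s.count <= 0:
                raise ValueError("shell counts must be > 0")


@dataclass
class Fixture:
    config: Configuration
    groups: Dict[str, np.ndarray]
    chain_id: np.ndarray
    masses: np.ndarray
    truth: str
    spec: FixtureSpec


def default_fixture_spec(archetype: str, seed: int = 0) -> FixtureSpec:
    """Canonical geometry for each archetype (radii in nm)."""
    box = 48.0
    shells: Tuple[Shell, ...] = ()
    if archetype == "vesicle":
        shells = (
            Shell("DomainL", 8.0, 0.8, 900),
            Shell("H+RNA", 14.0, 1.0, 2400),
            Shell("DomainL", 20.0, 1.0, 2400),
        )
    elif archetype == "multilayer":
        shells = (
            Shell("DomainL", 0.0, 6.0, 1200),  # filled ball, radius 6
            Shell("H+RNA", 11.0, 1.0, 2200),
            Shell("DomainL", 16.0, 1.0, 1600),
        )
    elif archetype == "biphasic":
        shells = (
            Shell("DomainL", 0.0, 7.0, 1600),  # filled ball, radius 7
            Shell("H+RNA", 11.5, 1.2, 2200),
        )
    elif archetype == "tadpole":
        shells = (
            Shell("DomainL", 8.0, 0.8, 900),
            Shell("H+RNA", 14.0, 1.0, 2400),
            Shell("DomainL", 20.0, 1.0, 2400),
        )
    return FixtureSpec(archetype=archetype, shells=shells, box_edge=box, seed=seed)


def _unit_dirs(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _split_hr(idx: np.ndarray, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Split an H+RNA selection into interleaved H and RNA halves."""
    perm = rng.permutation(idx)
    half = len(perm) // 2
    return perm[:half], perm[half:]


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministic bead placement for a fixture archetype.

    Returns the configuration, the standard analysis groups (DomainH,
    DomainL, RNA, H+RNA, all), pseudo-chain ids for chain-level clustering,
    unit masses, and the intended morphology label as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    box = spec.box_edge
    center = np.full(3, box / 2.0)
    positions: List[np.ndarray] = []
    group_of: List[str] = []
    chain_id: List[int] = []

    def add(points: np.ndarray, group: str, chains: Optional[np.ndarray] = None):
        start_chain = (max(chain_id) + 1) if chain_id else 0
        if chains is None:
            chains = start_chain + np.arange(len(points)) // 20
        positions.append(np.mod(points, box))
        group_of.extend([group] * len(points))
        chain_id.extend(int(c) for c in chains)

    arch = spec.archetype
    if arch in ("vesicle", "multilayer", "biphasic", "tadpole"):
        for shell in spec.shells:
            if shell.radius == 0.0:  # filled ball of radius = width
                radius = shell.width * rng.random(shell.count) ** (1.0 / 3.0)
            else:
                radius = shell.radius + shell.width * rng.normal(size=shell.count)
                radius = np.abs(radius)
            dirs = _unit_dirs(rng, shell.count)
            if arch == "tadpole" and shell.radius > 0.0:
                # partially formed vesicle: open both polar caps (50 degrees)
                # so the shell is hollow but angularly incomplete; antipodal
                # openings keep the center of mass at the geometric center
                cap = np.cos(np.deg2rad(50.0))
                keep = np.abs(dirs[:, 2]) < cap
                while keep.sum() < shell.count:
                    dirs = np.vstack([dirs, _unit_dirs(rng, shell.count)])
                    keep = np.abs(dirs[:, 2]) < cap
                dirs = dirs[keep][: shell.count]
            add(center + dirs * radius[:, None], shell.group)
        if arch == "tadpole":
            # small dense blobs at the opening rims ("double-tailed" form);
            # antipodal placement keeps the center of mass centered
            for sign in (1.0, -1.0):
                rim = center + sign * 14.0 * np.array([0.77, 0.0, 0.64])
                add(rim + 1.5 * rng.normal(size=(150, 3)), "H+RNA")
    elif arch == "uniform_gas":
        pts = rng.random((spec.n_beads, 3)) * box
        # mixed composition: half H+RNA material, half Domain L
        n_hr = spec.n_beads // 2
        add(pts[:n_hr], "H+RNA")
        add(pts[n_hr:], "DomainL")
    elif arch == "micelle_field":
        centers = np.array(
            [[x, y, z] for x in (12.0, 36.0) for y in (12.0, 36.0) for z in (12.0, 36.0)]
        )
        centers = centers + rng.normal(scale=0.5, size=centers.shape)
        for c in centers:
            core_r = 2.5 * rng.random(130) ** (1.0 / 3.0)
            add(c + _unit_dirs(rng, 130) * core_r[:, None], "H+RNA")
            shell_r = np.abs(3.4 + 0.6 * rng.normal(size=140))
            add(c + _unit_dirs(rng, 140) * shell_r[:, None], "DomainL")
    elif arch == "no_condensate":
        n_chains = 40
        grid = np.linspace(6.0, box - 6.0, 4)
        sites = np.array([[x, y, z] for x in grid for y in grid for z in grid])
        sites = sites[rng.permutation(len(sites))[:n_chains]]
        for k, site in enumerate(sites):
            walk = [site]
            for _ in range(9):
                step = _unit_dirs(rng, 1)[0] * 0.5
                walk.append(walk[-1] + step)
            group = "H+RNA" if k % 2 == 0 else "DomainL"
            add(np.array(walk), group, chains=np.full(10, k))

    pos = np.vstack(positions)
    group_of_arr = np.asarray(group_of, dtype=object)
    chain_arr = np.asarray(chain_id, dtype=np.int64)
    hr_idx = np.flatnonzero(group_of_arr == "H+RNA")
    h_idx, rna_idx = _split_hr(hr_idx, rng)
    groups = {
        "DomainH": np.sort(h_idx),
        "DomainL": np.flatnonzero(group_of_arr == "DomainL"),
        "RNA": np.sort(rna_idx),
        "H+RNA": hr_idx,
        "all": np.arange(len(pos)),
    }
    return Fixture(
        config=Configuration(pos, box),
        groups=groups,
        chain_id=chain_arr,
        masses=np.ones(len(pos)),
        truth=TRUTH[arch],
        spec=spec,
    )


# ---------------------------------------------------------------------------
# demo system presets
# ---------------------------------------------------------------------------

def _preset(grammar, n_protein, n_rna, box, protocol_kwargs, description,
            compute_heavy=False, rna_length=None):
    spec = SequenceSpec.from_grammar(grammar, rna_length=rna_length)
    comp = SystemComposition(
        protein_spec=spec,
        n_protein_chains=n_protein,
        n_rna_chains=n_rna,
        box_edge=box,
    )
    protocol = ProtocolSpec(**protocol_kwargs)
    meta = {"description": description, "compute_heavy": compute_heavy}
    return comp, protocol, meta


_DESK_PROTOCOL = dict(
    dt=10.0,
    n_steps=50_000,
    friction=0.01,
    temperature=300.0,
    expansion=5.0,
    stride=2500,
    preequil_steps=2000,
    pack_min_dist=0.6,
)

DEMO_PRESETS: Dict[str, Tuple] = {}


def _register_presets():
    DEMO_PRESETS["systemA_small"] = _preset(
        "R30(N3G2)2", 24, 24, 34.0, _DESK_PROTOCOL,
        "Desk-scale System A analogue: weak L-L and L-RNA, strong H-RNA; "
        "24 protein chains R30(N3G2)2 (40 residues) + 24 poly-U30 chains.",
    )
    DEMO_PRESETS["systemB_small"] = _preset(
        "R12(Q3G2)6", 24, 24, 30.0, dict(_DESK_PROTOCOL, n_steps=30_000),
        "Desk-scale System B analogue: attractive L-L via glutamine, "
        "weak L-RNA; R12(Q3G2)6 + U12.",
    )
    DEMO_PRESETS["systemC_small"] = _preset(
        "R12(F3G2)6", 24, 24, 30.0, dict(_DESK_PROTOCOL, n_steps=30_000),
        "Desk-scale System C analogue: strongly attractive F-rich Domain L; "
        "R12(F3G2)6 + U12.",
    )
    DEMO_PRESETS["protein_only_repulsive"] = _preset(
        "R30(KD)5", 24, 0, 34.0, _DESK_PROTOCOL,
        "Negative control: arginine-rich chains with zwitterionic repulsive "
        "Domain L and no RNA; no cluster growth expected.",
    )
    DEMO_PRESETS["fig2d_full"] = _preset(
        "R150(N3G2)10", 1600, 1600, 160.0,
        dict(dt=10.0, n_steps=50_000_000, friction=0.01, temperature=300.0,
             expansion=25.0, stride=100_000, preequil_steps=100_000,
             pack_min_dist=0.6),
        "Full-scale vesicle system: 1600 chains each of R150(N3G2)10 and "
        "U150 in a 160 nm box. Cluster-compute scale, not a desk job.",
        compute_heavy=True,
    )


_register_presets()


def demo_system(name: str) -> Tuple[SystemComposition, ProtocolSpec, Dict]:
    """Look up a named demo preset -> (composition, protocol, metadata)."""
    try:
        return DEMO_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(DEMO_PRESETS)}"
        ) from None
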