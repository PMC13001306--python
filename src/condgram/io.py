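"""Readers/writers, run configuration, and provenance.

Snapshots are PDB (one bead per residue; the domain label rides in the
chain ID column, bead diameter in Angstrom in the B-factor column, box in
CRYST1).  Trajectories are DCD with a JSON sidecar carrying times, stride
and the config hash.  Metrics export as tab-separated tables with
unit-bearing header comments.  Units in all files: nm, ps, kJ/mol, Da, e
(PDB and DCD store Angstrom, as their formats require).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from .analysis import ClusterMetrics, ContactProfile, MorphologyLabel, PMFProfile, RadialProfile
from .model_core import SystemTopology
from .simulator import Configuration, Trajectory

__all__ = [
    "RunConfig",
    "write_snapshot",
    "read_snapshot",
    "write_trajectory",
    "read_trajectory",
    "export_metrics",
]

_DOMAIN_TO_CHAIN = {"H": "H", "L": "L", "RNA": "R"}
_CHAIN_TO_DOMAIN = {v: k for k, v in _DOMAIN_TO_CHAIN.items()}


@dataclass
class RunConfig:
    """Serializable description of one run; hash makes outputs traceable."""

    protein: str = "R150(N3G2)10"
    rna_match_h: bool = True
    rna_length: Optional[int] = None
    n_protein_chains: int = 24
    n_rna_chains: int = 24
    box_edge: float = 34.0
    temperature: float = 300.0
    ionic_strength: float = 0.1
    eps_ah: float = 0.8368
    rc_ah: float = 2.0
    rc_dh: float = 4.0
    friction: float = 0.01
    dt: float = 10.0
    n_steps: int = 50_000
    stride: int = 2500
    seed: int = 0
    expansion: float = 5.0
    cluster_cutoff: float = 1.1
    contact_cutoff: float = 1.1
    rdf_bin_width: float = 0.75

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# snapshots (PDB)
# ---------------------------------------------------------------------------

def write_snapshot(config: Configuration, topo: SystemTopology, path) -> None:
    """One bead per residue; coordinates nm -> Angstrom at PDB precision."""
    import MDAnalysis as mda

    n = topo.n_beads
    u = mda.Universe.empty(
        n_atoms=n, n_residues=n, n_segments=1,
        atom_resindex=np.arange(n), trajectory=True,
    )
    u.add_TopologyAttr("name", [b[:4] for b in topo.names])
    u.add_TopologyAttr("resname", [b[:3] for b in topo.names])
    u.add_TopologyAttr("resid", (np.arange(n) % 9999) + 1)
    u.add_TopologyAttr("chainIDs",
                       [_DOMAIN_TO_CHAIN[d] for d in topo.domain_labels])
    u.add_TopologyAttr("tempfactors", topo.sigma * 10.0)  # diameter, Angstrom
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.atoms.positions = config.positions * 10.0
    u.dimensions = [config.box_edge * 10.0] * 3 + [90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_snapshot(path):
    """Read a bead snapshot back: (Configuration, names, domain_labels)."""
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            positions = u.atoms.positions / 10.0
            box = float(u.dimensions[0]) / 10.0
            names = [n.strip() for n in u.atoms.names]
            chains = [c.strip() for c in u.atoms.chainIDs]
    except Exception as exc:  # noqa: BLE001 - parse errors become one type
        raise ValueError(f"cannot parse snapshot {path}: {exc}") from exc
    labels = [_CHAIN_TO_DOMAIN.get(c, c) for c in chains]
    return Configuration(positions, box), names, labels


# ---------------------------------------------------------------------------
# trajectories (DCD + JSON sidecar)
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path, config_hash: str = "") -> None:
    from mdtraj.formats import DCDTrajectoryFile

    path = str(path)
    xyz = traj.positions_array() * 10.0  # nm -> Angstrom
    boxes = np.array([[f.box_edge * 10.0] * 3 for f in traj.frames])
    angles = np.full((traj.n_frames, 3), 90.0)
    with DCDTrajectoryFile(path, "w") as fh:
        fh.write(xyz, cell_lengths=boxes, cell_angles=angles)
    sidecar = {
        "n_frames": traj.n_frames,
        "times_ps": traj.times.tolist(),
        "stride": traj.stride,
        "config_hash": config_hash,
        "units": {"length": "Angstrom in file, nm in memory", "time": "ps"},
    }
    Path(path + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trajectory(path) -> Trajectory:
    from mdtraj.formats import DCDTrajectoryFile

    path = str(path)
    with DCDTrajectoryFile(path, "r") as fh:
        xyz, cell_lengths, _ = fh.read()
    sidecar_path = Path(path + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        times = np.asarray(sidecar["times_ps"], dtype=float)
        stride = int(sidecar["stride"])
        if sidecar.get("n_frames") != len(xyz):
            raise ValueError(
                f"frame count mismatch: sidecar says {sidecar.get('n_frames')}, "
                f"file holds {len(xyz)}"
            )
    else:
        times = np.arange(len(xyz), dtype=float)
        stride = 1
    frames = [
        Configuration(xyz[i] / 10.0, float(cell_lengths[i][0]) / 10.0)
        for i in range(len(xyz))
    ]
    return Trajectory(frames=frames, times=times, stride=stride)


# ---------------------------------------------------------------------------
# metrics export
# ---------------------------------------------------------------------------

def _header(title: str, units: str, config_hash: str) -> str:
    return (
        f"# {title}\n"
        f"# units: {units}\n"
        f"# config_hash: {config_hash or 'unset'}"
    )


def export_metrics(
    outdir,
    rdf: Optional[RadialProfile] = None,
    pmf: Optional[PMFProfile] = None,
    contacts: Optional[ContactProfile] = None,
    clusters: Optional[ClusterMetrics] = None,
    label: Optional[MorphologyLabel] = None,
    config_hash: str = "",
) -> List[Path]:
    """Write rdf.tsv / pmf.tsv / contacts.tsv / clusters.tsv / classification.json.

    Masked PMF bins are written as literal NA, never 0.  Identical inputs
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def fmt(x):
        return "NA" if (isinstance(x, float) and not np.isfinite(x)) else f"{x:.8g}"

    if rdf is not None:
        p = outdir / "rdf.tsv"
        cols = ["r_nm"] + list(rdf.g)
        lines = [_header("COM-centered radial distribution functions",
                         "r in nm; g dimensionless", config_hash)]
        lines.append("\t".join(cols))
        for i, r in enumerate(rdf.bin_centers):
            lines.append("\t".join([fmt(float(r))] + [fmt(float(rdf.g[c][i])) for c in rdf.g]))
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    if pmf is not None:
        p = outdir / "pmf.tsv"
        lines = [_header("Potential of mean force from g(r)",
                         "r in nm; pmf in kJ/mol; masked bins NA", config_hash)]
        lines.append("r_nm\tpmf_kJ_mol")
        for r, v in zip(pmf.bin_centers, pmf.pmf):
            lines.append(f"{fmt(float(r))}\t{fmt(float(v))}")
        lines.append(f"# weighted_mean_kJ_mol\t{fmt(pmf.weighted_mean)}")
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    if contacts is not None:
        p = outdir / "contacts.tsv"
        lines = [_header("Mean neighbor counts within the contact cutoff",
                         "counts per protein bead", config_hash)]
        lines.append("selection\tprotein_neighbors\trna_neighbors")
        lines.append(f"all\t{fmt(contacts.mean_protein_neighbors)}\t"
                     f"{fmt(contacts.mean_rna_neighbors)}")
        for dom, vals in contacts.by_domain.items():
            lines.append(f"Domain{dom}\t{fmt(vals['protein'])}\t{fmt(vals['rna'])}")
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    if clusters is not None:
        p = outdir / "clusters.tsv"
        lines = [_header("Cluster metrics time series",
                         f"time in ps; sizes in {clusters.level}s; rg in nm",
                         config_hash)]
        lines.append("time_ps\tn_clusters\tlargest_size\tlargest_rg_nm")
        for t, nc, ls, rg in zip(clusters.times, clusters.n_clusters,
                                 clusters.largest_size, clusters.largest_rg):
            lines.append(f"{fmt(float(t))}\t{int(nc)}\t{int(ls)}\t{fmt(float(rg))}")
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    if label is not None:
        p = outdir / "classification.json"
        payload = {
            "label": label.label,
            "evidence": {
                k: (v if isinstance(v, (str, int, float, bool, list, type(None)))
                    else repr(v))
                for k, v in label.evidence.items()
            },
            "config_hash": config_hash,
        }
        p.write_text(json.dumps(payload, indent=1, default=str))
        written.append(p)
    return written
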