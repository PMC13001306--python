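"""Bonded and nonbonded energetics of the coarse-grained model.

Three terms:

* harmonic bonds, U = 1/2 k (r - r0)^2;
* Ashbaugh-Hatch (AH) short-range pair potential: a Lennard-Jones form whose
  attractive branch is scaled by the mean hydrophobicity lambda_ij and which
  is shifted to vanish at its cutoff.  lambda = 0 recovers the purely
  repulsive Weeks-Chandler-Andersen (WCA) interaction;
* Debye-Hueckel (DH) screened electrostatics, shift-truncated at its cutoff.

Combining rules are arithmetic means: sigma_ij = (sigma_i + sigma_j)/2 and
lambda_ij = (lambda_i + lambda_j)/2.  Only directly bonded (1-2) pairs are
excluded from the nonbonded sums.  Minimum-image convention in cubic boxes
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .constants import COULOMB
from .model_core import SystemTopology, debye_kappa, dielectric

__all__ = [
    "InteractionParams",
    "lj",
    "ah_pair_energy",
    "dh_pair_energy",
    "bond_energy",
    "total_energy",
    "forces",
    "OverlapWarning",
    "TWO_POW_SIXTH",
]

TWO_POW_SIXTH = _kernels.TWO_POW_SIXTH

#: default AH energy scale: 0.2 kcal/mol, the published CALVADOS convention
DEFAULT_EPS_AH = 0.8368
DEFAULT_RC_AH = 2.0  # nm
DEFAULT_RC_DH = 4.0  # nm
#: pairs closer than this fraction of sigma_ij are reported as overlaps
OVERLAP_FLOOR = 0.4


class OverlapWarning(UserWarning):
    """Beads closer than the overlap floor were found (reported, not fatal)."""


@dataclass(frozen=True)
class InteractionParams:
    """Nonbonded interaction parameters.

    eps_ah is the AH energy scale in kJ/mol; rc_ah and rc_dh are the AH and
    DH cutoffs in nm; kappa the inverse Debye length in nm^-1; eps_r the
    relative permittivity used in the DH prefactor.
    """

    eps_ah: float = DEFAULT_EPS_AH
    rc_ah: float = DEFAULT_RC_AH
    rc_dh: float = DEFAULT_RC_DH
    kappa: float = 1.0417
    eps_r: float = 77.73

    def __post_init__(self) -> None:
        if self.eps_ah <= 0:
            raise ValueError("eps_ah must be > 0")
        if self.rc_dh < self.rc_ah:
            raise ValueError("rc_dh must be >= rc_ah")

    @classmethod
    def from_conditions(
        cls, temperature: float = 300.0, ionic_strength: float = 0.1, **overrides
    ) -> "InteractionParams":
        """Derive kappa and eps_r from temperature and ionic strength."""
        return cls(
            kappa=debye_kappa(ionic_strength, temperature),
            eps_r=dielectric(temperature),
            **overrides,
        )

    def wca_only(self) -> "InteractionParams":
        """Parameters for the repulsive pre-equilibration stage (handled by
        zeroing lambda and charge at the topology level; kept for clarity)."""
        return self


# ---------------------------------------------------------------------------
# scalar / vectorized pair potentials
# ---------------------------------------------------------------------------

def lj(r, sigma, eps):
    """Plain Lennard-Jones 4 eps [(s/r)^12 - (s/r)^6]; r > 0, in nm."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def ah_pair_energy(r, sigma_ij, lambda_ij, params: InteractionParams):
    """Ashbaugh-Hatch pair energy, kJ/mol (piecewise, zero beyond rc_ah)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    ulj = lj(np.where(r > 0, r, 1.0), sigma_ij, params.eps_ah)
    ulj_rc = lj(params.rc_ah, sigma_ij, params.eps_ah)
    inner = ulj - lambda_ij * ulj_rc + params.eps_ah * (1.0 - lambda_ij)
    outer = lambda_ij * (ulj - ulj_rc)
    out = np.where(r <= TWO_POW_SIXTH * sigma_ij, inner, outer)
    out = np.where(r > params.rc_ah, 0.0, out)
    return out if out.ndim else float(out)


def dh_pair_energy(r, qi, qj, params: InteractionParams):
    """Shift-truncated Debye-Hueckel pair energy, kJ/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    pref = COULOMB * qi * qj / params.eps_r
    shift = np.exp(-params.kappa * params.rc_dh) / params.rc_dh
    out = pref * (np.exp(-params.kappa * r) / r - shift)
    out = np.where(r > params.rc_dh, 0.0, out)
    return out if out.ndim else float(out)


def bond_energy(r, r0, k):
    """Harmonic bond energy 1/2 k (r - r0)^2, kJ/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    out = 0.5 * k * (r - r0) ** 2
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# whole-system evaluation
# ---------------------------------------------------------------------------

def build_pair_list(
    positions: np.ndarray, box: float, rlist: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Candidate (i<j) pairs within rlist under periodic minimum image.

    Uses a periodic KD-tree when the box can accommodate it, otherwise a
    brute-force scan (small or tightly cut systems).
    """
    if rlist < box / 2.0:
        wrapped = np.mod(positions, box)
        # guard against coordinates landing exactly on the box edge
        wrapped[wrapped >= box] = 0.0
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(rlist, output_type="ndarray")
        if pairs.size == 0:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        return (
            np.ascontiguousarray(pairs[:, 0].astype(np.int64)),
            np.ascontiguousarray(pairs[:, 1].astype(np.int64)),
        )
    return _kernels.all_pairs_within(np.ascontiguousarray(positions), box, rlist)


def _evaluate(
    positions: np.ndarray,
    box: float,
    topo: SystemTopology,
    params: InteractionParams,
    pair_list: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[np.ndarray, Dict[str, float], int]:
    positions = np.ascontiguousarray(positions, dtype=float)
    if pair_list is None:
        pair_list = build_pair_list(positions, box, params.rc_dh)
    pi, pj = pair_list
    out_forces = np.zeros_like(positions)
    e_bond = _kernels.bond_forces(
        positions, box, topo.bond_i, topo.bond_j, topo.bond_r0, topo.bond_k, out_forces
    )
    e_ah, e_dh, n_overlap = _kernels.pair_forces(
        positions,
        box,
        pi,
        pj,
        topo.sigma,
        topo.lam,
        topo.charge,
        topo.bonded_next,
        params.eps_ah,
        params.rc_ah,
        params.rc_dh,
        params.kappa,
        COULOMB / params.eps_r,
        OVERLAP_FLOOR,
        out_forces,
    )
    energies = {
        "bond": float(e_bond),
        "ah": float(e_ah),
        "dh": float(e_dh),
        "total": float(e_bond + e_ah + e_dh),
    }
    return out_forces, energies, int(n_overlap)


def total_energy(
    positions: np.ndarray,
    box: float,
    topo: SystemTopology,
    params: InteractionParams,
) -> Dict[str, float]:
    """Energy decomposition {bond, ah, dh, total} in kJ/mol.

    Overlapping beads (closer than the overlap floor) are reported through an
    ``n_overlaps`` entry and a warning, never a crash.
    """
    _, energies, n_overlap = _evaluate(positions, box, topo, params)
    energies["n_overlaps"] = n_overlap
    if n_overlap:
        warnings.warn(
            f"{n_overlap} bead pair(s) below the overlap floor", OverlapWarning,
            stacklevel=2,
        )
    if not np.isfinite(energies["total"]):
        raise FloatingPointError("non-finite total energy")
    return energies


def forces(
    positions: np.ndarray,
    box: float,
    topo: SystemTopology,
    params: InteractionParams,
) -> np.ndarray:
    """Per-bead forces -grad U, kJ mol^-1 nm^-1 (net force sums to zero)."""
    out, _, _ = _evaluate(positions, box, topo, params)
    return out
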