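"""Sequence grammar, bead parameterization, and closed-form physical quantities.

The designed proteins are two-domain low-complexity chains written in the
AmBn grammar: ``Am`` is Domain H (m residues of a single high-RNA-affinity
amino acid, typically arginine) and ``Bn`` is Domain L (n repeats of a short
low-affinity motif such as N3G2 = "NNNGG").  RNA is poly-U, one bead per
nucleotide, with its length usually matched to the Domain H length.

Beads carry the CALVADOS 2 single-bead parameters (diameter sigma,
hydrophobicity lambda, charge, mass), shipped as a plain-text table under
``condgram/data`` and overridable at load time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import (
    DA_TO_MG,
    E_CHARGE,
    EPS0_SI,
    KB_SI,
    N_AVOGADRO,
    NM3_TO_ML,
)

__all__ = [
    "BeadType",
    "ParameterTable",
    "SequenceSpec",
    "ChainTopology",
    "SystemTopology",
    "SystemComposition",
    "ParameterizationError",
    "build_protein_sequence",
    "build_protein",
    "build_rna",
    "parameterize",
    "dielectric",
    "debye_kappa",
    "system_density",
    "build_system",
]

#: harmonic bond force constant, kJ mol^-1 nm^-2
K_BOND = 1000.0
#: equilibrium bond length for peptide beads, nm
R0_PROTEIN = 0.38
#: equilibrium bond length for RNA beads, nm
R0_RNA = 0.5


class ParameterizationError(KeyError):
    """A residue or nucleotide code is missing from the parameter table."""


@dataclass(frozen=True)
class BeadType:
    """Per-residue/nucleotide interaction parameters of one bead type."""

    name: str
    sigma: float  # bead diameter, nm
    lam: float  # hydrophobicity, dimensionless
    charge: float  # elementary charges
    mass: float  # Da
    species: str  # "protein" or "rna"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"bead {self.name}: sigma must be > 0")
        if self.mass <= 0:
            raise ValueError(f"bead {self.name}: mass must be > 0")
        if self.species not in ("protein", "rna"):
            raise ValueError(f"bead {self.name}: unknown species {self.species!r}")


class ParameterTable:
    """Lookup of :class:`BeadType` by residue code, loadable from TSV."""

    def __init__(self, beads: Dict[str, BeadType]):
        self._beads = dict(beads)

    def __getitem__(self, code: str) -> BeadType:
        try:
            return self._beads[code]
        except KeyError:
            raise ParameterizationError(
                f"residue code {code!r} not in parameter table "
                f"(known: {''.join(sorted(self._beads))})"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self._beads

    def __iter__(self):
        return iter(self._beads.values())

    @classmethod
    def from_tsv(cls, path_or_lines) -> "ParameterTable":
        if isinstance(path_or_lines, (str,)):
            with open(path_or_lines) as fh:
                lines = fh.readlines()
        else:
            lines = list(path_or_lines)
        beads: Dict[str, BeadType] = {}
        header: Optional[List[str]] = None
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                continue
            row = dict(zip(header, cols))
            beads[row["name"]] = BeadType(
                name=row["name"],
                sigma=float(row["sigma"]),
                lam=float(row["lam"]),
                charge=float(row["charge"]),
                mass=float(row["mass"]),
                species=row["species"],
            )
        if not beads:
            raise ValueError("parameter table is empty")
        return cls(beads)

    @classmethod
    def default(cls) -> "ParameterTable":
        """The embedded CALVADOS 2 table (20 amino acids + the U bead)."""
        text = resources.files("condgram.data").joinpath("calvados2.tsv").read_text()
        return cls.from_tsv(text.splitlines())

    def override(self, code: str, **changes) -> "ParameterTable":
        """Return a copy of the table with one bead's fields replaced."""
        base = self[code]
        updated = {f: changes.get(f, getattr(base, f)) for f in
                   ("name", "sigma", "lam", "charge", "mass", "species")}
        beads = dict(self._beads)
        beads[code] = BeadType(**updated)
        return ParameterTable(beads)


# ---------------------------------------------------------------------------
# sequence grammar
# ---------------------------------------------------------------------------

_MOTIF_TOKEN = re.compile(r"([A-Z])(\d*)")
_GRAMMAR_TOKEN = re.compile(r"(?:\(([A-Z0-9]+)\)|([A-Z]))(\d+)")


def expand_motif(motif: str) -> str:
    """Expand compact motif notation, e.g. ``"N3G2"`` -> ``"NNNGG"``.

    Plain strings of residue letters pass through unchanged (``"KD"`` -> ``"KD"``).
    """
    if not motif:
        return ""
    out = []
    pos = 0
    for match in _MOTIF_TOKEN.finditer(motif):
        if match.start() != pos:
            raise ValueError(f"cannot parse motif {motif!r}")
        letter, count = match.groups()
        out.append(letter * (int(count) if count else 1))
        pos = match.end()
    if pos != len(motif):
        raise ValueError(f"cannot parse motif {motif!r}")
    return "".join(out)


@dataclass(frozen=True)
class SequenceSpec:
    """A two-domain protein in the AmBn grammar.

    Domain H is ``motif_H`` (a single residue letter) repeated ``m`` times;
    Domain L is the expanded ``motif_L`` repeated ``n`` times.
    ``rna_length`` of None means "match the RNA to Domain H" (length m).
    """

    motif_H: str
    m: int
    motif_L: str = ""
    n: int = 0
    rna_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.m < 0 or self.n < 0:
            raise ValueError("repeat counts must be >= 0")
        if len(self.motif_H) > 1:
            raise ValueError("Domain H is a single residue letter")

    @property
    def motif_L_expanded(self) -> str:
        return expand_motif(self.motif_L)

    @property
    def length(self) -> int:
        return self.m + self.n * len(self.motif_L_expanded)

    @property
    def matched_rna_length(self) -> int:
        """RNA length in length-matched mode: the Domain H length."""
        return self.m if self.rna_length is None else self.rna_length

    @classmethod
    def from_grammar(cls, text: str, rna_length: Optional[int] = None) -> "SequenceSpec":
        """Parse grammar strings like ``"R150(N3G2)10"``, ``"R150K50"``, ``"R150(KD)25"``.

        The first token is Domain H; the (optional) second token is Domain L.
        """
        text = text.strip()
        tokens: List[Tuple[str, int]] = []
        pos = 0
        for match in _GRAMMAR_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse grammar {text!r}")
            group, letter, count = match.groups()
            tokens.append((group if group is not None else letter, int(count)))
            pos = match.end()
        if pos != len(text) or not tokens:
            raise ValueError(f"cannot parse grammar {text!r}")
        if len(tokens) > 2:
            raise ValueError(
                f"grammar {text!r} has more than two domains; AmBn expects H then L"
            )
        motif_h, m = tokens[0]
        if len(motif_h) != 1:
            raise ValueError(f"Domain H motif {motif_h!r} must be a single residue")
        if len(tokens) == 2:
            motif_l, n = tokens[1]
        else:
            motif_l, n = "", 0
        return cls(motif_H=motif_h, m=m, motif_L=motif_l, n=n, rna_length=rna_length)

    def grammar(self) -> str:
        if self.n == 0:
            return f"{self.motif_H}{self.m}"
        motif = self.motif_L if len(self.motif_L) == 1 else f"({self.motif_L})"
        return f"{self.motif_H}{self.m}{motif}{self.n}"


def build_protein_sequence(spec: SequenceSpec) -> Tuple[str, List[str]]:
    """Return (residue string, per-residue domain labels) for a grammar spec.

    Domain H first (labels "H"), then Domain L (labels "L"); the total length
    is m + n * len(motif_L).
    """
    seq = spec.motif_H * spec.m + spec.motif_L_expanded * spec.n
    labels = ["H"] * spec.m + ["L"] * (spec.n * len(spec.motif_L_expanded))
    return seq, labels


# ---------------------------------------------------------------------------
# chain topology
# ---------------------------------------------------------------------------

@dataclass
class ChainTopology:
    """One linear chain: ordered beads, consecutive harmonic bonds, domain labels."""

    beads: List[BeadType]
    bonds: List[Tuple[int, int, float, float]]  # (i, j, r0 nm, k kJ/mol/nm^2)
    domain_labels: List[str]  # per bead, in {"H", "L", "RNA"}

    def __post_init__(self) -> None:
        for idx, (i, j, r0, k) in enumerate(self.bonds):
            if j != i + 1:
                raise ValueError("bonds must connect consecutive beads (linear chain)")
            if r0 <= 0 or k <= 0:
                raise ValueError("bond r0 and k must be positive")
        if len(self.domain_labels) != len(self.beads):
            raise ValueError("one domain label per bead required")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def sequence(self) -> str:
        return "".join(b.name for b in self.beads)

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(b, attr) for b in self.beads], dtype=float)


def parameterize(
    sequence: str,
    labels: Optional[Sequence[str]] = None,
    table: Optional[ParameterTable] = None,
    r0: float = R0_PROTEIN,
    kbond: float = K_BOND,
) -> ChainTopology:
    """Assign sigma/lambda/charge/mass to every residue of a linear chain.

    Pair combination (arithmetic means of sigma and lambda) is deferred to the
    force field; this only resolves per-bead parameters.
    """
    table = table or ParameterTable.default()
    beads = [table[code] for code in sequence]
    if labels is None:
        labels = ["H"] * len(beads)
    bonds = [(i, i + 1, r0, kbond) for i in range(len(beads) - 1)]
    return ChainTopology(beads=beads, bonds=bonds, domain_labels=list(labels))


def build_protein(spec: SequenceSpec, table: Optional[ParameterTable] = None) -> ChainTopology:
    seq, labels = build_protein_sequence(spec)
    return parameterize(seq, labels, table, r0=R0_PROTEIN)


def build_rna(length: int, table: Optional[ParameterTable] = None) -> ChainTopology:
    """Poly-U chain of identical RNA beads with r0 = 0.5 nm bonds."""
    if length < 1:
        raise ValueError("RNA length must be >= 1")
    return parameterize("U" * length, ["RNA"] * length, table, r0=R0_RNA)


# ---------------------------------------------------------------------------
# whole systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemComposition:
    """Chain counts, box, temperature and ionic strength: one simulation unit."""

    protein_spec: SequenceSpec
    n_protein_chains: int
    n_rna_chains: int
    box_edge: float  # nm
    temperature: float = 300.0  # K
    ionic_strength: float = 0.1  # mol/L

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box_edge must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be >= 0")
        if self.n_protein_chains < 0 or self.n_rna_chains < 0:
            raise ValueError("chain counts must be >= 0")


@dataclass
class SystemTopology:
    """Flattened multi-chain topology: per-bead arrays plus chain bookkeeping.

    ``bonded_next[i]`` is True when bead i is bonded to bead i+1, which
    together with linear chains fully encodes the 1-2 exclusion set.
    """

    names: List[str]
    sigma: np.ndarray
    lam: np.ndarray
    charge: np.ndarray
    mass: np.ndarray
    domain_labels: np.ndarray  # per-bead, str array in {"H","L","RNA"}
    chain_id: np.ndarray  # per-bead int
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    species: np.ndarray  # per-bead, "protein" or "rna"

    @property
    def n_beads(self) -> int:
        return int(self.sigma.shape[0])

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_beads else 0

    @property
    def bonded_next(self) -> np.ndarray:
        mask = np.zeros(self.n_beads, dtype=bool)
        mask[self.bond_i[self.bond_j == self.bond_i + 1]] = True
        return mask

    def group_indices(self) -> Dict[str, np.ndarray]:
        """Standard analysis selections: DomainH, DomainL, RNA, H+RNA, all."""
        lab = self.domain_labels
        groups = {
            "DomainH": np.flatnonzero(lab == "H"),
            "DomainL": np.flatnonzero(lab == "L"),
            "RNA": np.flatnonzero(lab == "RNA"),
        }
        groups["H+RNA"] = np.concatenate([groups["DomainH"], groups["RNA"]])
        groups["all"] = np.arange(self.n_beads)
        return groups


def concatenate_chains(chains: Sequence[ChainTopology]) -> SystemTopology:
    names: List[str] = []
    sigma, lam, charge, mass, labels, chain_id, species = [], [], [], [], [], [], []
    bi, bj, br0, bk = [], [], [], []
    offset = 0
    for cid, chain in enumerate(chains):
        for b in chain.beads:
            names.append(b.name)
            sigma.append(b.sigma)
            lam.append(b.lam)
            charge.append(b.charge)
            mass.append(b.mass)
            species.append(b.species)
        labels.extend(chain.domain_labels)
        chain_id.extend([cid] * chain.n_beads)
        for (i, j, r0, k) in chain.bonds:
            bi.append(i + offset)
            bj.append(j + offset)
            br0.append(r0)
            bk.append(k)
        offset += chain.n_beads
    return SystemTopology(
        names=names,
        sigma=np.asarray(sigma, dtype=float),
        lam=np.asarray(lam, dtype=float),
        charge=np.asarray(charge, dtype=float),
        mass=np.asarray(mass, dtype=float),
        domain_labels=np.asarray(labels, dtype=object),
        chain_id=np.asarray(chain_id, dtype=np.int64),
        bond_i=np.asarray(bi, dtype=np.int64),
        bond_j=np.asarray(bj, dtype=np.int64),
        bond_r0=np.asarray(br0, dtype=float),
        bond_k=np.asarray(bk, dtype=float),
        species=np.asarray(species, dtype=object),
    )


def build_system(comp: SystemComposition, table: Optional[ParameterTable] = None) -> SystemTopology:
    """All protein chains first, then all RNA chains, flattened."""
    table = table or ParameterTable.default()
    protein = build_protein(comp.protein_spec, table)
    chains: List[ChainTopology] = [protein] * comp.n_protein_chains
    if comp.n_rna_chains:
        rna = build_rna(comp.protein_spec.matched_rna_length, table)
        chains = chains + [rna] * comp.n_rna_chains
    return concatenate_chains(chains)


# ---------------------------------------------------------------------------
# closed-form physics
# ---------------------------------------------------------------------------

def dielectric(temperature: float) -> float:
    """Relative permittivity of water from the empirical polynomial.

    eps_r(T) = 5321/T + 233.76 - 0.9297 T + 1.417e-3 T^2 - 8.292e-7 T^3,
    the standard empirical water-permittivity form (eps_r(298.15 K) = 78.4).
    """
    T = float(temperature)
    if not (250.0 <= T <= 400.0):
        raise ValueError("temperature outside the fitted range 250-400 K")
    return 5321.0 / T + 233.76 - 0.9297 * T + 1.417e-3 * T**2 - 8.292e-7 * T**3


def debye_kappa(ionic_strength: float, temperature: float = 300.0) -> float:
    """Inverse Debye screening length kappa in nm^-1.

    kappa = sqrt(2 e^2 N_A I / (eps0 eps_r(T) kB T)) with I in mol/L.
    At I = 0.1 mol/L and T = 300 K the screening length 1/kappa is 0.96 nm.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return 0.0
    i_si = ionic_strength * 1000.0  # mol/m^3
    eps_r = dielectric(temperature)
    kappa_sq = (
        2.0 * E_CHARGE**2 * N_AVOGADRO * i_si
        / (EPS0_SI * eps_r * KB_SI * temperature)
    )
    return math.sqrt(kappa_sq) * 1e-9  # m^-1 -> nm^-1


def system_density(comp: SystemComposition, table: Optional[ParameterTable] = None) -> float:
    """Total mass concentration of a composition in mg/mL.

    Uses the parameter table's standard average residue/nucleotide masses and
    no terminal-group adjustments, so the number is reproducible bit-for-bit
    from the shipped table.
    """
    table = table or ParameterTable.default()
    seq, _ = build_protein_sequence(comp.protein_spec)
    protein_mass = sum(table[c].mass for c in seq)
    rna_mass = table["U"].mass * comp.protein_spec.matched_rna_length
    total_da = (
        comp.n_protein_chains * protein_mass + comp.n_rna_chains * rna_mass
    )
    volume_ml = comp.box_edge**3 * NM3_TO_ML
    return total_da * DA_TO_MG / volume_ml
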