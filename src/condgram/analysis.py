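"""Condensate-morphology statistics.

Everything the architecture calls rest on: single-linkage clustering under
periodic boundaries, cluster-size/radius-of-gyration time series,
center-of-mass (COM) centered radial distribution functions g(r) per bead
group, the potential of mean force PMF(r) = -kB T ln g(r), its
probability-weighted mean <PMF> = sum PMF g dr / sum g dr, contact numbers
within 11 A of each protein bead, and a rule-based classifier that turns
these profiles into one of the discrete architecture labels
(no_condensate, micelles, partial_vesicle, vesicle, multilayer, biphasic,
homogeneous).

COM-centered RDFs are shell-volume normalized against each group's global
mean number density, so a uniformly filled region gives a flat profile at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .constants import KB

__all__ = [
    "ClusterMetrics",
    "RadialProfile",
    "PMFProfile",
    "ContactProfile",
    "MorphologyLabel",
    "ClassifierThresholds",
    "find_clusters",
    "cluster_metrics",
    "condensate_com",
    "rdf_about_com",
    "rdf_between_groups",
    "pmf_from_rdf",
    "weighted_mean_pmf",
    "contact_numbers",
    "shell_coverage",
    "classify_morphology",
    "classify_configuration",
]

CONTACT_CUTOFF = 1.1  # nm (11 A)


def _pairs_within(positions: np.ndarray, box: float, cutoff: float) -> np.ndarray:
    """(i<j) index pairs with minimum-image distance <= cutoff."""
    positions = np.asarray(positions, dtype=float)
    if cutoff < box / 2.0:
        wrapped = np.mod(positions, box)
        wrapped[wrapped >= box] = 0.0
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        return pairs.reshape(-1, 2)
    n = positions.shape[0]
    d = positions[:, None, :] - positions[None, :, :]
    d -= box * np.round(d / box)
    dist = np.sqrt((d**2).sum(axis=-1))
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    return np.stack([ii, jj], axis=1)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def find_clusters(
    positions: np.ndarray,
    box: float,
    cutoff: float,
    chain_id: Optional[np.ndarray] = None,
    level: str = "bead",
) -> np.ndarray:
    """Single-linkage connected components over bead distances <= cutoff.

    ``level="bead"`` labels every bead; ``level="chain"`` merges clusters
    sharing a chain and returns one label per chain.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = positions.shape[0]
    pairs = _pairs_within(positions, box, cutoff)
    if level == "bead":
        graph = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(graph, directed=False)
        return labels
    if level != "chain":
        raise ValueError("level must be 'bead' or 'chain'")
    if chain_id is None:
        raise ValueError("chain-level clustering needs chain_id")
    n_chains = int(chain_id.max()) + 1
    ci = chain_id[pairs[:, 0]]
    cj = chain_id[pairs[:, 1]]
    mask = ci != cj
    graph = sparse.coo_matrix(
        (np.ones(mask.sum()), (ci[mask], cj[mask])), shape=(n_chains, n_chains)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


@dataclass
class ClusterMetrics:
    """Per-frame cluster statistics (chain- or bead-level sizes)."""

    times: np.ndarray
    n_clusters: np.ndarray
    largest_size: np.ndarray
    largest_rg: np.ndarray  # nm, mass-weighted
    level: str = "chain"


def condensate_com(
    positions: np.ndarray,
    box: float,
    masses: Optional[np.ndarray] = None,
    members: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mass-weighted center of mass, safe across the periodic boundary.

    Each coordinate is mapped to an angle on a circle of circumference
    ``box``; the COM is the angle of the mass-weighted mean phasor, so a
    condensate straddling the boundary gets its physical center.
    """
    pos = np.asarray(positions, dtype=float)
    if members is not None:
        pos = pos[members]
    if pos.shape[0] == 0:
        raise ValueError("empty selection")
    if masses is None:
        m = np.ones(pos.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if members is not None and m.shape[0] != pos.shape[0]:
            m = m[members]
    theta = 2.0 * np.pi * pos / box
    xi = (m[:, None] * np.cos(theta)).sum(axis=0)
    zeta = (m[:, None] * np.sin(theta)).sum(axis=0)
    return np.mod(np.arctan2(zeta, xi) * box / (2.0 * np.pi), box)


def _radius_of_gyration(positions, box, masses):
    com = condensate_com(positions, box, masses)
    d = positions - com
    d -= box * np.round(d / box)
    m = masses / masses.sum()
    return float(np.sqrt((m[:, None] * d**2).sum()))


def cluster_metrics(
    traj,
    box: float,
    cutoff: float = CONTACT_CUTOFF,
    chain_id: Optional[np.ndarray] = None,
    masses: Optional[np.ndarray] = None,
    level: str = "chain",
) -> ClusterMetrics:
    """Time series of cluster count, largest size, and largest-cluster Rg.

    ``traj`` may be a Trajectory or a list of (N,3) frames with times.
    """
    if hasattr(traj, "frames"):
        frames = [f.positions for f in traj.frames]
        times = np.asarray(traj.times)
        box = traj.frames[0].box_edge
    else:
        frames = list(traj)
        times = np.arange(len(frames), dtype=float)
    n_cl, largest, rgs = [], [], []
    for pos in frames:
        n = pos.shape[0]
        if masses is None:
            masses_arr = np.ones(n)
        else:
            masses_arr = masses
        labels = find_clusters(pos, box, cutoff, chain_id=chain_id, level=level)
        counts = np.bincount(labels)
        n_cl.append(len(counts))
        big = int(np.argmax(counts))
        largest.append(int(counts[big]))
        if level == "chain":
            members = np.flatnonzero(np.isin(chain_id, np.flatnonzero(labels == big)))
        else:
            members = np.flatnonzero(labels == big)
        rgs.append(_radius_of_gyration(pos[members], box, masses_arr[members]))
    return ClusterMetrics(
        times=times,
        n_clusters=np.asarray(n_cl),
        largest_size=np.asarray(largest),
        largest_rg=np.asarray(rgs),
        level=level,
    )


def largest_cluster_members(
    positions: np.ndarray,
    box: float,
    cutoff: float = CONTACT_CUTOFF,
    chain_id: Optional[np.ndarray] = None,
    level: str = "chain",
) -> np.ndarray:
    labels = find_clusters(positions, box, cutoff, chain_id=chain_id, level=level)
    counts = np.bincount(labels)
    big = int(np.argmax(counts))
    if level == "chain":
        return np.flatnonzero(np.isin(chain_id, np.flatnonzero(labels == big)))
    return np.flatnonzero(labels == big)


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

@dataclass
class RadialProfile:
    """COM-centered g(r) per selection group on uniform bins."""

    bin_centers: np.ndarray
    g: Dict[str, np.ndarray]
    counts: Dict[str, np.ndarray] = field(default_factory=dict)
    n_frames: int = 1

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


def rdf_about_com(
    traj,
    groups: Dict[str, np.ndarray],
    bins: np.ndarray,
    box: Optional[float] = None,
    masses: Optional[np.ndarray] = None,
    com_members: Optional[np.ndarray] = None,
    com_override: Optional[np.ndarray] = None,
) -> RadialProfile:
    """Shell-volume-normalized radial density about the condensate COM.

    For each frame the COM of ``com_members`` (default: all beads) is found
    PBC-safely; distances of every group's beads to it are histogrammed on
    ``bins`` and normalized by shell volume and the group's global mean
    number density, then averaged over frames.  A uniformly filled region
    therefore tends to a flat profile at 1.
    """
    if hasattr(traj, "frames"):
        frames = [f.positions for f in traj.frames]
        box = traj.frames[0].box_edge
    elif isinstance(traj, np.ndarray) and traj.ndim == 2:
        frames = [traj]
    else:
        frames = list(traj)
    if box is None:
        raise ValueError("box required when traj is an array")
    bins = np.asarray(bins, dtype=float)
    widths = np.diff(bins)
    if not np.allclose(widths, widths[0]):
        raise ValueError("bin widths must be uniform")
    shell_vol = 4.0 / 3.0 * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
    volume = box**3
    centers = 0.5 * (bins[:-1] + bins[1:])
    g = {name: np.zeros(len(centers)) for name in groups}
    counts = {name: np.zeros(len(centers)) for name in groups}
    for pos in frames:
        com = (
            com_override
            if com_override is not None
            else condensate_com(pos, box, masses, com_members)
        )
        d = pos - com
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(axis=1))
        for name, idx in groups.items():
            if len(idx) == 0:
                warnings.warn(f"empty group {name!r}; zero profile", stacklevel=2)
                continue
            hist, _ = np.histogram(r[idx], bins=bins)
            counts[name] += hist
            rho_mean = len(idx) / volume
            g[name] += hist / shell_vol / rho_mean
    for name in groups:
        g[name] /= len(frames)
    return RadialProfile(bin_centers=centers, g=g, counts=counts, n_frames=len(frames))


def rdf_between_groups(
    traj,
    group_a: np.ndarray,
    group_b: np.ndarray,
    bins: np.ndarray,
    box: Optional[float] = None,
) -> RadialProfile:
    """Species-pair radial distribution function g_ab(r) under minimum image.

    Standard pair-correlation normalization: counts of a-b pairs in a shell
    divided by the ideal-gas expectation N_a * rho_b * V_shell (frame
    averaged).  This is the profile behind the effective interaction
    strength between two bead species (e.g. Domain H vs RNA): an
    uncorrelated mixture gives g = 1, attraction g > 1 at contact,
    depletion g < 1.
    """
    if hasattr(traj, "frames"):
        frames = [f.positions for f in traj.frames]
        box = traj.frames[0].box_edge
    elif isinstance(traj, np.ndarray) and traj.ndim == 2:
        frames = [traj]
    else:
        frames = list(traj)
    if box is None:
        raise ValueError("box required when traj is an array")
    bins = np.asarray(bins, dtype=float)
    if bins[-1] > box / 2.0:
        raise ValueError("bins must stay within half the box edge")
    shell_vol = 4.0 / 3.0 * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
    centers = 0.5 * (bins[:-1] + bins[1:])
    counts = np.zeros(len(centers))
    set_b = np.zeros(0)
    in_a = np.zeros(0, dtype=bool)
    for pos in frames:
        n = pos.shape[0]
        if set_b.shape[0] != n:
            in_a = np.zeros(n, dtype=bool)
            in_a[group_a] = True
            in_b = np.zeros(n, dtype=bool)
            in_b[group_b] = True
            set_b = in_b
        pairs = _pairs_within(pos, box, bins[-1])
        if len(pairs):
            cross = (in_a[pairs[:, 0]] & set_b[pairs[:, 1]]) | (
                in_a[pairs[:, 1]] & set_b[pairs[:, 0]]
            )
            pairs = pairs[cross]
        if len(pairs):
            d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            d -= box * np.round(d / box)
            r = np.sqrt((d**2).sum(axis=1))
            hist, _ = np.histogram(r, bins=bins)
            counts += hist
    rho_b = len(group_b) / box**3
    expected = len(group_a) * rho_b * shell_vol * len(frames)
    g = counts / expected
    return RadialProfile(
        bin_centers=centers, g={"pair": g}, counts={"pair": counts},
        n_frames=len(frames),
    )


@dataclass
class PMFProfile:
    """PMF(r) = -kB T ln g(r) on bins where g > 0 (others masked)."""

    bin_centers: np.ndarray
    pmf: np.ndarray  # kJ/mol, NaN on masked bins
    valid: np.ndarray  # bool mask, True where g > 0
    weighted_mean: float  # kJ/mol


def pmf_from_rdf(profile: RadialProfile, temperature: float, group: str = "all") -> PMFProfile:
    """Potential of mean force from one group's radial profile.

    Bins with g = 0 are masked (NaN); they carry zero weight in the
    probability-weighted mean, which is computed here as well.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    g = profile.g[group]
    if not np.any(g > 0):
        raise ValueError("all-zero profile; nothing to take a PMF of")
    valid = g > 0
    pmf = np.full_like(g, np.nan)
    pmf[valid] = -KB * temperature * np.log(g[valid])
    wmean = float(np.sum(pmf[valid] * g[valid]) / np.sum(g[valid]))
    return PMFProfile(
        bin_centers=profile.bin_centers, pmf=pmf, valid=valid, weighted_mean=wmean
    )


def weighted_mean_pmf(pmf_profile: PMFProfile, profile: RadialProfile, group: str = "all") -> float:
    """<PMF> = sum PMF(r) g(r) dr / sum g(r) dr over valid bins.

    With uniform bins the dr factors cancel; zero-weight (g = 0) bins are
    excluded.  The result is invariant to uniform rescaling of g.
    """
    g = profile.g[group]
    if not np.array_equal(profile.bin_centers, pmf_profile.bin_centers):
        raise ValueError("profiles must share bins")
    valid = pmf_profile.valid
    total = np.sum(g[valid])
    if total <= 0:
        raise ValueError("zero total weight")
    return float(np.sum(pmf_profile.pmf[valid] * g[valid]) / total)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactProfile:
    """Mean neighbor counts within the contact cutoff around protein beads."""

    mean_protein_neighbors: float
    mean_rna_neighbors: float
    by_domain: Dict[str, Dict[str, float]]  # {"H": {"protein":..,"rna":..}, "L": ...}


def contact_numbers(
    positions_or_traj,
    topo,
    cutoff: float = CONTACT_CUTOFF,
    box: Optional[float] = None,
    exclude_bonded: bool = True,
) -> ContactProfile:
    """Average RNA and protein neighbors within ``cutoff`` of each protein bead.

    Averages over all protein beads (and frames, if a trajectory is given),
    and resolves the same counts by H/L domain label.  A bead is never its
    own neighbor; directly bonded neighbors are excluded by default.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if hasattr(positions_or_traj, "frames"):
        frames = [f.positions for f in positions_or_traj.frames]
        box = positions_or_traj.frames[0].box_edge
    else:
        frames = [np.asarray(positions_or_traj, dtype=float)]
    if box is None:
        raise ValueError("box required for a bare positions array")
    is_protein = topo.species == "protein"
    is_rna = ~is_protein
    labels = topo.domain_labels
    n = topo.n_beads
    prot_count = np.zeros(n)
    rna_count = np.zeros(n)
    bonded_next = topo.bonded_next
    for pos in frames:
        pairs = _pairs_within(pos, box, cutoff)
        if exclude_bonded and len(pairs):
            keep = ~((pairs[:, 1] == pairs[:, 0] + 1) & bonded_next[pairs[:, 0]])
            pairs = pairs[keep]
        for a, b in ((0, 1), (1, 0)):
            i = pairs[:, a]
            j = pairs[:, b]
            np.add.at(prot_count, i, is_protein[j].astype(float))
            np.add.at(rna_count, i, is_rna[j].astype(float))
    nf = len(frames)
    prot_count /= nf
    rna_count /= nf
    by_domain = {}
    for dom in ("H", "L"):
        sel = is_protein & (labels == dom)
        if sel.any():
            by_domain[dom] = {
                "protein": float(prot_count[sel].mean()),
                "rna": float(rna_count[sel].mean()),
            }
        else:
            by_domain[dom] = {"protein": 0.0, "rna": 0.0}
    if is_protein.any():
        mp = float(prot_count[is_protein].mean())
        mr = float(rna_count[is_protein].mean())
    else:
        mp = mr = 0.0
    return ContactProfile(
        mean_protein_neighbors=mp, mean_rna_neighbors=mr, by_domain=by_domain
    )


# ---------------------------------------------------------------------------
# morphology classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierThresholds:
    """Invented, documented decision thresholds; live in config, not code."""

    theta_hollow: float = 0.2  # central density below this fraction of peak = hollow
    flat_tol: float = 0.15  # relative fluctuation for "flat" profiles
    coverage_min: float = 0.85  # angular shell coverage for a closed vesicle
    micelle_min_clusters: int = 4
    micelle_size_ratio: float = 3.0  # max/median multi-chain cluster size
    core_frac: float = 0.25  # central region = this fraction of condensate radius
    peak_contrast: float = 2.0  # peak density vs the valley separating it from the HR shell
    min_peak_counts: int = 30  # aggregated counts for a peak window to matter


@dataclass
class MorphologyLabel:
    label: str
    evidence: Dict[str, object] = field(default_factory=dict)


def shell_coverage(
    positions: np.ndarray,
    box: float,
    com: np.ndarray,
    r_lo: float,
    r_hi: float,
    n_patches: int = 192,
) -> float:
    """Fraction of solid angle covered by beads in a radial band.

    Directions of beads with r in [r_lo, r_hi] from the COM are assigned to
    the nearest of ``n_patches`` Fibonacci-sphere patch centers; coverage is
    the occupied-patch fraction.  A closed shell scores ~1, a hemispherical
    cap ~0.5.
    """
    d = positions - com
    d -= box * np.round(d / box)
    r = np.sqrt((d**2).sum(axis=1))
    sel = (r >= r_lo) & (r <= r_hi)
    if not sel.any():
        return 0.0
    dirs = d[sel] / r[sel, None]
    k = np.arange(n_patches)
    golden = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - 2.0 * (k + 0.5) / n_patches
    phi = 2.0 * np.pi * k / golden
    rho = np.sqrt(1.0 - z**2)
    patches = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    nearest = np.argmax(dirs @ patches.T, axis=1)
    return len(np.unique(nearest)) / n_patches


def _smoothed_density(counts: np.ndarray, shell_vol: np.ndarray) -> np.ndarray:
    """Count-weighted 3-bin moving-average radial number density.

    Aggregating counts and volumes before dividing keeps the estimate stable
    in small central shells where per-bin statistics are Poisson-sparse.
    """
    kernel = np.ones(3)
    c = np.convolve(counts, kernel, mode="same")
    v = np.convolve(shell_vol, kernel, mode="same")
    return c / v


def _profile_features(profile: RadialProfile, thresholds: ClassifierThresholds):
    """Condensate radius, hollowness, flatness, and Domain L peak layout.

    All decisions are made on aggregated bin counts rather than raw g values
    so that sparse central bins cannot fire rules through Poisson noise.
    """
    r = profile.bin_centers
    dw = profile.bin_width
    edges = np.concatenate([r - dw / 2.0, [r[-1] + dw / 2.0]])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    counts = {k: np.asarray(v, dtype=float) for k, v in profile.counts.items()}
    feats: Dict[str, object] = {}

    rho_all = _smoothed_density(counts["all"], shell_vol)
    peak = float(np.max(rho_all))
    r_peak_all = float(r[np.argmax(rho_all)])
    # outermost radius still carrying appreciable density; the floor is low
    # so that dilute outer shells around a dense core still count as part
    # of the condensate
    occupied = np.flatnonzero(rho_all > 0.05 * peak)
    r_cond = float(r[occupied[-1]]) if len(occupied) else float(r[-1])
    feats["r_condensate"] = r_cond
    feats["r_peak_all"] = r_peak_all

    core = r < max(thresholds.core_frac * r_cond, 1.5 * dw)
    core_counts = counts["all"][core].sum()
    core_vol = shell_vol[core].sum()
    feats["core_density_ratio"] = float((core_counts / core_vol) / peak)

    # flatness: observed counts vs a uniform fill of the occupied sphere,
    # judged only on bins with enough expectation to be informative
    inside = r <= r_cond
    flat = True
    for name in ("all", "DomainL", "H+RNA"):
        c = counts.get(name)
        if c is None:
            continue
        n_inside = c[inside].sum()
        if n_inside == 0:
            continue
        expected = n_inside * shell_vol[inside] / shell_vol[inside].sum()
        usable = expected >= 10.0
        if not usable.any():
            continue
        rel = np.abs(c[inside][usable] - expected[usable]) / expected[usable]
        slack = thresholds.flat_tol + 3.0 / np.sqrt(expected[usable])
        if np.any(rel > slack):
            flat = False
    feats["flat"] = flat

    # Domain H-RNA main shell and Domain L layout relative to it
    if "H+RNA" in counts and counts["H+RNA"].sum() > 0:
        rho_hr = _smoothed_density(counts["H+RNA"], shell_vol)
        r_hr_peak = float(r[np.argmax(rho_hr)])
    else:
        r_hr_peak = np.nan
    feats["r_hr_peak"] = r_hr_peak
    feats["l_inner_peak"] = feats["l_outer_peak"] = False
    if "DomainL" in counts and counts["DomainL"].sum() > 0 and np.isfinite(r_hr_peak):
        rho_l = _smoothed_density(counts["DomainL"], shell_vol)
        inner = r < 0.8 * max(r_hr_peak, 2.0 * dw)
        outer = r > 1.2 * r_hr_peak
        for side, window in (("inner", inner), ("outer", outer)):
            if not window.any():
                continue
            best = int(np.argmax(rho_l[window]))
            r_peak = float(r[window][best])
            rho_peak = float(rho_l[window][best])
            # a Domain L layer must be separated from the H-RNA shell by a
            # genuine dip, not be the flank of one broad feature
            between = (r > min(r_peak, r_hr_peak)) & (r < max(r_peak, r_hr_peak))
            if not between.any():
                continue
            valley = float(np.min(rho_l[between]))
            significant = (
                rho_peak > thresholds.peak_contrast * valley
                and counts["DomainL"][window].sum() >= thresholds.min_peak_counts
            )
            feats[f"l_{side}_peak"] = bool(significant)
            if significant:
                feats[f"r_l_{side}"] = r_peak
    return feats


# a strict flat verdict logically excludes the layered labels, hence its rank
PRIORITY = [
    "no_condensate",
    "micelles",
    "homogeneous",
    "vesicle",
    "partial_vesicle",
    "multilayer",
    "biphasic",
]


def classify_morphology(
    profile: RadialProfile,
    metrics: Optional[ClusterMetrics] = None,
    coverage: Optional[float] = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> MorphologyLabel:
    """Discrete architecture call from converged profiles and cluster metrics.

    Decision rules, in priority order (all fired rules are recorded in the
    evidence): no condensate when the largest cluster has fewer than two
    chains; micelles when several comparable multi-chain clusters coexist;
    homogeneous when every profile is flat inside the condensate; vesicle
    when the core is hollow, the shell is angularly closed, and Domain L
    peaks bracket the Domain H-RNA shell; partial vesicle when hollow but
    open; multilayer when a filled Domain L core and an outer Domain L
    shell sandwich the Domain H-RNA layer; biphasic when the Domain L core
    has no outer Domain L shell.
    """
    fired: List[Tuple[str, str]] = []
    feats = _profile_features(profile, thresholds)
    if metrics is not None and len(metrics.largest_size):
        last = int(metrics.largest_size[-1])
        if metrics.level == "chain" and last < 2:
            fired.append(("no_condensate", f"largest cluster {last} chain(s)"))
        feats["n_clusters"] = int(metrics.n_clusters[-1])
    sizes = getattr(metrics, "multichain_sizes", None) if metrics is not None else None
    if sizes is not None and len(sizes):
        sizes = np.asarray(sizes)
        if (
            len(sizes) >= thresholds.micelle_min_clusters
            and np.max(sizes) / max(1.0, np.median(sizes)) <= thresholds.micelle_size_ratio
        ):
            fired.append(("micelles", f"{len(sizes)} comparable clusters"))
    if feats["flat"]:
        fired.append(("homogeneous", "all profiles flat inside the condensate"))
    hollow = feats["core_density_ratio"] < thresholds.theta_hollow
    feats["hollow"] = hollow
    feats["coverage"] = coverage
    if hollow:
        ordered = feats["l_inner_peak"] and feats["l_outer_peak"]
        closed = coverage is None or coverage >= thresholds.coverage_min
        if ordered and closed:
            fired.append(("vesicle", "hollow core, closed shell, L-HR-L layering"))
        else:
            fired.append(("partial_vesicle", "hollow core with open/incomplete shell"))
    else:
        if feats["l_inner_peak"] and feats["l_outer_peak"]:
            fired.append(("multilayer", "filled L core, HR shell, outer L shell"))
        elif feats["l_inner_peak"]:
            fired.append(("biphasic", "dense L core with HR shell, no outer L"))
    if not fired:
        fired.append(("homogeneous", "fallback: no structured profile detected"))
    fired.sort(key=lambda item: PRIORITY.index(item[0]))
    label, reason = fired[0]
    evidence = dict(feats)
    evidence["rules_fired"] = fired
    evidence["reason"] = reason
    return MorphologyLabel(label=label, evidence=evidence)


def classify_configuration(
    positions: np.ndarray,
    box: float,
    groups: Dict[str, np.ndarray],
    chain_id: np.ndarray,
    masses: Optional[np.ndarray] = None,
    cutoff: float = CONTACT_CUTOFF,
    bins: Optional[np.ndarray] = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> MorphologyLabel:
    """End-to-end classification of a single configuration.

    Finds chain-level clusters, centers profiles on the largest cluster's
    COM, measures the dense shell's angular coverage, and applies
    :func:`classify_morphology`.
    """
    positions = np.asarray(positions, dtype=float)
    labels = find_clusters(positions, box, cutoff, chain_id=chain_id, level="chain")
    counts = np.bincount(labels)
    big = int(np.argmax(counts))
    members = np.flatnonzero(np.isin(chain_id, np.flatnonzero(labels == big)))
    chain_sizes = counts[counts >= 2]
    if bins is None:
        bins = np.arange(0.0, box / 2.0, 0.75)
    com = condensate_com(positions, box, masses, members)
    profile = rdf_about_com(
        positions, groups, bins, box=box, masses=masses, com_override=com
    )
    metrics = ClusterMetrics(
        times=np.zeros(1),
        n_clusters=np.array([len(counts)]),
        largest_size=np.array([int(counts[big])]),
        largest_rg=np.array([_radius_of_gyration(
            positions[members], box,
            (masses if masses is not None else np.ones(len(positions)))[members],
        )]),
        level="chain",
    )
    metrics.multichain_sizes = chain_sizes  # census used by the micelle rule
    feats = _profile_features(profile, thresholds)
    r_hr = feats.get("r_hr_peak", np.nan)
    coverage = None
    if np.isfinite(r_hr) and r_hr > 0:
        band = 2.0 * profile.bin_width
        coverage = shell_coverage(positions, box, com, r_hr - band, r_hr + band)
    return classify_morphology(profile, metrics, coverage=coverage, thresholds=thresholds)
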