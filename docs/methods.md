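# Methods

## Model

`condgram` implements a residue-resolution coarse-grained model of
designer two-domain proteins mixed with single-stranded poly-U RNA, and
the analysis pipeline used to read out the internal architecture of the
condensates they form.

**Representation.** One bead per amino acid or nucleotide. Proteins are
written in the AmBn grammar: Domain H is `m` copies of a single
high-RNA-affinity residue (typically arginine), Domain L is `n` repeats of
a short auxiliary motif (e.g. N3G2 = NNNGG). RNA is a homopolymer of a
single U bead type; in length-matched mode its length equals the Domain H
length `m`.

**Energetics.** Three terms, all in kJ/mol with distances in nm:

- Harmonic bonds, U = ½ k (r − r0)², with k = 1000 kJ mol⁻¹ nm⁻²,
  r0 = 0.38 nm for peptide bonds and 0.5 nm for RNA bonds.
- Ashbaugh–Hatch (AH) short-range pairs: a Lennard-Jones potential whose
  attractive branch is scaled by the mean hydrophobicity
  λij = (λi + λj)/2 and which is shifted to vanish at its cutoff. For
  r ≤ 2^{1/6}σij the form is U_LJ − λ U_LJ(rc) + ε(1−λ); for larger r up
  to rc it is λ(U_LJ − U_LJ(rc)); zero beyond. λ = 0 reduces exactly to
  the purely repulsive WCA interaction. σij is the arithmetic mean of bead
  diameters.
- Debye–Hückel (DH) screened electrostatics,
  U = (qi qj e²/4πε0εr) exp(−κr)/r, shift-truncated at its cutoff. The
  inverse screening length κ = sqrt(2 e² N_A I / (ε0 εr(T) kB T)) uses the
  empirical water permittivity
  εr(T) = 5321/T + 233.76 − 0.9297 T + 1.417·10⁻³ T² − 8.292·10⁻⁷ T³.
  The leading term is 1/T — this is the standard empirical form and is
  validated by εr(298.15 K) ≈ 78.4; at I = 0.1 mol/L and 300 K the
  screening length is 0.96 nm. The ionic strength of all default
  conditions is read as 0.1 mol/L.

**Parameters.** Per-residue σ (van der Waals diameters), λ (CALVADOS 2
stickiness scale), integer charges at neutral pH (R, K = +1; D, E = −1;
H = 0), and standard average residue masses ship as a versioned
plain-text table (`condgram/data/calvados2.tsv`), overridable at load
time. The RNA bead has σ = 0.817 nm and λ = −0.027; its charge (−1 e, the
phosphate) and mass (306.17 Da, the UMP residue) are package choices, as
is leaving terminal-residue charge/mass modifications off — mass
concentrations quoted anywhere in the package are computed from exactly
this table, with no termini or water adjustments, so they are
reproducible bit-for-bit. Defaults that the underlying description leaves
open, all config-overridable: AH energy scale ε = 0.8368 kJ/mol
(0.2 kcal/mol), AH cutoff 2.0 nm, DH cutoff 4.0 nm, Langevin friction
0.01 ps⁻¹. Only directly bonded (1-2) pairs are excluded from nonbonded
sums. Cubic boxes and the minimum-image convention throughout; positions
are stored wrapped and analyses unwrap along bonds where molecules must
be whole.

## Assembly protocol

The simulation protocol mirrors lipid-vesicle self-assembly practice:

1. **Packing** — chains are placed as self-avoiding random walks with
   bonds at exactly r0, uniformly over the box, deterministic per seed.
   Beyond the 1-3 neighbor no pair comes closer than `min_dist`
   (default 0.6 nm). The 1-3 pair, whose span is capped by its two fixed
   bonds, gets a size-aware floor of 0.8 σ of the placed bead (capped by
   the reachable span); without it, folded-back next-nearest neighbors
   start high on the r⁻¹² core and the 10 fs time step loses energy.
2. **Repulsive pre-equilibration** — short Langevin bursts with all λ set
   to 0 (pure WCA) and charges off, plus an explicit soft half-harmonic
   repulsion between chain centers of mass (range ≈ the mean chain
   spacing, 50 kJ mol⁻¹ nm⁻²) that actively prevents premature
   clustering. The first burst runs at dt/10 to relax packing contacts.
   Bursts repeat until the chain-level cluster count equals the chain
   count at the analysis cutoff — the dispersal postcondition is an
   enforced contract, and failure to meet it within a bounded number of
   bursts is an error rather than a silent degradation.
3. **Box expansion** — the box edge grows by the protocol's `expansion`
   (25 nm at full scale); coordinates are not rescaled, chains are
   re-imaged whole.
4. **Production** — BAOAB Langevin dynamics at dt = 10 fs, friction
   0.01 ps⁻¹, Maxwell–Boltzmann initial velocities at the target
   temperature. Zero friction reduces the integrator exactly to velocity
   Verlet (NVE), which is how energy conservation is tested. A kinetic
   temperature exceeding 50× the target aborts the run with a
   diagnostic, as do non-finite positions.

Nonbonded evaluation uses a Verlet pair list (DH cutoff + 0.4 nm skin,
rebuilt when any bead has moved half the skin) built with a periodic
KD-tree, falling back to a brute-force scan when the box is too small;
the pair kernels are compiled (numba) and single-threaded, so
trajectories are bitwise reproducible for a fixed seed. Correctness of
the compiled path is defined by an O(N²) pure-Python oracle and by
central finite differences of the energy (relative force error < 10⁻⁵ in
the tests).

## Analysis

- **Clustering** — single-linkage connected components over bead
  distances ≤ 1.1 nm (the same 11 Å used for contacts; the cutoff is a
  package choice, config-overridable) under minimum image; chain-level
  mode merges clusters sharing a chain. Time series report cluster
  count, largest-cluster size, and the mass-weighted radius of gyration
  of the largest cluster, computed PBC-safely.
- **Condensate COM** — the mass-weighted circular mean per coordinate
  (each coordinate mapped to an angle on a circle of circumference equal
  to the box), so condensates straddling the boundary get their physical
  center.
- **COM-centered RDFs** — for each bead group (Domain H, Domain L, RNA,
  H+RNA, all), shell histograms about the condensate COM normalized by
  shell volume and the group's global mean number density: a uniformly
  filled region is flat at g = 1. The "H+RNA" selection is the union of
  H-labeled protein beads and RNA beads. Converged profiles use the
  final third of the trajectory by default.
- **PMF** — PMF(r) = −kB T ln g(r) on bins with g > 0; empty bins are
  masked (and carry zero weight anyway), avoiding −∞ without an
  arbitrary floor. The scalar summary is the probability-weighted mean
  ⟨PMF⟩ = Σ PMF g dr / Σ g dr over valid bins, invariant to uniform
  rescaling of g. kB = 0.0083145 kJ mol⁻¹ K⁻¹.
- **Effective species interactions** — for interaction-strength
  summaries between species (e.g. Domain H vs RNA across a stoichiometry
  series), the PMF is taken of the standard species-pair correlation
  function g_HR(r) (ideal-gas normalized) rather than the COM profile: a
  COM profile centered on the largest cluster reads strongly negative
  even for a transiently paired dispersed system, which is an artifact
  of the tiny-cluster center, whereas the pair RDF of a dispersed system
  is ≈ 1 and its ⟨PMF⟩ ≈ 0.
- **Contacts** — mean number of protein and RNA beads within 11 Å of
  each protein bead (minimum image, bonded neighbors excluded by
  default), also resolved by H/L domain label. This is the
  interaction-hierarchy readout: in the vesicle-forming systems RNA
  neighbors concentrate around Domain H.

## Morphology classification

The discrete architecture call is a documented rule engine over three
feature families, all computed from aggregated, 3-bin-smoothed shell
counts (raw per-bin g values in small central shells are Poisson-sparse
and would fire rules on noise):

- **Cluster census** (chain level): largest cluster < 2 chains →
  `no_condensate`; ≥ 4 multi-chain clusters of comparable size
  (max/median ≤ 3) → `micelles`.
- **Radial layout**: the condensate radius R is the outermost radius
  holding > 5% of the peak smoothed total density (a low floor, so
  dilute outer shells around a dense core still count). Hollow means the
  aggregated density inside 0.25 R is below θ_hollow = 0.2 of the peak.
  Domain L layers inside/outside the H+RNA shell must stand at twice the
  density of the valley separating them from it and carry ≥ 30 counts.
  Flatness compares observed shell counts with a uniform fill of the
  occupied sphere on bins with expectation ≥ 10, with 3/√n Poisson
  slack.
- **Angular coverage**: beads within ±2 bins of the H+RNA peak radius
  are binned onto 192 Fibonacci-sphere patches; coverage is the occupied
  fraction. This is the one feature a radial profile cannot carry: it
  separates closed vesicles (≈ 1) from partially formed ones (openings
  push coverage below 0.85).

Verdicts in priority order: no_condensate, micelles, homogeneous (a
strict flat verdict logically excludes the layered labels), vesicle
(hollow + closed + L-inside/HR/L-outside layering), partial_vesicle
(hollow but open or unordered), multilayer (filled L core, HR shell,
outer L shell), biphasic (L core, HR shell, no outer L). All fired rules
are recorded in the evidence, so ambiguous cases are auditable. Every
threshold lives in `ClassifierThresholds`, not in code paths.

## Synthetic fixtures and demo systems

Fixture archetypes place beads on spherical shells (uniform directions,
Gaussian radial jitter of the stated width) or filled balls around the
box center, with pseudo-chain ids so chain-level rules apply: a closed
three-shell vesicle (L at 8 nm, H+RNA at 14 nm, L at 20 nm), a
multilayer (filled L ball, HR shell, outer L shell), a biphasic droplet
(L ball + HR shell), a field of eight core-shell micelles, a partially
formed vesicle with two antipodal 50° openings plus small rim blobs
(single-opening geometry was rejected: it shifts the COM enough to fill
the radial core with shell beads, a centering artifact, and the
double-opening form matches the described multi-opening intermediates),
a uniform gas, and well-separated dispersed chains. Generation is
deterministic per seed and each fixture carries its ground-truth label;
the classifier must recover all seven archetypes across five seeds in
the test suite.

Demo presets shrink the simulated systems to desk scale while keeping the
interaction hierarchy (H-RNA strongest; L character per system class):
`systemA_small` is 24 R30(N3G2)2 chains + 24 length-matched U30 chains
packed in a 34 nm box with a 5 nm expansion (scaled to the box; 25 nm
belongs to the 115–160 nm full-scale boxes) and 50 000 production steps —
about 1.5 minutes on one core. Sizes were fixed once from diffusion-time
estimates: after expansion, chain surfaces are a few nm apart, so
electrostatically steered protein-RNA encounters occur well within the
run. These presets are qualitative analogues for testing the machinery
and the directions of the published trends (mixed clusters form; RNA
contacts Domain H over Domain L; the H-RNA pair ⟨PMF⟩ is clearly more
negative for condensing than for L-dominated non-condensing
compositions). They do not reproduce full-scale morphologies: closed
vesicle formation needs hundreds to thousands of 200-residue chains and
microsecond-scale reorganization, which is cluster-compute work — the
`fig2d_full` preset (1600+1600 chains, 160 nm box) is included but
flagged compute-heavy. What passing tests show is that the grammar,
energetics, protocol and statistics are implemented correctly and point
the right way at small scale, not that small systems form vesicles.

## Numerical choices and limitations

- Units package-wide: nm, ps, kJ/mol, Da, e (a consistent system:
  1 Da nm² ps⁻² = 1 kJ/mol). File formats store Å where the format
  demands it (PDB, DCD).
- Harmonic-oscillator and equipartition checks pin the integrator: a
  stretched dimer at zero temperature and friction oscillates at
  sqrt(k/μ) within 1%; a thermostatted dilute gas averages to the target
  temperature within 2%; NVE total energy drifts < 10⁻⁴ (relative) over
  10⁴ steps at dt = 1 fs.
- AH and DH forces are discontinuous at their cutoffs (energies are
  shifted, forces are not smoothed); at the default cutoffs the jumps
  are ~10⁻² kJ mol⁻¹ nm⁻¹ and do not measurably affect conservation.
- The packing floor interacts with the time step: contacts placed high
  on the repulsive core cost integration accuracy, which is why packing
  floors scale with bead size and the pre-equilibration soft-starts.
- Chain-level single-linkage clustering at 1.1 nm is aggressive at
  condensation densities: transient inter-chain touches merge clusters.
  This is the intended readout (it matches the contact definition) but
  means "number of clusters" saturates low once assemblies percolate.
- The classifier is calibrated on the idealized fixtures; applied to
  noisy simulation frames it is a coarse instrument, and its verdicts on
  small-system intermediates (e.g. "micelles" during early assembly) are
  descriptive, not claims about the full-scale steady state.
- Single-bead RNA with uniform charge ignores sequence, stacking and
  secondary structure; the model's RNA is a flexible polyanion, nothing
  more.
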