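# condgram

Coarse-grained modelling and morphology analysis of multiphase
protein–RNA condensates.

Membraneless vesicles, multilayered droplets and biphasic condensates can
all arise from the same minimal ingredients: a designer protein with a
high-RNA-affinity domain (H, e.g. polyarginine) and a low-affinity
auxiliary domain (L, e.g. NNNGG repeats), mixed with length-matched
poly-U RNA. `condgram` is for computational biophysicists who want to
simulate and classify these architectures: it implements the
residue-resolution bead model (one bead per residue/nucleotide), the
self-assembly protocol, and the statistics that turn trajectories into
architecture calls.

## Model

Proteins are written in the AmBn grammar — `R150(N3G2)10` is 150
arginines (Domain H) followed by ten NNNGG repeats (Domain L), 200
residues in all. Beads carry CALVADOS-2 parameters (diameter σ,
hydrophobicity λ, charge q, mass) and interact through

- harmonic bonds, U = ½ k (r − r0)², k = 1000 kJ mol⁻¹ nm⁻²,
  r0 = 0.38 nm (protein) / 0.5 nm (RNA);
- the Ashbaugh–Hatch potential — Lennard-Jones with its attractive
  branch scaled by λij = (λi+λj)/2 and shifted to zero at the cutoff;
  λ = 0 is the purely repulsive WCA limit;
- Debye–Hückel electrostatics, U = (qiqj e²/4πε0εr) e^{−κr}/r, with
  κ from the ionic strength and a temperature-dependent dielectric
  (κ⁻¹ = 0.96 nm at 0.1 mol/L, 300 K).

Assembly runs BAOAB Langevin dynamics (dt = 10 fs) over a four-stage
protocol: self-avoiding packing → repulsive pre-equilibration (WCA +
chain-chain repulsion until every chain is its own cluster) → box
expansion → production. Analyses include chain-level clustering,
COM-centered radial distribution functions g(r) per domain, the
potential of mean force PMF(r) = −kBT ln g(r) with its
probability-weighted mean ⟨PMF⟩ = Σ PMF·g dr / Σ g dr, contact numbers
within 11 Å, and a rule-based morphology classifier
(no_condensate / micelles / partial_vesicle / vesicle / multilayer /
biphasic / homogeneous).

## Worked example

Classify an idealized hollow vesicle, then run a desk-scale assembly:

```bash
$ condgram fixtures --archetype vesicle --seed 0 --out vesicle.pdb
vesicle
$ condgram classify --snapshot vesicle.pdb
vesicle
```

The `analysis/` scripts are numbered narrative drivers over the library.
`analysis/03_assembly_demo.py` runs 24 R30(N3G2)2 chains with 24
length-matched U30 chains through the full protocol (about two minutes on
one core) and prints:

```
stages: ['pack_random', 'repulsive_preequilibrate', 'expand_box', 'run_langevin']; production box 39 nm, 21 frames over 500 ps
chain clusters over time: [48, 48, 45, 42, 40, 36, 34, 33, 32, 32, 31, 28, 29, 29, 29, 29, 29, 30, 30, 30, 28]
largest cluster (chains): [1, 1, 2, 2, 3, 4, 3, 3, 4, 4, 4, 5, 5, 5, 5, 5, 5, 4, 4, 4, 4]
contact hierarchy: RNA neighbors per H bead 2.00 vs per L bead 0.09
morphology verdict: micelles (13 comparable clusters)
```

Reading this: 48 dispersed chains condense into ~13 small mixed
protein–RNA clusters within 500 ps — the micelle-stage intermediates of
the assembly pathway — and RNA packs against the arginine-rich Domain H
(2.00 RNA neighbors per H bead) rather than the auxiliary Domain L
(0.09), the interaction hierarchy that drives vesicle formation at full
scale. Cluster time series, g(r), PMF, and contact tables land in
`results/assembly_demo/` as TSV with units and a config hash in the
headers. Full-scale compositions (e.g. the `fig2d_full` preset: 1600
chains each of R150(N3G2)10 and U150 in a 160 nm box) are supported but
are cluster-compute jobs, not desk runs.

`docs/methods.md` documents the model, the protocol, every default, and
the classifier's decision rules.

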