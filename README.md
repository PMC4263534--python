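# atomstress

Atomic-resolution virial stress maps from molecular-dynamics trajectories.

Proteins, nucleic acids, and carbon nanomaterials are routinely discussed in
mechanical terms — tension in a disulfide bridge, compression behind a shock
front — yet most MD post-processing reports forces or fluctuations, not
stress. `atomstress` computes, for every atom of a simulation snapshot, the
**mean principal virial stress** (one-third of the trace of the atomic stress
tensor) and decomposes it by force-field term: bond, angle, dihedral,
Coulomb, van der Waals, generalized-Born implicit solvent, and (optionally)
kinetic. It is aimed at anyone asking *where* a simulated molecule or
material is under tension or compression, and *which* interaction is
responsible.

## The quantity computed

For atom *i* with characteristic volume *Vᵢ*, the per-term mean principal
stress is assembled from pairwise forces:

```
sᵢ(term) = −(1/(6·Vᵢ)) · Σⱼ  r⃗ᵢⱼ · f⃗ᵢⱼ          [potential terms]
sᵢ(kin)  = −mᵢ·|v⃗ᵢ|² / (3·Vᵢ)                     [optional kinetic term]
```

where f⃗ᵢⱼ is the force on *i* due to *j* attributed to that term and
r⃗ᵢⱼ = r⃗ᵢ − r⃗ⱼ. Tension is positive stress; the hydrostatic pressure is
its negation. Many-body terms (angle, torsion, generalized Born) are first
decomposed into *central* pairwise forces by writing their energies as
functions of interatomic distances and differentiating through those
distances, so per-atom sums reproduce the exact gradient and the stress
tensor stays symmetric — no 3×3 tensor is ever assembled, since the trace is
a sum of dot products. Torsion phases are restricted to {0, π}, where the
energy is a polynomial in cos φ and the classic sine-ratio singularity never
arises. The solvent term differentiates the full OBC generalized-Born
energy, including the chain-rule paths through every effective Born radius.

Characteristic volumes are uniform (box volume / atom count) when the frame
has a box, else a fixed carbon-atom volume (0.0206 nm³ by default). A 1.0 nm
cutoff limits nonbonded pairs; bonded-term pairs are always included. Units
are GROMACS-consistent internally (nm, ps, amu, kJ/mol, e); stresses are
reported in kbar (1 kJ·mol⁻¹·nm⁻³ = 16.6054 bar).

On top of the per-atom maps the package provides residue averaging per
snapshot, time statistics — mean, mean square fluctuation (MSF), and
standard error of the mean corrected for autocorrelation via the
statistical inefficiency — and between-condition difference maps with SEMs
combined in quadrature.

## Worked example

Generate a 5-atom validation structure (bonds, an angle, a torsion, charges,
LJ and GB parameters) with a short synthetic trajectory, then run the CLI:

```py
import numpy as np
from atomstress import fixtures as fx, model_io as mio
from atomstress.model_io import TrajectoryFrame

entry = fx.build_test_structures()["five_atom_gb"]
mio.write_topology(entry.topology, "five.top")
rng = np.random.default_rng(0)
mio.write_trajectory(
    [TrajectoryFrame(0.01 * k, entry.coordinates + rng.normal(scale=2e-3, size=(5, 3)))
     for k in range(5)], "five.trj")
```

```text
$ atomstress --topology five.top --trajectory five.trj --output-prefix demo --cutoff 2.0
INFO system: 5 atoms, 5 frames, terms {'bond': 3, 'angle': 1, 'dihedral': 1}
INFO no box; per-atom carbon volume will be used
INFO selection: 5 atoms; stress terms: ['angle', 'bond', 'coulomb', 'dihedral', 'gb', 'vdw']
demo_stress.tsv
demo_atom_total.pdb
demo_residue_total.pdb
demo_atom_msf.pdb
demo_residue_msf.pdb
```

The table has one row per (frame, atom), all values in kbar:

```text
time_ps  atom_index  residue_id  bond_kbar  angle_kbar  dihedral_kbar  coulomb_kbar  vdw_kbar  gb_kbar  total_kbar  hydrostatic_pressure_kbar
0        0           0           13.50      39.78       -9.24          11.80         -3.68     -7.22    44.94       -44.94
0        1           0           35.66      -77.17      8.08           -2.96         -3.82     -0.47    -40.68      40.68
```

Atom 0 is under net tension (total +44.9 kbar, hydrostatic pressure −44.9
kbar), dominated by the angle term; atom 1 is under compression. The four
PDB files carry the time-mean total stress and its MSF, per atom and per
residue, in the B-factor column (clamped to ±999.99; `--bfactor-scale`
rescales) for coloring in any molecular viewer. `--split` writes per-term
tables, plus bonded/nonbonded sums and the kinetic term with
`--velocities`.

A stretched diatomic makes the sign convention concrete: k_b = 1000
kJ·mol⁻¹·nm⁻², b₀ = 0.1 nm, separation 0.12 nm, V = 0.02 nm³ gives a bond
stress of +20 kJ·mol⁻¹·nm⁻³ = +0.332 kbar on each atom — tensile, so the
hydrostatic pressure is −0.332 kbar.

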