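# Methods

## Atomic virial stress

The package assigns each atom *i* a stress tensor built from the pairwise
forces it participates in plus an optional kinetic term, and reports only the
rotation-invariant scalar: the mean principal stress, one-third of the
tensor trace. Because trace(A+B) = trace(A) + trace(B), the total at an atom
is exactly the sum of the per-term values; the implementation exploits this
by never assembling the tensor — each pair contributes the scalar
r⃗ᵢⱼ·f⃗ᵢⱼ, identical from either atom's viewpoint.

Sign and normalization are pinned by two behavioral requirements rather than
by a formula transcription: a stretched harmonic bond must show *positive*
(tensile) stress, hence negative hydrostatic pressure, and a noninteracting
gas with velocities must show positive pressure recovering N·k_B·T/V. Both
are locked by tests. With f⃗ᵢⱼ the force on *i* from *j* and
r⃗ᵢⱼ = r⃗ᵢ − r⃗ⱼ this gives

    sᵢ(term) = −(1/(6Vᵢ)) Σⱼ r⃗ᵢⱼ·f⃗ᵢⱼ,    sᵢ(kin) = −mᵢ|v⃗ᵢ|²/(3Vᵢ),

and the mean atomic hydrostatic pressure of a periodic system equals the
standard virial pressure identically (a per-frame 1e-6 test on an LJ gas).

**Characteristic volumes.** Theory does not fix a single-atom volume. With a
box, every atom gets V_box/N, which preserves ΣVᵢ = V_box; without one
(implicit-solvent or vacuum trajectories), every atom gets the volume of a
carbon atom, taken as a 1.7 Å van-der-Waals sphere, (4/3)π(0.17 nm)³ ≈
0.0206 nm³, configurable. The policy is decided on the first frame and held
constant.

**Kinetic term.** Off by default (most stored trajectories lack velocities).
When enabled it uses raw atomic velocities; subtracting the selection's
center-of-mass velocity per frame is available (`remove_com_velocity`) as a
minimal local-frame correction but is off by default.

**Cutoff.** Nonbonded pairs are enumerated within 1.0 nm (configurable) with
minimum-image displacements in orthorhombic boxes; a cutoff beyond half the
shortest box edge is an error. Bonded-term pairs always enter regardless of
distance — dropping a bonded pair would silently break the
gradient-consistency property. Pair search uses `scipy.spatial.cKDTree`
(with `boxsize` for periodic frames) above 200 atoms and an O(N²) sweep
below; the two are equivalence-tested. Long-ranged (reciprocal-space)
electrostatics are intentionally out of scope: the dominant stress
contributions are short-ranged, and the target use is qualitative mapping.

## Pairwise decomposition of many-body terms

Angle and torsion gradients are made pairwise by expressing the energy as a
function of interatomic distances and differentiating through them; each
pair (a, b) then receives the central force −(∂V/∂r_ab)·ê_ab. For the angle
i–j–k, cos θ follows from the law of cosines in (r_ij, r_kj, r_ik), yielding
three pairwise forces. For the torsion i–j–k–l, cos φ is a rational function
of the six squared distances of the quadruple, and with phases restricted to
{0, π} the energy k(1 + cos(nφ − φ_s)) = k(1 ± T_n(cos φ)) is a Chebyshev
polynomial in cos φ — finite everywhere, including planar geometries, with
no sine-ratio evaluation. Other phases raise an explicit error. Degenerate
geometries (collinear angle arms, collinear consecutive torsion atoms) also
raise errors rather than returning zeros, which would corrupt stress maps
invisibly.

This central decomposition reproduces per-atom gradients exactly but is not
unique per pair; any gradient-consistent central split is acceptable for a
symmetric virial, and per-pair values may differ from other published
decompositions. Improper torsions, when present, use the same periodic
functional form.

The validation oracle is an independent scalar-loop energy evaluator
differentiated by central differences (step 1e-6 nm), sharing no code with
the vectorised kernels; agreement is enforced at relative 1e-6 across a
fixture catalog and hundreds of randomized geometries.

## Generalized Born (OBC) solvent stress

Born radii follow the Onufriev–Bashford–Case scheme: Hawkins–Cramer–Truhlar
pairwise descreening integrals (with the engulfed-atom correction) summed
into Ψᵢ = ρ̃ᵢ·Σⱼ H(rᵢⱼ), then Rᵢ⁻¹ = ρ̃ᵢ⁻¹ − ρᵢ⁻¹·tanh(αΨᵢ − βΨᵢ² + γΨᵢ³)
with α, β, γ = 1.0, 0.8, 4.85, offset 0.009 nm, solvent dielectric 80 and
solute dielectric 1 — all configurable. The polar energy is the Still
expression with f_GB = √(r² + RᵢRⱼ·exp(−r²/4RᵢRⱼ)), pairs counted once and
self terms −f·τ·qᵢ²/(2Rᵢ), so a single ion reproduces the closed-form Born
energy. No nonpolar/surface-area term is included.

For stress, the exact gradient of the energy — the direct r-derivative plus
every chain-rule path ∂G/∂R_k·∂R_k/∂r_kl — is folded into central pairwise
forces on the pair whose distance is differentiated. Self-energies
contribute only through Born-radius paths. Gradient consistency against
central differences through the full composition is tested at relative 1e-5;
radii and energies match a brute-force direct-summation oracle at 1e-10.

## Statistics

Residue-averaged stress is the arithmetic mean over the residue's atoms per
snapshot. MSF uses population normalization 1/N_s (the quantity mapped to
B-factors); the variance inside the SEM uses 1/(N_s−1). The statistical
inefficiency g = 1 + 2Σ_τ(1 − τ/N_s)ρ(τ) truncates the autocorrelation sum
at its first zero crossing and is clamped to ≥ 1; SEM = √(s²g/N_s).
Difference maps report mean deltas with SEMs combined in quadrature, and MSF
deltas without an error estimate. Residue averages are reported in each
residue's raw frame; they cannot be summed to recover the system virial,
which is a documented caveat, not corrected.

## Synthetic data and the mini-MD engine

All test inputs are generated programmatically. The catalog of 1–5-atom
structures places each term at hand-checkable geometries (equilibria,
stationary points, a stretched bond whose +0.332 kbar stress is computed by
hand). The graphene builder produces honeycomb ribbons and nanotubes with
embedded aromatic-carbon (sp², zero-charge) parameters from the published
GAFF "ca" set: b₀ = 0.1387 nm, k_b = 400 325 kJ·mol⁻¹·nm⁻² (½k convention),
θ₀ = 119.97°, k_θ = 562.16 kJ·mol⁻¹·rad⁻², proper torsion 15.167 kJ/mol
(n = 2, φ_s = π), periodic improper 4.602 kJ/mol per three-fold site,
σ = 0.33997 nm, ε = 0.3598 kJ/mol, 1-4 scales 1/1.2 and 0.5. Exclusions are
derived from graph distance (1-2, 1-3 excluded; 1-4 scaled).

The NVE integrator is velocity Verlet with a skin-based Verlet neighbour
list and an optional weak harmonic position restraint (0.1 kcal·mol⁻¹·Å⁻²)
that acts on the dynamics only — never on the stress terms. Inner loops are
numba-compiled with a numpy fallback; the two paths are equivalence-tested.
It conserves energy to <1e-4 over 10⁴ steps on a harmonic dimer and
reproduces the analytic oscillator period to 0.1%; it is not a
general-purpose MD engine (no thermostats, constraints, or PME).

What the generator emulates: ultra-cold, stiff, charge-free carbon lattices
under extreme localized excitation, and idealized gases/series for the
statistical machinery. What it does not: solvated biomolecular systems, bond
breaking (harmonic bonds cannot rupture, so hypervelocity impacts deposit
all energy elastically), finite temperature ensembles, or the
million-snapshot equilibrium trajectories on which protein-scale stress
statistics were originally demonstrated — passing tests therefore validate
the machinery, not force-field realism for proteins.

## Stress-wave experiments

Protocol per experiment: build an armchair sheet (~8×8 nm in the acceptance
script, ~2500 atoms), energy-minimize (L-BFGS), draw 1 K Maxwell–Boltzmann
velocities from the run seed, overwrite the central ~10 atoms' velocities
with a 20.5 km/s pulse (radial in-plane → longitudinal; +z out-of-plane →
transverse), integrate NVE at 0.05 fs with the weak restraint, snapshot
every 10 fs (0.45 ps for the longitudinal run, 0.9 ps for the transverse —
the fronts reach the boundary at roughly 0.35 and 0.6 ps).

The front radius per frame is the greatest in-plane distance from the pulse
center among atoms whose field value exceeds 25% of that frame's maximum;
the speed is the least-squares slope of radius versus time (nm/ps ≡ km/s).
Two analysis choices matter and are deliberate: the field is the *change*
relative to the initial frame (relaxed ribbons carry static edge stress that
would otherwise capture the threshold once the pulse spreads thin), and
frames whose radius exceeds 90% of the half-width are excluded (after the
front touches the boundary, reflections break the linear model).

Measured behaviour: the longitudinal tensile front propagates at ~19.6 km/s
(R² ≈ 0.999), close to the experimental graphene sound speed of ~21 km/s —
a leading-edge threshold metric tracks the acoustic front, which outruns the
strong high-tension band visible in stress-map animations of impact
simulations. The transverse displacement front propagates at ~5–6 km/s and
is visibly dispersive (it decelerates as the dimple spreads), so the fitted
speed depends mildly on sheet size and window. The strict ordering
longitudinal > transverse holds in every configuration tested.

## Known limitations

- Orthorhombic boxes only; triclinic input is rejected.
- Dihedral phases outside {0, π} are unsupported by design.
- No PME/reciprocal virial, no constraint (SHAKE) virial corrections —
  unconstrained trajectories are recommended for quantitative work.
- Off-diagonal stress components are not reported.
- B-factor columns clamp at ±999.99 kbar (PDB fixed-width); use
  `--bfactor-scale` for systems in the Mbar range.
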