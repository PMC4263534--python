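"""Internal unit system and physical constants.

Everything inside the package is GROMACS-consistent: lengths in nm, times in
ps, masses in amu (g/mol), energies in kJ/mol, charges in elementary charges.
In this system 1 amu·nm²·ps⁻² = 1 kJ/mol exactly, and 1 nm/ps = 1 km/s.
"""

# Coulomb constant f = 1/(4πε0) in kJ·mol⁻¹·nm·e⁻²
COULOMB_CONSTANT = 138.935458

# Boltzmann constant in kJ·mol⁻¹·K⁻¹ (CODATA R/1000)
BOLTZMANN_KJ_MOL_K = 0.008314462618

# 1 kJ·mol⁻¹·nm⁻³ expressed in bar (1000 / N_A / 1e-27 / 1e5 Pa·bar⁻¹)
BAR_PER_KJ_MOL_NM3 = 16.605390671738466

KBAR_PER_KJ_MOL_NM3 = BAR_PER_KJ_MOL_NM3 / 1000.0

KCAL_TO_KJ = 4.184

# 1 km/s = 1 nm/ps
KM_PER_S_PER_NM_PS = 1.0
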