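"""Physical constants and unit conversions.

Internal unit system: length nm, energy kJ/mol, mass Da (g/mol), time ps,
temperature K, charge in elementary-charge units.  This set is closed under
Newtonian dynamics: 1 kJ/mol / (1 g/mol) = 1 (nm/ps)^2.
"""

# CODATA 2018 exact values
AVOGADRO = 6.02214076e23          # 1/mol
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN_SI = 1.380649e-23       # J/K

#: Boltzmann constant in internal units, kJ mol^-1 K^-1
KB = BOLTZMANN_SI * AVOGADRO / 1000.0  # 0.008314462618

#: e^2 N_A / (4 pi eps0), in kJ nm mol^-1: Coulomb energy prefactor so that
#: u = COULOMB_PREFACTOR / eps_r * q_i q_j / r  with r in nm.
COULOMB_PREFACTOR = (
    ELEMENTARY_CHARGE**2 * AVOGADRO
    / (4.0 * 3.141592653589793 * VACUUM_PERMITTIVITY)
    * 1e9 / 1000.0
)

#: mol/L -> nm^-3 (number density of a 1 M solution)
MOLAR_TO_PER_NM3 = AVOGADRO * 1e-24

#: Da/nm^3 -> mg/mL (= g/L) mass-concentration conversion
DA_PER_NM3_TO_MG_PER_ML = 1e24 / AVOGADRO

#: mass of a water molecule, Da (added to a chain of residues to give the
#: peptide molecular weight)
WATER_MASS = 18.015

#: mass of H / OH, Da (terminal bead adjustments)
H_MASS = 1.008
OH_MASS = 17.007
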