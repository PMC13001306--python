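"""Physical constants in the package-wide unit system: nm, ps, kJ/mol, Da, e.

This unit system is internally consistent: 1 Da * nm^2 / ps^2 = 1 kJ/mol,
so masses, forces and velocities can be mixed without conversion factors.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.008314462618

#: Coulomb prefactor e^2 N_A / (4 pi eps0), kJ mol^-1 nm e^-2
COULOMB = 138.935458

#: Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

#: elementary charge, C (SI; used only inside the Debye-length formula)
E_CHARGE = 1.602176634e-19

#: vacuum permittivity, F m^-1 (SI; used only inside the Debye-length formula)
EPS0_SI = 8.8541878128e-12

#: Boltzmann constant, J K^-1 (SI; used only inside the Debye-length formula)
KB_SI = 1.380649e-23

#: 1 Da expressed in mg
DA_TO_MG = 1.66053906660e-21

#: 1 nm^3 expressed in mL
NM3_TO_ML = 1.0e-21
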