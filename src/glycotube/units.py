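"""Physical constants and unit conventions.

All coordinates are carried internally in angstrom; nanometre appears only
at format boundaries (GRO files, Lennard-Jones sigma) with the exact factor
of 10, and in box-volume bookkeeping for ion counts.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB_KJ_MOL_K = 0.0083144621

#: Coulomb prefactor f = 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB_KJ_MOL_NM_E2 = 138.935458

#: default aromatic C-C bond length, angstrom (0.1417 nm)
A_CC_DEFAULT = 1.417

#: Avogadro number expressed as particles per nm^3 for a 1 mol/L solution
N_A_PER_NM3_MOLAR = 0.6022140857

ANGSTROM_PER_NM = 10.0
NM_PER_ANGSTROM = 0.1
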