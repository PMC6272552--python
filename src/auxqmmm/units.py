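"""Physical constants and unit conversions.

Internal convention: Hartree atomic units everywhere (bohr, hartree, e,
electron mass).  File I/O and MM parameter files use the field's customary
units (Å, kcal/mol, degrees, amu, fs) and are converted on read.
"""

# CODATA length conversion; the inverse is the bohr radius in Å.
ANGSTROM_TO_BOHR = 1.8897261254578281
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR

HARTREE_TO_KCALMOL = 627.5094740631
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL

# Boltzmann constant in hartree/K
KB_HARTREE = 3.166811563e-6

# atomic mass unit in electron masses
AMU_TO_ME = 1822.888486209

# one atomic time unit in femtoseconds
AUT_TO_FS = 2.4188843265857e-2
FS_TO_AUT = 1.0 / AUT_TO_FS

DEG_TO_RAD = 0.017453292519943295
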