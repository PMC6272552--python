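# Generic parameter set for the shipped fixtures (kcal/mol, Angstrom, degrees).
# Flexible SPC-charge water (stiff bonds stand in for rigid constraints),
# united OPLS-like alkanes, and monatomic ions (nonbonded terms live on the
# atoms themselves).
BONDS
OW HW    450.0   0.9572
CT3 CT3  268.0   1.529
CT3 CT2  268.0   1.529
CT2 CT2  268.0   1.529
CT3 HA   340.0   1.090
CT2 HA   340.0   1.090
ANGLES
HW OW HW    55.0   104.52
CT3 CT2 CT2 58.35  112.7
CT2 CT2 CT2 58.35  112.7
CT3 CT2 CT3 58.35  112.7
HA CT3 HA   33.0   107.8
HA CT2 HA   33.0   107.8
HA CT3 CT2  37.5   110.7
HA CT2 CT2  37.5   110.7
HA CT2 CT3  37.5   110.7
HA CT3 CT3  37.5   110.7
UREY
HW OW HW    38.25  1.5139
DIHEDRALS
X CT2 CT2 X  0.160  3  0.0
X CT2 CT3 X  0.160  3  0.0
X CT3 CT3 X  0.160  3  0.0
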