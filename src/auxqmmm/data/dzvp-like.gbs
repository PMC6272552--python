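! Valence-double-zeta-plus-polarization set constructed in this package by
! splitting the minimal set's valence shells and adding one polarization
! shell per element (p on H/He, d on C/N/O).  It plays the role a DZVP-class
! set plays in production codes and is documented as this package's own.
H 0
S 2 1.00
      3.42525091    0.15432897
      0.62391373    0.53532814
S 1 1.00
      0.16885540    1.00000000
P 1 1.00
      0.80000000    1.00000000
****
He 0
S 2 1.00
      6.36242139    0.15432897
      1.15892300    0.53532814
S 1 1.00
      0.31364979    1.00000000
P 1 1.00
      1.00000000    1.00000000
****
C 0
S 3 1.00
     71.61683700    0.15432897
     13.04509600    0.53532814
      3.53051220    0.44463454
SP 2 1.00
      2.94124940   -0.09996723    0.15591627
      0.68348310    0.39951283    0.60768372
SP 1 1.00
      0.22228990    1.00000000    1.00000000
D 1 1.00
      0.75000000    1.00000000
****
N 0
S 3 1.00
     99.10616900    0.15432897
     18.05231200    0.53532814
      4.88566020    0.44463454
SP 2 1.00
      3.78045590   -0.09996723    0.15591627
      0.87849660    0.39951283    0.60768372
SP 1 1.00
      0.28571440    1.00000000    1.00000000
D 1 1.00
      0.90000000    1.00000000
****
O 0
S 3 1.00
    130.70932000    0.15432897
     23.80886100    0.53532814
      6.44360830    0.44463454
SP 2 1.00
      5.03315130   -0.09996723    0.15591627
      1.16959610    0.39951283    0.60768372
SP 1 1.00
      0.38038900    1.00000000    1.00000000
D 1 1.00
      1.10000000    1.00000000
****
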