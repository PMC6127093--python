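channel,x,y,z
Fp1,-0.029339,0.090295,-0.003315
Fp2,0.029339,0.090295,-0.003315
F7,-0.07681,0.055806,-0.003315
F3,-0.051776,0.063938,0.0475
Fz,0.0,0.068337,0.065993
F4,0.051776,0.063938,0.0475
F8,0.07681,0.055806,-0.003315
FC5,-0.084349,0.032379,0.029357
FC1,-0.035597,0.035597,0.080565
FC2,0.035597,0.035597,0.080565
FC6,0.084349,0.032379,0.029357
T7,-0.094942,-0.0,-0.003315
C3,-0.068337,-0.0,0.065993
Cz,0.0,0.0,0.095
C4,0.068337,0.0,0.065993
T8,0.094942,0.0,-0.003315
TP9,-0.081885,-0.026606,-0.040149
CP5,-0.084349,-0.032379,0.029357
CP1,-0.035597,-0.035597,0.080565
CP2,0.035597,-0.035597,0.080565
CP6,0.084349,-0.032379,0.029357
TP10,0.081885,-0.026606,-0.040149
P7,-0.07681,-0.055806,-0.003315
P3,-0.051776,-0.063938,0.0475
Pz,0.0,-0.068337,0.065993
P4,0.051776,-0.063938,0.0475
P8,0.07681,-0.055806,-0.003315
PO9,-0.050608,-0.069656,-0.040149
O1,-0.029339,-0.090295,-0.003315
Oz,0.0,-0.094942,-0.003315
O2,0.029339,-0.090295,-0.003315
PO10,0.050608,-0.069656,-0.040149
AF7,-0.055806,0.07681,-0.003315
AF3,-0.038593,0.082764,0.026186
AF4,0.038593,0.082764,0.026186
AF8,0.055806,0.07681,-0.003315
F5,-0.069254,0.060202,0.024588
F1,-0.027262,0.067475,0.061065
F2,0.027262,0.067475,0.061065
F6,0.069254,0.060202,0.024588
FT9,-0.081885,0.026606,-0.040149
FT7,-0.090295,0.029339,-0.003315
FC3,-0.06363,0.041322,0.057172
FC4,0.06363,0.041322,0.057172
FT8,0.090295,0.029339,-0.003315
FT10,0.081885,0.026606,-0.040149
C5,-0.08869,-0.0,0.034045
C1,-0.037119,-0.0,0.087448
C2,0.037119,0.0,0.087448
C6,0.08869,0.0,0.034045
TP7,-0.090295,-0.029339,-0.003315
CP3,-0.062784,-0.040772,0.058488
CPz,0.0,-0.037119,0.087448
CP4,0.062784,-0.040772,0.058488
TP8,0.090295,-0.029339,-0.003315
P5,-0.069254,-0.060202,0.024588
P1,-0.027262,-0.067475,0.061065
P2,0.027262,-0.067475,0.061065
P6,0.069254,-0.060202,0.024588
PO7,-0.055806,-0.07681,-0.003315
PO3,-0.038593,-0.082764,0.026186
POz,0.0,-0.08869,0.034045
PO4,0.038593,-0.082764,0.026186
PO8,0.055806,-0.07681,-0.003315
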