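label,x,y
Fp1,-0.247214,0.760845
Fpz,0.000000,0.800000
Fp2,0.247214,0.760845
AF7,-0.470228,0.647214
AF3,-0.235114,0.623607
AF4,0.235114,0.623607
AF8,0.470228,0.647214
F7,-0.647214,0.470228
F5,-0.485410,0.452671
F3,-0.323607,0.435114
F1,-0.161803,0.417557
Fz,0.000000,0.400000
F2,0.161803,0.417557
F4,0.323607,0.435114
F6,0.485410,0.452671
F8,0.647214,0.470228
FT9,-0.951057,0.309017
FT7,-0.760845,0.247214
FC5,-0.570634,0.235410
FC3,-0.380423,0.223607
FC1,-0.190211,0.211803
FCz,0.000000,0.200000
FC2,0.190211,0.211803
FC4,0.380423,0.223607
FC6,0.570634,0.235410
FT8,0.760845,0.247214
FT10,0.951057,0.309017
T7,-0.800000,0.000000
C5,-0.600000,0.000000
C3,-0.400000,0.000000
C1,-0.200000,0.000000
Cz,0.000000,0.000000
C2,0.200000,0.000000
C4,0.400000,0.000000
C6,0.600000,0.000000
T8,0.800000,0.000000
TP9,-0.951057,-0.309017
TP7,-0.760845,-0.247214
CP5,-0.570634,-0.235410
CP3,-0.380423,-0.223607
CP1,-0.190211,-0.211803
CPz,0.000000,-0.200000
CP2,0.190211,-0.211803
CP4,0.380423,-0.223607
CP6,0.570634,-0.235410
TP8,0.760845,-0.247214
TP10,0.951057,-0.309017
P7,-0.647214,-0.470228
P5,-0.485410,-0.452671
P3,-0.323607,-0.435114
P1,-0.161803,-0.417557
Pz,0.000000,-0.400000
P2,0.161803,-0.417557
P4,0.323607,-0.435114
P6,0.485410,-0.452671
P8,0.647214,-0.470228
PO7,-0.470228,-0.647214
PO3,-0.235114,-0.623607
PO4,0.235114,-0.623607
PO8,0.470228,-0.647214
O1,-0.247214,-0.760845
Oz,0.000000,-0.800000
O2,0.247214,-0.760845
CB1,-0.422618,-0.906308
CB2,0.422618,-0.906308
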