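Fp1
Fp7h
Fp7
Fp5h
Fp5
Fp3h
Fp3
Fp1h
Fpz
Fp2h
Fp4
Fp4h
Fp6
Fp6h
Fp8
Fp8h
Fp2
AFp7
AFp7h
AFp5
AFp5h
AFp3
AFp3h
AFp1
AFp1h
AFpz
AFp2h
AFp2
AFp4h
AFp4
AFp6h
AFp6
AFp8h
AFp8
AF7
AF7h
AF5
AF5h
AF3
AF3h
AF1
AF1h
AFz
AF2h
AF2
AF4h
AF4
AF6h
AF6
AF8h
AF8
AFF7
AFF7h
AFF5
AFF5h
AFF3
AFF3h
AFF1
AFF1h
AFFz
AFF2h
AFF2
AFF4h
AFF4
AFF6h
AFF6
AFF8h
AFF8
F7
F7h
F5
F5h
F3
F3h
F1
F1h
Fz
F2h
F2
F4h
F4
F6h
F6
F8h
F8
FFC7
FFC7h
FFC5
FFC5h
FFC3
FFC3h
FFC1
FFC1h
FFCz
FFC2h
FFC2
FFC4h
FFC4
FFC6h
FFC6
FFC8h
FFC8
FC7
FC7h
FC5
FC5h
FC3
FC3h
FC1
FC1h
FCz
FC2h
FC2
FC4h
FC4
FC6h
FC6
FC8h
FC8
FCC7
FCC7h
FCC5
FCC5h
FCC3
FCC3h
FCC1
FCC1h
FCCz
FCC2h
FCC2
FCC4h
FCC4
FCC6h
FCC6
FCC8h
FCC8
T7
C7h
C5
C5h
C3
C3h
C1
C1h
Cz
C2h
C2
C4h
C4
C6h
C6
C8h
T8
CCP7
CCP7h
CCP5
CCP5h
CCP3
CCP3h
CCP1
CCP1h
CCPz
CCP2h
CCP2
CCP4h
CCP4
CCP6h
CCP6
CCP8h
CCP8
CP7
CP7h
CP5
CP5h
CP3
CP3h
CP1
CP1h
CPz
CP2h
CP2
CP4h
CP4
CP6h
CP6
CP8h
CP8
CPP7
CPP7h
CPP5
CPP5h
CPP3
CPP3h
CPP1
CPP1h
CPPz
CPP2h
CPP2
CPP4h
CPP4
CPP6h
CPP6
CPP8h
CPP8
P7
P7h
P5
P5h
P3
P3h
P1
P1h
Pz
P2h
P2
P4h
P4
P6h
P6
P8h
P8
PPO7
PPO7h
PPO5
PPO5h
PPO3
PPO3h
PPO1
PPO1h
PPOz
PPO2h
PPO2
PPO4h
PPO4
PPO6h
PPO6
PPO8h
PPO8
PO7
PO7h
PO5
PO5h
PO3
PO3h
PO1
PO1h
POz
PO2h
PO2
PO4h
PO4
PO6h
PO6
PO8h
PO8
POO7
POO7h
POO5
POO5h
POO3
POO3h
POO1
POO1h
POOz
POO2h
POO2
POO4h
POO4
POO6h
POO6
POO8h
POO8
O1
O7h
O7
O5h
O5
O3h
O3
O1h
Oz
O2h
O4
O4h
O6
O6h
O8
O8h
O2
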