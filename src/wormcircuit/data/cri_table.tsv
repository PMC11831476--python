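neuron	cri
I1	76.20
SDQ	15.04
RIS	38.09
RID	11.17
I2	24.14
AQR	18.17
ALA	21.37
AVB	11.00
I3	73.24
PQR	21.58
PVQ	6.22
AVA	33.75
I4	48.71
ALM	16.92
ADA	13.50
PVC	12.56
I5	33.67
AVM	15.57
RIF	18.14
RIP	11.22
I6	19.02
PVM	21.70
BDU	16.73
URA	29.45
M1	24.11
PLM	16.86
PVR	10.77
RME_LR	30.14
M2	27.29
FLP	45.12
AVF	12.41
RME_DV	17.44
M3	23.28
DVA	22.71
AVH	22.14
RMD_DV	17.48
M4	46.37
PVD	23.26
PVP	17.54
RMD	13.30
M5	20.83
ADE	23.08
LUA	47.80
RIV	8.79
MC	39.46
PDE	66.95
PVN	110.22
RMH	16.11
MI	11.88
PHA	64.58
AVG	19.56
SAB	42.23
NSM	40.44
PHB	145.40
DVB	20.38
SMD	9.65
ASI	196.67
PHC	15.94
RIB	26.92
SMB	12.98
ASJ	114.12
IL2_DV	51.08
RIG	12.16
SIB	17.72
AWA	168.32
IL2_LR	35.32
RMG	7.73
SIA	25.58
ASG	39.42
CEP	16.85
AIB	5.76
DA	37.78
AWB	44.72
URY	22.48
RIC	31.01
PDA	59.73
ASEL	29.98
OLL	10.73
SAA	15.27
DB	34.03
ASER	87.19
OLQ	19.05
AVK	4.13
AS	19.04
ADF	77.80
IL1	32.00
DVC	36.16
PDB	8.43
AFD	148.39
AIN	42.26
AVJ	11.69
VA	54.20
AWC	114.14
AIM	12.75
PVT	30.11
VB	71.87
ASK	221.88
RIH	22.59
AVD	15.52
VD	52.25
ASH	70.08
URB	22.63
AVL	12.18
CAN	124.36
ADL	289.51
RIR	18.92
PVW	29.92
HSN	27.93
BAG	17.44
AIY	10.83
RIA	8.25
VC	20.47
URX	27.61
AIA	22.60
RIM	5.32
ALN	47.57
AUA	15.91
AVE	9.81
PLN	29.92
AIZ	9.92
RMF	18.69
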