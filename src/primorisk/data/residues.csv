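# Per-sample residue detections of the 83-sample strawberry monitoring
# campaign (mg/kg). Concentrations transcribe the campaign's published
# per-substance residue lists; the letter+number sample codes reproduce
# every assignment named in the report (non-compliant samples A5/S2/V1/I4,
# the 7-residue sample D2, pyrimethanil 2.000 in I5, fenpyroximate only in
# M3, lambda-cyhalothrin only in A7, tebufenpyrad 0.133 in D3, the
# tetraconazole+fenhexamid pair in E5, trifloxystrobin always jointly with
# fluopyram, difenoconazole always jointly with fluxapyroxad); remaining
# assignments are plausible reconstructions, since the full sample-level
# data were not deposited. Residue-free samples carry no rows; the
# campaign comprised 83 samples in total.
sample_id,pesticide,concentration_mg_kg
A5,Flupyradifurone,0.680
A5,Cyflumetofen,0.130
A5,Bupirimato,0.054
A5,Tetraconazolo,0.060
A5,Pirimentanil,0.160
A7,Lambda cialotrina,0.015
A7,Acetamiprid,0.012
S2,Cyflumetofen,0.627
S2,Bupirimato,0.130
S2,Spinosad,0.095
V1,Cyflumetofen,0.735
V1,Fluxapyroxad,0.480
V1,Difenconazolo,0.250
V1,Bupirimato,0.170
V1,Hexithiazox,0.037
I4,Spirotetrammato,0.340
I4,Fluopyram,0.014
I4,Cyflumetofen,0.100
I4,Etirimol,0.017
I4,Boscalid,0.012
I4,Pirimicarb,0.220
I5,Pirimentanil,2.000
I5,Bupirimato,0.350
D2,Fluopyram,0.110
D2,Pirimentanil,1.200
D2,Fluxapyroxad,0.650
D2,Difenconazolo,0.220
D2,Cyflumetofen,0.224
D2,Bupirimato,0.270
D2,Tetraconazolo,0.118
D3,Tebufenaprid,0.133
D3,Hexithiazox,0.075
E5,Tetraconazolo,0.100
E5,Fenhexamid,0.170
M3,Fenpyroximate,0.079
M3,Cyflumetofen,0.011
B1,Bupirimato,0.055
B1,Penconazolo,0.047
B1,Boscalid,0.080
B2,Bupirimato,0.062
B2,Penconazolo,0.022
B2,Fenhexamid,0.015
B3,Bupirimato,0.012
B3,Tetraconazolo,0.016
B3,Spinosad,0.012
B4,Bupirimato,0.220
B4,Pirimentanil,0.350
B4,Fenhexamid,0.161
B5,Bupirimato,0.075
B5,Etirimol,0.020
B5,Boscalid,0.130
B6,Bupirimato,0.096
B6,Tetraconazolo,0.012
B6,Spinosad,0.086
B7,Bupirimato,0.014
B7,Emamectina,0.013
F1,Fluopyram,0.100
F1,Trifloxystrobin,0.065
F1,Tetraconazolo,0.025
F2,Fluopyram,0.013
F2,Trifloxystrobin,0.010
F2,Clorantraniliprolo,0.010
F3,Fluopyram,0.031
F3,Trifloxystrobin,0.025
F3,Spinosad,0.015
F4,Fluopyram,0.035
F4,Trifloxystrobin,0.035
F4,Acetamiprid,0.033
F5,Fluopyram,0.077
F5,Trifloxystrobin,0.066
F5,Boscalid,0.054
F6,Fluopyram,0.116
F6,Trifloxystrobin,0.140
F6,Fenhexamid,0.051
F7,Fluopyram,0.200
F7,Trifloxystrobin,0.100
F7,Spinetoram,0.051
F8,Fluopyram,0.012
F8,Trifloxystrobin,0.013
X1,Fluxapyroxad,0.200
X1,Difenconazolo,0.070
X1,Etirimol,0.010
X2,Fluxapyroxad,0.500
X2,Difenconazolo,0.026
X2,Pirimentanil,0.085
X3,Fluxapyroxad,0.018
X3,Difenconazolo,0.010
X4,Fluxapyroxad,0.030
X4,Hexithiazox,0.050
X5,Fluxapyroxad,0.110
X5,Tetraconazolo,0.016
X6,Fluxapyroxad,0.150
X6,Boscalid,0.020
H1,Hexithiazox,0.020
H1,Spinosad,0.011
H2,Hexithiazox,0.010
H2,Emamectina,0.010
H3,Hexithiazox,0.072
H3,Tebufenaprid,0.023
H4,Hexithiazox,0.034
H4,Spinetoram,0.017
H5,Hexithiazox,0.012
H5,Clorantraniliprolo,0.012
G1,Cyflumetofen,0.256
G1,Cyflufenamid,0.015
G1,Fludioxonil,0.220
G2,Cyflumetofen,0.014
G2,Cyprodinil,0.260
G2,Penconazolo,0.052
G3,Fludioxonil,0.030
G3,Bifenazato,0.026
G3,Tebufenaprid,0.030
G4,Bifenazato,0.010
G4,Spirotetrammato,0.052
G4,Pirimicarb,0.090
G5,Captano,0.030
G5,Penthiopyrad,0.226
G5,Etirimol,0.054
G6,Penthiopyrad,0.021
G6,Azoxystrobin,0.012
G6,Emamectina,0.035
N1,Flupyradifurone,0.020
N1,Pirimentanil,0.011
N1,Spinosad,0.018
N2,Flupyradifurone,0.060
N2,Acetamiprid,0.013
K1,Penconazolo,0.018
K1,Tetraconazolo,0.018
L1,Etirimol,0.040
L1,Tetraconazolo,0.013
U1,Tebufenaprid,0.105
U1,Emamectina,0.031
W1,Fenhexamid,0.100
J1,Spinetoram,0.016
J1,Pirimicarb,0.047
J2,Spinetoram,0.039
J2,Pirimicarb,0.012
Y1,Cyflumetofen,0.023
Y2,Cyflumetofen,0.012
Y3,Cyflumetofen,0.013
Y4,Cyflumetofen,0.063
Y5,Cyflumetofen,0.070
Y6,Cyflumetofen,0.024
Y7,Cyflumetofen,0.034
Z1,Bifenazato,0.083
Z2,Bifenazato,0.080
Z3,Bifenazato,0.072
Z4,Bifenazato,0.012
Z5,Bifenazato,0.050
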