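# Regulatory reference values for the 31 active substances of the bundled
# monitoring campaign: class, EU Maximum Residue Limit for strawberries
# (mg/kg), Acute Reference Dose (mg/kg bw) and Acceptable Daily Intake
# (mg/kg bw/day). "-" = value not established by the authority.
#
# Transcription notes (source tables disagree in places; the value kept is
# the one arithmetically consistent with the campaign's printed acute and
# chronic results):
#   fenpyroximate: ARfD 0.02 (regulatory summary prints "-") and ADI 0.010
#     (regulatory summary prints 0.2); both taken from the exposure tables.
#   acetamiprid: ARfD 0.005 (narrative elsewhere cites 0.025).
#   spinetoram: ARfD 0.1 (narrative elsewhere cites 1).
#   spinosad: ADI 0.025 (regulatory summary prints 0.024).
#   ethirimol: ARfD and ADI both "Not applicable" per the regulatory summary.
pesticide,class,mrl_mg_kg,arfd_mg_kg_bw,adi_mg_kg_bw_day
hexythiazox,acaricide,6,-,0.03
cyflumetofen,acaricide,0.6,-,0.17
tebufenpyrad,acaricide,1,0.02,0.01
bifenazate,acaricide,3,0.1,0.01
fenpyroximate,acaricide,0.3,0.02,0.01
bupirimate,fungicide,1.5,-,0.05
fluxapyroxad,fungicide,4,0.25,0.02
difenoconazole,fungicide,2,0.16,0.01
cyflufenamid,fungicide,0.04,0.05,0.04
penconazole,fungicide,0.5,0.5,0.03
cyprodinil,fungicide,5,-,0.03
fludioxonil,fungicide,4,-,0.37
ethirimol,fungicide,0.3,Not applicable,Not applicable
pyrimethanil,fungicide,5,-,0.17
fluopyram,fungicide,2,0.5,0.012
trifloxystrobin,fungicide,1,0.5,0.1
tetraconazole,fungicide,0.15,0.05,0.004
boscalid,fungicide,6,-,0.04
fenhexamid,fungicide,10,-,0.2
captan,fungicide,1.5,0.9,0.25
penthiopyrad,fungicide,3,0.75,0.1
azoxystrobin,fungicide,10,-,0.2
spinosad,insecticide,0.3,-,0.025
chlorantraniliprole,insecticide,1,-,1.56
flupyradifurone,insecticide,0.4,0.15,0.064
lambda-cyhalothrin,insecticide,0.2,0.005,0.0025
spirotetramat,insecticide,0.3,1,0.05
spinetoram,insecticide,0.2,0.1,0.025
pirimicarb,insecticide,1.5,0.1,0.035
emamectin,insecticide,0.05,0.01,0.0005
acetamiprid,insecticide,0.5,0.005,0.005
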