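# Published per-substance summary of the 83-sample strawberry monitoring
# campaign: detection count, mean/min/max and total concentration (mg/kg)
# over the samples with a detection. Names appear in the mixed Italian/
# English spellings of the source report; loaders canonicalize them.
# For a few substances the published per-sample residue list is shorter
# than n_detect (the raw data were not deposited in full), so this summary
# is the authoritative input for composition shares and detection
# frequencies, while residues.csv carries the published per-sample values.
pesticide,class,n_detect,mean_mg_kg,min_mg_kg,max_mg_kg,total_mg_kg
Hexithiazox,acaricide,8,0.039,0.010,0.075,0.310
Cyflumetofen,acaricide,25,0.112,0.011,0.735,2.803
Tebufenaprid,acaricide,4,0.073,0.023,0.133,0.291
Bifenazato,acaricide,9,0.040,0.010,0.083,0.357
Fenpyroximate,acaricide,1,0.079,0.079,0.079,0.079
Bupirimato,fungicide,12,0.126,0.012,0.350,1.508
Fluxapyroxad,fungicide,8,0.267,0.018,0.650,2.138
Difenconazolo,fungicide,5,0.115,0.010,0.250,0.576
Cyflufenamid,fungicide,2,0.015,0.015,0.015,0.030
Penconazolo,fungicide,4,0.035,0.018,0.052,0.139
Cyprodinil,fungicide,1,0.260,0.260,0.260,0.260
Fludioxonil,fungicide,2,0.125,0.030,0.220,0.250
Etirimol,fungicide,6,0.025,0.010,0.054,0.151
Pirimentanil,fungicide,6,0.634,0.011,2.000,3.806
Fluopyram,fungicide,12,0.065,0.012,0.200,0.720
Trifloxystrobin,fungicide,9,0.052,0.010,0.140,0.464
Tetraconazolo,fungicide,13,0.034,0.012,0.118,0.437
Boscalid,fungicide,5,0.059,0.012,0.130,0.296
Fenhexamid,fungicide,5,0.099,0.015,0.170,0.497
Captano,fungicide,1,0.030,0.030,0.030,0.030
Penthiopyrad,fungicide,2,0.124,0.021,0.226,0.247
Azoxystrobin,fungicide,1,0.012,0.012,0.012,0.012
Spinosad,insecticide,9,0.030,0.011,0.095,0.273
Clorantraniliprolo,insecticide,3,0.011,0.010,0.012,0.034
Flupyradifurone,insecticide,4,0.195,0.020,0.680,0.780
Lambda cialotrina,insecticide,1,0.015,0.015,0.015,0.015
Spirotetrammato,insecticide,2,0.196,0.052,0.340,0.392
Spinetoram,insecticide,5,0.032,0.016,0.051,0.162
Pirimicarb,insecticide,4,0.092,0.012,0.220,0.369
Emamectina,insecticide,6,0.022,0.010,0.035,0.133
Acetamiprid,insecticide,3,0.019,0.012,0.033,0.058
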