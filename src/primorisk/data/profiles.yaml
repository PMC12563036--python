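# Consumption profiles for the single-commodity (strawberry) assessment.
# The default is the EFSA PRIMo v3.1 "NL toddler" subgroup (8-20 months),
# the most exposure-sensitive European subgroup per kg body weight.
# unit_weight_g below 25 g selects IESTI Case 1 (whole-unit commodities
# such as strawberries); the variability factor only enters Cases 2a/2b.
profiles:
  nl_toddler:
    label: NL toddler
    body_weight_kg: 10.20
    large_portion_g_day: 166.70
    mean_consumption_g_kgbw_day: 0.344
    unit_weight_g: 20.0
    processing_factor: 1.0
    conversion_factor: 1.0
    variability_factor: 1.0
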