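# Default domain weighting factors, from the staff-survey tiering of
# perceived domain importance (three tiers: 1.20 over-weighted, 1.00
# neutral, 0.75 under-weighted).
w1: 1.00   # attachment
w2: 0.75   # service density
w3: 1.20   # social and environmental factors
w4: 1.20   # psychosocial factors
w5: 0.75   # relationships
w6: 1.00   # activities of daily living
w7: 1.20   # medical complexity
w8: 0.75   # acute (hospital) utilization
w9: 1.00   # risk of harm to self or others
note: staff-survey three-tier weighting (defaults shipped with the package)
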