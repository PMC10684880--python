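scenario_id,scaled_fcs,heni_minutes
S1,65.46,60.21
S2M1,72.38,177.62
S2M2,70.90,177.01
S2M3,72.42,172.69
S3M1,72.48,176.45
S3M2,73.73,174.61
S3M3,72.81,172.55
S4M1,72.30,174.81
S4M2,73.08,173.52
S4M3,73.08,172.33
S5,71.79,168.06
S6M1,71.87,167.96
S6M2,73.38,169.84
S6M3,73.48,170.71
S7M1,73.77,181.73
S7M2,73.47,169.76
S7M3,73.44,170.50
S8M1,74.24,166.87
S8M2,73.46,169.65
S8M3,74.20,170.80
S9M1,73.16,171.55
S9M2,73.64,169.56
S9M3,74.13,169.21
S10,81.73,320.85
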