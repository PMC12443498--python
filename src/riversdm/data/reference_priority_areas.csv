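region,total_km2,inside_pa_km2,outside_pa_km2
entire_range,1319.12,144.55,1174.56
nepal,215.05,17.29,197.76
india,1013.63,126.5,887.14
bhutan,8.37,0.77,7.60
pakistan,71.89,0,71.89
bangladesh,10.17,0,10.17
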