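fatty_acid,Ascomycetes,Zygomycetes,Basidiomycetes,Actinobacteria,Firmicutes,Proteobacteria,Green algae,Cyanobacteria,Diatoms
12:00,0.06,0.03,0.04,0.01,0.05,0.03,,,
14:00,0.09,0.06,0.05,0.28,0.31,0.07,0.06,0.03,0.99
15:00,,,,0.11,0.1,0.02,,,
15:0 anteiso,,,,1.13,3.88,0.16,,,
15:0 iso,,,,0.78,2.25,0.1,,,
16:00,1,1,1,1,1,1,1,1,1
16:1ω7c,1.66,0.16,0.1,0.01,0.05,0.02,0.21,0.2,1.93
16:1ω9c,,,,,,,,0.29,0.02
16:2ω4,,,,,,,,,0.39
16:3ω4,,,,,,,,,0.69
17:00,0.04,0.03,0.03,0.04,0.02,0.02,,,
17:0 iso,,,,0.13,0.3,0.03,,,
18:00,0.24,0.2,0.17,0.07,0.06,0.05,0.09,0.05,0.07
18:1ω9c,2.87,1.98,1.1,0.64,0.04,0.01,0.3,0.38,0.07
18:1ω7c,0.13,0.09,0.11,,,,0.09,0.15,0.16
18:2ω6c,0.94,0.66,3.28,,,,0.38,0.45,0.08
18:3ω3,0.07,0.49,0.6,,,,2.27,0.83,0.03
20:5ω3,,,,,,,0.01,,1.76
22:6ω3,,,,,,,,,0.19
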