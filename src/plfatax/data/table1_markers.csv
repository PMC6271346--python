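fa_name,category,marker_of
16:1ω7c,MUFA,Bacteria; Bacillariophyceae (diatoms); Cyanophyceae (cyanobacteria); Prymnesiophyceae
16:1ω5c,MUFA,Mycorrhizal fungi
16:1ω8,MUFA,Type I methanotrophs (gamma-proteobacteria)
18:1ω9c,MUFA,Chlorophyceae (green algae); Cyanophyceae; Dinophyceae; Prymnesiophyceae; Gram-positive bacteria
18:1ω7c,MUFA,Bacillariophyceae; Cryptophyceae; Cyanophyceae; Prymnesiophyceae
18:1ω7t,MUFA,Gram-negative bacteria
18:1ω8,MUFA,Type II methanotrophs (alpha-proteobacteria)
3-OH 10:0,OH FA,Gram-negative bacteria
cy17:0,cyFA,Gram-negative bacteria; anaerobic bacteria
cy19:0,cyFA,Gram-negative bacteria; anaerobic bacteria
i-15:0,iso/anteiso FA,Gram-positive bacteria
a-17:0,iso/anteiso FA,Gram-positive bacteria
10-Me 16:0,10-Me FA,Actinomycetales (Actinobacteria)
16:2ω7,PUFA,Bacillariophyceae
16:2ω6,PUFA,Chlorophyta
16:2ω4,PUFA,Bacillariophyceae; Prasinophyceae
16:3ω4,PUFA,Bacillariophyceae
16:3ω3,PUFA,Chlorophyta
16:4ω3,PUFA,Chlorophyceae; Prasinophyceae
16:4ω1,PUFA,Bacillariophyceae (diatoms)
18:2ω6,PUFA,Chlorophyta; Cyanophyceae (freshwater); Dinophyceae; Prymnesiophyceae; Fungi
18:3ω6,PUFA,Cyanophyceae (freshwater); Saprophytic fungi
18:3ω3,PUFA,Chlorophyceae; Cryptophyceae; Cyanophyceae; Dinophyceae; Prasinophyceae; Prymnesiophyceae
18:4ω3,PUFA,Various algal groups
18:5ω3,PUFA,Dinophyceae
20:4ω6,PUFA,Bacillariophyceae; Rhodophyceae
20:5ω3,PUFA,Bacillariophyceae; Cryptophyceae; Dinophyceae; Pavlovophyceae; Rhodophyceae
22:5ω3,PUFA,Bacillariophyceae; Cryptophyceae; Prasinophyceae
22:6ω3,PUFA,Bacillariophyceae; Cryptophyceae; Dinophyceae; Haptophyta
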