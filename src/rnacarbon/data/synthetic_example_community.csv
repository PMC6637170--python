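taxon_id,name,relative_abundance
taxon_0003,synthetic organism 3,0.45839265693330167
taxon_0000,synthetic organism 0,0.29922069345695584
taxon_0005,synthetic organism 5,0.10481662980798734
taxon_0002,synthetic organism 2,0.06846228760363464
taxon_0001,synthetic organism 1,0.04038233925650645
taxon_0006,synthetic organism 6,0.02370612334787824
taxon_0004,synthetic organism 4,0.004489769747871118
taxon_0011,synthetic organism 11,0.0004096310474050147
taxon_0015,synthetic organism 15,0.00011845146478602768
taxon_0009,synthetic organism 9,1.4154237967070493e-06
taxon_0007,synthetic organism 7,1.909876861566981e-09
taxon_0010,synthetic organism 10,1.418929284906412e-17
taxon_0008,synthetic organism 8,2.3157751495498578e-22
taxon_0014,synthetic organism 14,4.8519494086384965e-26
taxon_0012,synthetic organism 12,5.540190711638703e-53
taxon_0020,synthetic organism 20,2.7084453901183433e-101
taxon_0016,synthetic organism 16,2.1205039516140165e-131
taxon_0013,synthetic organism 13,7.659862004392603e-142
taxon_0019,synthetic organism 19,2.5614316218019333e-154
taxon_0018,synthetic organism 18,8.908640221824259e-200
taxon_0022,synthetic organism 22,6.722660876466538e-243
taxon_0017,synthetic organism 17,3.430868132563e-312
taxon_0021,synthetic organism 21,0.0
taxon_0023,synthetic organism 23,0.0
taxon_0024,synthetic organism 24,0.0
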