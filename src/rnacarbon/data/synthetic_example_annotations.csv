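taxon_id,trophic_label,best_match_identity
taxon_0000,lithoautotroph,92.9
taxon_0001,heterotroph,96.6
taxon_0002,heterotroph,95.6
taxon_0003,heterotroph,97.8
taxon_0004,heterotroph,96.6
taxon_0005,lithoautotroph,94.1
taxon_0006,heterotroph,98.1
taxon_0007,lithoautotroph,91.7
taxon_0008,lithoautotroph,90.2
taxon_0009,heterotroph,90.9
taxon_0010,lithoautotroph,97.2
taxon_0011,heterotroph,94.6
taxon_0012,heterotroph,91.6
taxon_0013,heterotroph,95.0
taxon_0014,heterotroph,91.5
taxon_0015,heterotroph,97.0
taxon_0016,lithoautotroph,94.5
taxon_0017,lithoautotroph,93.8
taxon_0018,lithoautotroph,93.0
taxon_0019,lithoautotroph,96.3
taxon_0020,lithoautotroph,93.6
taxon_0021,heterotroph,90.9
taxon_0022,lithoautotroph,91.2
taxon_0023,lithoautotroph,99.6
taxon_0024,lithoautotroph,99.1
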