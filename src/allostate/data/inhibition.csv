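ligand_id,pct_inhibition
5,76.0
7,75.2
6,73.0
8,65.9
1,51.3
9,50.8
10,50.5
2,39.6
4,35.5
11,27.4
3,26.3
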