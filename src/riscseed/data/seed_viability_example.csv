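seed,viability,source
ACTGGG,37.6,published
GACTGG,28,published
ACAAAG,80,published
AATCTA,92.4,synthetic
AAAAAA,101.3,synthetic
AAACCC,88.0,synthetic
AAATTT,97.5,synthetic
ACGTAC,71.2,synthetic
ACGGGT,44.9,synthetic
AGGGGC,9.7,synthetic
ATATAT,99.1,synthetic
CAGTCA,68.3,synthetic
CCCCCC,31.0,synthetic
CCGGAA,52.6,synthetic
CGTACG,60.8,synthetic
CTGGGA,41.5,synthetic
GACTGA,55.4,synthetic
GCGCGC,18.2,synthetic
GGCAGT,35.7,synthetic
GGGGGC,4.1,synthetic
GGGGGG,2.0,synthetic
GTACGT,74.6,synthetic
TACGTA,83.9,synthetic
TAGCAT,90.2,synthetic
TCTAGA,86.1,synthetic
TGGAAT,63.4,synthetic
TGGTTT,95.0,synthetic
TTTAAA,102.8,synthetic
TTTTTT,104.5,synthetic
TTGCAA,79.3,synthetic
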