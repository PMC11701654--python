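assay	efo_id
sci-RNA-seq	EFO:0010550
10x 3' v1	EFO:0009901
10x 5' v1	EFO:0011025
10x 3' v2	EFO:0009899
10x 5' v2	EFO:0009900
10x 3' v3	EFO:0009922
10x 3' transcription profiling	EFO:0030003
10x 5' transcription profiling	EFO:0030004
10x technology	EFO:0008995
Seq-Well	EFO:0008919
Drop-seq	EFO:0008722
CEL-seq2	EFO:0010010
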