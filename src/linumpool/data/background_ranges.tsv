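fatty_acid	min_pct	max_pct
PAL	5	7.6
STE	2.7	6.4
OLE	12.9	24
LIO	11.9	72.4
LIN	2.7	65.3
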