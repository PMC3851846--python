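# extant adjacencies: tandem pair in A, conserved pair in B and in D
xA1	xA2
xB	yB
xD	yD
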