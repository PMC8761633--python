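key	score
GC/C./GC	1.00
GC/A./GC	0.40
GC/U./GC	0.70
GC/G./GC	0.20
GC/AU/GC	0.85
GC/UA/GC	0.30
GC/CG/GC	0.50
GC/GC/GC	0.55
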