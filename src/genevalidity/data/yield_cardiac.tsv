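gene	condition	substantial	yield_fraction
MYBPC3	HCM	True	0.40
MYH7	HCM	True	0.30
FHL1	HCM	False	0.01
DMD	DCM	True	0.08
MYH7	DCM	False	0.04
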