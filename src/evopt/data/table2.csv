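temperature_C,wb_percent,pH,activity
28,80,6,398.03
26,70,4,144.45
26,90,8,49.38
30,90,4,93.74
30,70,8,144.12
28,80,6,398.47
30,90,8,195.13
26,90,4,114.85
30,70,4,106.97
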