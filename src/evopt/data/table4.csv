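run_id,temperature_C,pH,wb_percent,cycle1,cycle2
A1,28,6,80,406.17,389.89
A2,26,4,70,158.97,129.93
A3,26,8,90,48.63,50.12
A4,30,4,90,88.80,98.69
A5,30,8,70,153.34,134.86
A6,28,6,80,412.79,384.16
A7,30,8,90,189.32,200.94
A8,26,4,90,107.69,122.02
A9,30,4,70,110.26,103.69
A10,26,8,70,99.30,110.53
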