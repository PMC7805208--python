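# Validation case 2: maize silage diluted with water
label: case2
composition: {MS: 0.5238, PM: 0.0, W: 0.4762}
Xc: 286.61
f_pr: 0.1105
f_li: 0.0547
f_ch: 0.6998
f_ine: 0.1360
F_IN: 87.5
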