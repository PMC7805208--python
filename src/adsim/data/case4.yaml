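# Validation case 4: maize silage diluted with pig manure
label: case4
composition: {MS: 0.5161, PM: 0.4839, W: 0.0}
Xc: 334.10
f_pr: 0.1268
f_li: 0.0496
f_ch: 0.5746
f_ine: 0.2497
F_IN: 87.5
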