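# Validation case 3: maize silage diluted with pig manure
label: case3
composition: {MS: 0.5082, PM: 0.4918, W: 0.0}
Xc: 331.95
f_pr: 0.1272
f_li: 0.0495
f_ch: 0.5721
f_ine: 0.2519
F_IN: 87.5
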