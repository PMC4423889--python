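probe_id	direction
ebv-miR-BART2-3p	down
ebv-miR-BART2-5p	up
ebv-miR-BART6-3p	up
ebv-miR-BART9	up
ebv-miR-BART15	up
ebv-miR-BHRF1-3	up
hsv1-miR-H1	up
hsv1-miR-H4-3p	down
kshv-miR-K12-7	up
hcmv-miR-US5-2	up
hcmv-miR-US33-3p	up
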