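alias	canonical
hsv1-miR-H1	hsv1-miR-H1-5p
hsv1-miR-H4-5p	hsv1-miR-H4-3p
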