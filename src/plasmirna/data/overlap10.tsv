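probe_id
hsa-miR-302c-3p
hsa-miR-592
hsa-miR-484
hsa-miR-1260a
hsa-miR-493-3p
hsa-miR-514a-3p
hsa-miR-145-5p
hsa-miR-30a-5p
hsa-miR-124-3p
hsa-miR-483-5p
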