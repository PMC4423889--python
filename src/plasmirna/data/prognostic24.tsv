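probe_id	direction
hsa-miR-101-3p	up
hsa-miR-1260a	up
hsa-miR-145-5p	up
hsa-miR-185-5p	up
hsa-miR-18a-5p	up
hsa-miR-1913	up
hsa-miR-29c-3p	up
hsa-miR-302c-3p	up
hsa-miR-30a-5p	up
hsa-miR-30d-5p	up
hsa-miR-30e-5p	up
hsa-miR-483-5p	up
hsa-miR-484	up
hsa-miR-493-3p	up
hsa-miR-525-3p	up
hsa-miR-548d-3p	up
hsa-miR-548d-5p	up
hsa-miR-566	up
hsa-miR-592	up
hsa-miR-620	up
hsa-miR-124-3p	down
hsa-miR-155-5p	down
hsa-miR-514a-3p	down
hsa-miR-653-5p	down
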