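probe_id	logfc	gbm_known	blood_cell
hsa-miR-383-5p	-1.85	0	0
hsa-miR-660-5p	-1.82	0	1
hsa-miR-103a-3p	-1.62	0	1
hsa-miR-503-5p	-1.55	0	1
hsa-miR-320a	-1.33	0	1
hsa-miR-579-3p	-1.32	0	0
hsa-miR-302c-3p	-1.23	1	0
hsa-miR-492	-1.10	0	0
hsa-miR-508-3p	-1.05	0	0
hsa-miR-148b-3p	-1.03	0	1
hsa-miR-649	-1.00	0	0
hsa-miR-10b-5p	1.12	1	0
hsa-miR-487b-3p	1.13	0	1
hsv1-miR-H1-5p	1.16	NA	0
hsa-miR-613	1.31	0	0
hsa-miR-122-5p	1.49	0	0
hsa-miR-142-3p	1.54	1	1
hsa-miR-193a-3p	2.37	1	1
hsa-miR-603	2.68	0	0
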