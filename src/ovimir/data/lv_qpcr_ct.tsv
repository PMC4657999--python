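panel	assay	ct	sd
novel	miR-146b-5p	33.129	0.398256617
novel	miR-151-5p	26.257	0.634608124
novel	miR-378-3p	20.907	0.181923092
novel	miR-423-5p	29.107	0.114140675
novel	miR-145-5p	27.725	0.284937142
novel	miR-222-3p	30.578	0.713898269
novel	miR-330-3p	30.898	0.977237439
novel	miR-324-5p	26.172	1.767929513
novel	miR-2285x-3p	28.181	0.25621647
novel	miR-4005-5p	28.181	0.25621647
novel	U6	25.338	0.144719684
known	miR-21-5p	26.25	0.221885857
known	miR-493-5p	34.25	0.41585374
known	miR-494-3p	21.73	1.291861135
known	miR-133-3p	14.44	2.278697632
known	U6	18.59	1.383107503
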