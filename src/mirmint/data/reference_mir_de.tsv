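mir	position	logfc_day0	logfc_day7	logfc_day14	p_day0	p_day7	p_day14
hsa-miR-378	Ch5q32	-0.938	-0.323	0.109	0.00015
hsa-miR-34a	Ch1p36	0.777	0.781	0.327	0.00177	0.00171
hsa-miR-1225-3p	Ch16p13	1.206	0.142	0.050	0.00193
hsa-miR-1305	Ch4q34	0.757	-0.965	1.750	0.00466	0.00108	0.00001
hsa-miR-1238	Ch19p13	0.969	0.627	-0.302	0.00593
hsa-miR-425*	Ch3p21	0.910	0.537	-0.199	0.00841
hsa-miR-191*	Ch3p21	1.027	0.553	-0.216	0.00859
hsa-miR-892b	ChXq27	0.176	-1.047	0.999		0.00006	0.00008
hsa-miR-139-3p	Ch11q13	0.024	-1.562	1.013		0.00017	0.00289
hsa-miR-500	ChXp11	0.008	-0.249	0.818			0.00066
hsa-miR-760	Ch1p22	-0.058	-0.251	0.737			0.00199
hsa-miR-1299	Ch9q21	-0.040	-0.260	0.778			0.00234
hsa-miR-342-3p	Ch14q32	-0.834	-0.808	-1.018			0.00428
hsa-miR-1181	Ch19p13	0.045	0.385	0.672			0.00473
hsa-miR-516a-5p	Ch19q13	-0.001	-0.049	0.512			0.00529
hsa-miR-1288	Ch17p11	0.575	-0.866	1.269			0.00547
hsa-miR-150*	Ch19q13	0.177	0.113	0.784			0.00663
hsa-miR-1914*	Ch20q13	0.276	-0.230	1.040			0.00669
hsa-miR-26b	Ch2q35	-0.433	-0.443	-0.687			0.00809
hsa-miR-520e	Ch19q13	0.036	0.231	0.610			0.00809
hsa-miR-202	Ch10q26	0.007	-0.255	0.607			0.00882
hsa-miR-1469	Ch15q26	-0.032	-0.146	0.579			0.00892
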