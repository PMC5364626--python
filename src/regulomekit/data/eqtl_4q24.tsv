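snp	position	fev1_pvalue	ints12_eqtl_fdr	ints12_effect	gstcd_eqtl_fdr	gstcd_effect
rs11732650	106973680	6.83E-09	0.000397993	-0.53	1	0
rs11722225	106985879	7.08E-09	0.000397993	-0.53	1	0
rs11726124	106985945	6.63E-09	0.000397993	-0.53	1	0
rs11728716	106975445	8.44E-09	0.000397993	-0.53	1	0
rs17036090	106813023	3.84E-08	0.000397993	-0.51	1	0.01
rs11735851	106916703	1.90E-09	0.000397993	-0.51	1	0.02
rs17036225	106929541	3.33E-09	0.000397993	-0.51	1	0.02
rs11736859	106928234	2.86E-09	0.000397993	-0.51	1	0.02
rs11727745	106935976	5.47E-09	0.000397993	-0.51	1	0.02
rs10516528	106959042	6.27E-09	0.000397993	-0.51	1	0.02
rs17036139	106852106	1.25E-09	0.000397993	-0.51	1	0.02
rs11727189	106838589	3.38E-09	0.000397993	-0.51	1	0.02
rs11731417	106965461	5.96E-09	0.000397993	-0.53	1	0
rs11733287	106924788	2.32E-09	0.000397993	-0.53	1	0
rs11728044	106824235	1.95E-09	0.000397993	-0.51	1	0.02
rs11733225	106924812	2.34E-09	0.000397993	-0.51	1	0.02
rs10516525	106887474	1.44E-09	0.000397993	-0.51	1	0.02
rs11724839	106857705	1.79E-09	0.000397993	-0.51	1	0.02
rs10516526	106908353	6.67E-10	0.000397993	-0.51	1	0.02
rs17036142	106854185	1.11E-09	0.000397993	-0.51	1	0.02
rs12374256	106836810	1.88E-09	0.000658031	-0.52	1	0.03
rs11097901	106949382	6.32E-09	0.000953622	-0.47	1	0.02
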