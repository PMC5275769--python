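gene	fold_change	tumor_level	nontumor_level	fdr
GSK3B	1.36	1929	1416	0.00082
NTRK2	0.29	416	1460	0.01
SH2B3	1.67	656	392	0.0016
NRAS	1.55	2175	1400	0.00001
CRKL	1.62	3560	2196	0.0000024
SORT1	0.37	1422	3810	0.0000001
BCL2	0.42	131	311	0.000013
MAP3K1	0.69	747	1076	0.0044
NGFRAP1	1.63	1564	958	0.000418
MAPK13	0.76	1579	2075	0.173
RPS6KA5	0.62	176	286	0.0005
TP53	0.69	966	1406	0.102
PLCG1	1.64	1409	862	0.0000001
PIK3CD	2.65	859	323	0.0000001
JUN	0.81	6250	7702	0.193
PIK3R3	0.59	385	650	0.0022
RPS6KA6	0.066	1.98	30	0.0000001
PIK3R1	0.42	851	2024	0.0000002
IRS1	1.86	1487	800	0.000447
PLCG2	1.3	407	313	0.0922
GAB1	0.69	595	868	0.00469
AKT3	1.52	292	192	0.034
PIK3CA	1.52	642	423	0.000438
SH2B1	0.69	617	891	0.00033
IRAK1	1.57	4523	2883	0.000008
ATF4	0.75	4968	6651	0.0015
MAP3K5	1.18	786	667	0.197
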