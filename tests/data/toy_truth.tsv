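probe	toy
P00001	0.0
P00002	0.0
P00003	0.0
P00004	1.176383
P00005	0.0
P00006	0.0
P00007	0.0
P00008	0.0
P00009	0.0
P00010	0.0
P00011	2.551673
P00012	0.0
P00013	1.206581
P00014	0.0
P00015	0.0
P00016	0.0
P00017	0.0
P00018	0.0
P00019	0.0
P00020	0.0
P00021	0.0
P00022	0.0
P00023	0.0
P00024	0.0
P00025	0.0
P00026	0.0
P00027	0.0
P00028	0.0
P00029	0.0
P00030	0.0
P00031	0.0
P00032	0.0
P00033	0.0
P00034	0.0
P00035	0.0
P00036	0.0
P00037	0.0
P00038	2.42756
P00039	0.0
P00040	0.0
P00041	2.985127
P00042	0.0
P00043	0.0
P00044	0.0
P00045	0.0
P00046	0.0
P00047	0.0
P00048	0.0
P00049	0.0
P00050	0.0
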