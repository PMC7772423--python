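family	gene	alias	name	fpkm_mock	fpkm_cln1	log2fc_printed	q
VGCC-aux-a2d	CACNA2D2	a2d-2	Calcium voltage-gated channel auxiliary subunit alpha2delta 2	132.30	61.13	-1.11	0.001
VGCC-aux-a2d	CACNA2D3	a2d-3	Calcium voltage-gated channel auxiliary subunit alpha2delta 3	1.86	7.11	1.94	0.001
VGCC-aux-gamma	CACNG2	gamma2	Calcium voltage-gated channel auxiliary subunit gamma 2	3.13	1.46	-1.10	0.037
VGKC-Kv	KCNA3	Kv1.3	Potassium voltage-gated channel subfamily A member 3	1.26	0.26	-2.25	0.002
VGKC-Kv	KCNB1	Kv2.1	Potassium voltage-gated channel subfamily B member 1	2.78	1.23	-1.18	0.001
VGKC-Kv	KCNH4	Kv12.3	Potassium voltage-gated channel subfamily H member 4	1.50	0.67	-1.16	0.006
VGKC-Kv	KCNH6	Kv11.2	Potassium voltage-gated channel subfamily H member 6	16.04	7.82	-1.04	0.001
VGKC-Kv	KCNQ3	Kv7.3	Potassium voltage-gated channel subfamily Q member 3	0.93	0.17	-2.46	0.001
VGKC-Kv	KCNQ5	Kv7.5	Potassium voltage-gated channel subfamily Q member 5	1.95	4.46	1.20	0.029
K2P	KCNK1	K2P1.1	Potassium two pore domain channel subfamily K member 1	19.93	7.27	-1.46	0.001
K2P	KCNK3	K2P3.1	Potassium two pore domain channel subfamily K member 3	6.84	3.13	-1.13	0.001
K2P	KCNK6	K2P6.1	Potassium two pore domain channel subfamily K member 6	1.82	0.86	-1.09	0.015
Kir	KCNJ2	Kir2.1	Potassium inwardly rectifying channel subfamily J member 2	2.14	0.71	-1.59	0.003
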