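# Synthetic recipe table shaped like a literature survey of IVT and
# Vaccinia-capping reaction buffers (11 IVT sources, 3 capping sources),
# on a 1x concentration basis in mM.  The IVT per-component medians are
# Tris-HCl 41.1, MgCl2 9.9, DTT 7.4, spermidine 1.8, NTPs 2.0; the capping
# recipes are identical across sources.  All source labels are invented.
source	reaction_type	component	concentration_mM
ivt01	IVT	Tris-HCl	10
ivt01	IVT	MgCl2	5
ivt01	IVT	DTT	1
ivt01	IVT	spermidine	1
ivt01	IVT	NTPs	0.5
ivt02	IVT	Tris-HCl	20
ivt02	IVT	MgCl2	6
ivt02	IVT	DTT	2
ivt02	IVT	spermidine	1
ivt02	IVT	NTPs	1
ivt02	IVT	NaCl	6
ivt03	IVT	Tris-HCl	30
ivt03	IVT	MgCl2	8
ivt03	IVT	DTT	5
ivt03	IVT	spermidine	1.5
ivt03	IVT	NTPs	1
ivt04	IVT	Tris-HCl	40
ivt04	IVT	MgCl2	9
ivt04	IVT	DTT	5
ivt04	IVT	spermidine	1.5
ivt04	IVT	NTPs	1.5
ivt04	IVT	Triton X-100	0.05
ivt05	IVT	Tris-HCl	40
ivt05	IVT	MgCl2	9.5
ivt05	IVT	DTT	6
ivt05	IVT	spermidine	1.75
ivt05	IVT	NTPs	2
ivt06	IVT	Tris-HCl	41.1
ivt06	IVT	MgCl2	9.9
ivt06	IVT	DTT	7.4
ivt06	IVT	spermidine	1.8
ivt06	IVT	NTPs	2
ivt07	IVT	Tris-HCl	42
ivt07	IVT	MgCl2	10
ivt07	IVT	DTT	10
ivt07	IVT	spermidine	2
ivt07	IVT	NTPs	2.5
ivt07	IVT	KCl	50
ivt08	IVT	Tris-HCl	50
ivt08	IVT	MgCl2	12
ivt08	IVT	DTT	10
ivt08	IVT	spermidine	2
ivt08	IVT	NTPs	4
ivt08	IVT	NaCl	10
ivt09	IVT	Tris-HCl	75
ivt09	IVT	MgCl2	15
ivt09	IVT	DTT	10
ivt09	IVT	spermidine	2
ivt09	IVT	NTPs	5
ivt10	IVT	Tris-HCl	80
ivt10	IVT	MgCl2	20
ivt10	IVT	DTT	10
ivt10	IVT	spermidine	2.5
ivt10	IVT	NTPs	7.5
ivt10	IVT	Triton X-100	0.05
ivt11	IVT	Tris-HCl	100
ivt11	IVT	MgCl2	25
ivt11	IVT	DTT	20
ivt11	IVT	spermidine	4
ivt11	IVT	NTPs	10
ivt11	IVT	Tween-20	0.1
cap01	capping	Tris-HCl	50
cap01	capping	MgCl2	1
cap01	capping	DTT	1
cap02	capping	Tris-HCl	50
cap02	capping	MgCl2	1
cap02	capping	DTT	1
cap03	capping	Tris-HCl	50
cap03	capping	MgCl2	1
cap03	capping	DTT	1
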