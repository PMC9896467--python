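method	E	GPCR	IC	NR
Bigram-PSSM	0.546	0.282	0.390	0.411
iDTI-ESBoost	0.680	0.500	0.480	0.701
NRLMF	0.892	0.749	0.906	0.701
BLM-NII	0.869	0.709	0.909	0.701
SPLCMF	0.881	0.754	0.938	0.533
WNN-GIP	0.706	0.520	0.717	0.589
NetLapRLS	0.786	0.617	0.820	0.463
SELF-BLM	0.639	0.599	0.744	0.457
SSELM-neg	0.982	0.991	0.982	0.946
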