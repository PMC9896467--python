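method	E	GPCR	IC	NR
Bigram-PSSM	0.948	0.872	0.889	0.869
iDTI-ESBoost	0.969	0.932	0.937	0.929
NRLMF	0.987	0.969	0.989	0.950
BLM-NII	0.985	0.966	0.984	0.917
SPLCMF	0.970	0.942	0.981	0.828
WNN-GIP	0.964	0.944	0.959	0.901
NetLapRLS	0.969	0.904	0.956	0.844
SELF-BLM	0.860	0.894	0.925	0.773
SSELM-neg	0.986	0.993	0.988	0.969
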