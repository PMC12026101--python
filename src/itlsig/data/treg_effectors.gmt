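TREG_DIRECT_EFFECTORS	curated direct immunosuppressive effector candidates expressed by regulatory T cells (editable)	CD274	PDCD1LG2	NT5E	ENTPD1	LGALS1	TGFB1	IL10	EBI3	IL12A	CTLA4	LAG3	TIGIT	GZMB	PRF1	FASLG	IDO1	IL2RA	FOXP3
TGFBR2_ITL	six-gene TGFBR2-induced immunosuppressive Treg-like signature	CD274	NT5E	ENTPD1	LGALS1	PDCD1LG2	TGFB1
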