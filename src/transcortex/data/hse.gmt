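HSE	human supragranular enriched genes	BEND5	C1QL2	CACNA1E	COL24A1	COL6A1	CRYM	KCNC3	KCNH4	LGALS1	MFGE8	NEFH	PRSS12	SCN3B	SCN4B	SNCG	SV2C	SYT2	TPBG	VAMP1
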