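# Paralogous marker families flanking the OVOL loci (genes absent from
# this map are treated as singleton families).
gene_id	family_id
BANF1	BANF
BANF2	BANF
SNX32	SNX
SNX5	SNX
AKT2a	AKT2
AKT2b	AKT2
OVOL1	OVOL
OVOL2	OVOL
OVOL3	OVOL
OVOL3b	OVOL
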