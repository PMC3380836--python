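# Gene-order cards for the published OVOL1/OVOL2/OVOL3(b) loci,
# transcribed from the figures of the source study. One row per gene;
# rank is the gene-order index on the contig; is_focal marks the focal
# position (an empty gene_id on a focal row marks a lost focal gene).
genome	contig	rank	gene_id	family_id	strand	is_focal
human	chr11	1	SIPA1	SIPA1	+	0
human	chr11	2	RELA	RELA	-	0
human	chr11	3	KAT5	KAT5	+	0
human	chr11	4	OVOL1	OVOL	-	1
human	chr11	5	SNX32	SNX	+	0
human	chr11	6	MUS81	MUS81	+	0
human	chr11	7	RIBP	RIBP	-	0
human	chr11	8	FOSL1	FOSL1	+	0
human	chr11	9	BANF1	BANF	+	0
mouse	chr19	1	SIPA1	SIPA1	+	0
mouse	chr19	2	RELA	RELA	-	0
mouse	chr19	3	KAT5	KAT5	+	0
mouse	chr19	4	OVOL1	OVOL	-	1
mouse	chr19	5	SNX32	SNX	+	0
mouse	chr19	6	MUS81	MUS81	+	0
mouse	chr19	7	RIBP	RIBP	-	0
mouse	chr19	8	FOSL1	FOSL1	+	0
mouse	chr19	9	BANF1	BANF	+	0
zebrafish	chr7	1	DYSF	DYSF	+	0
zebrafish	chr7	2	EXOC6B	EXOC6B	-	0
zebrafish	chr7	3	DAK	DAK	+	0
zebrafish	chr7	4	OVOL1	OVOL	+	1
zebrafish	chr7	5	MUS81	MUS81	+	0
zebrafish	chr7	6	COL4A5	COL4A5	-	0
human	chr20	1	RRBP1	RRBP1	+	0
human	chr20	2	BANF2	BANF	-	0
human	chr20	3	SNX5	SNX	-	0
human	chr20	4	OVOL2	OVOL	-	1
human	chr20	5	CSRP2BP	CSRP2BP	+	0
human	chr20	6	POLR3F	POLR3F	+	0
human	chr20	7	RBBP9	RBBP9	+	0
human	chr20	8	SEC23B	SEC23B	+	0
human	chr20	9	DTD1	DTD1	-	0
human	chr19	1	LIN37	LIN37	+	0
human	chr19	2	PRODH2	PRODH2	+	0
human	chr19	3	KIRREL2	KIRREL2	-	0
human	chr19	4	APLP1	APLP1	+	0
human	chr19	5	NFKBID	NFKBID	+	0
human	chr19	6	LRFN3	LRFN3	+	0
human	chr19	7	SDHAF1	SDHAF1	+	0
human	chr19	8	CLIP3	CLIP3	-	0
human	chr19	9	OVOL3	OVOL	+	1
human	chr19	10	POLR2I	POLR2I	+	0
human	chr19	11	CAPNS1	CAPNS1	+	0
human	chr19	12	COX7A1	COX7A1	-	0
mouse	chr7	1	LIN37	LIN37	+	0
mouse	chr7	2	PRODH2	PRODH2	+	0
mouse	chr7	3	KIRREL2	KIRREL2	-	0
mouse	chr7	4	APLP1	APLP1	+	0
mouse	chr7	5	NFKBID	NFKBID	+	0
mouse	chr7	6	LRFN3	LRFN3	+	0
mouse	chr7	7	SDHAF1	SDHAF1	+	0
mouse	chr7	8	CLIP3	CLIP3	-	0
mouse	chr7	9	OVOL3	OVOL	+	1
mouse	chr7	10	POLR2I	POLR2I	+	0
mouse	chr7	11	CAPNS1	CAPNS1	+	0
mouse	chr7	12	COX7A1	COX7A1	-	0
fugu	scaffold_orig	1	LIN37	LIN37	+	0
fugu	scaffold_orig	2	PRODH2	PRODH2	+	0
fugu	scaffold_orig	3	KIRREL2	KIRREL2	-	0
fugu	scaffold_orig	4	APLP1	APLP1	+	0
fugu	scaffold_orig	5			+	1
fugu	scaffold_orig	6	POLR2I	POLR2I	+	0
fugu	scaffold_orig	7	CAPNS1	CAPNS1	+	0
fugu	scaffold_orig	8	COX7A1	COX7A1	-	0
fugu	scaffold_orig	9	AKT2a	AKT2	+	0
fugu	scaffold_455	1	AMOT	AMOT	+	0
fugu	scaffold_455	2	HLCS	HLCS	+	0
fugu	scaffold_455	3	REXO2	REXO2	-	0
fugu	scaffold_455	4	DMPK	DMPK	+	0
fugu	scaffold_455	5	OVOL3b	OVOL	+	1
fugu	scaffold_455	6	AKT2b	AKT2	+	0
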