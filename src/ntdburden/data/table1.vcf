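##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=8>
##contig=<ID=10>
##contig=<ID=12>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript accession">
##INFO=<ID=CDNA,Number=1,Type=String,Description="HGVS cDNA change">
##INFO=<ID=PROT,Number=1,Type=String,Description="HGVS protein change">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=PPH2,Number=1,Type=String,Description="PolyPhen-2 category">
##INFO=<ID=PPH2_SCORE,Number=1,Type=String,Description="PolyPhen-2 score">
##INFO=<ID=AF_GNOMAD,Number=1,Type=String,Description="gnomAD allele frequency">
##INFO=<ID=AF_EXAC,Number=1,Type=String,Description="ExAC allele frequency">
##INFO=<ID=AF_EVS,Number=1,Type=String,Description="EVS allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Forward-strand read depth per allele">
##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Reverse-strand read depth per allele">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	F224_fa	F224_mo	F224_p1	F224_p2	3646_fa	3646_mo	3646_p1	3646_s1	3646_c1	25_fa	25_mo	25_p1	260_fa	260_mo	260_p1	270_fa	270_mo	270_p1	270_p2
1	11851333	.	G	A	.	.	GENE=MTHFR;TRANSCRIPT=NM_005957.4;CDNA=c.1683G>A;PROT=p.(Trp561Ter);CSQ_CLASS=stop_gained	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/1:99:32:11,6:10,5	0/1:99:28:10,5:9,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
8	12957469	.	C	T	.	.	GENE=DLC1;TRANSCRIPT=NM_006094.4;CDNA=c.1066C>T;PROT=p.(Gln356Ter);CSQ_CLASS=stop_gained	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:34:12,6:11,5	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
8	13357460	.	C	T	.	.	GENE=DLC1;TRANSCRIPT=NM_006094.4;CDNA=c.121C>T;PROT=p.(Gln41Ter);CSQ_CLASS=stop_gained	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/1:99:31:11,5:10,5	0/1:99:29:10,5:10,4	0/1:99:33:12,6:10,5	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
10	33197323	.	A	AA	.	.	GENE=ITGB1;TRANSCRIPT=NM_133376.2;CDNA=c.2303_2304insA;PROT=p.(Lys768fs);CSQ_CLASS=frameshift	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/1:99:31:11,6:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
12	99042236	.	G	GT	.	.	GENE=APAF1;TRANSCRIPT=NM_181868.1;CDNA=c.99_100insT;PROT=p.(Gly33fs);CSQ_CLASS=frameshift	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0
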