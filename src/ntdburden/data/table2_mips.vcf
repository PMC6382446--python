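##fileformat=VCFv4.2
##contig=<ID=15>
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
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	10179	10194	10278	10190	10322	20871	20785
15	59464211	.	A	G	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.A44G;PROT=p.(Asn15Ser);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.901;AF_EVS=0.0;AF_GNOMAD=2.031e-05	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
15	59464231	.	A	G	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.A49G;PROT=p.(Lys17Glu);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.85;AF_EVS=0.0;AF_GNOMAD=1.625e-05	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
15	59519705	.	G	T	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.G595T;PROT=p.(Val199Leu);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.848;AF_EVS=0.0;AF_GNOMAD=8.122e-06	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0
15	59519746	.	A	G	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.A554G;PROT=p.(Asp185Gly);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.866;AF_EVS=0.001157407;AF_GNOMAD=0.002103	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:32:11,6:10,5
15	59520001	.	C	T	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.900C>T;PROT=p.(Arg300Cys);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.95;AF_GNOMAD=0.052	GT:GQ:DP:ADF:ADR	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4
15	59521002	.	G	A	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.1200G>A;PROT=p.(Ala400Thr);CSQ_CLASS=missense;PPH2=benign;PPH2_SCORE=0.21;AF_GNOMAD=0.0007	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0
15	59564603	.	G	A	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.G2345A;PROT=p.(Arg782Gln);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.93;AF_EVS=0.0	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
15	59564608	.	A	G	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.A2365G;PROT=p.(Lys789Glu);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.925;AF_EVS=0.0;AF_GNOMAD=1.84e-05	GT:GQ:DP:ADF:ADR	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
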