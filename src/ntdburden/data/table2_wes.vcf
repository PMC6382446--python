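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
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	201	265	553	28	552	389	574
15	59453352	.	G	C	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.2705G>C;PROT=p.(Gly902Ala);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.993;AF_EVS=0.0	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4
15	59464193	.	G	A	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.2383G>A;PROT=p.(Gly795Arg);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.997;AF_EVS=7.7e-05;AF_GNOMAD=0.0005989	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0
15	59497622	.	C	G	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.1593C>G;PROT=p.(Ile531Met);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.988;AF_EVS=0.00648;AF_GNOMAD=0.007179	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/1:99:32:11,6:10,5	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
15	59506892	.	C	G	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.1135C>G;PROT=p.(His379Asp);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.982;AF_EVS=0.001543;AF_GNOMAD=0.00132	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4	0/1:99:28:10,5:9,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
15	59519746	.	A	G	.	.	GENE=MYO1E;TRANSCRIPT=NM_004998.3;CDNA=c.554A>G;PROT=p.(Asp185Gly);CSQ_CLASS=missense;PPH2=probably_damaging;PPH2_SCORE=0.99;AF_EVS=0.001157;AF_GNOMAD=0.002103	GT:GQ:DP:ADF:ADR	0/1:99:30:11,5:10,4	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0
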