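##fileformat=VCFv4.2
##contig=<ID=4>
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
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	25_fa	25_mo	25_p1
4	77356500	.	C	T	.	.	GENE=SHROOM3;TRANSCRIPT=NM_020859.4;CDNA=c.1320C>T;PROT=p.(Gln440Ter);CSQ_CLASS=stop_gained	GT:GQ:DP:ADF:ADR	0/0:99:30:15,0:15,0	0/0:99:30:15,0:15,0	0/1:99:30:11,5:10,4
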