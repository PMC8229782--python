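# Genotype counts for seven index SNPs genotyped individually in a Polish
# colorectal-cancer case-control verification cohort (465 cases, ~1079 controls;
# per-SNP totals differ slightly through missing calls). m = minor allele.
snp_id	region	minor_allele	major_allele	case_mm	case_mM	case_MM	ctrl_mm	ctrl_mM	ctrl_MM
rs17575184	1p31.1 NEGR1 intron	A	G	1	58	406	11	210	852
rs10935945	3q25.2 LINC02006 intron	T	C	117	244	103	195	516	363
rs10838094	11p15.4 OR51B5 intron	A	G	92	238	134	97	251	189
rs12424924	12p12.1 PYROXD1 intron	A	G	16	133	311	25	173	346
rs11060839	12q24.33 PIWIL1 intron	A	G	21	152	287	27	278	760
rs9927668	16p13.2 intergenic	C	T	46	193	222	179	482	412
rs12935896	17q23.2 BCAS3 intron	C	T	21	152	292	68	409	594
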