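snp_id	chrom	pos	minor_allele	major_allele	case_hom_minor	case_het	case_hom_major	control_hom_minor	control_het	control_hom_major	case_missing	control_missing
rs879215	18	40557661	T	C	19	207	762	58	704	1759	0	0
rs4243267	18	40656531	G	T	99	427	462	340	1184	997	0	0
rs4441358	18	40657643	G	A	97	428	463	340	1182	999	0	0
rs4536548	18	40659924	A	G	99	428	461	340	1184	997	0	0
rs4130047	18	40678235	C	T	176	477	335	330	1172	1018	0	1
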