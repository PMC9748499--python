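# source: conformance fixture
# seed: 0
transcript_id	snp_id	replicate_id	tissue	genotype_sampled	total_reads	distal_reads
AT1G00010	AT1G00010_s0	r1	scion	A	120	2
AT1G00010	AT1G00010_s0	r2	scion	A	98	0
AT1G00010	AT1G00010_s1	r1	scion	A	120	1
AT1G00010	AT1G00010_s1	r2	scion	A	101	3
AT2G00020	AT2G00020_s0	r1	scion	A	55	12
AT2G00020	AT2G00020_s0	r2	scion	A	61	9
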