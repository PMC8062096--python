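# Gapped/ungapped Karlin parameters for common BLAST scoring schemes,
# transcribed from NCBI's published parameter tables.
# For nucleotide programs the "matrix" column carries the match reward and
# "mismatch" the penalty; for protein matrices mismatch is ".".
# gap_open = gap_extend = 0 denotes ungapped (linear) scoring.
program	matrix	mismatch	gap_open	gap_extend	lambda	K	H	alpha	beta
blastn	2	-3	5	2	0.625	0.41	0.78	0.8	-2
blastn	1	-2	0	0	1.28	0.46	0.85	1.5	-2
blastp	BLOSUM62	.	11	1	0.267	0.041	0.14	1.9	-30
blastp	BLOSUM62	.	0	0	0.3176	0.134	0.4012	0.7916	-3.2
tblastx	2	-3	5	2	0.625	0.41	0.78	0.8	-2
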