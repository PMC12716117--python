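# Curated prohormone processing-product regions, 1-based inclusive residue
# coordinates on the full precursor (first residue of the signal peptide = 1).
# Note: GRPP is stored as 18-52 (the boundary used for regional trend counting);
# the canonical mature GRPP peptide is GCG 21-50 and is contained in this interval.
gene	region	first_aa	last_aa
GCG	GRPP	18	52
GCG	glucagon	53	81
GCG	oxyntomodulin	53	89
GCG	glicentin	21	89
GCG	GLP-1	98	128
GCG	major proglucagon fragment	92	178
INS	B chain	25	54
INS	C peptide	57	87
INS	A chain	90	110
CHGA	vasostatin-1	19	94
CHGA	vasostatin-1/2	19	131
CHGA	EA-92	134	225
CHGA	LF-19/catestatin	358	390
CHGA	GR-44	413	456
SST	somatostatin-14	103	116
SST	somatostatin-28	89	116
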