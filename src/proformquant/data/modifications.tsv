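# Modification delta-mass table. delta_da is derived from the elemental formula
# (monoisotopic); observed_da, where given, is the empirically reported shift for
# tentative assignments and takes precedence when matching observed mass shifts.
# formula syntax: space-separated element+signed count, e.g. "O1 H-2".
name	delta_da	formula	observed_da	sites
Met-loss	-131.04052	C-5 H-9 N-1 O-1 S-1		N-term
Acetyl	42.01057	C2 H2 O1		N-term
Acetyl (K)	42.01057	C2 H2 O1		K
Amidated	-0.98401	H1 N1 O-1		C-term
Carbamyl	43.00581	C1 H1 N1 O1		N-term
Carbamyl (K)	43.00581	C1 H1 N1 O1		K
Deamidated	0.98401	H-1 N-1 O1		N,Q
Methyl	14.01566	C1 H2		K,R
Dimethyl	28.03132	C2 H4		K,R
Cation:Fe[III]	52.91145	Fe1 H-3		D,E
Phospho	79.96632	H1 O3 P1		S,T,Y
Gln->pyro-Glu	-17.02656	H-3 N-1		N-term Q
Glu->pyro-Glu	-18.01057	H-2 O-1		N-term E
Oxidation	15.99491	O1		C,M,W
Dioxidation	31.98982	O2		C,M,W
Carbonyl	13.97925	O1 H-2	13.98	any
Allysine	-1.03165	O1 N-1 H-3	-1.03	K
Leu/Ile->Ala	-42.04698	C-3 H-6	-42.01	L,I
His->Ala	-66.02180	C-3 H-2 N-2	-66.01	H
Hex(2)HexNAc(1)NeuGc(3)	1448.45622	C53 H84 N4 O42	1448.66	S,T
Lysinylation	128.09501	C6 H12 N2 O1	128.08	N-term
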