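enzyme	recognition
AgeI	ACCGGT
ApaI	GGGCCC
AscI	GGCGCGCC
AvrII	CCTAGG
BamHI	GGATCC
BglII	AGATCT
BsrGI	TGTACA
EcoRI	GAATTC
EcoRV	GATATC
HindIII	AAGCTT
KpnI	GGTACC
MluI	ACGCGT
NcoI	CCATGG
NdeI	CATATG
NheI	GCTAGC
NotI	GCGGCCGC
PacI	TTAATTAA
PstI	CTGCAG
SacI	GAGCTC
SalI	GTCGAC
SbfI	CCTGCAGG
SmaI	CCCGGG
SpeI	ACTAGT
SphI	GCATGC
XbaI	TCTAGA
XhoI	CTCGAG
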