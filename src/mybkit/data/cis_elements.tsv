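name	iupac_pattern	category
ABRE	ACGTGGC	hormone-responsive
TGACG-motif	TGACG	hormone-responsive
CGTCA-motif	CGTCA	hormone-responsive
GARE-motif	TCTGTTG	hormone-responsive
TCA-element	CCATCTTTTT	hormone-responsive
MBS	CAACTG	stress-responsive
LTR	CCGAAA	stress-responsive
TC-rich-repeats	ATTTTCTTCA	stress-responsive
DRE-core	RCCGAC	stress-responsive
W-box	TTGACC	stress-responsive
TATA-box	TATAWAW	core-promoter
CAAT-box	CCAAT	core-promoter
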