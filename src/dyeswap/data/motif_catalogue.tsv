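# Small editable catalogue of plant cis-regulatory elements (IUPAC patterns).
name	pattern
ACGT element, G-box	CACGTG
CRT/DRE-like motif	DRCCGACNW
Coupling element 3-like	ACGCGTGTCCTC
TCA1MOTIF-like	TCATCTTCTT
ATHB6COREAT	CAATTATTA
PIATGAPB	GTGATCAC
ABRE-like	ACGTGKC
Evening element	AAAATATCT
W-box	TTGACC
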