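name	pattern	category	note
AE-box	AGAAACAA	light	Part of a module for light response
ARE	TGGTTT	stress	Cis-acting regulatory element essential for the anaerobic induction
Box 4	ATTAAT	light	Part of a conserved DNA module involved in light responsiveness
C-box	CTGACGTCAG	light	Cis-acting regulatory element involved in light responsiveness
G-box	CACGAC	light	Cis-acting regulatory element involved in light responsiveness
GAG-motif	AGAGAGT	light	Part of light responsive element
GARE-motif	AAACAGA	hormone	Gibberellin-responsive element
Gap-box	AAATGGAGA	light	Part of light responsive element
LAMP-element	CCAAAACCA	light	Part of light responsive element
MBS	CAACTG	stress	MYB binding site involved in drought-inducibility
Sp1	CC(G/A)CCC	light	Light responsive element
TATC-box	TATCCCA	hormone	Cis-acting element involved in gibberellin-responsiveness
TCA-element	CCATCTTTTT	hormone	Cis-acting element involved in salicylic acid responsiveness
TCT-motif	TCTTAC	light	Part of light responsive element
Circadian	CAANNNNATC	other	Cis-acting regulatory element involved in circadian control
ABRE	TACGTG	hormone	Cis-acting element involved in the abscisic acid responsiveness
C-repeat/DRE	TGGCCGAC	stress	Regulatory element involved in cold- and dehydration responsiveness
CATT-motif	GCATTC	light	Part of a light responsive element
GC-motif	CCCCCG	stress	Enhancer-like element involved in anoxic specific inducibility
HSE	AAAAAATTTC	stress	Cis-acting element involved in heat stress responsiveness
I-box	GATATGG	light	Part of light responsive element
MNF1	GTGCCC(A/T)	light	Light responsive element
P-box	CCTTTTG	hormone	Gibberellin-responsive element
TC-rich repeats	ATTTTCTTCA	stress	Cis-acting element involved in defense and stress responsiveness
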