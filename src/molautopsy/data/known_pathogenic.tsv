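gene	hgvs_c	phenotype
RYR2	c.7601T>C	CPVT
SCN9A	c.2971G>T	Epilepsy
SCN10A	c.742G>C	BrS
HCN4	c.2275G>A	BrS
MYH7	c.4377G>T	HCM
PKP2	c.1132C>T	ARVC/D
TTR	c.424G>A	Amyloidosis
TRPM4	c.1575G>A	Progressive familial heart block
AKAP9	c.11272C>T	LQTS
MYH6	c.3010G>T	HCM
THBD	c.302G>T	Thrombophilia
DSP	c.268C>T	ARVC/D
RYR2	c.9673G>A	CPVT
TRPM4	c.1697C>T	Progressive familial heart block
SCN10A	c.3704C>T	BrS
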