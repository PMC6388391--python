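#version sre-lite-1
# Simplified splicing-regulatory-element library: consensus-derived
# enhancer weight matrices (rows A/C/G/T) and silencer hexamer words.
# Synthetic in-package approximation; not a replica of any external predictor.
WORDS	ESS_hex
TAGGGT
TAGGGA
TCCTCC
CCTCCC
GTAGGT
TGTAGG
TTCTCT
TCTCTC
GGGTGG
GGTGGG
MATRIX	SRSF1_like	5.2
A	0.55	1.00	1.00	0.55	1.00	1.00	0.55
C	0.10	0.10	0.10	0.10	0.10	0.10	0.10
G	1.00	0.55	0.55	1.00	0.55	0.55	1.00
T	0.10	0.10	0.10	0.10	0.10	0.10	0.10
MATRIX	SRSF2_like	6.2
A	1.00	0.55	0.55	1.00	0.55	0.55	1.00	0.10
C	0.10	0.10	0.10	0.10	0.10	0.10	0.10	1.00
G	0.55	1.00	1.00	0.55	1.00	1.00	0.55	0.10
T	0.10	0.10	0.10	0.10	0.10	0.10	0.10	0.55
MATRIX	SRSF5_like	5.2
A	1.00	0.10	1.00	1.00	0.55	1.00	1.00
C	0.10	1.00	0.10	0.10	0.10	0.10	0.10
G	0.55	0.10	0.55	0.55	1.00	0.55	0.55
T	0.10	0.55	0.10	0.10	0.10	0.10	0.10
MATRIX	SRSF6_like	4.65
A	0.10	0.55	0.10	0.55	0.10	0.10
C	0.55	0.10	1.00	0.10	0.55	1.00
G	0.10	1.00	0.10	1.00	0.10	0.10
T	1.00	0.10	0.55	0.10	1.00	0.55
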