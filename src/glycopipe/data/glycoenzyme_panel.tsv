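# curated glycobiogenesis enzyme panel: per-protein TM counts,
# stoichiometry-normalized spectra, detected glycosites and putative sequons
gene_id	symbol	family	tm_count	protein_spectra	detected_glycosites	putative_sequons
108105	B3gnt5	transferase	1	2.0	1	4
54616	Extl3	transferase	1	2.0	1	4
320011	Ugcgl1	transferase	0	9.0	1	3
99151	Cercam	transferase	0	3.0	1	4
68292	Stt3b	transferase	10	5.0	1	6
223827	Glt8d3	transferase	1	5.0	1	3
103963	Rpn1	transferase	1	6.0	1	2
234407	Glt25d1	transferase	0	24.0	1	3
56386	B4galt6	transferase	1	4.0	1	9
12182	Bst1	hydrolase	1	3.0	1	4
14387	Gaa	hydrolase	1	7.5	4	7
14667	Gm2a	hydrolase	0	2.0	1	1
110006	Gusb	hydrolase	1	1.5	2	4
17159	Man2b1	hydrolase	0	2.0	3	11
14466	Gba	hydrolase	0	31.0	2	5
17939	Naga	hydrolase	0	2.5	2	3
100340	Smpdl3b	hydrolase	0	5.5	2	5
12494	Cd38	hydrolase	1	21.0	4	4
11605	Gla	hydrolase	1	7.0	1	3
17156	Man1a2	hydrolase	1	3.0	1	1
17158	Man2a1	hydrolase	1	2.0	3	3
66967	Edem3	hydrolase	1	15.0	1	7
15587	Hyal2	hydrolase	0	18.0	3	5
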