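lipid_class	category	n_chains	ether
CE	sterols	1	0
Cer	sphingolipids	2	0
HexCer	sphingolipids	2	0
SM	sphingolipids	2	0
DAG	glycerolipids	2	0
TAG	glycerolipids	3	0
CL	glycerophospholipids	4	0
PA	glycerophospholipids	2	0
PC	glycerophospholipids	2	0
PE	glycerophospholipids	2	0
PG	glycerophospholipids	2	0
PI	glycerophospholipids	2	0
PS	glycerophospholipids	2	0
PC O-	glycerophospholipids	2	1
PE O-	glycerophospholipids	2	1
LPA	glycerophospholipid intermediates	1	0
LPC	glycerophospholipid intermediates	1	0
LPE	glycerophospholipid intermediates	1	0
LPG	glycerophospholipid intermediates	1	0
LPI	glycerophospholipid intermediates	1	0
LPS	glycerophospholipid intermediates	1	0
LPC O-	glycerophospholipid intermediates	1	1
LPE O-	glycerophospholipid intermediates	1	1
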