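# Predication counts per KEGG Pathways-in-Cancer component pathway at each
# filtering stage of the literature-mining pipeline (raw extraction, argument
# distance <=1, duplicate removal, symbol normalization, document frequency >=2).
pathway	citations	raw	dist	uniq	norm	freq
p53	5726	14085	3747	2771	1287	155
Apoptosis	13797	27421	6183	5028	1382	93
Cell Cycle	40328	96696	26944	21367	7825	822
PPAR	7701	6730	1708	1388	298	14
VEGF	6102	7875	2416	1940	609	62
MAPK	41455	84611	23341	18639	5859	538
Wnt	2236	2013	685	581	181	8
TGF-beta	14868	23803	7136	5427	1620	126
mTOR	2447	2952	857	740	175	4
Jak-STAT	1121	3193	868	741	275	14
ErbB	4400	7947	2162	1864	710	67
Adherens Junction	6397	6616	1673	1334	275	3
Focal Adhesion	1169	2227	563	510	91	0
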