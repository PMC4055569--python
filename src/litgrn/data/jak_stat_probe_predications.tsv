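# Three Jak-STAT predications that correspond to KEGG-curated interactions but
# are removed by the filtering pipeline: the first by the argument-distance
# filter, the other two (each asserted in a single citation) by the
# document-frequency filter.
pmid	subject	predicate	object	subject_distance	object_distance
9000001	Jak1	INTERACTS_WITH	PTPN11	1	2
9000002	Jak1	INTERACTS_WITH	STAT1	1	1
9000003	GRB2	INTERACTS_WITH	PTPN11	1	1
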