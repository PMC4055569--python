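# Manual literature validation counts for the 92 novel (non-KEGG) interactions
# in the inferred p53 network, and for the 38 interactions with |weight| > 0.1.
group	validation_type	count	total
all	interaction_stated	72	92
all	no_interaction_stated	20	92
all	correct_sign	75	92
all	inverse_sign	17	92
all	correct_sign_and_interaction	55	92
all	wrong_sign_or_interaction	37	92
weighted	interaction_stated	32	38
weighted	no_interaction_stated	6	38
weighted	correct_sign	34	38
weighted	inverse_sign	4	38
weighted	correct_sign_and_interaction	28	38
weighted	wrong_sign_or_interaction	10	38
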