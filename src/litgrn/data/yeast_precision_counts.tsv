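# Yeast cell-cycle network precision against a BioGRID interaction set,
# at increasing absolute-weight thresholds.
weight_threshold	pred_genes	pred_edges	found_genes	found_edges
0	349	520	346	147
0.001	349	300	346	90
0.01	349	244	346	72
0.1	349	67	346	21
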