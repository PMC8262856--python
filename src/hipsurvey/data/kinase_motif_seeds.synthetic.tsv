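# Synthetic seed-alignment blocks for the four canonical Hanks-type kinase
# motifs (Gly-rich loop, activation loop, catalytic motif, Mg-binding motif).
# These are constructed fixtures using standard eukaryotic-protein-kinase
# motif vocabulary, not sequences extracted from any published alignment;
# replace with your own seed blocks for real surveys.
# Columns: motif_name <TAB> seed_sequence.  Threshold lines: !threshold <TAB> motif <TAB> bits
!threshold	gly_rich_loop	10.0
!threshold	activation_loop	10.0
!threshold	catalytic_motif	10.0
!threshold	mg_binding_motif	10.0
gly_rich_loop	GTGSFGTV
gly_rich_loop	GTGSFGTV
gly_rich_loop	GSGSFGTV
gly_rich_loop	GTGAFGTV
gly_rich_loop	GTGSFGKV
gly_rich_loop	GTGSYGTV
activation_loop	TEYMAPEV
activation_loop	TEYMAPEV
activation_loop	TEYVAPEV
activation_loop	SEYMAPEV
activation_loop	TEYMAPEI
activation_loop	TDYMAPEV
catalytic_motif	HRDLKPEN
catalytic_motif	HRDLKPEN
catalytic_motif	HRDLKPQN
catalytic_motif	HRDIKPEN
catalytic_motif	HGDLKPEN
catalytic_motif	HRDLKPEN
mg_binding_motif	DFGLAKAE
mg_binding_motif	DFGLAKAE
mg_binding_motif	DFGLSKAE
mg_binding_motif	DFGIAKAE
mg_binding_motif	DFGLAKSE
mg_binding_motif	DFGLARAE
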