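# Synthetic stand-in for the human HLTF HIRAN reference domain used as the
# coordinate system for DNA-binding motif conservation scoring.  The real
# HLTF HIRAN domain (PDB 4XZF) defines four short DNA-binding sequence
# motifs plus a duplex-DNA-stacking Phe in the NAF motif; here a
# constructed 100-residue reference embeds the packaged HIRAN profile
# consensus (residues 9-38) and places four analogous motif windows, with
# the Phe of the NAF window marked.  Replace with a real reference
# alignment for genuine HLTF-coordinate analyses.
!reference	hltf_hiran_synthetic
!sequence	MARLVDTNQVELLGSNGQRFEVPNSAFVHLVNAGKVKLSQENAFKDGTRLNLHRSDLEKVTGWKLVARNPENAGRVYTQEWTSDLMKHGVDERLSAQWTN
# motif windows: !motif <TAB> name <TAB> start <TAB> end (1-based inclusive on the reference)
!motif	m1_ssdna	9	18
!motif	m2_loop	24	31
!motif	naf	40	48
!motif	m4_pocket	63	71
# NAF-motif phenylalanine column (1-based reference residue)
!naf_phe	44
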