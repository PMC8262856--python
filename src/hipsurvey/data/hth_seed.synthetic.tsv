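# Synthetic seed block for the 22-position helix-turn-helix weight matrix
# (Dodd & Egan style window scan).  The published matrix values are not
# freely redistributable, so this package ships a constructed stand-in
# built from canonical HTH vocabulary; replace the file to use a real
# calibrated matrix.  Calibration of the call threshold uses a fixed
# random-sequence ensemble (seed recorded below).
# Columns: hth <TAB> seed_sequence (length 22)
!calibration_seed	20210
!calibration_n	5000
hth	GLSQEELAEKVGVSQSTISRWE
hth	GLSQEELAEKVGVSQSTISRWE
hth	GLSQEELADKVGVSQSAISRWE
hth	GLSQSELAEKVGVSQSTISNWE
hth	GLTQEELAEKVGVSQPTISRWE
hth	GLSQEELAEKIGVSQSTVSRWE
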