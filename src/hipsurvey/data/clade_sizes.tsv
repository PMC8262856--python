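# Published clade summary of the 1,239-kinase Hip tree survey:
# main clade, number of kinase genes, TA gene organization(s).
clade	n_kinases	organizations
I	712	hipBA
II	73	hipBA
III	48	hipBST
IV	14	hipBA
V	9	hipBA
VI	36	hipBA
VII	132	hipBA,hipAB
VIII	21	hipBA
IX	12	hipEB
X	101	hipH_mono
XI	81	hipRF,hipRG,hipMP,hipL_mono,hipIN,hipJS
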