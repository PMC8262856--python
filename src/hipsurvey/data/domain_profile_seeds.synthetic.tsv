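# Synthetic seed-alignment blocks for antitoxin / kinase-internal domain
# profiles: HipS-like, Stl-like, gamma-delta-resolvase-like and HIRAN.
# Constructed fixtures (the published survey identified these domains by
# structure-prediction servers whose models are not distributable); the
# resolvase block borrows serine-recombinase motif vocabulary.  Replace
# with curated seed blocks for real surveys.
# Columns: domain <TAB> seed_sequence.  Threshold lines: !threshold <TAB> domain <TAB> bits
!threshold	HipS_like	45.0
!threshold	Stl_like	45.0
!threshold	resolvase_like	45.0
!threshold	HIRAN	45.0
HipS_like	KVWEFRHNDALVGTLSYDPEAGRWLIAPQM
HipS_like	KVWEFRHNDALVGTLSYDPEAGRWLIAPQM
HipS_like	KVWEYRHNDALVGTLSYDPEAGKWLIAPQM
HipS_like	KVWEFRHNDSLVGTLAYDPEAGRWLIAPQM
HipS_like	RVWEFRHNDALVGTLSYDPEAGRWLIVPQM
Stl_like	MNTYGERLKALMDESGLSQRELARQVNIPQ
Stl_like	MNTYGERLKALMDESGLSQRELARQVNIPQ
Stl_like	MNTYGDRLKALMDESGLSQRELSRQVNIPQ
Stl_like	MNTYGERLRALMDEAGLSQRELARQVNIPQ
Stl_like	MNSYGERLKALMDESGLSQKELARQVNIPQ
resolvase_like	RVFGYARVSTDDQNLDLQRDALTKAGCEKI
resolvase_like	RVFGYARVSTDDQNLDLQRDALTKAGCEKI
resolvase_like	RVFGYARVSTDDQNLELQRDALTKAGCDKI
resolvase_like	RIFGYARVSTDDQNLDLQRNALTKAGCEKI
resolvase_like	RVFGYGRVSTDDQNLDLQRDALSKAGCEKI
HIRAN	QVELLGSNGQRFEVPNSAFVHLVNAGKVKL
HIRAN	QVELLGSNGQRFEVPNSAFVHLVNAGKVKL
HIRAN	QVELLGSNGERFEVPNSAFVHLINAGKVKL
HIRAN	QVEMLGSNGQRFEVPNTAFVHLVNAGKVKL
HIRAN	QVELLGANGQRFEVPNSAFVHLVNAGRVKL
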