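#symbol	mark	role
DNMT1	5mc	writer
DNMT3A	5mc	writer
DNMT3B	5mc	writer
TET1	5mc	eraser
TET2	5mc	eraser
TET3	5mc	eraser
MBD1	5mc	reader
MBD2	5mc	reader
MBD3	5mc	reader
MBD4	5mc	reader
MECP2	5mc	reader
NEIL1	5mc	reader
NTHL1	5mc	reader
SMUG1	5mc	reader
TDG	5mc	reader
UHRF1	5mc	reader
UHRF2	5mc	reader
UNG	5mc	reader
ZBTB33	5mc	reader
ZBTB38	5mc	reader
ZBTB4	5mc	reader
METTL3	m6a	writer
METTL14	m6a	writer
WTAP	m6a	writer
VIRMA	m6a	writer
RBM15	m6a	writer
RBM15B	m6a	writer
ZC3H13	m6a	writer
CBLL1	m6a	writer
FTO	m6a	eraser
ALKBH5	m6a	eraser
YTHDC1	m6a	reader
YTHDC2	m6a	reader
YTHDF1	m6a	reader
YTHDF2	m6a	reader
YTHDF3	m6a	reader
IGF2BP1	m6a	reader
IGF2BP2	m6a	reader
IGF2BP3	m6a	reader
HNRNPA2B1	m6a	reader
HNRNPC	m6a	reader
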