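# Modified-ribonucleotide parent table: CCD component id -> parent base letter.
# Users may extend this via ChainFilter/parser options; unmapped codes become N.
PSU	U
H2U	U
5MU	U
4SU	U
OMU	U
UR3	U
5BU	U
1MA	A
2MA	A
A2M	A
MA6	A
6MZ	A
MIA	A
T6A	A
5MC	C
OMC	C
4OC	C
1MG	G
2MG	G
M2G	G
7MG	G
OMG	G
G7M	G
YG	G
QUO	G
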