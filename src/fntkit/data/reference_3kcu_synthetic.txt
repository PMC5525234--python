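# Default reference annotation for the FNT coordinate frame, in the residue
# numbering of the E. coli FocA crystal structure (PDB 3KCU).
#
# The sequence below is SYNTHETIC: it was constructed to carry the asserted
# FocA residue identities at every annotated position (constriction sites,
# channel-facing positions, helix-interface positions) with plausible filler
# elsewhere (hydrophobic inside segments, polar in loops).  It is NOT the
# 3KCU crystal sequence.  Users may substitute the real FocA sequence in a
# file of this format without code changes.
#
# Format:
#   top-level "key = value" pairs: offset (reference number of the first
#   sequence character) and sequence (one line, unwrapped).
#   [segments]          name start end          (1-based, inclusive)
#   [constrictions]     site positions...       (ascending, space-separated)
#   [known_residues]    position residue

offset = 21
sequence = EPPSSGGGSDIFITIFLAMIAGIIISFAVMMALFIADDESGEGIAVLLLAAGAAFMIGLIVCVIMGLDLFTSTLFMFLMKFPEDDNFAIMFINLVLLMFGNAFGAILMVIVVMIPNDNSESSDPGGNDNDSSDEGGDNPGFLFMMVLGMAANILVCFAVVFAIIESEMFVKMFAMLIAVIIFMFLGLEHLFANVLALFIGLFIFGNEDNNNPSDGNSDDDEESGGDFFMFFAANFAFMFLGNAIGGFLFLGMVLVSEDGE

[segments]
TM1 31 56
TM2a 64 85
OMEGA 86 93
TM2b 94 101
TM3 107 134
TM4 161 184
TM5a 188 204
S 205 209
TM5b 210 224
TM6 247 275

[constrictions]
central 75 202 209 212
slit_closed 79 89 91 175
slit_open 79 89 90 172 175

[known_residues]
34 T
37 L
38 A
41 A
42 G
45 I
46 S
48 A
72 G
75 F
78 G
79 L
82 C
83 V
86 G
88 D
89 L
90 F
91 T
92 S
93 T
100 K
113 N
120 G
121 N
124 G
125 A
129 V
167 L
168 G
171 A
172 N
175 V
176 C
178 A
179 V
191 K
195 M
199 V
202 F
206 G
208 E
209 H
212 A
213 N
220 G
254 N
261 G
262 N
265 G
266 G
271 G
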