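# 21 primary amines: hydrogen-suppressed (heavy-atom) molecular graphs,
# experimental boiling points (deg C) and the published descriptor values
# (xi_c, W, ENM1, ENM2, ENM3) stored verbatim, including suspected typos.
# One compound per block:
#   compound: <name>
#   bp: <boiling point, deg C>
#   printed: <xi_c> <W> <ENM1> <ENM2> <ENM3>
#   edges: <u>-<v> ...

compound: n-propylamine
bp: 49
printed: 14 10 58 45 24
edges: 1-2 2-3 3-4

compound: 2-aminopropane
bp: 33
printed: 9 9 39 18 21
edges: 1-2 1-3 1-4

compound: 2-amino-2-methylpropane
bp: 46
printed: 12 16 56 32 36
edges: 1-2 1-3 1-4 1-5

compound: 2-aminobutane
bp: 63
printed: 19 18 101 82 40
edges: 1-2 1-3 1-4 4-5

compound: 2-methylpropylamine
bp: 69
printed: 19 18 101 82 40
edges: 1-2 1-3 1-4 4-5

compound: n-butylamine
bp: 77
printed: 24 20 126 108 42
edges: 1-2 2-3 3-4 4-5

compound: 2-amino-2-methylbutane
bp: 78
printed: 24 28 162 131 62
edges: 1-2 1-3 1-4 1-5 5-6

compound: 2-aminopentane
bp: 92
printed: 31 32 199 174 63
edges: 1-2 1-3 1-4 4-5 5-6

compound: 3-methylbutylamine
bp: 96
printed: 31 31 199 174 63
edges: 1-2 1-3 1-4 4-5 5-6

compound: 2-methylbutylamine
bp: 96
printed: 29 32 175 162 59
edges: 1-2 1-3 3-4 1-5 5-6

compound: n-pentylamine
bp: 104
printed: 38 35 258 225 68
edges: 1-2 2-3 3-4 4-5 5-6

compound: 4-methylpentylamine
bp: 125
printed: 47 50 379 332 95
edges: 1-2 1-3 1-4 4-5 5-6 6-7

compound: n-hexylamine
bp: 130
printed: 54 56 442 388 98
edges: 1-2 2-3 3-4 4-5 5-6 6-7

compound: 3-methylpentylamine
bp: 114
printed: 45 50 339 318 90
edges: 1-2 1-3 3-4 1-5 5-6 6-7

compound: 4-aminoheptane
bp: 139
printed: 61 75 531 488 121
edges: 1-2 1-3 3-4 4-5 1-6 6-7 7-8

compound: 2-aminoheptane
bp: 142
printed: 65 79 623 546 131
edges: 1-2 1-3 1-4 4-5 5-6 6-7 7-8

compound: n-heptylamine
bp: 155
printed: 74 84 722 654 136
edges: 1-2 2-3 3-4 4-5 5-6 6-7 7-8

compound: n-octylamine
bp: 180
printed: 96 120 1078 972 178
edges: 1-2 2-3 3-4 4-5 5-6 6-7 7-8 8-9

compound: n-nonylamine
bp: 201
printed: 122 165 1562 1425 228
edges: 1-2 2-3 3-4 4-5 5-6 6-7 7-8 8-9 9-10

compound: 2-aminoundecane
bp: 237
printed: 169 275 2687 2474 339
edges: 1-2 1-3 1-4 4-5 5-6 6-7 7-8 8-9 9-10 10-11 11-12

compound: 3-aminopentane
bp: 91
printed: 29 31 175 162 59
edges: 1-2 1-3 3-4 1-5 5-6
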