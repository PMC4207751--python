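# Signature-motif profiles of the six opisthokont GPAT/DHAPAT subclasses.
#
# Each subclass carries four degenerate motif patterns (the sequential
# blocks of the pfam01553 acyltransferase domain) and the three
# distance-between-motifs (DBM) intervals: residues strictly between
# motifs I & II, II & III and III & IV.
#
# Token notation: literals; "x" = any standard residue; "φ" = V,I,L,F,W,Y,M;
# "π" = P,G,A,S; "[+]" = K,R,H; "[A/B]" = alternatives; "[-/N]" = optional
# position allowing N.  "hallmark" lists 0-based indices of the positions
# that diagnostically define each motif (the catalytic H/D dyad of motif I,
# the binding-site R of motif II, the F/E/G triad of motif III, the P of
# motif IV).
#
# The trailing "x D" of the fGPAT-A motif II pattern is transcribed as two
# positions (a wildcard then aspartate); the run-together printing of the
# source notation makes one-token "xD" an alternative reading.
fGPAT-A:
  motif_I:   {pattern: "H x N Q F φ D",            hallmark: [0, 6]}
  motif_II:  {pattern: "φ π V x R [π/φ] x D",      hallmark: [4]}
  motif_III: {pattern: "F P E G G S H D",          hallmark: [0, 2, 3]}
  motif_IV:  {pattern: "φ φ P [V/C] G",            hallmark: [2]}
  dbm_I_II: [35, 46]
  dbm_II_III: [97, 132]
  dbm_III_IV: [26, 28]

fGPAT-B:
  motif_I:   {pattern: "H x N x φ φ D",            hallmark: [0, 6]}
  motif_II:  {pattern: "φ P φ x R x x x",          hallmark: [4]}
  motif_III: {pattern: "F P E G [G/I/T] S [H/Y] x", hallmark: [0, 2, 3]}
  motif_IV:  {pattern: "φ φ P [C/T/V] π",          hallmark: [2]}
  dbm_I_II: [36, 40]
  dbm_II_III: [21, 104]
  dbm_III_IV: [29, 35]

eGPAT:
  motif_I:   {pattern: "H [S/T] [S/T] [P/φ] φ D",  hallmark: [0, 5]}
  motif_II:  {pattern: "φ [M/W] F [-/N] R x",      hallmark: [4]}
  motif_III: {pattern: "F P E G T C φ N N",        hallmark: [0, 2, 3]}
  motif_IV:  {pattern: "φ x P φ A",                hallmark: [2]}
  dbm_I_II: [36, 42]
  dbm_II_III: [23, 27]
  dbm_III_IV: [18, 18]

mitoGPAT:
  motif_I:   {pattern: "H [+] S H φ D",            hallmark: [0, 5]}
  motif_II:  {pattern: "F F I [+] R [+] φ",        hallmark: [4]}
  motif_III: {pattern: "F φ E G [G/S/T] R [S/T] R", hallmark: [0, 2, 3]}
  motif_IV:  {pattern: "φ φ P φ [π/N]",            hallmark: [2]}
  dbm_I_II: [38, 39]
  dbm_II_III: [30, 32]
  dbm_III_IV: [28, 28]
  # Two surveyed metazoan/filasterean mitoGPATs carry 65 residues between
  # motifs II and III; hard DBM filtering would reject them, which is why
  # classification defaults to soft spacing penalties.
  dbm_exceptions:
    dbm_II_III: [65]

fGDPAT:
  motif_I:   {pattern: "H [+] S H φ D",            hallmark: [0, 5]}
  motif_II:  {pattern: "φ φ I R R x φ",            hallmark: [4]}
  motif_III: {pattern: "F φ E G [G/T] R [S/T] R",  hallmark: [0, 2, 3]}
  motif_IV:  {pattern: "φ x P φ π",                hallmark: [2]}
  dbm_I_II: [38, 38]
  dbm_II_III: [27, 27]
  dbm_III_IV: [28, 28]

DHAPAT:
  motif_I:   {pattern: "H [+] [S/T] Y φ D",        hallmark: [0, 5]}
  motif_II:  {pattern: "F φ M R R [S/T] F",        hallmark: [4]}
  motif_III: {pattern: "F φ E G T R S R",          hallmark: [0, 2, 3]}
  motif_IV:  {pattern: "φ x P φ π",                hallmark: [2]}
  dbm_I_II: [38, 39]
  dbm_II_III: [28, 30]
  dbm_III_IV: [28, 28]
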