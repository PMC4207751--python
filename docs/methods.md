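# Methods

This note documents the models, parameter choices and numerical
conventions behind `acylscan`, and what the synthetic benchmarks do and
do not establish about real data.

## Motif grammar

Patterns are space-delimited tokens over the 20 standard residues.
Residue classes: `π` = {P, G, A, S}, `φ` = {V, I, L, F, W, Y, M},
`[+]` = {K, R, H}.  The membership of `[+]` is a package choice: the
notation tradition it follows defines `π` and `φ` but leaves the
positive class open; histidine is included because it is protonatable
at physiological pH and every motif context in which the symbol occurs
is basic.  It can be overridden via
`acylscan.alphabet.set_plus_class`.

A bracketed alternative containing `-` (e.g. `[-/N]`) is modelled as an
*optional* position: the motif may be one residue shorter.  This
follows the alignment-notation reading in which `-` denotes absence.
Optional positions cannot be hallmarks.

Residues outside the 20-letter alphabet (B, Z, X, U, ...) match only
the full wildcard `x`.  Rationale: an ambiguity code must never satisfy
a specific — least of all a hallmark — requirement; conservative
matching avoids false hallmark hits at the price of occasionally
missing a true motif in low-quality sequence.

The fGPAT-A motif II pattern ends in a run-together `xD` in the source
notation; it is transcribed as two positions (wildcard, then
aspartate), flagged in the fixture file comments.  Hallmark positions
(the catalytic H/D dyad of motif I, the binding-site arginine of motif
II, the F/E/G triad of motif III, the proline of motif IV) are carried
in the fixture file as explicit indices, not in the pattern string.

### Specificity weights

A matched position allowing set *A* scores `w = log2(20 / |A|)` bits —
the log-odds of the match under a uniform background.  The synthetic
generator's default uniform composition makes these weights exact; a
Robinson–Robinson composition option exists for more realistic residue
frequencies, under which the weights remain a useful but no longer
exact log-odds.

## Chain scanning and DBM

The distance between motifs (DBM) counts residues **strictly between**
the last residue of the upstream motif and the first residue of the
downstream one.  This convention reproduces the published interval
readings (e.g. 97–132 between motifs II and III of fGPAT-A read from a
motif-II end to a motif-III start).  An `inclusive` convention (+2,
counting the boundary residues) is available behind a switch for
sensitivity checks only; all shipped intervals are in the strict
convention.

`scan_chain` finds the maximum-score in-order, non-overlapping
placement of motifs I–IV by dynamic programming over per-motif
occurrence lists.  The score is the sum of matched-position weights
plus a spacing term per adjacent pair: 0 inside the profile interval;
in `soft` mode −0.5 per residue outside; in `hard` mode such chains
are discarded.  The −0.5 penalty is arbitrary but fixed; only score
*orderings* are interpreted, never absolute values.  Ties are broken
toward more motifs placed, then the lexicographically smallest
placement tuple, making results independent of evaluation order.  The
DP provably equals brute-force enumeration of all motif combinations
(tested against an independent exhaustive oracle).

Soft mode is the classification default because two surveyed
mitochondrial GPATs are footnoted with 65 residues between motifs II
and III — far outside the [30, 32] fixture interval — and hard
filtering would reject such genuine members.  The fixture file records
this exception list.

Partial chains: classification falls back to three-motif chains (one
motif skipped, spacing across the skip unconstrained) and labels such
calls `partial`.

One textual discrepancy is resolved in favour of the printed table:
the fGPAT-A motif II–III interval is shipped as [97, 132] although the
running text says "99–132" once.

## PTS1 detection

The peroxisomal targeting signal check is a rule-based tripeptide
classifier: tier `canonical` = `[S/A/C][K/R/H][L/M]`, tier `relaxed`
additionally admits G/P/T at −3 and I/F at −1.  It replaces externally
hosted position-weight predictors whose scoring functions are not
published; it depends only on the final three residues (property-tested)
and is documented as a deliberate simplification.  It does not attempt
organism-specific weighting, PTS2 detection, or numeric signal-strength
scores.

## Classification

Each protein is scanned against all six profiles in soft mode.  The
H→D spacing of the winning chain's motif I (5 residues in fGPAT-A/B,
4 in the other four subclasses — a consistency the shipped fixtures
are tested to imply) acts as a hard filter: candidates from the
opposite branch are discarded.  The winner must beat the runner-up by
`min_margin` (default 2.0 bits, slightly above one wildcard-position
weight step, so that a single degenerate-position difference cannot
decide a call).  When the margin is inconclusive but every contender
belongs to the mitoGPAT/fGDPAT/DHAPAT branch — whose motifs I–IV are
nearly identical — the call is the branch label `GDPAT-like` together
with the PTS1 flag, a deliberate refusal to assign substrate
preference from motifs alone.  No numeric rule separates fGPAT-A from
fGPAT-B in the source material beyond clade membership; the
motif-score rule used here is a stand-in and is reported as such.
GPAT2 is treated as a divergent mitochondrial GPAT, not a seventh
profile.

## Homology survey

BLASTp is replaced by exact Smith–Waterman (biopython's pairwise
aligner; BLOSUM62, gap open 11, extend 1 — standard protein-search
defaults; a gap of length g costs 11 + g).  At the survey's scale
(proteomes of 10²–10³ sequences) heuristic seeding buys nothing.
E-values use the Karlin–Altschul form `K·m·n·exp(−λS)` with the
published gapped-BLOSUM62 constants λ = 0.267, K = 0.041
(configurable), where `n` is the **total database length** (the summed
residue count of the searched proteome), matching how database search
tools define E.  Under the generator's uniform composition these
constants are approximate — uniform sequences produce somewhat higher
chance scores than natural-composition ones — which is one reason
validation never rests on the E-value alone.

A candidate is validated only if all three hold:

1. **Score screen** — E ≤ 0.05 against a seed (first iteration), or,
   from the second iteration, a motif-anchored PSSM score of at least
   `pssm_threshold` (default 0.3) of the profile's maximum attainable
   score.  The PSSM admission threshold is deliberately coarse: its job
   is to nominate candidates cheaply, not to decide.
2. **Motif evidence** — at least `min_motif_evidence` (default 2) of
   the subclass's *informative* motifs occur in the sequence, where
   informative means the pattern carries ≥ 15 bits of specificity.
   The weakly constrained motif IV patterns (≈ 10–12 bits) occur by
   chance in a few hundred residues of random sequence and never count.
   Every shipped profile offers at least two informative motifs; the
   requirement is automatically capped at what a profile offers.
3. **Reciprocal best hit** — searching the hit back against the
   reference proteome must return one of that family's seeds as the
   top-scoring sequence, under the permissive retrieval cutoff E ≤ 10
   (rank, not significance, is what is being tested), and the seed
   score must exceed the best non-seed reference score by
   `rbh_margin` (default 10 raw score units).  The margin suppresses
   rank-by-luck among near-tied chance scores.

The three gates fail independently for random sequences (chance
E-value survival, chance motif occurrence and chance reciprocal rank
are essentially uncorrelated once the motif evidence is required
twice), which is what drives the measured zero false-validation rate.

The profile is a motif-anchored PSSM, not a full profile HMM: columns
cover the concatenated motif I–IV windows only (occupancy-weighted for
the one optional position), with no insert/delete states.  The
discriminative signal exploited by the analysis lives in the motif
blocks; modelling inter-motif regions would add parameters without
adding signal at these data sizes.  Column log-odds are
`log2((c + αq) / ((N + 20α) q))` with flat pseudocount α = 0.5 and
background q (the generator's composition).  PSSM chain placement uses
the same soft spacing penalty as the scanner, over the top-8 offsets
per block.

The loop adds validated candidates, rebuilds each family profile from
its seeds plus chain-complete validated members (members whose motifs
have drifted off-pattern contribute to presence calls but not to the
profile), and stops at the first iteration that adds nothing —
termination is guaranteed by monotone growth of a bounded set.

## Clustering

Distances are 1 − identity of the global Needleman–Wunsch alignment
(same matrix and gaps), identity being identities over alignment
columns.  No model correction is applied by default — only clade
structure, not branch length, is interpreted — but a Poisson
correction −ln(1 − d) is available.  Neighbor joining uses the
standard Q-criterion with a deterministic tie-break (the pair whose
smallest contained leaf labels sort first), and clamps negative branch
lengths to zero, shifting the deficit to the sister branch so the
joined pair's path length is preserved.  Clade membership is an exact
bipartition lookup on the unrooted tree; trivial bipartitions (single
taxa, the full set) are always clades.  Bootstrap support, Bayesian
posteriors, model selection and alignment masking are out of scope.

## Synthetic data

A planted member is `flank + motif I + gap(dbm1) + ... + motif IV +
flank [+ PTS1]`: motif residues uniform over each position's allowed
set, spacings uniform over the profile intervals, flanks and gaps from
the background composition (uniform by default), lengths in
[350, 650].  Members declared PTS1-free have their C-terminal
tripeptide redrawn if it is PTS1-positive by chance, so the `none`
label is exact.  Noise draws depend only on seed and position, so the
mutated-site sets at different noise levels are nested — accuracy
curves across noise levels compare corruptions of the *same* base
sequences.  `conservative` noise spares hallmark residues and a
planted PTS1 tripeptide; `harsh` spares nothing.

Survey scenarios mutate one founder per subclass to the requested
divergence (default 0.05) to make orthologue sets, **sparing the full
motif windows and the C-terminal tripeptide**: the premise of
motif-based detection is that purifying selection holds the catalytic
motifs (and the targeting status) fixed on timescales where the rest
of the sequence drifts.  Decoys are i.i.d. background.  The default
8-proteome plan covers the survey's qualitative regimes: a yeast-like
taxon with only fGPAT-A paralogues, fungi with the novel GDPATs, a
basal fungus carrying both microsomal types, metazoans with the
mitoGPAT/DHAPAT pair, a single-enzyme reduced parasite, and an
all-decoy control.

The chained-detectability ("two-step") scenario plants `A`, a close
orthologue of the seed with freshly drawn pattern-valid motifs
(detected at iteration 1 through flank similarity), and `B`, which
copies `A`'s motifs exactly but has random flanks and sits at legal
spacings as far from the seed's as the intervals allow.  fGPAT-B is
the default family because its wide motif II–III interval (21–104)
gives `B` the most room: no single local alignment can chain `B`'s
motif blocks against the seed, so `B` fails the E-value screen in
round 1 and is recovered in round 2 purely through `A`'s contribution
to the profile (against a seed-only profile `B` scores far below
threshold; against the seed+A profile it scores at the maximum).

What the synthetic benchmarks do **not** show: the generator has no
indel process (beyond the one optional motif position), no rate
heterogeneity, no domain architecture beyond the single motif chain,
and independent flanks — so perfect recovery here bounds, but does not
guarantee, behaviour on real proteomes, where paralogue history,
composition bias and fragmentary gene models all intrude.

## Problem sizes and determinism

The shipped test suite and the acceptance script use: 50 members per
subclass for noise-free recovery; an 8 × 300-protein scenario for
presence/absence recovery; 20 replicate 3 × 60 scenarios for decoy
precision; 200 (tests) / 100 (script) motif-enriched sequences for the
chain-DP oracle and 200 short pairs for the alignment oracle; 50
random additive matrices and 20 three-family replicates for
clustering.  These sizes give each stochastic check an expected
failure signal well above its threshold while keeping a full run in
the minutes range on one CPU.  All randomness flows from explicit
seeds; reports contain no timestamps, and a pipeline rerun with the
same configuration is byte-identical.

## Known limitations

* E-value calibration assumes the published gapped-BLOSUM62 constants;
  under unusual compositions the absolute E-values are approximate
  (the validation stack, not the E-value, carries precision).
* The fGPAT-A / fGPAT-B separation is a motif-score heuristic, not a
  published rule; borderline members of these sister clades may swap.
* The PTS1 check knows nothing about organism-specific preferences or
  signal strength.
* `GDPAT-like` calls are deliberately coarse; resolving them requires
  phylogenetic or biochemical evidence outside this package's scope.
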