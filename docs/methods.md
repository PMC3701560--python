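# Methods

This note documents the models and procedures implemented in `zfscan`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## The profile HMM

Each family is modelled by a simplified Plan-7-style local profile with
match, insert and delete states per node.

**Architecture.** Match columns of the seed alignment are those whose gap
fraction is *strictly* below `match_column_gap_threshold` (default 0.5); a
column exactly at the threshold is an insert column (a tie rule has to be
picked; this one is tested). An explicit Stockholm `#=GC RF` annotation
overrides the rule. Entry is uniform over match states (1/M each), and each
match state carries exit probability 1/M (total exit mass 1); paths
therefore begin and end at match states, which is what makes single-residue
spurious matches expensive (entry + exit ≈ −2·log₂M bits).

**Parameters.** Match emissions use Laplace pseudocounts, p(a) = (n_a + α) /
(n + 20α) with α = `pseudocount_alpha` (default 1). Transitions are
estimated from the observed column-to-column state paths of the alignment
rows, with the same α spread over each state's outgoing fan (M→{M,I,D},
I→{M,I}, D→{M,D}); transition pairs with no edge in the model (I↔D) are
rare in practice and contribute no counts. Insert emissions are tied to the
background. The background itself is estimated from the alignment's
ungapped residues and always receives one pseudocount per letter so that
log-odds stay finite; with no countable residues it degenerates to the
uniform 1/20. `X` residues are scored at background frequency (log-odds 0)
in both match and insert states.

**Scoring.** The reported score is the Viterbi (best-path) log₂-odds in
bits against an i.i.d. background null over the same residues — Viterbi
rather than Forward because it is deterministic and directly checkable
against exhaustive path enumeration (the test suite verifies exact
agreement for all profiles with M ≤ 4 against all sequences of length ≤ 6
over a reduced alphabet). Multi-domain sequences are handled by greedy
iterated local alignment: the best domain is taken, its residues masked,
and the search repeats on the remaining segments while the best remaining
domain scores above 0 bits. The full-sequence score is the sum of accepted
per-domain scores; the best-domain score is the largest. Envelopes are
1-based inclusive and disjoint by construction.

**Calibration.** Per-profile Gumbel nulls are fitted by the method of
moments (λ = π/(s√6), μ = x̄ − γ/λ) on Viterbi full scores of random
sequences drawn i.i.d. from the profile background at a fixed length
(default 400). Moments rather than maximum likelihood: simpler, and
accurate to a few percent at the sample sizes used (verified against draws
with known parameters; the acceptance suite requires λ within 5% at
n = 10 000). Random sequences with no admissible path (possible only at
α = 0) are dropped from the fit, provided at least half the sample
remains. E-values are E = m·P(S ≥ s) for a database of m sequences,
computed with `expm1` for numerical stability in the far tail.

## Score scale and thresholds

Because the model pays genuine transition probabilities against a
transition-free null, absolute bit scores are much smaller than those of
profile-search tools whose null includes a length model: with a 3-row seed
alignment and α = 1, each M→M step costs ~0.58 bits, so a true but
diverged 300-residue member scores ~5–15 bits while calibrated random
sequences score −10.6 ± 0.6. The classic "forward to validation only above
100 bits" filter therefore belongs to another tool's scale; it remains the
config default for procedural fidelity, but the benchmark configuration
sets `score_threshold` to 1 bit — any confidently positive log-odds — and
lets the calibrated E ≤ 0.001 filter carry specificity. The 1-bit floor
comes from the calibration geometry (the E = 0.001 crossing for a
56-sequence proteome sits near −5.6 bits; random maxima almost never reach
0), not from fitting recovery results.

## Reciprocal validation

Candidates are aligned against the complete reference database by exact
affine-gap Smith–Waterman (BLOSUM62; gap of length g costs 11 + (g−1)·1,
the standard protein-search defaults). No seeding heuristics: the
reference database is three proteomes by design, so exhaustive search is
affordable and removes a stochastic dependency. Subjects are ranked by raw
score (score order equals E-value order for a fixed database), ties broken
by subject accession; a candidate is accepted iff one of its top
`max_reference_hits` (default 3) subjects is on the family's master list.
Traceback prefers diagonal over vertical over horizontal moves, making
spans and identities deterministic. The kernel is verified against an
independent plain-Python affine-gap reference (itself checked against full
path enumeration at tiny lengths) and against Biopython's PairwiseAligner.

## Rounds, refinement, and the missing check

Accepted members are threaded into the family alignment by Viterbi
traceback against the current profile: match/delete states land in
existing match columns, insert-state residues and unaligned flanks open
fresh all-gap columns (members sharing an anchor share columns,
left-aligned). The alignment is rebuilt into new profiles between rounds;
accepted sets only ever grow, since each round's acceptances are merged
into the running state. From round 2, a clade-specific profile is built
for any taxonomic group contributing at least `min_clade_seqs` (default 4)
alignment rows — below that a clade profile is mostly pseudocount noise —
and species of that group are scanned with it, others with the general
profile.

After the final round, every (species, family) pair with no members, in a
group where the family was otherwise found, is re-checked in two stages:
a re-scan with the final post-refinement profile, then a focused
Smith–Waterman search using up to 3 donor members from the same group
(same-phylum donors preferred). Donor hits must score at least
`focused_min_score_ratio` (default 0.2) of the donor's self-score before
reaching reciprocal validation — without this floor, compositionally
biased decoys occasionally reach validation on noise-level hits and can
match a master accession by chance within the top-3 window. Only if both
stages fail is the family declared *missing*; if the group has no members
at all, the pair is *not assessed*. A candidate that validates for two
families aborts the run with a report: with disjoint master lists this
indicates malformed inputs, not a tie to adjudicate.

## Reporting

Within one species and family, members whose pairwise alignment covers at
least 95% of the shorter sequence at identity ≥ `duplicate_identity`
(default 0.99) are collapsed as duplicate records (lexicographically
smallest accession retained); anything less similar counts as a paralog.
The thresholds automate what is classically a manual inspection step and
are deliberately conservative. Phylum-level presence uses an any-species
rule, so one missing gene model does not erase a phylum. A family's block
is the most basal group (in the taxonomy's explicit basal-to-derived group
order) with phylum-level presence; a family seen in exactly one species is
labelled "none" rather than given a block. Holes require a phylum of ≥ 3
species with ≥ 80% of the peers possessing the family; loners require a
group of ≥ 5 species with ≤ 10% of peers possessing it. The support floors
keep tiny clades from generating flags; "almost all" has to be quantified
somewhere, and these values are configurable.

## The synthetic corpus

The simulator evolves each family's root protein down a fixed topology
(root → group ancestor → phylum ancestor → species) over a 20-species,
8-phylum, 4-group taxonomy mirroring a protist/plant/fungus/metazoan
survey at desk scale. Defaults define the benchmark study condition:
6 families of length 300 introduced at staggered groups, substitution
probability 0.15/site/branch under a BLOSUM62-derived conditional model
(so diverged members remain detectable the way real homologs are), indels
at 0.01/site with geometric mean length 2, loss probability 0.1/species in
eligible groups, duplication probability 0.1 (a near-identical
within-species copy), and 50 decoys per species (half shuffled members —
the hardest composition-matched negatives — half random background
proteins of length 150–450). Each root carries a 28-residue low-entropy
signature core anchored by two cysteines and two histidines, echoing a
C2H2-type zinc finger, mutating at a quarter of the global rate and
excluded from indels. Column homology is tracked through every indel, so
seed alignments (the three reference species' members) and full true
alignments are exact projections, not re-alignments. Two optional
injections create clean flag scenarios: a forced single-species loss
(suppressing random loss in the rest of that phylum) and a loner family
present as two near-identical copies in one reference species — seeded in
a reference species precisely so that a master-list entry exists and the
pipeline has a fair chance to find it.

What the benchmark does **not** emulate: realistic branch lengths or rate
heterogeneity beyond the core/flank split, domain-architecture shuffling,
alternative isoforms, annotation noise other than decoys, and families
related to *each other* (cross-family confusion is tested only through
composition-matched decoys). Passing it shows the machinery is correct and
the reciprocal logic is sound under honest divergence; it does not show
field performance on real proteomes.

## Numerical and engineering notes

Dynamic-programming inner loops (Viterbi with envelope tracking, a
traceback variant, and Smith–Waterman score/full kernels) are
numba-compiled; all other logic is plain NumPy/Python. Determinism: every
stochastic step derives its seed from the run seed (calibration seeds mix
the family, clade tag and round via CRC32), dictionary iterations are
sorted, and identical seeds produce byte-identical call-table exports (a
tested invariant). Problem sizes throughout (20 species, ~56-sequence
proteomes, 6 families, calibration n = 500 at length 400 in pipeline runs,
n = 10 000 in the direct calibration check) were chosen so the full
benchmark including five seeds runs in a few minutes on one core.
Degenerate inputs fail loudly: empty sequences, alignments with no match
columns, uncalibrated E-value requests, constant calibration scores and
ragged alignments all raise typed errors naming the offender.
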