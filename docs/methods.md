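# Methods

## The two-step editing model

`tagback` designs both transformations of the indirect (two-step) strategy
for precision editing of genomic features that lack a usable RNA-guided
nuclease (RGN) target of their own — short, A/T-rich cis-regulatory motifs
being the canonical case. Step one deletes an expanded window around the
feature and installs a short engineered RGN site (the *landing pad*) by
homology-directed repair (HDR); step two cuts the landing pad and restores
the window with the feature either wild-type or edited. The design problem
the package solves is therefore fourfold: find a cuttable, specific guide
near the feature; construct a landing pad that exists nowhere else in the
genome; assemble the two donor DNAs; and produce a validation-primer set
whose colony-PCR banding pattern distinguishes the wild-type (+),
knock-out (Δ) and add-back (AB) genome states.

HDR is modeled as exact, seamless, arm-anchored replacement: the interval
between the donor's two homology-arm anchor points is substituted by the
donor payload, on every haplotype contig of the locus's ploidy group. The
model predicts intended outcomes only; NHEJ indels, partial integration
and mosaicism are out of scope. Two consequences of the model are treated
as testable predictions rather than bugs: a wild-type add-back donor
restores the + genome byte-for-byte, and heterozygous variants inside the
replaced interval collapse to the donor allele (loss of heterozygosity).

## Target motifs and matching

Motif strings use IUPAC codes with `{n}`/`{n,m}` quantifiers, `|` cut
marks inside the spacer, and one `>`/`<` PAM separator
(`N{17}|N{3}>NGG` = SpCas9; `TTTV<N{20}` = Cas12a-style). Matching is
per-position set membership; ranged quantifiers match as the union of
their fixed-length expansions, so no window length is shadowed by greedy
matching. Genomic `N` (assembly gap) matches only motif code `N`,
preventing phantom targets in gaps. Multiple cut marks are stored but only
the PAM-proximal one drives the reported cut coordinate (blunt-cut model).

## Guide quality control

Default gates (all overridable per config key):

| gate | default | meaning |
|---|---|---|
| polyT | ≤ 4.5 | longest strand-specific T homopolymer in the spacer; runs of ≥ 5 fail |
| GC | 25–75 % | spacer G+C percentage |
| errors | budget 5, uniqueness 1 | off-target sites enumerated up to 5 mismatches; a guide fails when any non-identical site lies within 1 mismatch |
| on-target | ≥ 45 | pluggable scorer; the built-in surrogate is rule-based, NOT a trained model, and outputs are labeled accordingly |
| off-target | ≥ 90 | aggregate specificity, 100·100/(100+Σ per-hit) |

The polyT definition (longest run) is the simplest function consistent
with a fractional threshold of 4.5; the original fractional scoring
function is not published, so this is a documented choice. Per-hit
off-target scores use the published 20-entry position-weight vector
(position 1 = PAM-distal) with the mean-pairwise-distance and 1/n² terms;
n=0 scores 100 and n=1 scores 100·(1−W[p]). Spacers longer than 20 extend
the PAM-distal end with weight 0; shorter spacers use the PAM-proximal
tail. A CFD-style table scorer is provided but requires a user-supplied
TSV; without one the feature is disabled with an explicit message.

Off-target enumeration is exhaustive and PAM-anchored: every window whose
PAM satisfies the motif's PAM pattern, on both strands, is Hamming-compared
to the spacer (numpy broadcast over a per-genome window matrix). Hamming
(substitutions-only) keeps the definition oracle-checkable; indel-tolerant
alignment is deliberately not the default. On diploid inputs the
homologous window on the sister haplotype at the same coordinates is the
same locus and is excluded from the off-target list.

## Feature expansion

When no QC-passing target lies wholly inside the feature, bounds grow
alternately one step left, one step right (step 50 bp, symmetric
preference) until one does, capped at a total width of 4096 bp; hitting
the cap raises a "not editable" error. The alternation is deterministic by
construction, which makes the minimal-expansion property testable. When
haplotypes are present the homology arms flanking the final bounds are
compared ungapped; a mismatch fraction above 5 % (or any length
difference, i.e. an indel) flags the locus. Alignment-based arm comparison
is intentionally not used — indels are flagged conservatively instead.

## Landing-pad generation

The insert is rejection-sampled from the motif (uniform base choice per
ambiguity code), kept only if it passes the polyT/GC gates and its spacer
has ≥ 6 mismatches (`min_genome_distance`) to every motif-compatible
window in the genome on both strands. Six gives one mismatch of margin
over the 5-error off-target budget. Sampling is deterministic given the
seed and errors out after a bounded number of attempts. Donor arms default
to 50 nt (hard floor 20), consistent with donors assembled from annealed
100-mer oligos around a 23 nt insert; each arm must occur exactly once per
haplotype contig of the locus and nowhere else. The insert's own spacer is
re-scored against the Δ genome and reported, but a sub-threshold score
does not fail the design.

## Primer design

Candidates are enumerated by sliding window (lengths 18–28, both strands)
over role regions: sF/sR in flanking sequence shared by all three states,
oF/oR inside the state-specific region (landing pad for Δ, restored
payload for AB), iF/iR wholly inside the insert or feature, AmpF/AmpR at
the step-2 donor ends. Hard gates: GC 25–75 %, homopolymer ≤ 4, 3'-G/C
clamp, no self-complementary 3' tail ≥ 4 nt. Melting temperatures come
from a nearest-neighbor duplex model (unified ΔH/ΔS dinucleotide
parameters, terminal initiation terms, entropic salt correction
0.368·(N−1)·ln[Mon⁺], defaults 50 mM monovalent / 500 nM primer) — a
deliberate replacement for full folding thermodynamics, accurate for
perfect duplexes and cross-checkable against an independent implementation
of the same parameter set.

All weighting forms are this package's own choices, since no published
formulas exist for this step: primer weight is a product of Gaussian
penalties around Tm 60 °C (σ 2.5), GC 50 % (σ 10) and length 20 nt (σ 2);
pair weight multiplies the two primer weights by a ΔTm Gaussian (σ 2 °C)
and a 0.1 dimer factor when the primers share a cross-complementary run of
≥ 8 nt. The set weight is the product of pair weights over the required
amplicons (sF/sR, the four junction pairs, internal pairs, AmpF/AmpR),
zero when a sequence is reused across roles. Simulated annealing over role
assignments (initial temperature 10, geometric cooling 0.995, 20 000
iterations, seeded Metropolis) returns the best-seen set; on instances
small enough to enumerate it provably equals exhaustive search (tested).
Optional roles with no candidates — or internal pairs that cannot yield a
product, e.g. inside a 23 nt landing pad — are dropped with a note, as a
usable iF/iR pair need not exist.

In-silico PCR uses exact full-length primer matching by default (a
mismatch-tolerance flag exists; the 3'-terminal 3 nt must always match),
both primer-role orientations, non-overlapping sites, and a 5 kb amplicon
cap; length spans both primer outer coordinates. The cPCR verdict follows
the decision logic of the validation scheme: sF/sR either amplifies only
the Δ genome under the cap (large deleted window), or amplifies all three
states with pairwise-distinct lengths (small window, resolved by band
migration). A wild-type add-back is sequence-identical to +, so sF/sR
alone can never separate those two states; the junction (oF/oR) and
landing-pad pairs carry that information.

## Synthetic genomes

The generator emulates a small A/T-rich fungal-like assembly: i.i.d.
sequence at a chosen GC fraction (default 0.38), features planted verbatim
at fixed positions, optional decoy near-matches of a spacer with a chosen
mismatch count, and an optional second haplotype carrying SNVs at a
per-site rate (default exclusion radius 3000 bp around planted features,
so that a design made from one haplotype integrates and restores exactly
on both; set it to 0 to study loss of heterozygosity). What it does not
model: repeats, segmental duplication, indel polymorphism, composition
heterogeneity, and real gene annotation. Passing tests on these genomes
therefore validate the algorithms' correctness and determinism, not their
behavior on repeat-rich real assemblies, where arm-uniqueness and
off-target structure are harsher.

## Problem sizes and numerical choices

The test suite and the acceptance script run the round-trip experiment on
25 genomes of 10–40 kb (alternating haploid/diploid, SNV rate 0.004),
oracle-equivalence checks on 100 random instances of 0.15–8 kb, annealing
optimality on 20 instances of ≤ 256 assignments, and the editability sweep
on a 100 kb genome with 200 loci and 11 feature sizes (1–1024 bp, powers
of two). These sizes were chosen so the full suite completes in well under
a minute of compute per criterion on one CPU while still exercising every
code path at meaningful scale. Ties in target ranking break by (contig,
start, strand); all randomness flows from one root seed through stable
per-stage hashes, so every artifact is a pure function of (inputs, config,
seed). Scores are clipped to their documented ranges; degenerate inputs
(empty hit lists, empty candidate roles, features at contig edges) have
defined behavior covered by tests.

## Known limitations

- The on-target surrogate is a stand-in; absolute on-target scores are not
  comparable to trained-model scores, only the gating behavior is.
- Hamming-only off-target search misses bulged sites.
- Arm anchoring on a polymorphic haplotype accepts a unique best
  approximate match (≤ 5 % substitutions); highly repetitive arms that tie
  are rejected rather than guessed.
- The sweep's "editable" verdicts use the same QC as single-locus design
  but do not attempt donor construction or primer design per locus.
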