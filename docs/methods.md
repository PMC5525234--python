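# Methods

`fntkit` analyzes Formate/Nitrite Transporter (FNT) family proteins in a
common structural coordinate system and quantifies the features that
distinguish the family's eight prokaryotic subfamilies. This note records
the models, parameters and numerical choices behind each stage, and what
the synthetic test substrate does and does not establish about real data.

## The reference frame

All positions are expressed in the residue numbering of the *E. coli* FocA
crystal structure (PDB 3KCU), the field's conventional frame for this
family. The frame consists of:

* ten segments (1-based, inclusive): TM1 31–56, TM2a 64–85, Ω-loop 86–93,
  TM2b 94–101, TM3 107–134, TM4 161–184, TM5a 188–204, S-loop 205–209,
  TM5b 210–224, TM6 247–275. TM2 and TM5 are the broken helices of the
  hourglass fold; the Ω- and S-loops carry the gate and constriction
  residues and are treated as alignable segments, not flexible loops.
* two constrictions: the central constriction (75, 202, 209, 212;
  canonically F/F/H/A) and the cytoplasmic slit, which has a closed state
  (79, 89, 91, 175; LLTV) and an open state in which Thr-91 swings away
  and Phe-90/Asn-172 move in (79, 89, 90, 172, 175; LLFNV).

The bundled reference annotation ships a **synthetic** sequence constructed
to carry the documented FocA residue identities at every annotated
position (52 positions: constriction residues, channel-facing residues,
and the small/weakly-polar helix-interface positions), with hydrophobic
filler inside segments and polar filler in loops. It is not the 3KCU
crystal sequence; users with the real sequence can substitute it in the
same file format and every invariant is re-validated at load time.

## Constriction scoring

Two per-site scalars summarize a constriction:

* **CHI** (cumulative hydropathy index): the sum of Kyte–Doolittle
  hydropathy values of the site residues. Dimensionless; higher = more
  hydrophobic. The hypothetical all-Ile four-residue slit scores +18.0;
  the canonical FFHA central site scores +4.2.
* **CVV** (cumulative van der Waals volume): the sum of Creighton
  per-residue volumes, in Å³. Higher = more occluded. FFHA sums to 455 Å³.

Both scales are the standard published tables; they are locked by a dozen
exactly reproduced literature values in the test suite, which
over-determines every residue those strings use. Sites containing an
alignment gap are reported `complete=False` with no numeric score — data,
not an error. Outlier channels are flagged per (group, site, state) by a
z-score rule (default k = 2.5, population SD; zero spread flags nothing)
or a percentile rule (k-th/100−k-th percentiles; unlike the z-score rule
it is sensitive to duplicated entries). No published threshold exists for
"unusual"; both rules are exposed and defaults documented here.

## Position mapping

Queries are mapped by global affine-gap alignment (Gotoh three-state DP,
BLOSUM62, gap open 11 / extend 1, free terminal gaps in either sequence)
with one structural modification: **gap opening costs 3× more when the gap
starts strictly inside a contiguous block of segment positions**, for
deletions and insertions alike. This implements, at sequence level, the
constraint that transmembrane helices of this family align without gaps.
Two boundary details matter and were chosen deliberately:

* adjacent segments with no intervening loop (TM2a/Ω/TM2b and
  TM5a/S/TM5b are contiguous in 3KCU numbering) count as one block, so a
  cheap junction gap cannot shift the register through the block;
* a deletion *beginning* at a loop|segment boundary pays only the base
  cost, so an entirely missing helix opens its gap exactly at the segment
  start and reads as coverage 0.0 rather than smearing.

Traceback tie-breaks are fixed (match > gap-in-query > gap-in-reference;
end-cell preference corner, then later reference, then later query rows),
so maps are deterministic. The DP engine is validated against a
brute-force affine-gap oracle on random sequence pairs. Ambiguity codes
(X etc.) score the matrix floor and can never be favorable matches.

**Iterative refinement.** After classification, sequences are re-aligned
once against the majority consensus of their own group (expressed in
frame coordinates; majority-gap positions fall back to the reference
residue). This mirrors the subfamily-specific template choice of
structure-guided alignment: a query is anchored by the residues its own
subfamily conserves, not only those shared with FocA. Refinement removes
the rare (≈1–3%) one-residue register slips that occur where a subfamily
has diverged from the reference, and is what makes per-position
conservation statistics accurate at the 1% level. Groups smaller than 10
keep their reference-aligned maps.

## Sequence QC

Screening follows the family's screening conventions: sequences shorter
than 150 residues are discarded (`too_short`; a six-helix channel cannot
be shorter), sequences with any segment coverage below 0.5 are discarded
(`missing_segment`; the threshold is this package's choice — only
"missing segments" is documented, with no number), alignments scoring
below a configurable floor are `unalignable`. Redundancy is removed by
greedy clustering at 98% identity (identity = matches / shorter sequence
length, the CD-HIT convention; visit order descending length then id),
with one documented exception: equally identical sequences from
*different* species are retained.

## Conservation statistics

Per reference position, conservation is computed over the sequences that
possess the position: gaps are excluded from the denominator and an
all-gap column is reported missing, not 0%. Class percentages are sums of
member-residue frequencies; the default registry is small/weakly-polar
{G,A,S,T,C} (the canonical set for helix-packing positions), aromatic
{F,Y,W}, hydrophobic {A,V,L,I,M,F,C,W}, acidic {D,E}, basic {K,R},
hydrophilic {N,Q,S,T,H,D,E,K,R}. The last two sets are conventions, not
family properties; they are configurable and results that depend on them
should say so. Percentages print to one decimal.

One estimator caveat: at the first position of a segment that follows a
length-contracted loop, the gap-excluded estimator conditions on the
aligner having *not* absorbed the position into the adjacent deletion
block, which slightly enriches matching residues (observed ≲ +5% at
~2–3 such positions per subfamily at cohort scale). Interior positions
are unaffected.

Region lengths (N-terminus, inter-segment loops A–E, C-terminus) are
measured from the query indices: residues before the first mapped TM1
position, between consecutive segments, and after the last mapped TM6
position.

## Pairwise comparisons

Identity and similarity are computed over the reference positions inside
the ten segments where *both* sequences are ungapped — the structured
core, excluding termini and variable loops — so coverage differences are
not double-penalized. Similarity counts identities plus substitutions
with positive BLOSUM62 score (the family literature does not define
"similarity"; this is the standard convention and the matrix is a
parameter). Group matrices average all unordered within-group pairs on
the diagonal (singletons report missing) and all cross pairs off it.

## Subfamily classification

The eight prokaryotic subfamilies — FocA, FdhC (formate), NirC-α/β/γ
(nitrite), HSC (hydrosulphide), YfdC-α/β (uncharacterized) — were
originally defined by phylogenetic inference. This package **does not
infer trees**. It encodes the subfamily-diagnostic conservation at
fifteen reference positions (202, 212, 79, 90, 172, 86, 92, 93, 100,
208, 34, 37, 113, 167, 254) as per-subfamily profiles: an allowed residue
set per position, weighted by the observed conservation fraction.
A sequence's score against a profile is the weight-normalized matched
fraction; a gap at a diagnostic position subtracts half its weight
(missing evidence is weaker than contradicting evidence).

Classification is argmax over profiles with a margin rule: candidates
within `margin_min` (default 0.05) of the best score form a tie set, and
a unique most-specific candidate — strictly largest total diagnostic
weight — wins it. The specificity step is necessary, not cosmetic: the
diagnostic table leaves YfdC-β undefined at three positions where YfdC-α
is constrained, so YfdC-β's diagnostics nest inside YfdC-α's and a
perfect YfdC-α sequence scores 1.0 on both; the sequence is better
explained by the profile that constrains more positions. If no candidate
is strictly most specific the sequence is `unclassified` — this margin
rule is the package's stand-in for poorly resolved phylogenetic
placement, not a reproduction of it.

## Operon context

Gene neighborhoods are scanned up to 3 genes up- and downstream on the
same strand (both configurable) for partner enzymes, matched
case-insensitively against a keyword registry: *pfl* (pyruvate formate
lyase / formate acetyltransferase) implying FocA-like formate channels,
*fdh* (formate dehydrogenase) implying FdhC, *nirBD* (nitrite reductase)
implying NirC, *asrABC* (sulfite reductase) implying HSC. The nearest
match decides; equidistant ties break downstream. BLAST-based rescue of
unannotated neighbors is out of scope; the registry is user-extensible.
Inputs are GFF3 (CDS features) or a 6-column TSV
(contig, start, end, strand, locus_tag, product), 1-based inclusive.

## The synthetic cohort generator

The generator produces cohorts whose statistical structure matches what
the conservation and subfamily tables describe, with full ground truth.
Per subfamily a consensus spans TM1–TM6: diagnostic positions take the
first allowed residue of the profile, the 52 annotated near-invariant
positions take their reference residue, and the remaining filler is drawn
deterministically (seed 0) from a hydrophobic alphabet in segments and a
polar alphabet in loops, shared family-wide. A per-subfamily 20% of
filler positions (`background_divergence`) is then re-drawn from
**conservative alternatives** (BLOSUM62 ≥ 0). Conservative divergence is
both realistic — transmembrane cores diverge conservatively — and the
property that keeps the structure-anchored register recoverable from
sequence alone; unconstrained divergence makes helices intrinsically
ambiguous to align and is precisely the regime in which the original
analyses needed 3-D structure.

Per sequence: protected positions (diagnostics + near-invariant) emit the
consensus residue with probability `diagnostic_fidelity` (default 0.99),
else a uniform random other residue; every other position substitutes
with probability `mutation_rate` (default 0.1, uniform over the 19
alternatives, no matrix bias); loop and termini lengths are drawn from
per-region normal models rounded to integers (defaults: N-term 28±5 but
48±6 for YfdC, matching their reported long N-termini; loops A–E 7±2,
5±1, 10±3, 3±1, 8±2 with NirC-α's short loop A / long loop C and FocA's
long loop E; C-term 12±4 but 24±5 for FocA and YfdC-α). Indels never
occur inside segments. Feature tables place each FNT gene on its own
contig among filler genes; exactly round(`operon_fraction`·n) genes
(default 15%) receive a partner enzyme within the window on the same
strand, drawn only from subfamilies with known partners (YfdC has none,
so fractions demanding more partnered genes than partnered subfamilies
provide are rejected). All randomness flows from one seeded generator;
fixed seed ⇒ byte-identical FASTA/GFF3/TSV output.

**What passing tests show — and don't.** On this substrate the pipeline
recovers emission probabilities within binomial uncertainty, ≥95% of
subfamily labels at 10% mutation, and the exact operon fraction. Real FNT
sequences are harder in specific ways the generator deliberately omits:
inter-subfamily divergence is far deeper (~25–35% core identity vs ~60%
here), substitutions are matrix-biased, indel placement is less tidy, and
annotation text is noisy. Results on real data therefore depend on the
structure-anchored gap model and refinement more heavily than the tests
exercise, and the classifier remains a profile encoder, not a phylogeny.

## Statistical check design

The conservation-recovery acceptance test evaluates ~1,456 per-position
binomial comparisons simultaneously (8 subfamilies × 182 segment
positions, n = 500 each). At a 3-SD per-position tolerance the expected
number of honest exceedances is ≈4, so the suite asserts the family-wise
version of the same claim: no position beyond 4.5 SD, at most 1% of
positions beyond 3 SD, and the exampled near-invariant position (His-209)
within plain 3 SD in every subfamily. Defects this test is designed to
catch (register shifts, boundary leaks) appeared during development as
10–25 SD deviations affecting >2% of positions.

## Problem sizes and determinism

Default test problem sizes: 500 sequences per subfamily for conservation
recovery, 200 per subfamily for classification recovery, 250 per
subfamily for operon recovery, 12 per subfamily for matrix/region
properties, 6 per subfamily for end-to-end determinism. The full pipeline
writes no timestamps; reports depend only on inputs and parameters, and
two identical runs are byte-identical (asserted in the suite). Numerics:
alignment scores are float64; tie-breaks are fixed as described;
percentages round only at the reporting layer.
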