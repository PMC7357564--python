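# Methods

This note documents the models and procedures `ilpminer` implements, the
parameters that matter, what the synthetic data emulates, and the design
choices made where the design was genuinely open.

## The detection model: the six-cysteine framework

An insulin-like peptide (ilp) precursor is recognized by the spacing of
six cysteines forming the three disulfide bridges of the insulin fold:
two B-chain cysteines, then — across the connecting C peptide — an
adjacent CC pair, a cysteine three residues later, and a final A-chain
cysteine. `match_framework` searches a protein for the leftmost
assignment of six cysteines satisfying per-interval spacing bounds
(`FrameworkPattern.gaps`, residues strictly between consecutive
cysteines):

| interval | default | meaning |
|---|---|---|
| C1–C2 | 5–40 | B-chain span |
| C2–C3 | 5–200 | C peptide (highly variable) |
| C3–C4 | 0 | adjacent CC pair |
| C4–C5 | 3 | exactly three residues |
| C5–C6 | 6–30 | A-chain tail |

The defaults encode the canonical insulin fold; all bounds are
config-exposed because the underlying biology states only "six
cysteines in the typical locations". `allow_extra_cysteines` (off by
default) records rather than rejects additional interior cysteines —
needed for the decapod relaxin variant that carries a seventh cysteine.
The search is a depth-first scan over cysteine positions in ascending
order with interval pruning, so the first complete assignment is the
lexicographically smallest one; a brute-force subset enumeration serves
as its oracle in the tests.

Family assignment applies three ordered rules: (1) a C-terminal
extension of ≥ 40 residues after C6 plus either the GTVx₁Px₂(F/Y) motif
or an arginine-rich segment → aIGF; (2) best normalized
global-alignment identity against the reference panel ≥ 0.5 → that
family (ties broken lexicographically); (3) a short extension with
uniformly low similarity → *gonadulin-candidate*. The hedged label is
deliberate: divergence is the gonadulin signature, and nothing in rule 3
positively identifies a gonadulin, so the pipeline never claims more
than candidacy. Both thresholds (`min_ext` 40 aa, `s_min` 0.5) are
invented, config-exposed operating points; the normalized identity is
identically aligned residue pairs in a Needleman–Wunsch alignment
(match 2 / mismatch −1 / gap −2) divided by the longer length.

The signal-peptide call is a deterministic two-part heuristic — a
hydrophobic core (7-residue Kyte–Doolittle window mean ≥ 1.5 starting in
the first 30 residues) followed by the classic (−3,−1) small-residue
rule ({A,G,S,C,T}) — and is **not** equivalent to a trained predictor;
it exists so annotations are complete and testable. Convertase cleavage
prediction is deliberately absent: gonadulin and aIGF are likely not
made by neuroendocrine cells, so neuroendocrine convertase rules would
not apply.

## The mining loop

Permissive translated BLAST at extreme E-values is re-expressed as exact
short-seed matching: a mate is recruited iff it shares one exact seed
with the query (4-mer amino-acid seeds against all six mate
translations for protein queries; 21-mer nucleotide seeds on both
strands otherwise). Recruited mates are assembled by greedy
overlap-layout: containment absorption, then repeated merging of the
pair with the longest suffix/prefix overlap (≥ 25 nt at 100% identity by
default), in any relative orientation, with ties broken by
lexicographic contig-id pair so assembly is fully deterministic. The
loop re-recruits with the growing contigs and stops when the recruited
identifier set gains nothing or after `max_rounds` (10). Convergence of
the recruited set is our proxy for "the transcript is complete" — the
original stopping rule is a human judgement with no algorithmic
definition. No splice-graph handling: alternative isoforms may assemble
into two contigs; isoform arithmetic happens downstream in expression.

## Expression: half spots per million spots

A *spot* is one sequencing unit (a read pair or single read); each mate
is a *half spot*. Expression of a gene in an archive is the number of
half spots sharing an exact ≥ 32 nt substring with the gene's coding
sequence (either strand; UTRs are excluded from the query precisely so
shared untranslated stretches cannot inflate counts), normalized as
count × 10⁶ / total **spots**. The asymmetry — half spots in the
numerator, spots in the denominator — mirrors the published convention
and means paired-end archives can read up to twice a per-read
normalization; `expression.denominator` exposes the alternative.
Isoform partitioning is identifier-set arithmetic: with A and B the
matching mate-identifier sets, shared = |A∩B| and the specific counts
are |A|−shared and |B|−shared, which makes a_only + b_only + shared =
union_total an identity. Each identifier enters each initial count once,
which is what makes the subtraction exact. Fold changes between archives
return ∞ for x/0 (zero-expression tissues are real) and NaN for 0/0,
never an exception.

One subtlety the tests pin down: "a read is shared iff its origin
window lies entirely in the isoform-common region" is exact only when
`min_match` equals the read length; at smaller `min_match` a
junction-spanning read still shares ≥ `min_match` nt with the other
isoform through the common prefix or suffix. The truth-table oracle
implements the `min_match`-aware rule and the tests check both regimes.

## Trees

Arthropod ilp precursors cannot be aligned position-homologously outside
the cysteines, so the package builds *similarity* trees, not
phylogenies: progressive alignment of the full, uncurated precursors
(3-mer-distance UPGMA guide tree; profile–profile Gotoh alignment with
BLOSUM62 expected scores, gap open 10 / extend 0.5), p-distances over
positions ungapped in both rows, canonical neighbor joining
(Q criterion; ties by lexicographic label pair; negative branch lengths
clamped to zero with the deficit moved to the sibling), and column
bootstrap supports (resample columns with replacement, rebuild, count
bipartition frequencies). NJ recovers additive metrics exactly — the
tests verify topology and branch lengths on random additive matrices
and cross-check against an independent NJ implementation. "Well
aligned" filtering is operationalized as column gap-fraction filtering
(default 0.5 when enabled); dropping whole sequences instead is
available behind a flag but has no default, since the original phrase
does not say which was meant. Receptor-style trees restrict positions
to transmembrane segments: maximal runs of 19-residue Kyte–Doolittle
window means ≥ 1.6, concatenated in sequence order.

A known limitation: when whole families share almost nothing, the
profile aligner can stagger two family blocks into complementary gaps,
leaving few comparable positions for those pairs and making their
p-distance an artifact of whatever does align (often the signal
peptide). This is inherent to similarity trees on uncurated alignments
of this divergence; supports should be read per-clade, and panels should
carry several members per family (the shipped analyses use three).

## The synthetic data: what it emulates, and what it does not

`simulate` generates the structures the analysis assumes, with complete
truth tables:

- **Genes.** Each family has a synthetic archetype template: a 15-residue
  signal peptide (MK + 10 hydrophobics + AGA), the framework cysteines at
  family-specific spacings, and family-specific conserved fractions of
  template positions between members (relaxin 0.80 > aIGF 0.70 >
  insulin 0.65 > gonadulin 0.45) — ordering the families by the relative
  conservation they show in real data, with gonadulin divergence the
  defining extreme. Non-conserved positions are filled uniformly from
  the 19 non-cysteine residues, so the framework is a sharp truth
  signal. The archetype aIGF gene has exactly four coding exons; exon 3
  carries a mid-exon alternative splice site whose included last part
  encodes an arginine-rich segment with two extra cysteines, and exon 4
  encodes the GTVx₁Px₂(F/Y) motif; splicing the segment out yields the
  short isoform. Relaxin genes can optionally carry the seventh,
  decapod-style cysteine. Exon boundaries are codon-aligned (phase 0) —
  real ilp genes splice mid-codon; nothing downstream depends on the
  difference, but genomic coordinates should not be read as biologically
  shaped.
- **Genomes.** Clusters of genes (default gonadulin–aIGF–relaxin, the
  triplication arrangement) are planted with exact intergenic distances
  between coding regions, in an i.i.d. 40% GC decoy background with no
  repeat structure. Introns open with GT, close with AG, and carry
  stop codons in all frames immediately after the donor so reading
  frames cannot run through them; a scrubbing pass then mutates
  background cysteines until no ORF outside the planted genes matches
  the default framework pattern at ≥ 60 aa — making "zero decoy hits" a
  designed property of the background, verified by scanning, rather
  than a probabilistic hope.
- **Reads.** Transcript choice is multinomial over abundance weights;
  fragment starts are uniform; paired mates are forward/reverse with a
  fixed insert; errors are i.i.d. substitutions. `tile_reads` gives the
  deterministic end-to-end tiling regime used for assembly benchmarks
  (uniform sampling leaves transcript termini uncovered at practical
  depths, which is a read-sampling fact, not an assembler defect).

Passing tests on this generator demonstrate the *logic* of every stage —
framework detection, recruitment, assembly, counting, partitioning,
tree grouping, synteny labelling — under the stated statistical
structure. They do not demonstrate robustness to what the generator
omits: sequencing-error profiles and quality models, rRNA/adapter
contamination, repeats and paralogous near-duplicates, fragment-length
biases, UTRs, or mid-codon splice phases.

## Problem sizes and seeds

The shipped analyses use desk-scale sizes chosen to exercise each claim
well away from its failure modes: a 5-cluster genome in 1 Mb of decoy
(15 genes) for recovery; a 900 nt transcript tiled at ~33× error-free
coverage with a 60 nt seed for the mining benchmark; 2 000 spots for
isoform partitioning; 200 random additive matrices of up to 12 taxa for
NJ; 100 bootstrap replicates over a fixed 12-precursor panel (three
members per family) for the grouping claim; and simulated expression
archives of 50 000 spots with a 30× planted gonadulin abundance
contrast between a queen-larva-like archive and six worker/male-like
archives — a strong gonadal-induction condition consistent with the
≥ 15-fold contrasts reported for real larval archives, sized so the
Poisson noise of the smallest counts cannot blur the planted ratio.
Every stochastic step takes an explicit seed; gene and template
construction hash (name, seed) pairs into independent streams, so all
outputs are pure functions of (spec, seed) across platforms.
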