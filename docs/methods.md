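# Methods

`estkit` re-implements, as a tested library, the bespoke computational
stages of a genome-wide EST (expressed sequence tag) transcriptome
analysis of the kind applied to cotton (*Gossypium hirsutum*): read
cleaning, similarity clustering of assembled contigs, pileup-based
SNP/indel mining with depth-stratified evidence rules, EST-SSR
detection with PCR primer design, and homology-based miRNA discovery
with hairpin metrics and target prediction. External-database steps
(vector/rRNA screening, repeat masking, BLAST annotation, GO/KEGG
enrichment) are out of scope; contaminant screening is an explicit
logged no-op.

Coordinates are 0-based, half-open everywhere except the blast-style
and VCF-style tabular reports, which follow their formats' 1-based
conventions.

## Read cleaning

Poly-A (3′) and poly-T (5′) tails are trimmed when a terminal run
contains at least `min_tail` = 10 tail bases with at most
`max_mismatch` = 1 interruption; the run must begin with the tail base
at its inner boundary, so internal homopolymers survive. These
defaults are this package's declared choices (upstream pipelines defer
to tool defaults that are not published); trimming is idempotent.

Low-complexity masking is DUST-style: each sliding window (default
64 nt) is scored `sum_t c_t(c_t-1)/2 / (window-3)` over its 3-mer
counts `c_t`, and every position of any window scoring above the
threshold (default 2) becomes N. Masking never changes sequence
length, and a lower threshold masks a superset of positions.

Reads under 100 nt are then discarded ("under" read strictly: a 100-nt
read is kept). The candidate CDS of a contig is its longest ORF over
all six frames (ATG to stop); because ESTs are fragments, an ORF
running off the 3′ end without a stop is eligible. Ties break to the
plus strand, then the lower start.

## Pairwise alignment and clustering

A seed-and-extend nucleotide aligner stands in for BLASTn: shared
exact 11-mers nominate diagonals; each diagonal receives a banded
(±20) Smith–Waterman alignment with affine gaps (match +1, mismatch
−2; a gap of length L costs −5 − 2L). Identity counts gap columns in
the denominator. E-values use the Karlin–Altschul form
`E = K·m·n·exp(−λS)` with ungapped nucleotide parameters λ = 1.28,
K = 0.46, declared in output headers; this is an internal substitute,
not a BLAST reconstruction, but it is E-value-denominated so the
published thresholds can be applied.

Clusters are connected components over edges where the better directed
best-hit has E < 1e-30 **and** identity > 90 % (both strict);
components of size ≥ 2 are clusters, the rest are reported
unclustered. Cross-set similarity reports, per E-value cutoff, the
fraction of queries with ≥ 1 hit in a reference set and the fraction
of references hit — monotone non-increasing as the cutoff tightens.

## SNP/indel mining

A contig alignment is a gapped consensus plus equal-length read rows;
`.` is pad (outside a read's span), `-` is a deletion assertion, and N
counts toward neither depth nor support. Per column, every
non-consensus allele is tested against depth-stratified support
minima:

| column depth | minimum variant reads |
|---|---|
| ≤ 4 | uncallable |
| 5–6 | 2 |
| 7–8 | 3 |
| 9–12 | 4 |
| ≥ 13 | 5 |

Depth is judged per column, not per contig: this stricter local
reading avoids calls under low-coverage contig ends. Tri-allelic
columns may emit one call per qualifying allele. Adjacent passed indel
columns with identical supporting reads merge into one indel event
(one biological insertion/deletion spans several alignment columns).

Per-contig frequencies (passed events per ungapped consensus
nucleotide) are standardised across contigs with the sample (n−1)
standard deviation; a contig is *significant* at z > 1.6449 (one-sided
P < 0.05) and *highly significant* at z > 2.3263 (P < 0.01). The test
is upper-tail only — the question is which contigs are unusually
polymorphic. Zero spread flags nothing and logs a warning.

## EST-SSRs and primers

Perfect tandem repeats of primitive 2–6 nt units are reported when
they reach 6 (di-), 5 (tri-) or 4 (tetra-/penta-/hexa-nucleotide)
repeats; homopolymers are excluded, a tract is reported only at its
primitive unit length, and loci never overlap another locus of the
same canonical class. The canonical class label is the
lexicographically smallest string among all rotations of the unit and
of its reverse complement, written `rep/revcomp(rep)` (e.g. AAG/CTT).

Primer design enumerates flanking candidates of 18–24 nt (optimum 20)
with GC 40–65 % (optimum 50) and products of 100–300 nt containing the
locus strictly inside. Melting temperature is the Wallace rule
`Tm = 2(A+T) + 4(G+C)`, chosen over nearest-neighbour thermodynamics
because it is deterministic and parameter-free and places the
20-mer/50 %-GC optimum exactly at the 60 °C annealing optimum. The
pair minimising `|Tm−60| + 0.5|GC−50| + |len−20|` (summed over both
primers) `+ |ΔTm|` wins; ties break to the smaller product, then the
leftmost pair. The penalty weights are this package's choices — only
the ranges and optima are externally given. A locus with no
satisfiable pair is reported as "no primer"; loci are never suppressed
for being near sequence ends, the two decisions are independent.

## miRNA discovery

Known plant matures (miRBase-style names; family = the digits after
"miR") are matched gap-free on both strands of every sequence with up
to 4 substitutions — the convention of homology-based EST-mining
methods, exposed as configuration. Around each hit, precursor windows
extend the mature by a 0–280 nt grid (20-nt steps) each side, keeping
total lengths of 60–300 nt (the plant pre-miRNA size range), clipped
at sequence ends. Minus-strand windows are reverse-complemented so the
precursor is always in mature-sense orientation.

**Folding.** The built-in engine maximises total pair weight (GC = 3,
AU = 2, GU = 1) over nested structures with a minimum hairpin loop of
3, via a Nussinov-style dynamic programme (numba-accelerated, with a
pure-Python fallback; an exhaustive enumeration oracle checks it at
small n). Traceback is deterministic: the 5′-most base prefers its
3′-most admissible partner. Reported MFE is therefore a model-unit
magnitude, not kcal/mol; AMFE = MFE/len×100 and MFEI = AMFE/GC% remain
well-defined, and the folding engine is pluggable — any callable
returning (dot-bracket, energy magnitude), e.g. a thermodynamic
folder, can replace it, in which case MFE is in kcal/mol magnitudes.

**Screening.** A candidate passes when the mature is 18–24 nt and at
least 14 of its bases pair into a *compact duplex core*: one partner
region with at most 4 internal unpaired bases, entirely on one side of
the mature, with partner positions strictly decreasing (a single stem,
no multiloop junction between mature and star arm). The compactness
bound matters because the weight-maximising fold has no loop
penalties: without it, a mature can "pair" into unrelated flank by
cherry-picking bases across large asymmetric loops, and such
pseudo-hairpins can out-rank the real stem on MFEI. Pairs outside the
core are treated as folding noise. The arm label (5′/3′) follows the
side of the duplex core: partners 3′ of the mature place it before the
terminal loop (5′ arm) and vice versa. Per (source, family, strand)
the lowest-mismatch then highest-MFEI candidate is kept; sense and
antisense hairpins are distinct discoveries (with a perfect stem the
reference matches both strands exactly, so collapsing strands would
make the choice arbitrary).

**Targets.** The reverse complement of each mature slides over
plus-strand transcripts without gaps. Each window is scored: mismatch
1.0, G:U wobble 0.5, doubled at mature positions 2–13 (the
seed-critical region). A site is rejected for any non-wobble mismatch
at positions 10–11 (the cleavage site), for more than 2 consecutive
mismatches, or for a total score above 4.0. Overlapping accepted
windows of one miRNA–transcript pair collapse to the best-scoring.

## Synthetic data

Each generator threads one `numpy.random.Generator` seeded explicitly
(no global state) and returns a truth manifest listing every planted
feature, so recovery is scored exactly.

- **Contig alignments**: uniform-random consensus; about half the
  reads span the whole contig, the rest random sub-intervals, so depth
  varies; each planted SNP/deletion is carried by exactly the evidence
  threshold's number of covering reads (or a requested support);
  independent substitution errors elsewhere. Planted columns are ≥ 2
  apart so indel events never merge.
- **SSR sequences**: tracts laid left-to-right between rejection-
  sampled repeat-free flanks (≥ 50 nt separation); flanks are resampled
  when they would extend a tract's period.
- **Hairpin ESTs**: precursor = mature + random loop (≥ 6 nt) +
  reverse-complemented star arm (or the mirror for a 3′-arm mature),
  with requested star-arm substitutions, in random flanks, optionally
  reverse-complemented for minus-strand cases; construction is
  resampled until the folder pairs ≥ 14 mature bases. Flanks are
  additionally rejection-sampled so that neither flank can pair the
  mature or star arm into a ≥ 14-bp compact duplex of its own — a flank
  containing a chance near-complement would plant a second, spurious
  hairpin and make the arm genuinely ambiguous.
- **Target transcripts**: a perfectly complementary site edited to a
  requested mismatch/wobble pattern (validated against the acceptance
  rules; impossible patterns raise), planted in random background.

These inputs deliberately reproduce only the statistical structure
each stage assumes — not transcriptome composition, expression levels,
sequencing chemistry or library bias — so green recovery tests show
the algorithms implement their rules exactly, not that the rules
suffice on real libraries.

## Problem sizes and numerics

The property suites run at: 1,000 synthetic contig alignments
(200 nt, 5–14 reads) against an independent per-column counter; 10,000
contigs for significance calibration (flagged fraction within
[0.045, 0.055] of the nominal 5 %); 500 random 5-kb sequences against
a brute-force SSR enumerator; 1,000 random ≤ 18-nt sequences against
exhaustive folding enumeration; 100 planted hairpins (both arms, both
strands) for end-to-end recovery; and 200 synthetic SSR loci for
primer-constraint compliance. Scores and thresholds are exact integer
or decimal comparisons except floating-point formula checks, which use
relative tolerances around 1e-9.

## Known limitations

- Folding energies are model units; published MFE/MFEI magnitudes from
  thermodynamic folders are not comparable (plug in such a folder for
  kcal/mol).
- The aligner's E-values use fixed ungapped Karlin–Altschul parameters
  without edge-effect correction; they order hits sensibly but are not
  BLAST-identical.
- Dataset-level published counts (contig totals, genome-wide SNP/SSR/
  target counts, cross-species similarity percentages) depend on full
  public EST downloads and reference databases and are out of scope.
- No base-quality awareness, haplotype phasing, compound/interrupted
  SSRs, or primer cross-dimer thermodynamics.
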