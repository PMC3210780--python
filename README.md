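# estkit

Genome-wide EST (expressed sequence tag) transcriptome mining for
species without an assembled genome — built around the analysis
pipeline applied to the cotton (*Gossypium hirsutum*) EST collection.
For researchers who have a pile of single-pass cDNA reads and
assembled contigs and want, from sequence alone: clean reads, gene
clusters, candidate SNPs/indels, EST-SSR markers with PCR primers, and
homology-predicted miRNAs with their targets.

## What it computes

- **Cleaning** — poly-A/T tail trimming, DUST-style low-complexity
  masking (score `Σ c_t(c_t−1)/2 / (w−3)` over window 3-mer counts),
  sub-100-nt filtering, and the longest-ORF candidate-CDS rule.
- **Clustering** — seed-and-extend local alignment with
  Karlin–Altschul E-values (`E = K·m·n·e^{−λS}`, λ = 1.28, K = 0.46);
  clusters are connected components of pairs with E < 1e-30 and
  identity > 90 %.
- **Polymorphism** — per-column pileups over contig multiple
  alignments; a variant allele needs ≥ 2 supporting reads at column
  depth 5–6, ≥ 3 at 7–8, ≥ 4 at 9–12, ≥ 5 at ≥ 13 (depth ≤ 4 is
  uncallable). Per-contig frequencies are standardised
  (`z = (f − f̄)/s`); contigs are flagged at z > 1.6449 (P < 0.05) and
  z > 2.3263 (P < 0.01), one-sided.
- **EST-SSRs** — maximal perfect 2–6 nt tandem repeats at ≥ 6/5/4/4/4
  repeats, canonical motif classes (e.g. AAG/CTT), and flanking primer
  pairs (18–24 nt, GC 40–65 %, product 100–300 nt, Wallace-rule
  `Tm = 2(A+T) + 4(G+C)`).
- **miRNAs** — gap-free matching of known plant matures (≤ 4
  mismatches, both strands), precursor-window folding with a weighted
  base-pair-maximisation DP (GC = 3, AU = 2, GU = 1; pluggable for a
  thermodynamic folder), hairpin metrics GC %, MFE,
  AMFE = MFE/len·100, MFEI = AMFE/GC %, duplex-geometry screening, and
  complementarity-scored target prediction (mismatch 1.0, G:U 0.5,
  doubled at mature positions 2–13, hard rules at positions 10–11).
- **Synthetic data** — seeded generators with truth manifests for
  every stage, so the whole pipeline is testable without downloads.

The packaged table `src/estkit/data/cotton_mirna_table.tsv` transcribes the 87
published cotton miRNA records used by the summary statistics.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Summary statistics of the packaged cotton miRNA table:

```sh
$ estkit summarize
{
  "length_max": 24,
  "length_mean": 20.3,
  "length_min": 18,
  "length_mode": 21,
  "length_sd": 1.4,
  "max_family_size": 6,
  "n_antisense": 32,
  "n_arm3": 50,
  "n_arm5": 37,
  "n_families": 57,
  "n_multi_member_families": 13,
  "n_records": 87,
  "n_sense": 55,
  "n_single_member_families": 44
}
```

Read: 87 miRNAs in 57 families (44 with a single member, largest
family 6 members); mature lengths 18–24 nt, mean 20.3 ± 1.4 with 21 nt
most common; 55 sense / 32 antisense to their source sequence; 50 on
the 3′ hairpin arm, 37 on the 5′ arm.

Discovering a planted hairpin and a target site from the library:

```python
from estkit import MatureRef, discover_mirnas, predict_targets
from estkit.synthetic_data import gen_hairpin_est, gen_target_transcript

ref = MatureRef("ath-miR156a", "UGACAGAAGAGAGUGAGCAC")
est, truth = gen_hairpin_est(ref, arm="5p", strand="+", seed=7)
(cand,) = [c for c in discover_mirnas([est], [ref]) if c.strand == "+"]
print(cand.ref_name, cand.location, f"MFEI {cand.mfei:.2f}")
# ath-miR156a 5p MFEI 2.10

tr, site = gen_target_transcript(ref, [(15, "wobble")], seed=8)
for s in predict_targets([(ref.name, ref.sequence)], [tr]):
    print(s.start, s.end, s.score, s.gu_pairs)
# 197 217 0.5 1
```

The candidate reports the planted arm and strand with MFEI computed
from its folded precursor; the target site scores 0.5 — one G:U wobble
outside the seed-critical region.

Other CLI entry points: `estkit clean`, `estkit cluster`,
`estkit variants`, `estkit ssr`, `estkit mirna`, `estkit targets`,
`estkit simulate` (synthetic inputs plus JSON truth manifests).

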