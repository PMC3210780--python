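"""Seeded generators for pipeline-shaped synthetic inputs.

Each generator returns its artificial input together with a
:class:`TruthManifest` recording every planted feature, so recovery can
be scored exactly.  All randomness flows through one
``numpy.random.default_rng(seed)`` per call; the same seed always
reproduces the same output byte for byte.

These generators emulate the statistical structure each analysis stage
assumes (planted variants at controlled depth, perfect SSR tracts in
repeat-free flanks, designed stem-loops carrying a known mature,
planted target sites) and deliberately nothing else about real EST
data: no realistic transcriptome composition, expression levels,
chimeras, or library biases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import Seq, revcomp
from .polymorphism import ContigAlignment, GAP, PAD, min_support
from .ssr_primer import DEFAULT_MIN_REPEATS, is_primitive, scan_ssrs
from .mirna import (
    DEFAULT_CRITERIA,
    MatureRef,
    _duplex_core,
    fold,
    pair_table,
    score_site,
)

log = logging.getLogger("estkit")

_BASES = np.array(list("ACGT"))


@dataclass
class TruthManifest:
    """Ground truth for one generated input."""

    kind: str                       # variant | ssr | hairpin | target
    items: List[dict]
    params: Dict[str, object]
    seed: int


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


# ---------------------------------------------------------------------------
# contig alignments with planted variants
# ---------------------------------------------------------------------------

def gen_contig_alignment(
    n_reads: int,
    length: int,
    n_snps: int,
    n_indels: int,
    error_rate: float = 0.0,
    seed: int = 0,
    support: Optional[int] = None,
    full_span_fraction: float = 0.5,
    contig_id: str = "synthetic_contig",
) -> Tuple[ContigAlignment, TruthManifest]:
    """A contig alignment with planted SNPs/deletions and random errors.

    The consensus is uniform over {A,C,G,T}.  Roughly
    ``full_span_fraction`` of the reads span the whole contig; the rest
    cover random sub-intervals, so per-column depth varies.  Each
    planted variant is assigned to ``support`` reads covering its
    column (default: exactly the evidence threshold for that column's
    depth); independent substitution errors at ``error_rate`` are
    sprinkled over non-planted columns.  Planted columns are spaced at
    least 2 apart so indel events never merge.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    consensus = _random_dna(rng, length)
    # read spans
    spans = []
    for r in range(n_reads):
        if rng.random() < full_span_fraction or length < 40:
            spans.append((0, length))
        else:
            a = int(rng.integers(0, length // 4 + 1))
            b = int(rng.integers(3 * length // 4, length)) + 1
            spans.append((a, b))
    rows = [list(consensus[a:b].rjust(b, PAD).ljust(length, PAD)) for a, b in spans]
    # pick planted columns: depth >= 5 under the spans, spaced >= 2 apart
    items: List[dict] = []
    taken: List[int] = []
    order = rng.permutation(length)
    wanted = [("SNP", None)] * n_snps + [("indel", None)] * n_indels
    for kind, _ in wanted:
        placed = False
        for col in order:
            col = int(col)
            if any(abs(col - t) < 2 for t in taken):
                continue
            covering = [r for r in range(n_reads) if spans[r][0] <= col < spans[r][1]]
            depth = len(covering)
            thr = min_support(depth)
            if support is not None:
                sup = support
            elif np.isfinite(thr):
                sup = int(thr)
            elif n_reads <= 4:
                sup = min(2, depth)  # deliberately uncallable contig
            else:
                continue  # default: plant only at callable columns
            if sup > depth or sup < 1:
                continue
            carriers = sorted(rng.choice(covering, size=sup, replace=False).tolist())
            cons_base = consensus[col]
            if kind == "SNP":
                allele = _mutate_base(rng, cons_base)
            else:
                allele = GAP
            for r in carriers:
                rows[r][col] = allele
            taken.append(col)
            items.append(
                {
                    "kind": kind,
                    "column": col,
                    "consensus_allele": cons_base,
                    "variant_allele": allele,
                    "support": sup,
                    "depth": depth,
                    "carriers": [f"read{r}" for r in carriers],
                    "expected_pass": bool(np.isfinite(thr) and sup >= thr),
                }
            )
            placed = True
            break
        if not placed:
            raise ValueError("could not place a planted variant (requested support too high?)")
    # independent sequencing errors outside planted columns
    if error_rate > 0:
        for r in range(n_reads):
            a, b = spans[r]
            for col in range(a, b):
                if col in taken:
                    continue
                if rng.random() < error_rate:
                    if rows[r][col] in "ACGT":
                        rows[r][col] = _mutate_base(rng, rows[r][col])
    aln = ContigAlignment(
        contig_id, consensus, [(f"read{r}", "".join(rows[r])) for r in range(n_reads)]
    )
    manifest = TruthManifest(
        kind="variant",
        items=items,
        params={
            "n_reads": n_reads,
            "length": length,
            "n_snps": n_snps,
            "n_indels": n_indels,
            "error_rate": error_rate,
            "support": support,
        },
        seed=seed,
    )
    return aln, manifest


# ---------------------------------------------------------------------------
# SSR-bearing sequences
# ---------------------------------------------------------------------------

def _repeat_free_flank(rng: np.random.Generator, n: int, max_tries: int = 200) -> str:
    """Random DNA containing no reportable SSR (rejection-sampled)."""
    for attempt in range(max_tries):
        cand = _random_dna(rng, n)
        if not scan_ssrs(Seq("flank", cand)):
            if attempt > 20:
                log.info("flank rejection sampling took %d tries", attempt + 1)
            return cand
    raise RuntimeError(f"no repeat-free flank of length {n} in {max_tries} tries")


def gen_ssr_sequence(
    motifs_with_repeats: Sequence[Tuple[str, int]],
    flank_len: int = 200,
    seed: int = 0,
    seq_id: str = "synthetic_ssr",
) -> Tuple[Seq, TruthManifest]:
    """A sequence with planted perfect SSR tracts in repeat-free flanks.

    Tracts are laid out left to right separated by >= 50 nt of
    repeat-free spacer; outer flanks are ``flank_len`` nt.  Motifs must
    be primitive; repeat counts may be below threshold on purpose (the
    manifest records whether each tract is expected to be reported).
    """
    rng = np.random.default_rng(seed)
    parts = [_repeat_free_flank(rng, flank_len)]
    items = []
    pos = flank_len
    for i, (motif, reps) in enumerate(motifs_with_repeats):
        motif = motif.upper()
        if not is_primitive(motif) or not 2 <= len(motif) <= 6:
            raise ValueError(f"motif {motif!r} must be primitive, length 2-6")
        tract = motif * reps
        # the preceding part must not extend the tract's period leftwards
        while parts[-1].endswith(motif[-1]):
            parts[-1] = _repeat_free_flank(rng, len(parts[-1]))
        items.append(
            {
                "motif": motif,
                "repeats": reps,
                "start": pos,
                "end": pos + len(tract),
                "expected_reported": reps >= DEFAULT_MIN_REPEATS[len(motif)],
            }
        )
        parts.append(tract)
        pos += len(tract)
        spacer_len = max(50, flank_len if i == len(motifs_with_repeats) - 1 else 50)
        spacer = _repeat_free_flank(rng, spacer_len)
        # avoid accidental extension of the tract into the spacer
        while spacer.startswith(motif[0]):
            spacer = _repeat_free_flank(rng, spacer_len)
        parts.append(spacer)
        pos += spacer_len
    seq = Seq(seq_id, "".join(parts))
    manifest = TruthManifest(
        kind="ssr",
        items=items,
        params={"flank_len": flank_len, "motifs": list(map(list, motifs_with_repeats))},
        seed=seed,
    )
    return seq, manifest


# ---------------------------------------------------------------------------
# hairpin-bearing ESTs
# ---------------------------------------------------------------------------

def _flank_forms_pseudo_duplex(flank: str, arms: Sequence[str]) -> bool:
    """True when ``flank`` can pair an arm into a compact >=14-bp duplex.

    A flank that happens to contain a near-complement of the mature (or
    of the star arm) plants a second, spurious hairpin in the read, so
    such flanks are rejected: the generator promises exactly one
    admissible stem-loop per sequence.
    """
    for arm in arms:
        probe = flank + arm
        structure, _ = fold(probe)
        span = (len(flank), len(probe))
        if _duplex_core(pair_table(structure), span, DEFAULT_CRITERIA) is not None:
            return True
    return False


def gen_hairpin_est(
    mature: MatureRef,
    arm: str = "5p",
    stem_mismatches: int = 0,
    flank_len: int = 60,
    loop_len: int = 8,
    seed: int = 0,
    strand: str = "+",
    seq_id: str = "synthetic_hairpin_est",
    max_attempts: int = 100,
) -> Tuple[Seq, TruthManifest]:
    """An EST-like DNA sequence containing a designed miRNA stem-loop.

    The precursor is mature + loop + revcomp(mature) for a 5' arm (the
    mirror construction for a 3' arm), with ``stem_mismatches``
    substitutions injected into the partner strand, embedded in random
    flanks; with ``strand`` '-' the whole EST carries the reverse
    complement.  Construction is resampled until the built-in folder
    pairs at least 14 mature bases (error after ``max_attempts``).
    """
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    if loop_len < 6:
        raise ValueError("loop_len must be >= 6")
    mat_dna = mature.sequence.replace("U", "T")
    lm = len(mat_dna)
    rng = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        partner = list(revcomp(mat_dna))
        if stem_mismatches:
            idx = rng.choice(len(partner), size=stem_mismatches, replace=False)
            for i in idx:
                partner[i] = _mutate_base(rng, partner[i])
        partner_s = "".join(partner)
        loop = _random_dna(rng, loop_len)
        if arm == "5p":
            prec = mat_dna + loop + partner_s
            m_start = 0
        else:
            prec = partner_s + loop + mat_dna
            m_start = lm + loop_len
        structure, _ = fold(prec)
        pt = pair_table(structure)
        paired = sum(1 for i in range(m_start, m_start + lm) if pt[i] != -1)
        if paired < 14:
            continue
        arms = (mat_dna, "".join(partner))
        left = _random_dna(rng, flank_len)
        right = _random_dna(rng, flank_len)
        if flank_len >= 20:
            tries = 0
            while _flank_forms_pseudo_duplex(left, arms):
                left = _random_dna(rng, flank_len)
                tries += 1
                if tries > 50:
                    break
            while _flank_forms_pseudo_duplex(right, arms):
                right = _random_dna(rng, flank_len)
                tries += 1
                if tries > 100:
                    break
            if tries > 100:
                continue  # resample the whole construction
        est_plus = left + prec + right
        est = est_plus if strand == "+" else revcomp(est_plus)
        offset_plus = flank_len + m_start
        manifest = TruthManifest(
            kind="hairpin",
            items=[
                {
                    "mature": mature.sequence,
                    "ref_name": mature.name,
                    "family": mature.family,
                    "arm": arm,
                    "strand": strand,
                    "precursor_start": flank_len,
                    "precursor_end": flank_len + len(prec),
                    "mature_offset_plus": offset_plus,
                    "stem_mismatches": stem_mismatches,
                }
            ],
            params={
                "flank_len": flank_len,
                "loop_len": loop_len,
                "attempts": attempt + 1,
            },
            seed=seed,
        )
        return Seq(seq_id, est), manifest
    raise RuntimeError(
        f"could not satisfy the >=14 paired-mature-bases guarantee in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# target transcripts
# ---------------------------------------------------------------------------

def _complement_site(mature_rna: str) -> List[str]:
    """Perfectly complementary target window (mRNA sense, 5'->3')."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    # mature position p (1-based) faces window index lm - p
    lm = len(mature_rna)
    win = [""] * lm
    for p in range(1, lm + 1):
        win[lm - p] = comp[mature_rna[p - 1]]
    return win


def gen_target_transcript(
    mature: MatureRef,
    site_spec: Sequence[Tuple[int, str]] = (),
    length: int = 300,
    seed: int = 0,
    seq_id: str = "synthetic_transcript",
) -> Tuple[Seq, TruthManifest]:
    """A transcript carrying one planted miRNA target site.

    ``site_spec`` lists (mature_position_1based, kind) edits applied to
    the perfectly complementary site: kind 'mismatch' substitutes a
    non-pairing, non-wobble base; kind 'wobble' turns the pair into a
    G:U pair (only possible opposite mature G or U; error otherwise).
    The expected score under the scoring rules is recorded in the
    manifest; a spec the acceptance rules would reject (mismatch at
    positions 10-11, >2 consecutive mismatches) raises ValueError.
    The background is dinucleotide-shuffle-like random sequence.
    """
    rng = np.random.default_rng(seed)
    mat = mature.sequence
    lm = len(mat)
    if length < lm + 20:
        raise ValueError("transcript too short for a site plus background")
    win = _complement_site(mat)
    for p, kind in site_spec:
        if not 1 <= p <= lm:
            raise ValueError(f"mature position {p} out of range")
        m = mat[p - 1]
        ti = lm - p
        if kind == "wobble":
            if m == "G":
                win[ti] = "U"
            elif m == "U":
                win[ti] = "G"
            else:
                raise ValueError(f"no G:U wobble possible opposite mature {m} at {p}")
        elif kind == "mismatch":
            comp = {"A": "U", "U": "A", "G": "C", "C": "G"}[m]
            wob = {"G": "U", "U": "G"}.get(m)
            choice = [b for b in "ACGU" if b != comp and b != wob and b != m]
            win[ti] = choice[rng.integers(0, len(choice))]
        else:
            raise ValueError(f"unknown site edit kind {kind!r}")
    window = "".join(win)
    scored = score_site(mat, window)
    if scored is None:
        raise ValueError("site_spec is rejected by the target-site rules")
    site_dna = window.replace("U", "T")
    pos = int(rng.integers(10, length - lm - 10))
    background = _random_dna(rng, length)
    residues = background[:pos] + site_dna + background[pos + lm :]
    manifest = TruthManifest(
        kind="target",
        items=[
            {
                "mirna": mature.name,
                "start": pos,
                "end": pos + lm,
                "expected_score": scored[0],
                "mismatches": scored[1],
                "gu_pairs": scored[2],
            }
        ],
        params={"length": length, "site_spec": list(map(list, site_spec))},
        seed=seed,
    )
    return Seq(seq_id, residues), manifest
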