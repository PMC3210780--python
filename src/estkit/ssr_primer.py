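"""Perfect microsatellite (EST-SSR) scanning and flanking-primer design.

Scans for perfect di- through hexa-nucleotide tandem repeats with
motif-size-specific minimum repeat counts (6, 5, 4, 4, 4), names each
locus by its canonical motif class (lexicographic minimum over
rotations of the unit and of its reverse complement), and designs
flanking PCR primer pairs under length 18-24 nt (optimum 20), GC
40-65% (optimum 50), product 100-300 nt and a 60 degC optimal
annealing temperature, with Tm by the Wallace rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import Seq, revcomp

DEFAULT_MIN_REPEATS: Dict[int, int] = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class SSRLocus:
    seq_id: str
    start: int            # 0-based half-open on the source sequence
    end: int
    motif: str            # repeat unit as found
    canonical_motif: str  # e.g. "AAG/CTT"
    repeats: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.repeats:
            raise ValueError("locus span != unit_len * repeats")

    @property
    def unit_len(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class PrimerPair:
    left: str             # 5'->3' on the forward strand
    right: str            # 5'->3' on the reverse strand
    tm_left: float
    tm_right: float
    gc_left: float
    gc_right: float
    product_size: int
    penalty: float
    left_start: int = 0   # 0-based forward-strand start of the left primer
    right_end: int = 0    # 0-based half-open end of the product


def is_primitive(unit: str) -> bool:
    """True when the unit is not a whole-number repeat of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Canonical class label for a primitive repeat unit.

    Among all rotations of the unit and of its reverse complement, the
    lexicographically smallest string is the representative; the label
    is "representative/reverse-complement-of-representative".  The
    label is invariant under rotation and reverse complementation of
    the input.
    """
    unit = unit.upper()
    if not 2 <= len(unit) <= 6:
        raise ValueError("unit length must be 2-6")
    if not is_primitive(unit):
        raise ValueError(f"unit {unit!r} is not primitive")
    rc = revcomp(unit)
    rotations = {unit[i:] + unit[:i] for i in range(len(unit))}
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    rep = min(rotations)
    return f"{rep}/{revcomp(rep)}"


def scan_ssrs(
    seq: Seq, min_repeats: Dict[int, int] = DEFAULT_MIN_REPEATS
) -> List[SSRLocus]:
    """All maximal perfect tandem repeats meeting the repeat thresholds.

    Only primitive units of length 2-6 are reported (a dinucleotide
    tract is never re-reported as its tetranucleotide doubling, and
    homopolymers are excluded).  A locus is maximal: it cannot be
    extended by one more full unit on either side.  Loci overlapping a
    longer locus of the same canonical class are suppressed.
    """
    res = seq.residues
    n = len(res)
    found: List[SSRLocus] = []
    for L, min_rep in sorted(min_repeats.items()):
        i = 0
        while i + 2 * L <= n:
            if res[i : i + L] != res[i + L : i + 2 * L]:
                i += 1
                continue
            # maximal run with period L starting at i
            j = i + L
            while j < n and res[j] == res[j - L]:
                j += 1
            repeats = (j - i) // L
            unit = res[i : i + L]
            if repeats >= min_rep and is_primitive(unit) and "N" not in unit:
                found.append(
                    SSRLocus(
                        seq_id=seq.id,
                        start=i,
                        end=i + L * repeats,
                        motif=unit,
                        canonical_motif=canonical_motif(unit),
                        repeats=repeats,
                    )
                )
            i = j - L + 1  # first position after the run that can start a new run
    # suppress loci overlapping a longer locus of the same canonical class
    found.sort(key=lambda l: (-(l.end - l.start), l.start, l.unit_len))
    kept: List[SSRLocus] = []
    for loc in found:
        clash = any(
            k.canonical_motif == loc.canonical_motif
            and k.start < loc.end
            and loc.start < k.end
            for k in kept
        )
        if not clash:
            kept.append(loc)
    kept.sort(key=lambda l: (l.start, l.unit_len))
    return kept


def melting_temp(primer: str) -> float:
    """Wallace-rule melting temperature: 2*(A+T) + 4*(G+C) degC."""
    primer = primer.upper()
    if not 10 <= len(primer) <= 36:
        raise ValueError("primer length must be 10-36 nt")
    if "N" in primer:
        raise ValueError("primer contains N")
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


def gc_percent(s: str) -> float:
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class PrimerParams:
    len_min: int = 18
    len_max: int = 24
    len_opt: int = 20
    gc_min: float = 40.0
    gc_max: float = 65.0
    gc_opt: float = 50.0
    tm_opt: float = 60.0
    product_min: int = 100
    product_max: int = 300


DEFAULT_PRIMER_PARAMS = PrimerParams()


def _candidates(res: str, lo: int, hi: int, p: PrimerParams):
    """Primer candidates (start, end, tm, gc, partial_penalty) fully
    inside [lo, hi) on the forward strand, satisfying per-primer
    constraints."""
    out = []
    for start in range(lo, hi):
        for length in range(p.len_min, p.len_max + 1):
            end = start + length
            if end > hi:
                break
            sub = res[start:end]
            if "N" in sub:
                continue
            gc = gc_percent(sub)
            if not p.gc_min <= gc <= p.gc_max:
                continue
            tm = melting_temp(sub)
            pen = abs(tm - p.tm_opt) + 0.5 * abs(gc - p.gc_opt) + 1.0 * abs(length - p.len_opt)
            out.append((start, end, tm, gc, pen))
    return out


def design_primers(
    seq: Seq, locus: SSRLocus, params: PrimerParams = DEFAULT_PRIMER_PARAMS
) -> Optional[PrimerPair]:
    """Best flanking primer pair for an SSR locus, or None.

    Candidates are enumerated in the flanks (left primer wholly before
    the locus, right primer wholly after), each 18-24 nt with GC in
    40-65%; the product must span 100-300 nt with the locus strictly
    inside.  Pair penalty = sum of per-primer |Tm-60| + 0.5|GC-50| +
    |len-20| plus the pair's |Tm_left - Tm_right|; the minimum-penalty
    pair wins, ties broken by smaller product then leftmost.
    """
    if locus.seq_id != seq.id:
        raise ValueError("locus is not from this sequence")
    res = seq.residues
    n = len(res)
    # product covers [left_start, right_end); constrain search windows
    left_lo = max(0, locus.end - params.product_max)
    lefts = [c for c in _candidates(res, left_lo, locus.start, params)]
    rights = _candidates(res, locus.end, min(n, locus.start + params.product_max), params)
    if not lefts or not rights:
        return None
    r_start = np.array([c[0] for c in rights])
    r_end = np.array([c[1] for c in rights])
    r_tm = np.array([c[2] for c in rights])
    r_pen = np.array([c[4] for c in rights])
    best = None  # (penalty, product, left_start, left_candidate, right_idx)
    for lcand in lefts:
        ls, le, ltm, lgc, lpen = lcand
        product = r_end - ls
        ok = (product >= params.product_min) & (product <= params.product_max)
        if not ok.any():
            continue
        total = lpen + r_pen + np.abs(ltm - r_tm)
        total = np.where(ok, total, np.inf)
        idx = int(np.lexsort((r_start, product, total))[0])
        if not ok[idx]:
            continue
        cand = (float(total[idx]), int(product[idx]), ls, lcand, idx)
        if best is None or cand[:3] < best[:3]:
            best = cand
    if best is None:
        return None
    penalty, product, _, lcand, ridx = best
    ls, le, ltm, lgc, lpen = lcand
    rs, re, rtm, rgc, rpen = rights[ridx]
    left_seq = res[ls:le]
    right_seq = revcomp(res[rs:re])
    return PrimerPair(
        left=left_seq,
        right=right_seq,
        tm_left=ltm,
        tm_right=rtm,
        gc_left=lgc,
        gc_right=rgc,
        product_size=int(re - ls),
        penalty=float(penalty),
        left_start=ls,
        right_end=re,
    )
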