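"""Homology-based miRNA discovery and target prediction.

Known plant mature miRNAs are matched gap-free (both strands, up to a
mismatch budget) against EST/contig sequences; candidate precursor
windows around each match are excised on a flank grid, folded, and
screened on hairpin geometry and the standard EST-mining metrics:
GC%, MFE, AMFE = MFE/len*100 and MFEI = AMFE/GC%.

The built-in folding engine is a weighted base-pair-maximisation
dynamic programme (GC=3, AU=2, GU=1, minimum loop 3) rather than a
nearest-neighbour thermodynamic model: it is deterministic,
dependency-free, admits an exhaustive-search oracle, and preserves the
hairpin geometry and MFEI screening logic; its energies are model
units, not kcal/mol.  Any callable with the same ``fold`` signature
(e.g. a thermodynamic folder) can be plugged into the pipeline.

Target sites are scored by weighted complementarity: mismatch 1.0,
G:U wobble 0.5, doubled within mature positions 2-13, no gaps; a site
needs score <= 4.0, perfect pairing (wobble allowed) at positions
10-11, and no more than 2 consecutive mismatches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import Seq, revcomp

# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------

_FAMILY_RE = re.compile(r"miR(\d+)", re.IGNORECASE)


def assign_family(name: str) -> str:
    """Family token: the digits following 'miR' in a miRBase-style name.

    Letter/isoform suffixes and arm tags are ignored: ath-miR156a ->
    '156', ghr-miR2948-5p -> '2948', osa-miR399d.2 -> '399'.
    """
    m = _FAMILY_RE.search(name)
    if not m:
        raise ValueError(f"cannot parse miRNA family from name {name!r}")
    return m.group(1)


@dataclass(frozen=True)
class MatureRef:
    """A known mature miRNA reference (miRBase-style)."""

    name: str
    sequence: str  # RNA (U, not T)
    family: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if not 18 <= len(seq) <= 26:
            raise ValueError(f"{self.name}: mature length {len(seq)} outside 18-26")
        object.__setattr__(self, "sequence", seq)
        if not self.family:
            object.__setattr__(self, "family", assign_family(self.name))


def read_mature_fasta(path) -> List[MatureRef]:
    from Bio import SeqIO

    return [MatureRef(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# homology matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureHit:
    seq_id: str
    offset: int      # 0-based start of the match on the source sequence
    strand: str      # '+': sequence carries the mature; '-': its revcomp does
    ref: MatureRef
    mismatches: int


def _hamming(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def match_known(
    seqs: Sequence[Seq], refs: Sequence[MatureRef], max_mismatch: int = 4
) -> List[MatureHit]:
    """Gap-free matches of known matures against every sequence window.

    Each reference (as DNA) and its reverse complement slide over every
    sequence; windows within ``max_mismatch`` substitutions are hits
    (strand '-' for the reverse complement).  Per (sequence, reference,
    strand) only the minimum-mismatch hit is kept (leftmost on ties).
    """
    if not refs:
        raise ValueError("empty reference set")
    hits: List[MatureHit] = []
    for s in seqs:
        res = s.residues
        for ref in refs:
            probe_f = ref.sequence.replace("U", "T")
            m = len(probe_f)
            if m > len(res):
                continue
            for strand, probe in (("+", probe_f), ("-", revcomp(probe_f))):
                best: Optional[Tuple[int, int]] = None
                for off in range(len(res) - m + 1):
                    d = _hamming(res[off : off + m], probe, max_mismatch)
                    if d <= max_mismatch and (best is None or d < best[0]):
                        best = (d, off)
                        if d == 0:
                            break
                if best is not None:
                    hits.append(MatureHit(s.id, best[1], strand, ref, best[0]))
    return hits


# ---------------------------------------------------------------------------
# precursor excision
# ---------------------------------------------------------------------------

def excise_precursors(
    seq: Seq,
    hit: MatureHit,
    flank_steps: Sequence[int] = tuple(range(0, 281, 20)),
    total_min: int = 60,
    total_max: int = 300,
) -> List[Tuple[int, int, int]]:
    """Candidate precursor windows (start, end, mature_offset) around a hit.

    The mature is extended upstream and downstream by every pair of
    grid amounts, windows clipped at the sequence ends; only windows
    with total length in [total_min, total_max] are kept, deduplicated.
    """
    n = len(seq)
    lm = len(hit.ref.sequence)
    if lm > n:
        return []
    windows = set()
    for up in flank_steps:
        for down in flank_steps:
            start = max(0, hit.offset - up)
            end = min(n, hit.offset + lm + down)
            if total_min <= end - start <= total_max:
                windows.add((start, end))
    return sorted((s, e, hit.offset - s) for s, e in windows)


# ---------------------------------------------------------------------------
# folding (weighted base-pair maximisation, pluggable)
# ---------------------------------------------------------------------------

MIN_LOOP = 3

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_PAIR_W = np.zeros((4, 4), dtype=np.int64)
_PAIR_W[2, 1] = _PAIR_W[1, 2] = 3  # G-C
_PAIR_W[0, 3] = _PAIR_W[3, 0] = 2  # A-U
_PAIR_W[2, 3] = _PAIR_W[3, 2] = 1  # G-U


def _fill_dp_python(enc: np.ndarray) -> np.ndarray:
    n = enc.shape[0]
    M = np.zeros((n, n), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                w = _PAIR_W[enc[i], enc[k]]
                if w > 0:
                    inner = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    rest = M[k + 1, j] if k + 1 <= j else 0
                    v = w + inner + rest
                    if v > best:
                        best = v
            M[i, j] = best
    return M

try:  # jit-compile the DP fill; fall back to pure Python
    from numba import njit

    _fill_dp = njit(_fill_dp_python)
except Exception:  # pragma: no cover
    _fill_dp = _fill_dp_python


def fold(rna: str) -> Tuple[str, float]:
    """Fold an RNA into its maximum-weight nested structure.

    Dynamic programme over nested structures maximising the sum of pair
    weights (GC=3, AU=2, GU=1) with a minimum hairpin loop of 3
    unpaired bases.  Returns (dot-bracket structure, MFE magnitude).
    Traceback is deterministic: the 5'-most base prefers pairing with
    the 3'-most admissible partner, bifurcating at the smallest split.
    """
    rna = rna.upper().replace("T", "U")
    if len(rna) < 10:
        raise ValueError("sequence shorter than 10 nt")
    try:
        enc = np.array([_ENC[c] for c in rna], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-ACGU(T) character {e.args[0]!r}") from None
    n = len(rna)
    M = _fill_dp(enc)
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            paired = False
            # prefer pairing i, with the 3'-most partner achieving the optimum
            for k in range(j, i + MIN_LOOP, -1):
                w = _PAIR_W[enc[i], enc[k]]
                if w == 0:
                    continue
                inner = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                rest = M[k + 1, j] if k + 1 <= j else 0
                if w + inner + rest == M[i, j]:
                    struct[i] = "("
                    struct[k] = ")"
                    if k + 1 <= j:
                        stack.append((k + 1, j))
                    i, j = i + 1, k - 1
                    paired = True
                    break
            if not paired:
                i += 1
    return "".join(struct), float(M[0, n - 1])


def pair_table(structure: str) -> List[int]:
    """Partner index per position (-1 if unpaired); raises on imbalance."""
    pt = [-1] * len(structure)
    stack: List[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced structure")
    return pt


def hairpin_loops(structure: str) -> List[Tuple[int, int]]:
    """(p, q) closing pairs of hairpin loops (no pair strictly inside)."""
    pt = pair_table(structure)
    loops = []
    for p, q in ((i, pt[i]) for i in range(len(pt)) if pt[i] > i):
        if all(pt[k] == -1 for k in range(p + 1, q)):
            loops.append((p, q))
    return loops


# ---------------------------------------------------------------------------
# hairpin metrics and screening
# ---------------------------------------------------------------------------

def hairpin_metrics(
    precursor: str,
    structure: str,
    mfe: float,
    mature_span: Tuple[int, int],
) -> Tuple[float, float, float, str]:
    """(GC%, AMFE, MFEI, location) for a folded precursor.

    AMFE = MFE / len * 100; MFEI = AMFE / GC%.  Location is derived
    from the side of the mature's pairing partners: the terminal loop
    of the mature's stem lies between the mature and its partners, so
    partners entirely 3' of the mature place it before the loop ('5p')
    and partners entirely 5' place it after ('3p').  A mature whose
    partners straddle it, or that pairs with itself, sits across the
    terminal loop ('loop'); an entirely unpaired mature gives 'NA'.
    Zero GC makes MFEI undefined and raises ValueError (candidate
    rejected upstream).
    """
    n = len(precursor)
    gc = 100.0 * sum(1 for c in precursor.upper() if c in "GC") / n
    if gc == 0.0:
        raise ValueError("GC% is zero; MFEI undefined")
    amfe = mfe / n * 100.0
    mfei = amfe / gc
    s, e = mature_span
    pt = pair_table(structure)
    core = _duplex_core(pt, mature_span, DEFAULT_CRITERIA)
    if core is not None:
        partners = [j for _, j in core]  # judge by the duplex core
    else:
        partners = [pt[i] for i in range(s, e) if pt[i] != -1]
    if not partners:
        loc = "NA"
    elif all(j >= e for j in partners):
        loc = "5p"
    elif all(j < s for j in partners):
        loc = "3p"
    else:
        loc = "loop"
    return gc, amfe, mfei, loc


@dataclass(frozen=True)
class MiRNACandidate:
    """A screened miRNA candidate with its precursor and hairpin metrics."""

    mature_seq: str      # RNA
    lm: int
    strand: str          # relative to the source EST/contig
    location: str        # '5p' or '3p'
    precursor_seq: str   # RNA, mature-sense orientation
    structure: str
    gc_pct: float
    mfe: float
    amfe: float
    mfei: float
    source_id: str
    family: str
    ref_name: str
    mismatches_vs_ref: int
    mature_start: int    # offset of the mature within the precursor

    def __post_init__(self) -> None:
        if not 18 <= self.lm <= 24:
            raise ValueError("mature length outside 18-24")
        if self.mfei < 0:
            raise ValueError("negative MFEI")


@dataclass(frozen=True)
class ScreenCriteria:
    lm_min: int = 18
    lm_max: int = 24
    min_paired_mature: int = 14
    max_partner_defect: int = 4   # unpaired bases tolerated inside the star arm


DEFAULT_CRITERIA = ScreenCriteria()


def _duplex_core(pt: List[int], span: Tuple[int, int], crit: ScreenCriteria):
    """Largest compact miRNA:star duplex core, or None.

    The core is a maximal set of the mature's base pairs whose partner
    positions fall in one contiguous region containing at most
    ``max_partner_defect`` unpaired bases (a real star arm tolerates
    only small bulges; pairings cherry-picked from unrelated sequence
    need large asymmetric loops).  Pairs outside the core are treated
    as folding noise.  Requirements: core size >= min_paired_mature,
    partners entirely outside the mature and on one side of it, and
    strictly decreasing with mature position (one stem, no multiloop
    junction between mature and star).  Returns the core pair list or
    None when no admissible core exists.
    """
    s, e = span
    pairs = [(i, pt[i]) for i in range(s, e) if pt[i] != -1]
    if len(pairs) < crit.min_paired_mature:
        return None
    js = sorted(j for _, j in pairs)
    best = None
    for a in range(len(js)):
        for b in range(a + crit.min_paired_mature - 1, len(js)):
            count = b - a + 1
            if js[b] - js[a] + 1 - count <= crit.max_partner_defect:
                if best is None or count > best[0]:
                    best = (count, js[a], js[b])
    if best is None:
        return None
    _, lo, hi = best
    core = [(i, j) for i, j in pairs if lo <= j <= hi]
    prev = None
    for i, j in core:
        if s <= j < e:  # pairs inside the mature itself
            return None
        if prev is not None and j >= prev:  # multiloop junction
            return None
        prev = j
    if not (all(j >= e for _, j in core) or all(j < s for _, j in core)):
        return None
    return core


def _mature_geometry_ok(structure: str, span: Tuple[int, int], crit: ScreenCriteria) -> bool:
    """True when the mature sits on one arm of a compact duplex."""
    return _duplex_core(pair_table(structure), span, crit) is not None


def screen_candidates(
    cands: Sequence[MiRNACandidate], criteria: ScreenCriteria = DEFAULT_CRITERIA
) -> List[MiRNACandidate]:
    """Hairpin-quality screen and per-(source, family) deduplication.

    A candidate passes when its mature is 18-24 nt, lies entirely on
    one arm (no base in the terminal loop), has at least 14 bases
    paired within a single stem segment (no multiloop junction).  Per
    (source_id, family, strand) the lowest-mismatch then highest-MFEI
    candidate is kept: a sense and an antisense hairpin on the same
    source are distinct discoveries (antisense candidates are counted
    in their own right downstream).
    """
    passed = []
    for c in cands:
        if not criteria.lm_min <= c.lm <= criteria.lm_max:
            continue
        if c.location not in ("5p", "3p"):
            continue
        span = (c.mature_start, c.mature_start + c.lm)
        if not _mature_geometry_ok(c.structure, span, criteria):
            continue
        passed.append(c)
    best: Dict[Tuple[str, str, str], MiRNACandidate] = {}
    for c in passed:
        key = (c.source_id, c.family, c.strand)
        prev = best.get(key)
        if prev is None or (c.mismatches_vs_ref, -c.mfei) < (prev.mismatches_vs_ref, -prev.mfei):
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.source_id, c.family))


def discover_mirnas(
    seqs: Sequence[Seq],
    refs: Sequence[MatureRef],
    max_mismatch: int = 4,
    flank_steps: Sequence[int] = tuple(range(0, 281, 20)),
    criteria: ScreenCriteria = DEFAULT_CRITERIA,
    folder: Callable[[str], Tuple[str, float]] = fold,
) -> List[MiRNACandidate]:
    """Full pipeline: match -> excise -> fold -> metrics -> screen."""
    by_id = {s.id: s for s in seqs}
    cands: List[MiRNACandidate] = []
    for hit in match_known(seqs, refs, max_mismatch):
        src = by_id[hit.seq_id]
        lm = len(hit.ref.sequence)
        for start, end, moff in excise_precursors(src, hit, flank_steps):
            window = src.residues[start:end]
            if hit.strand == "+":
                prec_dna = window
                mstart = moff
            else:
                prec_dna = revcomp(window)
                mstart = len(window) - (moff + lm)
            prec = prec_dna.replace("T", "U")
            if "N" in prec:
                continue
            structure, mfe = folder(prec)
            try:
                gc, amfe, mfei, loc = hairpin_metrics(
                    prec, structure, mfe, (mstart, mstart + lm)
                )
            except ValueError:
                continue
            if loc not in ("5p", "3p"):
                continue
            cands.append(
                MiRNACandidate(
                    mature_seq=prec[mstart : mstart + lm],
                    lm=lm,
                    strand=hit.strand,
                    location=loc,
                    precursor_seq=prec,
                    structure=structure,
                    gc_pct=gc,
                    mfe=mfe,
                    amfe=amfe,
                    mfei=mfei,
                    source_id=hit.seq_id,
                    family=hit.ref.family,
                    ref_name=hit.ref.name,
                    mismatches_vs_ref=hit.mismatches,
                    mature_start=mstart,
                )
            )
    return screen_candidates(cands, criteria)


# ---------------------------------------------------------------------------
# target prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    target_id: str
    start: int     # 0-based half-open on the transcript
    end: int
    score: float
    mismatches: int
    gu_pairs: int


_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def score_site(mature: str, window: str) -> Optional[Tuple[float, int, int]]:
    """Score one mature/target-window duplex, or None when disqualified.

    ``mature`` is the miRNA (RNA, 5'->3'); ``window`` is the candidate
    transcript site (mRNA sense, 5'->3') of the same length.  Mature
    position p (1-based) faces window position len-p.  Penalties:
    mismatch 1.0, G:U wobble 0.5, doubled at mature positions 2-13.
    Disqualified by any mismatch at positions 10-11 or by more than 2
    consecutive mismatches.  Returns (score, mismatches, gu_pairs).
    """
    lm = len(mature)
    if len(window) != lm:
        raise ValueError("window length != mature length")
    mature = mature.upper().replace("T", "U")
    window = window.upper().replace("T", "U")
    score = 0.0
    mism = gu = run = 0
    for p in range(1, lm + 1):
        m = mature[p - 1]
        t = window[lm - p]
        if _RNA_COMP.get(m) == t:
            run = 0
            continue
        wobble = (m == "G" and t == "U") or (m == "U" and t == "G")
        weight = 2.0 if 2 <= p <= 13 else 1.0
        if wobble:
            score += 0.5 * weight
            gu += 1
            run = 0
        else:
            if p in (10, 11):
                return None
            score += 1.0 * weight
            mism += 1
            run += 1
            if run > 2:
                return None
    return score, mism, gu


def predict_targets(
    mirnas: Sequence[Tuple[str, str]],
    transcripts: Sequence[Seq],
    max_score: float = 4.0,
) -> List[TargetSite]:
    """Complementarity-scored target sites on plus-strand transcripts.

    ``mirnas`` is a sequence of (id, mature RNA) pairs.  Every window
    of every transcript is scored against each mature; windows passing
    the rules with score <= ``max_score`` are kept, and overlapping
    accepted windows of one miRNA-transcript pair collapse to the
    best-scoring (leftmost on ties).
    """
    sites: List[TargetSite] = []
    for mid, mature in mirnas:
        mature = mature.upper().replace("T", "U")
        lm = len(mature)
        for tr in transcripts:
            res = tr.residues
            accepted: List[TargetSite] = []
            for off in range(len(res) - lm + 1):
                window = res[off : off + lm]
                if "N" in window:
                    continue
                r = score_site(mature, window)
                if r is None or r[0] > max_score:
                    continue
                accepted.append(
                    TargetSite(mid, tr.id, off, off + lm, r[0], r[1], r[2])
                )
            # collapse overlapping windows to the best-scoring
            accepted.sort(key=lambda s: (s.score, s.start))
            chosen: List[TargetSite] = []
            for site in accepted:
                if all(site.end <= c.start or site.start >= c.end for c in chosen):
                    chosen.append(site)
            sites.extend(sorted(chosen, key=lambda s: s.start))
    return sites
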