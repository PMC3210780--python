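"""Pairwise nucleotide alignment, clustering and cross-set similarity.

A light seed-and-extend aligner stands in for BLASTn: shared exact
k-mers nominate diagonals, and a banded affine-gap local alignment
around the best diagonals produces hits with identity, raw score,
bitscore and a Karlin-Altschul E-value (E = K*m*n*exp(-lambda*S), with
ungapped nucleotide parameters lambda=1.28, K=0.46 declared in output
headers).  Cluster membership follows the E-value < 1e-30 AND
identity > 90% rule, with clusters as connected components of size >= 2.

Gap model: a gap of length L costs gap_open + L*gap_extend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .preprocess import Seq

LAMBDA = 1.28
K_PARAM = 0.46


@dataclass(frozen=True)
class ScoringParams:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    k: int = 11          # seed word size
    band: int = 20       # half-width of the DP band around a seed diagonal


DEFAULT_SCORING = ScoringParams()


@dataclass(frozen=True)
class PairwiseHit:
    """One local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    identity_pct: float
    aligned_len: int
    score: int
    bitscore: float
    evalue: float
    mismatches: int = 0
    gap_opens: int = 0
    qstart: int = 0   # 0-based half-open on the query
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative evalue")


@dataclass(frozen=True)
class Cluster:
    members: frozenset

    @property
    def size(self) -> int:
        return len(self.members)


def bitscore(score: float, lam: float = LAMBDA, k: float = K_PARAM) -> float:
    return (lam * score - math.log(k)) / math.log(2)


def evalue(score: float, m: int, n: int, lam: float = LAMBDA, k: float = K_PARAM) -> float:
    return k * m * n * math.exp(-lam * score)


def _kmer_index(s: str, k: int) -> Dict[str, List[int]]:
    idx: Dict[str, List[int]] = {}
    for i in range(len(s) - k + 1):
        idx.setdefault(s[i : i + k], []).append(i)
    return idx


def shared_seed_diagonals(a: str, b: str, k: int) -> List[int]:
    """Diagonals (i - j) carrying at least one shared exact k-mer,
    ordered by decreasing seed support."""
    idx = _kmer_index(b, k)
    support: Dict[int, int] = {}
    for i in range(len(a) - k + 1):
        for j in idx.get(a[i : i + k], ()):
            d = i - j
            support[d] = support.get(d, 0) + 1
    return sorted(support, key=lambda d: (-support[d], d))


def _banded_local_align(
    a: str, b: str, diag: int, p: ScoringParams
) -> Tuple[int, int, int, int, int, int, int, int, int]:
    """Banded Smith-Waterman (affine gaps, Gotoh) around ``diag``.

    Returns (score, matches, mismatches, gap_opens, columns, qstart,
    qend, sstart, send) for the best local path restricted to cells
    with |(i - j) - diag| <= band.  Coordinates 0-based half-open.
    """
    la, lb = len(a), len(b)
    band = p.band
    NEG = -(10 ** 9)
    go, ge = p.gap_open, p.gap_extend
    # states: H (i,j consumed as column), E (gap in a: b advances), F (gap in b)
    Hs: Dict[Tuple[int, int], int] = {}
    Es: Dict[Tuple[int, int], int] = {}
    Fs: Dict[Tuple[int, int], int] = {}
    # pointer value: previous state letter, or 'S' for local start
    ptr: Dict[Tuple[str, int, int], str] = {}
    best = (0, -1, -1)
    for i in range(la):
        j0 = max(0, i - diag - band)
        j1 = min(lb - 1, i - diag + band)
        for j in range(j0, j1 + 1):
            sub = p.match if a[i] == b[j] else p.mismatch
            h_prev = Hs.get((i - 1, j - 1), NEG)
            e_prev = Es.get((i - 1, j - 1), NEG)
            f_prev = Fs.get((i - 1, j - 1), NEG)
            base, src = 0, "S"
            if h_prev > base:
                base, src = h_prev, "H"
            if e_prev > base:
                base, src = e_prev, "E"
            if f_prev > base:
                base, src = f_prev, "F"
            H = base + sub
            Hs[(i, j)] = H
            ptr[("H", i, j)] = src
            e_open = Hs.get((i, j - 1), NEG) + go + ge
            e_ext = Es.get((i, j - 1), NEG) + ge
            if e_open >= e_ext:
                Es[(i, j)] = e_open
                ptr[("E", i, j)] = "H"
            else:
                Es[(i, j)] = e_ext
                ptr[("E", i, j)] = "E"
            f_open = Hs.get((i - 1, j), NEG) + go + ge
            f_ext = Fs.get((i - 1, j), NEG) + ge
            if f_open >= f_ext:
                Fs[(i, j)] = f_open
                ptr[("F", i, j)] = "H"
            else:
                Fs[(i, j)] = f_ext
                ptr[("F", i, j)] = "F"
            if H > best[0]:
                best = (H, i, j)
    score, bi, bj = best
    if score <= 0:
        return (0, 0, 0, 0, 0, 0, 0, 0, 0)
    matches = mismatches = gap_opens = columns = 0
    i, j, state = bi, bj, "H"
    while True:
        columns += 1
        if state == "H":
            if a[i] == b[j]:
                matches += 1
            else:
                mismatches += 1
            prev = ptr[("H", i, j)]
            i, j = i - 1, j - 1
            if prev == "S":
                break
            state = prev
        elif state == "E":
            prev = ptr[("E", i, j)]
            if prev == "H":
                gap_opens += 1
            j -= 1
            state = prev
        else:
            prev = ptr[("F", i, j)]
            if prev == "H":
                gap_opens += 1
            i -= 1
            state = prev
    return (score, matches, mismatches, gap_opens, columns,
            i + 1, bi + 1, j + 1, bj + 1)


def align_pair(
    a: Seq,
    b: Seq,
    params: ScoringParams = DEFAULT_SCORING,
    db_len: Optional[int] = None,
    max_diagonals: int = 8,
) -> List[PairwiseHit]:
    """Seed-and-extend local alignment of ``a`` against ``b``.

    Shared exact k-mers nominate diagonals; each diagonal group gets a
    banded affine-gap local alignment (band +/- ``params.band``).  The
    best non-overlapping hits (on the query) are returned sorted by
    score.  ``db_len`` substitutes for len(b) in the E-value search
    space when searching against a database.  No shared k-mer yields an
    empty list.
    """
    if len(a) < params.k or len(b) < params.k:
        raise ValueError("sequences shorter than the seed length")
    diags = shared_seed_diagonals(a.residues, b.residues, params.k)
    if not diags:
        return []
    m, n = len(a), (db_len if db_len is not None else len(b))
    raw = []
    for d in diags[:max_diagonals]:
        res = _banded_local_align(a.residues, b.residues, d, params)
        if res[0] > 0:
            raw.append(res)
    raw.sort(key=lambda r: -r[0])
    hits: List[PairwiseHit] = []
    covered: List[Tuple[int, int]] = []
    for score, matches, mism, gaps, cols, qs, qe, ss, se in raw:
        if any(qs < e and qe > s for s, e in covered):
            continue
        covered.append((qs, qe))
        hits.append(
            PairwiseHit(
                query_id=a.id,
                subject_id=b.id,
                identity_pct=100.0 * matches / cols,
                aligned_len=cols,
                score=score,
                bitscore=bitscore(score),
                evalue=evalue(score, m, n),
                mismatches=mism,
                gap_opens=gaps,
                qstart=qs,
                qend=qe,
                sstart=ss,
                send=se,
            )
        )
    return hits


def best_hit(a: Seq, b: Seq, params: ScoringParams = DEFAULT_SCORING,
             db_len: Optional[int] = None) -> Optional[PairwiseHit]:
    hits = align_pair(a, b, params, db_len=db_len)
    return hits[0] if hits else None


def build_clusters(
    seqs: Sequence[Seq],
    evalue_max: float = 1e-30,
    identity_min: float = 90.0,
    params: ScoringParams = DEFAULT_SCORING,
) -> Tuple[List[Cluster], List[str]]:
    """Connected-component clustering under the similarity rule.

    An undirected edge joins two sequences when the better of the two
    directed best hits has evalue < ``evalue_max`` AND identity_pct >
    ``identity_min`` (both strict, per the defining wording).  Clusters
    are the connected components of size >= 2, sorted largest first;
    ids in no such component are returned separately as unclustered.
    """
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    # candidate pairs share at least one k-mer
    kidx: Dict[str, set] = {}
    for si, s in enumerate(seqs):
        for i in range(len(s) - params.k + 1):
            kidx.setdefault(s.residues[i : i + params.k], set()).add(si)
    pairs = set()
    for members in kidx.values():
        if len(members) > 1:
            mm = sorted(members)
            for x in range(len(mm)):
                for y in range(x + 1, len(mm)):
                    pairs.add((mm[x], mm[y]))
    g = nx.Graph()
    g.add_nodes_from(ids)
    for x, y in sorted(pairs):
        hx = best_hit(seqs[x], seqs[y], params)
        hy = best_hit(seqs[y], seqs[x], params)
        for h in (hx, hy):
            if h and h.evalue < evalue_max and h.identity_pct > identity_min:
                g.add_edge(seqs[x].id, seqs[y].id)
                break
    clusters = []
    unclustered = []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            clusters.append(Cluster(frozenset(comp)))
        else:
            unclustered.extend(comp)
    clusters.sort(key=lambda c: (-c.size, min(c.members)))
    return clusters, sorted(unclustered)


def cross_set_hit_fraction(
    queries: Sequence[Seq],
    refs: Sequence[Seq],
    cutoffs: Sequence[float] = (1e-10, 1e-30, 1e-50, 1e-100),
    params: ScoringParams = DEFAULT_SCORING,
) -> Dict[float, Tuple[float, float]]:
    """Fraction of sequences with a hit across two sets, per E-value cutoff.

    For each cutoff E the result maps E -> (fraction of queries with at
    least one hit at evalue <= E against any ref, fraction of refs hit
    by at least one query).  Fractions are monotone non-increasing as
    the cutoff tightens.  Empty refs give all-zero fractions.
    """
    out: Dict[float, Tuple[float, float]] = {}
    if not refs or not queries:
        return {c: (0.0, 0.0) for c in cutoffs}
    db_len = sum(len(r) for r in refs)
    q_len = sum(len(q) for q in queries)
    q_best = [math.inf] * len(queries)
    r_best = [math.inf] * len(refs)
    for qi, q in enumerate(queries):
        for ri, r in enumerate(refs):
            if len(q) < params.k or len(r) < params.k:
                continue
            h = best_hit(q, r, params, db_len=db_len)
            if h:
                q_best[qi] = min(q_best[qi], h.evalue)
                # ref-side E-value uses the query set as the database
                e_r = evalue(h.score, len(r), q_len)
                r_best[ri] = min(r_best[ri], e_r)
    for c in cutoffs:
        fq = sum(1 for e in q_best if e <= c) / len(queries)
        fr = sum(1 for e in r_best if e <= c) / len(refs)
        out[c] = (fq, fr)
    return out


def write_hits_tsv(hits: Iterable[PairwiseHit], path) -> None:
    """12-column blast-tabular-style report (1-based inclusive coords)."""
    with open(path, "w") as fh:
        fh.write(f"# estkit align; lambda={LAMBDA} K={K_PARAM}\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        str(h.aligned_len),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.qstart + 1),
                        str(h.qend),
                        str(h.sstart + 1),
                        str(h.send),
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
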