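"""Independent brute-force oracles used by the test suite.

Each oracle is written directly from the operation's definition
(exhaustive enumeration, naive per-window or per-column recomputation)
and shares no code path with the implementation it checks.
"""

from collections import Counter
from itertools import product

# ---------------------------------------------------------------------------
# DUST-style window scoring (naive per-window recount)
# ---------------------------------------------------------------------------

def dust_masked_positions(res: str, window: int, threshold: float) -> set:
    masked = set()
    n = len(res)
    for start in range(0, n - window + 1):
        counts = Counter(res[i : i + 3] for i in range(start, start + window - 2))
        score = sum(c * (c - 1) for c in counts.values()) / 2.0 / (window - 3)
        if score > threshold:
            masked.update(range(start, start + window))
    return masked


# ---------------------------------------------------------------------------
# six-frame ORF enumeration
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}


def _rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def enumerate_orfs(res: str):
    """All (length, strand_rank, fwd_start, fwd_end, strand) ORFs, 6 frames."""
    out = []
    n = len(res)
    for strand, s in (("+", res), ("-", _rc(res))):
        for frame in range(3):
            i = frame
            while i + 3 <= n:
                if s[i : i + 3] == "ATG":
                    j = i + 3
                    stopped = False
                    while j + 3 <= n:
                        if s[j : j + 3] in _STOPS:
                            j += 3
                            stopped = True
                            break
                        j += 3
                    end = j
                    if end - i >= 6:
                        if strand == "+":
                            out.append((end - i, 0, i, end, strand))
                        else:
                            out.append((end - i, 1, n - end, n - i, strand))
                    # next ATG strictly after this one, same frame
                    i += 3
                else:
                    i += 3
    return out


def longest_orf(res: str):
    """(start, end, strand) of the longest ORF, ties: + first, lower start."""
    orfs = enumerate_orfs(res)
    if not orfs:
        return None
    best = min(orfs, key=lambda o: (-o[0], o[1], o[2]))
    return best[2], best[3], best[4]


# ---------------------------------------------------------------------------
# unbanded local alignment (Gotoh), gap cost = open + L*extend
# ---------------------------------------------------------------------------

def smith_waterman_score(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend)
            H[i][j] = max(0.0, max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1], 0.0) + sub)
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# per-column pileup counting
# ---------------------------------------------------------------------------

def _support_needed(depth: int):
    if depth <= 4:
        return None
    if depth <= 6:
        return 2
    if depth <= 8:
        return 3
    if depth <= 12:
        return 4
    return 5


def pileup_passed_calls(consensus: str, rows):
    """Set of (column, kind, variant_allele) passing the evidence rules."""
    out = set()
    for col in range(len(consensus)):
        tally = Counter()
        for _, r in rows:
            c = r[col]
            if c not in (".", "N"):
                tally[c] += 1
        depth = sum(tally.values())
        need = _support_needed(depth)
        if need is None:
            continue
        cons = consensus[col]
        for allele, cnt in tally.items():
            if allele == cons or cnt < need:
                continue
            kind = "indel" if (allele == "-" or cons == "-") else "SNP"
            out.add((col, kind, allele))
    return out


# ---------------------------------------------------------------------------
# SSR brute force
# ---------------------------------------------------------------------------

_SSR_MIN = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}


def _primitive(u: str) -> bool:
    return all(not (len(u) % d == 0 and u == u[:d] * (len(u) // d)) for d in range(1, len(u)))


def _canon(u: str) -> str:
    rc = _rc(u)
    rots = {u[i:] + u[:i] for i in range(len(u))} | {rc[i:] + rc[:i] for i in range(len(rc))}
    rep = min(rots)
    return rep + "/" + _rc(rep)


def brute_force_ssrs(res: str):
    """All maximal primitive perfect tandem repeats >= threshold, with
    same-canonical-class overlap suppression (longest first)."""
    raw = []
    n = len(res)
    for L, min_rep in _SSR_MIN.items():
        for i in range(n - 2 * L + 1):
            unit = res[i : i + L]
            if "N" in unit or not _primitive(unit):
                continue
            r = 1
            while res[i + r * L : i + (r + 1) * L] == unit:
                r += 1
            if r < min_rep:
                continue
            # maximal by one full unit either side
            if i >= L and res[i - L : i] == unit:
                continue
            if res[i + r * L : i + (r + 1) * L] == unit:
                continue
            raw.append((i, i + r * L, unit, r, _canon(unit)))
    raw.sort(key=lambda t: (-(t[1] - t[0]), t[0], len(t[2])))
    kept = []
    for s, e, unit, r, canon in raw:
        if any(c == canon and s < ke and ks < e for ks, ke, _, _, c in kept):
            continue
        kept.append((s, e, unit, r, canon))
    kept.sort(key=lambda t: (t[0], len(t[2])))
    return kept


# ---------------------------------------------------------------------------
# exhaustive nested-structure folding
# ---------------------------------------------------------------------------

_W = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
      ("G", "U"): 1, ("U", "G"): 1}


def max_fold_score(rna: str) -> int:
    """Maximum total pair weight over all nested structures, min loop 3,
    by memoised exhaustive enumeration of pair sets."""
    rna = rna.upper().replace("T", "U")
    n = len(rna)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def enum(i: int, j: int):
        if j - i < 4:
            return (0,)
        scores = set(enum(i + 1, j))
        for k in range(i + 4, j + 1):
            w = _W.get((rna[i], rna[k]))
            if w is None:
                continue
            for left in enum(i + 1, k - 1):
                for right in enum(k + 1, j):
                    scores.add(w + left + right)
        return tuple(scores)

    return max(enum(0, n - 1))


def structure_score(rna: str, structure: str) -> int:
    rna = rna.upper().replace("T", "U")
    stack, total = [], 0
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            total += _W[(rna[j], rna[i])]
    return total


def check_structure_valid(structure: str, min_loop: int = 3) -> bool:
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                return False
            j = stack.pop()
            if i - j - 1 < min_loop:
                return False
    return not stack


# ---------------------------------------------------------------------------
# primer enumeration
# ---------------------------------------------------------------------------

def brute_force_best_primer(res: str, locus_start: int, locus_end: int):
    """(penalty, product, left_start) of the best constraint-satisfying
    primer pair by full enumeration, or None."""

    def gc(s):
        return 100.0 * sum(1 for c in s if c in "GC") / len(s)

    def tm(s):
        return 2.0 * sum(1 for c in s if c in "AT") + 4.0 * sum(1 for c in s if c in "GC")

    best = None
    n = len(res)
    for ls in range(0, locus_start):
        for ll in range(18, 25):
            le = ls + ll
            if le > locus_start:
                break
            left = res[ls:le]
            if "N" in left or not 40 <= gc(left) <= 65:
                continue
            for rs in range(locus_end, n):
                for rl in range(18, 25):
                    re_ = rs + rl
                    if re_ > n:
                        break
                    product = re_ - ls
                    if product > 300:
                        break
                    if product < 100:
                        continue
                    right = res[rs:re_]
                    if "N" in right or not 40 <= gc(right) <= 65:
                        continue
                    pen = (abs(tm(left) - 60) + 0.5 * abs(gc(left) - 50) + abs(ll - 20)
                           + abs(tm(right) - 60) + 0.5 * abs(gc(right) - 50) + abs(rl - 20)
                           + abs(tm(left) - tm(right)))
                    cand = (pen, product, ls)
                    if best is None or cand < best:
                        best = cand
    return best
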