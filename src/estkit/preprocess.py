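"""EST cleaning and ORF calling.

Emulates the pre-assembly cleaning steps that can be performed without
external contaminant databases: poly-A/T tail trimming, DUST-style
low-complexity masking, and a minimum-length filter (reads shorter than
100 nt are discarded).  Also provides the longest-ORF rule used to
nominate a candidate CDS for an assembled contig.

Vector/adapter, mitochondrial and rRNA screening, and repeat masking
against curated repeat libraries all require external databases and are
deliberately represented by a logged no-op (:func:`screen_contaminants`).

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

log = logging.getLogger("estkit")

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Seq:
    """A DNA sequence record.

    Residues are stored uppercase and restricted to {A, C, G, T, N}.
    ``source_tag`` carries an optional free-text library/tissue label.
    """

    id: str
    residues: str
    source_tag: Optional[str] = None

    def __post_init__(self) -> None:
        res = self.residues.upper()
        if not res:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(res) - VALID_BASES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame on a sequence.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    sequence regardless of strand; ``frame`` is the reading frame on the
    strand carrying the ORF.
    """

    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if self.end - self.start < 6:
            raise ValueError("ORF shorter than 6 nt")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# poly-A/T trimming
# ---------------------------------------------------------------------------

def _tail_trim_len(residues: str, base: str, min_tail: int, max_mismatch: int) -> int:
    """Length of the longest valid 3'-terminal tail of ``base``.

    A valid tail starts with ``base``, contains at least ``min_tail``
    copies of it, and at most ``max_mismatch`` other characters
    (interruptions).  Scans ``residues`` from its 3' end.
    """
    best = 0
    n_base = 0
    n_mm = 0
    n = len(residues)
    for k in range(1, n + 1):
        c = residues[n - k]
        if c == base:
            n_base += 1
            if n_base >= min_tail:
                best = k
        else:
            n_mm += 1
            if n_mm > max_mismatch:
                break
    return best


def trim_poly_at(seq: Seq, min_tail: int = 10, max_mismatch: int = 1) -> Optional[Seq]:
    """Remove terminal poly-A (3') and poly-T (5') tails.

    A tail is a terminal run of >= ``min_tail`` A's (3' end) or T's
    (5' end) allowing up to ``max_mismatch`` interrupting bases; the run
    must begin at the sequence terminus side with the tail base.
    Internal homopolymer runs are untouched and the operation is
    idempotent.  Returns ``None`` when trimming empties the sequence
    (the read is discarded, never returned as an empty ``Seq``).
    """
    if min_tail < 5:
        raise ValueError("min_tail must be >= 5")
    res = seq.residues
    cut3 = _tail_trim_len(res, "A", min_tail, max_mismatch)
    res = res[: len(res) - cut3]
    cut5 = _tail_trim_len(res[::-1], "T", min_tail, max_mismatch)
    res = res[cut5:]
    if not res:
        log.warning("trim_poly_at: %s emptied by trimming; discarded", seq.id)
        return None
    if res == seq.residues:
        return seq
    return Seq(seq.id, res, seq.source_tag)


# ---------------------------------------------------------------------------
# low-complexity masking (DUST-style)
# ---------------------------------------------------------------------------

def _dust_score(counts: dict, window: int) -> float:
    # sum over triplet multiplicities c*(c-1)/2, normalised by window-3
    s = sum(c * (c - 1) for c in counts.values()) / 2.0
    return s / (window - 3)


def mask_low_complexity(seq: Seq, window: int = 64, threshold: float = 2.0) -> Seq:
    """Mask low-complexity regions with N.

    Every ``window``-length sliding window is scored by the DUST
    statistic: sum over distinct 3-mers t of c_t(c_t - 1)/2, divided by
    (window - 3), where c_t is the 3-mer's count in the window.  All
    positions of any window scoring strictly above ``threshold`` are
    replaced by N; everything else is untouched, so the output length
    equals the input length.  Sequences shorter than ``window`` are
    returned unmasked.
    """
    if window < 8:
        raise ValueError("window must be >= 8")
    res = seq.residues
    n = len(res)
    if n < window:
        return seq
    counts: dict = {}
    for i in range(window - 2):
        t = res[i : i + 3]
        counts[t] = counts.get(t, 0) + 1
    mask = [False] * n
    for start in range(0, n - window + 1):
        if start > 0:
            gone = res[start - 1 : start + 2]
            counts[gone] -= 1
            if counts[gone] == 0:
                del counts[gone]
            new = res[start + window - 3 : start + window]
            counts[new] = counts.get(new, 0) + 1
        if _dust_score(counts, window) > threshold:
            for p in range(start, start + window):
                mask[p] = True
    if not any(mask):
        return seq
    masked = "".join("N" if m else c for c, m in zip(res, mask))
    return Seq(seq.id, masked, seq.source_tag)


def filter_min_length(seqs: Iterable[Seq], min_len: int = 100):
    """Split sequences into (kept, discarded) by length.

    Sequences strictly shorter than ``min_len`` are discarded ("under
    100 nt": the 100-nt boundary is kept).  Input order is preserved.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept, discarded = [], []
    for s in seqs:
        (kept if len(s) >= min_len else discarded).append(s)
    return kept, discarded


def screen_contaminants(seqs: list) -> list:
    """Vector/mitochondrial/rRNA screening placeholder.

    Contaminant screening needs curated external databases (vector sets,
    organellar and rRNA references, repeat libraries), which this
    package does not bundle; sequences pass through unchanged and a
    warning is logged once per call.
    """
    log.warning(
        "screen_contaminants: no contaminant databases bundled; "
        "%d sequences passed through unscreened", len(seqs),
    )
    return list(seqs)


# ---------------------------------------------------------------------------
# longest-ORF CDS rule
# ---------------------------------------------------------------------------

def translate(cds: str) -> str:
    """Translate a CDS, stopping at (and excluding) the first stop codon."""
    aa = []
    for i in range(0, len(cds) - 2, 3):
        res = CODON_TABLE.get(cds[i : i + 3], "X")
        if res == "*":
            break
        aa.append(res)
    return "".join(aa)


def _orfs_one_strand(res: str):
    """Yield (start, end, frame, has_stop) for ORFs on one strand.

    An ORF runs ATG..stop within a frame; an ATG whose frame reaches the
    sequence end without a stop yields an open 3' end (ESTs are
    fragments), truncated at the last complete codon.
    """
    n = len(res)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = res[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                yield start, i + 3, frame, True
                start = None
        if start is not None:
            end = start + ((n - start) // 3) * 3
            if end - start >= 6:
                yield start, end, frame, False


def find_longest_orf(seq: Seq) -> Optional[OrfCall]:
    """Longest ORF over all six frames; the candidate CDS.

    Ties are broken by strand (+ before -) then by lower forward-strand
    start.  Reverse-strand ORFs are reported in forward coordinates.
    Returns ``None`` when no frame contains an ATG-initiated ORF of at
    least 6 nt.
    """
    res = seq.residues
    n = len(res)
    candidates = []
    for start, end, frame, has_stop in _orfs_one_strand(res):
        prot = translate(res[start:end])
        candidates.append(OrfCall(start, end, "+", frame, prot))
    rc = revcomp(res)
    for start, end, frame, has_stop in _orfs_one_strand(rc):
        prot = translate(rc[start:end])
        candidates.append(OrfCall(n - end, n - start, "-", frame, prot))
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda o: (-(o.end - o.start), 0 if o.strand == "+" else 1, o.start),
    )


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a FASTA file into a list of :class:`Seq`."""
    from Bio import SeqIO

    return [Seq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[Seq], path, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def clean_ests(
    seqs: Iterable[Seq],
    min_len: int = 100,
    poly_tail: int = 10,
    poly_mismatch: int = 1,
    dust_window: int = 64,
    dust_threshold: float = 2.0,
):
    """Full cleaning pass: trim tails, mask low complexity, length-filter.

    Returns (clean, report) where report is a list of (id, reason) rows
    for discarded reads.
    """
    report = []
    trimmed = []
    for s in seqs:
        t = trim_poly_at(s, poly_tail, poly_mismatch)
        if t is None:
            report.append((s.id, "empty_after_poly_trim"))
            continue
        trimmed.append(mask_low_complexity(t, dust_window, dust_threshold))
    kept, short = filter_min_length(trimmed, min_len)
    report.extend((s.id, f"length_under_{min_len}") for s in short)
    return kept, report
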