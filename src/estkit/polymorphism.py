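"""SNP/indel mining from per-contig multiple alignments.

Variants are called from per-column pileups of an EST contig's multiple
alignment under depth-stratified evidence thresholds: a column is
callable only when covered by at least 5 reads, and the variant allele
must be seen at least 2 times at depth 5-6, 3 times at depth 7-8,
4 times at depth 9-12, and 5 times at depth >= 13.  Per-contig SNP and
indel frequencies (per ungapped consensus nt) are then standardised
across contigs (z-scores) and contigs with significantly high
frequencies are flagged at one-sided P < 0.05 and P < 0.01.

Alignment convention: '-' is an alignment gap (a read covers the column
and asserts a deletion); '.' is pad (the column lies outside the read's
span and contributes nothing).  N contributes to neither depth nor
support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

log = logging.getLogger("estkit")

PAD = "."
GAP = "-"
BASES = "ACGT"

# one-sided standard-normal thresholds: P<0.05 and P<0.01
Z_SIGNIFICANT = 1.6449
Z_HIGHLY_SIGNIFICANT = 2.3263


@dataclass
class ContigAlignment:
    """A consensus plus gapped member-read rows for one contig.

    All rows have the same length as the (gapped) consensus.  Pad
    characters mark columns outside a read's span; gaps are real
    deletion assertions.
    """

    contig_id: str
    consensus: str
    rows: List[Tuple[str, str]]  # (read_id, gapped read string)

    def __post_init__(self) -> None:
        n = len(self.consensus)
        if not self.rows:
            raise ValueError(f"{self.contig_id}: alignment has no reads")
        for rid, r in self.rows:
            if len(r) != n:
                raise ValueError(
                    f"{self.contig_id}/{rid}: row length {len(r)} != consensus {n}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.consensus)

    def depth(self, col: int) -> int:
        """Reads covering ``col`` with an informative character."""
        return sum(
            1 for _, r in self.rows if r[col] != PAD and r[col] != "N"
        )

    def ungapped_consensus_length(self) -> int:
        return sum(1 for c in self.consensus if c != GAP)


@dataclass(frozen=True)
class VariantCall:
    contig_id: str
    column: int            # 0-based alignment column
    kind: str              # 'SNP' or 'indel'
    consensus_allele: str
    variant_allele: str    # base for SNP; '-' (deletion) or base (insertion)
    support: int
    depth: int
    passed: bool
    supporting_reads: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.support <= self.depth:
            raise ValueError("support must satisfy 0 < support <= depth")
        if self.passed and (self.depth < 5 or self.support < min_support(self.depth)):
            raise ValueError("passed call violates the evidence thresholds")


@dataclass
class ContigVariantSummary:
    contig_id: str
    n_snp: int
    n_indel: int
    length: int
    snp_freq: float
    indel_freq: float
    z_snp: Optional[float] = None
    z_indel: Optional[float] = None
    snp_class: str = "none"
    indel_class: str = "none"


def min_support(depth: int) -> float:
    """Minimum variant-read count required at a given column depth.

    Depth <= 4 is uncallable (returns +inf): polymorphism is definable
    only where more than four reads cover the column.  Depth 5-6 needs
    the variant seen at least twice, 7-8 three times, 9-12 four times,
    and >= 13 five times.
    """
    if depth < 0:
        raise ValueError("negative depth")
    if depth <= 4:
        return math.inf
    if depth <= 6:
        return 2
    if depth <= 8:
        return 3
    if depth <= 12:
        return 4
    return 5


def call_variants(aln: ContigAlignment, verbose: bool = False) -> List[VariantCall]:
    """Call SNPs and indels from per-column pileups.

    Per column, informative characters (bases and gaps; never N or pad)
    are tallied.  Each non-consensus base with count >= the depth's
    support threshold yields a passed SNP (base consensus) or insertion
    indel (gap consensus); a gap tally meeting the threshold against a
    base consensus yields a deletion indel.  Tri-allelic columns can
    emit one call per qualifying allele.  With ``verbose`` sub-threshold
    disagreements at callable depth are also emitted with passed=False.
    """
    calls: List[VariantCall] = []
    cons = aln.consensus
    for col in range(aln.n_columns):
        tallies: Dict[str, List[str]] = {}
        for rid, r in aln.rows:
            c = r[col]
            if c == PAD or c == "N":
                continue
            tallies.setdefault(c, []).append(rid)
        depth = sum(len(v) for v in tallies.values())
        if depth == 0:
            continue
        thr = min_support(depth)
        cons_allele = cons[col]
        for allele, readers in sorted(tallies.items()):
            if allele == cons_allele:
                continue
            support = len(readers)
            passed = support >= thr
            if allele == GAP:
                kind = "indel"       # deletion relative to consensus
            elif cons_allele == GAP:
                kind = "indel"       # insertion relative to consensus
            else:
                kind = "SNP"
            if passed or verbose:
                calls.append(
                    VariantCall(
                        contig_id=aln.contig_id,
                        column=col,
                        kind=kind,
                        consensus_allele=cons_allele,
                        variant_allele=allele,
                        support=support,
                        depth=depth,
                        passed=bool(passed),
                        supporting_reads=frozenset(readers),
                    )
                )
    return calls


def merge_indel_events(calls: Sequence[VariantCall]) -> int:
    """Count indel events, merging adjacent passed indel columns.

    Runs of consecutive alignment columns whose passed indel calls share
    an identical supporting-read set collapse to one event (a single
    biological insertion/deletion spans several columns).
    """
    indels = sorted(
        (c for c in calls if c.kind == "indel" and c.passed),
        key=lambda c: c.column,
    )
    events = 0
    prev_col = None
    prev_readers = None
    for c in indels:
        if (
            prev_col is not None
            and c.column == prev_col + 1
            and c.supporting_reads == prev_readers
        ):
            prev_col = c.column
            continue
        events += 1
        prev_col = c.column
        prev_readers = c.supporting_reads
    return events


def summarize_contig(
    aln: ContigAlignment, calls: Sequence[VariantCall]
) -> ContigVariantSummary:
    """Per-contig variant counts and frequencies (z filled later).

    Frequencies are per ungapped consensus nucleotide; adjacent passed
    indel columns with the same supporting reads count as one event.
    """
    length = aln.ungapped_consensus_length()
    if length == 0:
        raise ValueError(f"{aln.contig_id}: zero-length consensus")
    for c in calls:
        if c.contig_id != aln.contig_id:
            raise ValueError("calls from a different contig")
    n_snp = sum(1 for c in calls if c.kind == "SNP" and c.passed)
    n_indel = merge_indel_events(calls)
    return ContigVariantSummary(
        contig_id=aln.contig_id,
        n_snp=n_snp,
        n_indel=n_indel,
        length=length,
        snp_freq=n_snp / length,
        indel_freq=n_indel / length,
    )


def classify_significance(
    summaries: Sequence[ContigVariantSummary], which: str = "SNP"
) -> List[ContigVariantSummary]:
    """Standardise per-contig frequencies and flag significant contigs.

    z_i = (f_i - mean(f)) / sd(f) with the sample sd (n-1) over all
    contigs; a contig is 'significant' when z > 1.6449 (one-sided
    P < 0.05) and 'highly_significant' when z > 2.3263 (P < 0.01).
    With zero frequency spread, all classes stay 'none' and a warning
    is logged.  Summaries are modified in place and returned.
    """
    if which not in ("SNP", "indel"):
        raise ValueError("which must be 'SNP' or 'indel'")
    if len(summaries) < 2:
        raise ValueError("need at least 2 contigs")
    freqs = np.array(
        [s.snp_freq if which == "SNP" else s.indel_freq for s in summaries]
    )
    mean = float(freqs.mean())
    sd = float(freqs.std(ddof=1))
    if sd == 0.0:
        log.warning("classify_significance: zero frequency spread; nothing flagged")
        for s in summaries:
            if which == "SNP":
                s.z_snp, s.snp_class = 0.0, "none"
            else:
                s.z_indel, s.indel_class = 0.0, "none"
        return list(summaries)
    for s, f in zip(summaries, freqs):
        z = (float(f) - mean) / sd
        if z > Z_HIGHLY_SIGNIFICANT:
            cls = "highly_significant"
        elif z > Z_SIGNIFICANT:
            cls = "significant"
        else:
            cls = "none"
        if which == "SNP":
            s.z_snp, s.snp_class = z, cls
        else:
            s.z_indel, s.indel_class = z, cls
    return list(summaries)


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------

def read_aligned_fasta(path, contig_id: Optional[str] = None) -> ContigAlignment:
    """Read one contig alignment from aligned FASTA.

    The first record is the gapped consensus; the rest are member
    reads.  '.' is pad; leading and trailing '-' runs in a read are
    interpreted as pad (the read does not span those columns).
    """
    from Bio import SeqIO

    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) < 2:
        raise ValueError(f"{path}: need a consensus plus at least one read")
    cons = str(recs[0].seq).upper()
    rows = []
    for rec in recs[1:]:
        r = str(rec.seq).upper()
        core = r.strip(GAP + PAD)
        lead = len(r) - len(r.lstrip(GAP + PAD))
        rows.append((rec.id, PAD * lead + core + PAD * (len(r) - lead - len(core))))
    return ContigAlignment(contig_id or recs[0].id, cons, rows)


def read_ace(path) -> List[ContigAlignment]:
    """Read contig alignments from an ACE assembly file."""
    from Bio.Sequencing import Ace

    out = []
    for contig in Ace.parse(str(path)):
        cons = contig.sequence.upper().replace("*", GAP)
        n = len(cons)
        starts = {rd.name: rd.padded_start for rd in contig.af}
        rows = []
        for read in contig.reads:
            seq = read.rd.sequence.upper().replace("*", GAP)
            start = starts[read.rd.name] - 1  # ACE is 1-based
            row = [PAD] * n
            for k, c in enumerate(seq):
                pos = start + k
                if 0 <= pos < n:
                    row[pos] = c
            rows.append((read.rd.name, "".join(row)))
        out.append(ContigAlignment(contig.name, cons, rows))
    return out
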