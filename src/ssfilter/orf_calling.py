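"""Six-frame ORF discovery and source-priority reconciliation.

ORFs are reported as 1-based inclusive spans on the forward coordinate
system of the transcript (``start < end`` always; ``strand`` carries the
reading direction).  The stop codon, when present, is part of the span;
ORFs that run off the transcript edge without a stop are flagged partial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ssfilter.io_formats import DataError, HomologyHit
from ssfilter.leakage_filter import revcomp

__all__ = ["OrfCall", "find_orfs_sixframe", "reconcile_orfs", "strand_restrict"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


@dataclass
class OrfCall:
    transcript_id: str
    start: int
    end: int
    strand: str  # "plus" | "minus"
    frame: int  # 0/1/2 offset on the reading strand
    source: str = "builtin_sixframe"  # or "priority_external"
    mode: str = "start_to_stop"  # or "stop_to_stop"
    partial: bool = False
    best_hit: HomologyHit | None = None
    orf_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"ORF start {self.start} > end {self.end}")
        if not self.orf_id:
            self.orf_id = (
                f"{self.transcript_id}:{self.start}-{self.end}"
                f"({'+' if self.strand == 'plus' else '-'})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def reading_sequence(self, transcript_seq: str) -> str:
        """Nucleotides of the ORF in reading order."""
        sub = transcript_seq[self.start - 1 : self.end]
        return sub if self.strand == "plus" else revcomp(sub)


def _scan_frame(work: str, frame: int, min_len: int, mode: str) -> list[tuple[int, int, bool]]:
    """Maximal ORFs in one frame of *work*; returns (start0, end0, partial)."""
    out: list[tuple[int, int, bool]] = []
    n = len(work)
    orf_start: int | None = None
    p = frame
    while p + 3 <= n:
        codon = work[p : p + 3]
        if orf_start is None:
            if mode == "stop_to_stop":
                if codon not in STOP_CODONS:
                    orf_start = p
            elif codon == START_CODON:
                orf_start = p
        if orf_start is not None and codon in STOP_CODONS:
            if p + 3 - orf_start >= min_len:
                out.append((orf_start, p + 2, False))
            orf_start = None
        p += 3
    if orf_start is not None and p - orf_start >= min_len:
        out.append((orf_start, p - 1, True))  # ran off the edge, no stop
    return out


def find_orfs_sixframe(
    seq: str,
    transcript_id: str = "",
    min_len: int = 300,
    mode: str = "start_to_stop",
    include_partial: bool = True,
) -> list[OrfCall]:
    """All maximal ORFs of at least *min_len* bp on both strands, all
    three frames.

    ``start_to_stop`` ORFs run from the first ATG after the previous stop
    to a stop codon (inclusive); ``stop_to_stop`` ORFs run from the first
    codon after the previous stop.  *min_len* includes the stop codon.
    Output order is deterministic: by (start, strand, end).
    """
    if min_len < 3 or min_len % 3:
        raise DataError("min_len must be >= 3 and divisible by 3")
    if mode not in ("start_to_stop", "stop_to_stop"):
        raise DataError(f"unknown ORF mode {mode!r}")
    seq = seq.upper()
    n = len(seq)
    calls: list[OrfCall] = []
    for strand, work in (("plus", seq), ("minus", revcomp(seq))):
        for frame in (0, 1, 2):
            for s0, e0, partial in _scan_frame(work, frame, min_len, mode):
                if partial and not include_partial:
                    continue
                if strand == "plus":
                    start, end = s0 + 1, e0 + 1
                else:
                    start, end = n - e0, n - s0
                calls.append(
                    OrfCall(
                        transcript_id=transcript_id,
                        start=start,
                        end=end,
                        strand=strand,
                        frame=frame,
                        mode=mode,
                        partial=partial,
                    )
                )
    calls.sort(key=lambda o: (o.start, o.strand != "plus", o.end))
    return calls


def _overlaps(a: OrfCall, b: OrfCall, overlap_frac: float) -> bool:
    shared = min(a.end, b.end) - max(a.start, b.start) + 1
    return shared > overlap_frac * min(a.length_bp, b.length_bp)


def _admit(
    candidates: list[OrfCall], admitted: list[OrfCall], overlap_frac: float
) -> None:
    """Longest-first greedy admission against everything already admitted."""
    for o in sorted(candidates, key=lambda o: (-o.length_bp, o.start, o.strand != "plus")):
        if not any(_overlaps(o, a, overlap_frac) for a in admitted):
            admitted.append(o)


def reconcile_orfs(
    priority_orfs: list[OrfCall],
    builtin_orfs: list[OrfCall],
    overlap_frac: float = 0.5,
) -> list[OrfCall]:
    """Merge external (priority) and builtin ORF calls for one transcript.

    Admission order: (1) priority plus-strand, (2) priority minus-strand,
    (3) builtin any strand — each candidate is admitted only if it shares
    no more than *overlap_frac* of the shorter ORF's span with anything
    already admitted.  Within a stage longer ORFs win.
    """
    for o in priority_orfs:
        o.source = "priority_external"
    admitted: list[OrfCall] = []
    _admit([o for o in priority_orfs if o.strand == "plus"], admitted, overlap_frac)
    _admit([o for o in priority_orfs if o.strand == "minus"], admitted, overlap_frac)
    _admit(list(builtin_orfs), admitted, overlap_frac)
    admitted.sort(key=lambda o: (o.start, o.strand != "plus", o.end))
    return admitted


def strand_restrict(orfs: list[OrfCall], sslr: float | None = None) -> list[OrfCall]:
    """Keep only ORFs on the strand carrying the longest ORF.

    On a cross-strand tie in longest length, the strand the SSLR predicts
    as sense wins (negative SSLR → plus) when an SSLR is given, else plus.
    """
    if not orfs:
        return []
    longest = max(o.length_bp for o in orfs)
    strands = {o.strand for o in orfs if o.length_bp == longest}
    if len(strands) == 1:
        keep = strands.pop()
    elif sslr is not None and sslr > 0:
        keep = "minus"
    else:
        keep = "plus"
    return [o for o in orfs if o.strand == keep]
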