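"""Orientation tallies, SSLR, read-pair support, and coverage dips.

Under the dUTP strand-specific protocol the second-in-pair read of a
proper pair maps to the sense (plus) strand, so sense transcripts have a
negative SSLR and antisense artifacts a positive one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from ssfilter.io_formats import DataError, PairMapping

__all__ = [
    "PairOrientationCounts",
    "SslrValue",
    "CoverageProfile",
    "SupportDecision",
    "tally_orientation",
    "compute_sslr",
    "support_filter",
    "coverage_profile",
    "per_base_depth",
]


@dataclass
class PairOrientationCounts:
    """Per-transcript tallies of proper-pair orientations.

    ``n_read1_plus``: proper pairs whose first-in-pair read mapped on the
    plus strand; ``n_read2_plus``: likewise for the second-in-pair read.
    For FR-oriented proper pairs every pair falls in exactly one bucket.
    """

    transcript_id: str
    n_read1_plus: int = 0
    n_read2_plus: int = 0

    @property
    def n_proper_pairs(self) -> int:
        return self.n_read1_plus + self.n_read2_plus


@dataclass(frozen=True)
class SslrValue:
    """Strand-specific log ratio, log2((read1+ + pc) / (read2+ + pc))."""

    transcript_id: str
    sslr: float
    pseudocount: float = 0.5


@dataclass
class CoverageProfile:
    transcript_id: str
    per_base_depth: np.ndarray
    window_means: list[float]
    n_dips: int

    @property
    def mean_depth(self) -> float:
        return float(self.per_base_depth.mean()) if len(self.per_base_depth) else 0.0


@dataclass(frozen=True)
class SupportDecision:
    transcript_id: str
    n_proper_pairs: int
    kept: bool
    reason: str


def tally_orientation(mappings: Iterable[PairMapping]) -> dict[str, PairOrientationCounts]:
    """Count proper-pair orientations per transcript.

    Each proper pair contributes once per (read_id, transcript) pair, so a
    multi-mapped pair counts once on every transcript it maps to.  The
    pair's bucket is inferred from whichever mate is seen first: under FR
    orientation, first-in-pair-on-plus is equivalent to
    second-in-pair-on-minus.
    """
    counts: dict[str, PairOrientationCounts] = {}
    seen: set[tuple[str, str]] = set()
    for m in mappings:
        if not m.is_proper_pair:
            continue
        key = (m.transcript_id, m.read_id)
        if key in seen:
            continue
        seen.add(key)
        c = counts.setdefault(m.transcript_id, PairOrientationCounts(m.transcript_id))
        read1_on_plus = (m.mate_rank == "first_in_pair") == (m.strand == "plus")
        if read1_on_plus:
            c.n_read1_plus += 1
        else:
            c.n_read2_plus += 1
    return counts


def compute_sslr(counts: PairOrientationCounts, pseudocount: float = 0.5) -> SslrValue:
    """SSLR = log2((n_read1_plus + pc) / (n_read2_plus + pc)).

    The symmetric pseudocount keeps the value finite for zero counts and
    makes swapping the two tallies negate the SSLR exactly.
    """
    if pseudocount <= 0:
        raise DataError("pseudocount must be > 0")
    sslr = math.log2((counts.n_read1_plus + pseudocount) / (counts.n_read2_plus + pseudocount))
    return SslrValue(counts.transcript_id, sslr, pseudocount)


def support_filter(
    counts: Mapping[str, PairOrientationCounts], min_pairs: int = 20
) -> dict[str, SupportDecision]:
    """Keep transcripts with at least *min_pairs* proper pairs (inclusive)."""
    if min_pairs < 0:
        raise DataError("min_pairs must be >= 0")
    out: dict[str, SupportDecision] = {}
    for tid, c in counts.items():
        kept = c.n_proper_pairs >= min_pairs
        out[tid] = SupportDecision(
            tid,
            c.n_proper_pairs,
            kept,
            "ok" if kept else "low_support",
        )
    return out


def per_base_depth(mappings: Iterable[PairMapping], transcript_len: int) -> np.ndarray:
    """Depth of aligned bases (M/=/X) per reference position, 0-indexed."""
    depth = np.zeros(transcript_len, dtype=np.int64)
    for m in mappings:
        for s, e in m.aligned_ref_blocks:
            if s < 1 or e > transcript_len:
                raise DataError(
                    f"block [{s},{e}] outside transcript {m.transcript_id!r} (len {transcript_len})"
                )
            depth[s - 1 : e] += 1
    return depth


def coverage_profile(
    mappings: Iterable[PairMapping],
    transcript_id: str,
    transcript_len: int,
    window_bp: int = 100,
    dip_fold: float = 5.0,
) -> CoverageProfile:
    """Windowed coverage means and dip count for one transcript.

    The transcript is cut into consecutive *window_bp* windows (a trailing
    remainder is kept only if it is at least half a window).  A dip is a
    strictly greater-than *dip_fold* ratio between the means of adjacent
    windows; a zero-mean window next to a covered one always counts (this
    keeps the dip count invariant under uniform depth scaling).
    """
    if transcript_len <= 0:
        raise DataError("transcript_len must be positive")
    if window_bp < 1:
        raise DataError("window_bp must be >= 1")
    if dip_fold <= 1:
        raise DataError("dip_fold must be > 1")
    depth = per_base_depth((m for m in mappings if m.transcript_id == transcript_id), transcript_len)
    bounds = list(range(0, transcript_len, window_bp))
    means: list[float] = []
    for b in bounds:
        win = depth[b : b + window_bp]
        if len(win) < window_bp and len(win) < window_bp / 2:
            break  # drop a short trailing remainder
        means.append(float(win.mean()))
    n_dips = 0
    for a, b in zip(means, means[1:]):
        lo, hi = min(a, b), max(a, b)
        if lo == 0.0:
            if hi > 0.0:
                n_dips += 1
        elif hi / lo > dip_fold:
            n_dips += 1
    return CoverageProfile(transcript_id, depth, means, n_dips)
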