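"""Two-pool differential-expression ratios with mode centering.

The comparison is descriptive (no replicates, DSN-normalized libraries):
a per-transcript log2 ratio of the two pools' read counts, normalized by
subtracting the center of the most populated 0.1-wide histogram bin.
Transcripts with no reads in a pool get a pseudo-count of 0.5 so that
pool-exclusive transcripts remain analyzable.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from ssfilter.io_formats import DataError

__all__ = ["DeRecord", "compute_ratios", "mode_center", "fold_change_table"]


@dataclass
class DeRecord:
    transcript_id: str
    count_pool_a: float
    count_pool_b: float
    raw_log2_ratio: float
    normalized_log2_ratio: float | None = None


def compute_ratios(
    counts_a: Mapping[str, float],
    counts_b: Mapping[str, float],
    min_reads: int = 50,
    zero_value: float = 0.5,
) -> list[DeRecord]:
    """Per-transcript raw log2 ratios of pool A over pool B.

    Only transcripts with a pooled total strictly above *min_reads* are
    included; a zero count is replaced by *zero_value* before the ratio.
    """
    records: list[DeRecord] = []
    for tid in sorted(set(counts_a) | set(counts_b)):
        a = float(counts_a.get(tid, 0))
        b = float(counts_b.get(tid, 0))
        if a < 0 or b < 0:
            raise DataError(f"negative count for {tid!r}")
        if a + b <= min_reads:
            continue
        ea = a if a > 0 else zero_value
        eb = b if b > 0 else zero_value
        records.append(DeRecord(tid, a, b, math.log2(ea / eb)))
    return records


def mode_center(records: Sequence[DeRecord], bin_width: float = 0.1) -> float:
    """Center the mode of the raw-ratio histogram on zero.

    Bins are ``[k*w, (k+1)*w)``; the offset is the center of the most
    populated bin (ties: the bin whose center is nearer 0, then the lower
    bin).  Every record's ``normalized_log2_ratio`` is set to
    ``raw - offset``; the offset is returned.
    """
    if not records:
        raise DataError("mode_center needs at least one record")
    if bin_width <= 0:
        raise DataError("bin_width must be positive")
    bins = Counter(math.floor(r.raw_log2_ratio / bin_width) for r in records)
    best = max(bins.items(), key=lambda kv: (kv[1], -abs((kv[0] + 0.5) * bin_width), -kv[0]))
    offset = (best[0] + 0.5) * bin_width
    for r in records:
        r.normalized_log2_ratio = r.raw_log2_ratio - offset
    return offset


def fold_change_table(
    records: Sequence[DeRecord], thresholds: Sequence[float] = (2.0, 16.0)
) -> dict[float, int]:
    """Count records exceeding each fold-change threshold in either direction."""
    for f in thresholds:
        if f <= 1:
            raise DataError("fold-change thresholds must be > 1")
    out: dict[float, int] = {}
    for f in thresholds:
        cut = math.log2(f)
        out[f] = sum(
            1
            for r in records
            if r.normalized_log2_ratio is not None and abs(r.normalized_log2_ratio) > cut
        )
    return out
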