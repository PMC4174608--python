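"""Pileup-based substitution-site screening against the assembly consensus.

The assembly itself is the reference, so the consensus at each position
is the majority of observed bases.  Only substitutions are considered;
deletions spanning a position and non-ACGT calls add depth but are
excluded from the allele-fraction denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from ssfilter.io_formats import DataError, PairMapping

__all__ = ["PileupColumn", "SubstitutionSite", "build_pileup", "call_substitutions", "write_vcf"]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PileupColumn:
    transcript_id: str
    position_1based: int
    base_counts: dict[str, int]  # over {A,C,G,T}
    n_skipped: int = 0  # N / non-ACGT calls and spanning deletions

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.n_skipped


@dataclass(frozen=True)
class SubstitutionSite:
    transcript_id: str
    position_1based: int
    consensus_base: str
    alt_base: str
    alt_fraction: float
    depth: int
    tier: str  # "relaxed_5pct" | "strict_20pct"


def build_pileup(
    mappings: Iterable[PairMapping], drop_duplicates: bool = True
) -> list[PileupColumn]:
    """Per-position base counts from mappings carrying aligned bases.

    Mappings without ``aligned_bases`` are ignored.  Duplicate-flagged
    records (FLAG 0x400) are dropped by default.  Columns are emitted for
    covered positions only, ordered by (transcript, position).
    """
    counts: dict[tuple[str, int], list[int]] = {}  # [A,C,G,T,skipped]
    for m in mappings:
        if m.aligned_bases is None:
            continue
        if drop_duplicates and m.is_duplicate:
            continue
        i = 0
        for s, e in m.aligned_ref_blocks:
            for pos in range(s, e + 1):
                base = m.aligned_bases[i]
                i += 1
                cell = counts.setdefault((m.transcript_id, pos), [0, 0, 0, 0, 0])
                idx = _BASE_IDX.get(base)
                if idx is None:
                    cell[4] += 1
                else:
                    cell[idx] += 1
        for s, e in m.deleted_ref_blocks:
            for pos in range(s, e + 1):
                counts.setdefault((m.transcript_id, pos), [0, 0, 0, 0, 0])[4] += 1
    return [
        PileupColumn(tid, pos, dict(zip(_BASES, cell[:4])), cell[4])
        for (tid, pos), cell in sorted(counts.items())
    ]


def call_substitutions(
    columns: Iterable[PileupColumn],
    min_depth: int = 21,
    relaxed_frac: float = 0.05,
    strict_frac: float = 0.20,
) -> Iterator[SubstitutionSite]:
    """Emit non-consensus bases exceeding the relaxed fraction.

    Only columns with depth >= *min_depth* (i.e. strictly more than 20
    reads at the default) are evaluated.  The consensus is the majority
    base (ties broken in A<C<G<T order).  Fractions are computed over the
    ACGT base counts (skips excluded) and compared strictly: a site enters
    the relaxed tier when its fraction exceeds *relaxed_frac* and is
    upgraded to strict only when it exceeds *strict_frac*.
    """
    if not (0 < relaxed_frac < 1 and 0 < strict_frac < 1):
        raise DataError("fractions must be in (0,1)")
    if relaxed_frac > strict_frac:
        raise DataError("relaxed_frac must be <= strict_frac")
    for col in columns:
        if col.depth < min_depth:
            continue
        total = sum(col.base_counts.values())
        if total == 0:
            continue
        consensus = max(_BASES, key=lambda b: (col.base_counts[b], -_BASE_IDX[b]))
        for base in _BASES:
            if base == consensus:
                continue
            frac = col.base_counts[base] / total
            if frac > relaxed_frac:
                yield SubstitutionSite(
                    transcript_id=col.transcript_id,
                    position_1based=col.position_1based,
                    consensus_base=consensus,
                    alt_base=base,
                    alt_fraction=frac,
                    depth=col.depth,
                    tier="strict_20pct" if frac > strict_frac else "relaxed_5pct",
                )


def write_vcf(sites: Iterable[SubstitutionSite], path: str) -> None:
    """Minimal VCF: CHROM = transcript ID, REF = consensus, INFO = AF/DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=TIER,Number=1,Type=String,Description="Calling tier">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.position_1based}\t.\t{s.consensus_base}\t"
                f"{s.alt_base}\t.\tPASS\tAF={s.alt_fraction:.4f};DP={s.depth};TIER={s.tier}\n"
            )
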