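"""Detection and removal of antisense "leakage" duplicate transcripts.

Imperfect second-strand degradation in a dUTP library lets a fraction of
fragments sequence from the wrong strand; assemblers then emit a
reverse-complement copy of a genuine sense transcript.  Such a copy (a)
matches the sense transcript in the alternate orientation over >80% of
the shorter member, and (b) has a strongly positive SSLR while the sense
member's SSLR is strongly negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ssfilter.io_formats import HomologyHit, TranscriptRecord

__all__ = [
    "LeakagePair",
    "find_alternate_orientation_pairs",
    "apply_leakage_rules",
    "find_reverse_complement_hits",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class LeakagePair:
    """A candidate (sense, antisense) duplicate pair.

    The member with the lower SSLR is labelled sense.  The overlap
    fraction is the union of reversed-orientation HSP intervals projected
    on the shorter member, over that member's length.
    """

    sense_id: str
    antisense_id: str
    overlap_fraction_of_shorter: float
    sense_sslr: float
    antisense_sslr: float
    sense_len: int
    antisense_len: int

    @property
    def length_ratio(self) -> float:
        return self.antisense_len / self.sense_len


def _union_len(intervals: Iterable[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def find_alternate_orientation_pairs(
    hits: Iterable[HomologyHit],
    sslr: Mapping[str, float],
    lengths: Mapping[str, int],
    min_overlap: float = 0.80,
) -> list[LeakagePair]:
    """Candidate leakage pairs from self-vs-self nucleotide hits.

    Only reversed-orientation HSPs (exactly one of query/subject with
    descending coordinates) count; self-hits are ignored; hits naming an
    unknown transcript are skipped.  A pair is emitted when the merged
    HSP span on the shorter member exceeds *min_overlap* of its length.
    Output is independent of (A,B)/(B,A) hit ordering.
    """
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in lengths or h.subject_id not in lengths:
            continue  # unknown transcript: skip hit
        if h.query_strand == h.subject_strand:
            continue  # same orientation: not leakage evidence
        pair = tuple(sorted((h.query_id, h.subject_id)))
        # project the HSP on the shorter member
        shorter = min(pair, key=lambda t: (lengths[t], t))
        if shorter == h.query_id:
            iv = (min(h.q_start, h.q_end), max(h.q_start, h.q_end))
        else:
            iv = (min(h.s_start, h.s_end), max(h.s_start, h.s_end))
        spans.setdefault(pair, []).append(iv)

    out: list[LeakagePair] = []
    for (a, b), ivs in sorted(spans.items()):
        shorter = min((a, b), key=lambda t: (lengths[t], t))
        frac = _union_len(ivs) / lengths[shorter]
        if frac <= min_overlap:
            continue
        sslr_a = sslr.get(a, 0.0)
        sslr_b = sslr.get(b, 0.0)
        if sslr_a <= sslr_b:
            sense, anti = a, b
        else:
            sense, anti = b, a
        out.append(
            LeakagePair(
                sense_id=sense,
                antisense_id=anti,
                overlap_fraction_of_shorter=frac,
                sense_sslr=min(sslr_a, sslr_b),
                antisense_sslr=max(sslr_a, sslr_b),
                sense_len=lengths[sense],
                antisense_len=lengths[anti],
            )
        )
    return out


def apply_leakage_rules(
    pairs: Iterable[LeakagePair],
    sslr_neg_max: float = -2.5,
    sslr_pos_min: float = 1.5,
    max_len_excess: float = 0.10,
    mode: str = "strict",
) -> dict[str, LeakagePair]:
    """Decide which antisense members to discard.

    Strict mode (default) discards the positive-SSLR member of a pair iff
    the sense SSLR is below *sslr_neg_max*, the antisense SSLR is above
    *sslr_pos_min*, and the antisense member is at most *max_len_excess*
    longer than the sense member.  Permissive mode discards on a positive
    antisense SSLR alone.  Pairs are evaluated independently; a transcript
    is discarded if any pair triggers, which makes the decision set
    idempotent and order-independent.
    """
    discards: dict[str, LeakagePair] = {}
    for p in sorted(pairs, key=lambda p: (p.antisense_id, p.sense_id)):
        if mode == "permissive":
            trigger = p.antisense_sslr > 0
        else:
            trigger = (
                p.sense_sslr < sslr_neg_max
                and p.antisense_sslr > sslr_pos_min
                and p.antisense_len <= p.sense_len * (1.0 + max_len_excess)
            )
        if trigger and p.antisense_id not in discards:
            discards[p.antisense_id] = p
    return discards


def find_reverse_complement_hits(
    transcripts: Sequence[TranscriptRecord],
    k: int = 31,
    min_hit_len: int = 60,
) -> list[HomologyHit]:
    """Hermetic fallback for the external all-vs-all nucleotide search.

    Exact k-mer seeding of each transcript's reverse complement against
    every other transcript, with greedy ungapped extension; emits
    reversed-orientation hits (query coordinates descending) in the
    14-column hit model.  Intended for tests and small runs — production
    users should supply real BLASTN tabular output.
    """
    index: dict[str, list[tuple[int, int]]] = {}
    for ti, t in enumerate(transcripts):
        seq = t.sequence
        for j in range(0, len(seq) - k + 1):
            index.setdefault(seq[j : j + k], []).append((ti, j))

    hits: list[HomologyHit] = []
    for ai, a in enumerate(transcripts):
        rc = revcomp(a.sequence)
        la = len(rc)
        # matches already found per (target, diagonal), to skip redundant seeds
        covered: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for i in range(0, la - k + 1):
            for bi, j in index.get(rc[i : i + k], ()):
                if bi == ai:
                    continue
                diag = i - j
                if any(s <= i <= e for s, e in covered.get((bi, diag), ())):
                    continue
                bseq = transcripts[bi].sequence
                i0, j0 = i, j
                while i0 > 0 and j0 > 0 and rc[i0 - 1] == bseq[j0 - 1]:
                    i0 -= 1
                    j0 -= 1
                i1, j1 = i + k - 1, j + k - 1
                while i1 + 1 < la and j1 + 1 < len(bseq) and rc[i1 + 1] == bseq[j1 + 1]:
                    i1 += 1
                    j1 += 1
                covered.setdefault((bi, diag), []).append((i0, i1))
                mlen = i1 - i0 + 1
                if mlen < min_hit_len:
                    continue
                hits.append(
                    HomologyHit(
                        query_id=a.transcript_id,
                        subject_id=transcripts[bi].transcript_id,
                        evalue=10.0 ** (-min(180, mlen // 2)),
                        # rc position i maps to forward position la - i (1-based)
                        q_start=la - i0,
                        q_end=la - i1,
                        s_start=j0 + 1,
                        s_end=j1 + 1,
                        q_len=la,
                        s_len=len(bseq),
                        db="nucl_self",
                        bitscore=2.0 * mlen,
                    )
                )
    return hits
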