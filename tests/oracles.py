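"""Independent brute-force oracles used to freeze expected values.

These are deliberately written against the *definitions* (per-base walks,
codon splitting, direct metric arithmetic) and share no code with the
package implementations they check.
"""

from __future__ import annotations

import re
from collections import Counter

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# --- CIGAR ----------------------------------------------------------------

def cigar_blocks_bruteforce(cigar: str, pos_1based: int) -> list[tuple[int, int]]:
    """Per-base reference walk; aligned positions grouped into runs."""
    ref = pos_1based
    aligned_positions: list[int] = []
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(n)
        if op in "M=X":
            for _ in range(n):
                aligned_positions.append(ref)
                ref += 1
        elif op in "DN":
            ref += n
        # I, S, H, P consume no reference
    blocks: list[tuple[int, int]] = []
    for p in aligned_positions:
        if blocks and blocks[-1][1] == p - 1:
            blocks[-1] = (blocks[-1][0], p)
        else:
            blocks.append((p, p))
    return blocks


# --- six-frame ORFs -------------------------------------------------------

def orfs_bruteforce(seq: str, min_len: int = 300, mode: str = "start_to_stop"):
    """Stop-index segmentation in each of six frames.

    Returns a set of (start, end, strand, frame, partial) with 1-based
    inclusive forward coordinates.
    """
    stops = {"TAA", "TAG", "TGA"}
    out = set()
    n = len(seq)
    for strand in ("plus", "minus"):
        w = seq if strand == "plus" else rc(seq)
        for f in range(3):
            codons = [(i, w[i : i + 3]) for i in range(f, n - 2, 3)]
            # segment boundaries at stop codons
            segments = []
            cur: list[tuple[int, str]] = []
            for i, c in codons:
                cur.append((i, c))
                if c in stops:
                    segments.append((cur, False))
                    cur = []
            if cur:
                segments.append((cur, True))  # runs off the edge
            for seg, partial in segments:
                if mode == "start_to_stop":
                    starts = [i for i, c in seg if c == "ATG"]
                    if not starts:
                        continue
                    s0 = starts[0]
                else:
                    s0 = seg[0][0]
                e0 = seg[-1][0] + 2
                if e0 - s0 + 1 < min_len:
                    continue
                if strand == "plus":
                    start, end = s0 + 1, e0 + 1
                else:
                    start, end = n - e0, n - s0
                out.add((start, end, strand, f, partial))
    return out


# --- pileup ---------------------------------------------------------------

def pileup_bruteforce(mappings) -> dict[tuple[str, int], tuple[Counter, int]]:
    """(transcript, pos) -> (Counter over ACGT, n_skipped)."""
    cols: dict[tuple[str, int], tuple[Counter, int]] = {}
    for m in mappings:
        if m.aligned_bases is None or m.is_duplicate:
            continue
        positions = [p for s, e in m.aligned_ref_blocks for p in range(s, e + 1)]
        for p, b in zip(positions, m.aligned_bases):
            cnt, sk = cols.setdefault((m.transcript_id, p), (Counter(), 0))
            if b in "ACGT":
                cnt[b] += 1
            else:
                cols[(m.transcript_id, p)] = (cnt, sk + 1)
        for s, e in m.deleted_ref_blocks:
            for p in range(s, e + 1):
                cnt, sk = cols.setdefault((m.transcript_id, p), (Counter(), 0))
                cols[(m.transcript_id, p)] = (cnt, sk + 1)
    return cols


# --- Table-style scoring --------------------------------------------------

def score_bruteforce(t, ev, ctx, w) -> float:
    """Naive re-evaluation of the 19 weighted metrics, written longhand."""

    def safe(num, den):
        return num / den if den else 0.0

    total = 0.0
    for hit, wts in ((ev.first_uniref, (w.a1, w.a2, w.a3, w.a4, w.a5)),
                     (ev.first_nr, (w.a6, w.a7, w.a8, w.a9, w.a10))):
        if hit is None:
            continue
        db = hit.db
        scov = abs(hit.s_end - hit.s_start) + 1
        qcov = abs(hit.q_end - hit.q_start) + 1
        total += wts[0] * safe(scov, hit.s_len)
        total += wts[1] * safe(qcov, len(t.sequence))
        total += wts[2] * safe(scov, ctx.longest_subject_hit_len.get(db, 0))
        total += wts[3] * safe(qcov, ctx.longest_query_hit_len.get(db, 0))
        sign = -1.0 if hit.q_start > hit.q_end else 1.0
        total += wts[4] * sign * safe(-ev.sslr, ctx.max_abs_sslr)
    total += w.a11 * safe(-ev.sslr, ctx.max_abs_sslr)
    total += w.a12 * safe(len(t.sequence), ctx.longest_transcript_len)

    if ev.orfs:
        subjects = set()
        for o in ev.orfs:
            if o.best_hit is not None:
                subjects.add(o.best_hit.subject_id)
        total += w.b1 * safe(1 - len(subjects), len(subjects))

        plus = [o for o in ev.orfs if o.strand == "plus"]
        minus = [o for o in ev.orfs if o.strand == "minus"]
        if plus and minus:
            ratio = -min(len(plus), len(minus)) / max(len(plus), len(minus))
            p_hit = any(o.best_hit is not None for o in plus)
            m_hit = any(o.best_hit is not None for o in minus)
            if p_hit and m_hit:
                total += w.b2 * ratio
            elif p_hit or m_hit:
                total += w.b3 * ratio
            else:
                total += w.b4 * ratio
        total += w.b5 * (1 - len(ev.orfs)) / len(ev.orfs)
        if plus and minus:
            sign = 0.0
        elif plus:
            sign = 1.0
        else:
            sign = -1.0
        total += w.b6 * sign * safe(-ev.sslr, ctx.max_abs_sslr)

    total += w.c1 * -safe(ev.n_dips, ctx.max_dips)
    return total
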