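"""Readers and writers for the external formats the pipeline touches.

Dialects (strict):

* FASTA — unique headers; sequences are uppercased and must be over
  ``{A,C,G,T,N}``.  Trinity-style IDs ``comp<i>_c<j>_seq<k>`` yield the
  component ``comp<i>_c<j>``; other IDs need an explicit component map
  (otherwise each transcript is its own component).
* SAM (text) — FLAG/RNAME/POS/CIGAR are required; reference blocks come
  from M/=/X CIGAR operations.  I/S/H consume no reference; D/N consume
  reference but contribute no aligned base.
* BLAST tabular — outfmt-6 with ``qlen``/``slen`` appended as columns
  13-14; plain 12-column input is accepted only with sidecar length maps.
* GFF3 — 1-based inclusive coordinates, ``ID=`` attribute.

All coordinates are 1-based inclusive internally, matching SAM/GFF3/BLAST.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "TranscriptRecord",
    "PairMapping",
    "HomologyHit",
    "SamWarnings",
    "DataError",
    "component_of",
    "read_fasta",
    "write_fasta",
    "read_sam_pairs",
    "read_blast_tab",
    "first_hits",
    "write_orfs_gff3",
    "read_orfs_gff3",
    "write_report_tsv",
    "read_report_tsv",
]

_TRINITY_ID = re.compile(r"^(comp\d+_c\d+)_seq\d+$", re.IGNORECASE)
_VALID_NT = frozenset("ACGTN")


class DataError(ValueError):
    """Malformed or inconsistent input data (exit code 3 at the CLI)."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled putative transcript."""

    transcript_id: str
    component_id: str
    sequence: str

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class PairMapping:
    """One alignment line of a paired-end read against a transcript.

    ``aligned_ref_blocks`` are 1-based inclusive ``(start, end)`` intervals
    covered by M/=/X operations; ``deleted_ref_blocks`` are the reference
    spans consumed by D operations (they add pileup depth but no base).
    ``aligned_bases`` holds one base per aligned reference position, in
    block order, when the SAM line carried a SEQ field.
    """

    transcript_id: str
    read_id: str
    mate_rank: str  # "first_in_pair" | "second_in_pair"
    strand: str  # "plus" | "minus"
    start_1based: int
    aligned_ref_blocks: list[tuple[int, int]]
    is_proper_pair: bool
    is_duplicate: bool = False
    deleted_ref_blocks: list[tuple[int, int]] = field(default_factory=list)
    aligned_bases: str | None = None


@dataclass
class HomologyHit:
    """One tabular homology hit (protein or nucleotide).

    For translated searches the query strand is minus iff
    ``q_start > q_end`` (BLAST convention); likewise for the subject side
    of nucleotide searches.
    """

    query_id: str
    subject_id: str
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_len: int
    s_len: int
    db: str = "other"
    subject_taxon: str | None = None
    pident: float = 100.0
    bitscore: float = 0.0

    @property
    def query_strand(self) -> str:
        return "minus" if self.q_start > self.q_end else "plus"

    @property
    def subject_strand(self) -> str:
        return "minus" if self.s_start > self.s_end else "plus"

    @property
    def query_covered(self) -> int:
        return abs(self.q_end - self.q_start) + 1

    @property
    def subject_covered(self) -> int:
        return abs(self.s_end - self.s_start) + 1


@dataclass
class SamWarnings:
    """Counted, non-fatal anomalies seen while reading a SAM file."""

    missing_cigar: int = 0
    unpaired: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.missing_cigar + self.unpaired + self.unmapped


def component_of(transcript_id: str, component_map: Mapping[str, str] | None = None) -> str:
    """Component for a transcript ID: sidecar map first, then the Trinity
    ``comp<i>_c<j>_seq<k>`` pattern, else the ID itself (singleton)."""
    if component_map is not None and transcript_id in component_map:
        return component_map[transcript_id]
    m = _TRINITY_ID.match(transcript_id)
    if m:
        return m.group(1)
    return transcript_id


def read_fasta(
    path: str | Path, component_map: Mapping[str, str] | None = None
) -> Iterator[TranscriptRecord]:
    """Stream transcripts from a FASTA file.

    Raises :class:`DataError` on duplicate IDs or non-``{A,C,G,T,N}``
    characters (the offending record is named).
    """
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tid = rec.id
        if tid in seen:
            raise DataError(f"duplicate transcript ID: {tid!r}")
        seen.add(tid)
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_NT
        if bad:
            raise DataError(
                f"record {tid!r} contains non-IUPAC-DNA characters: {sorted(bad)}"
            )
        if not seq:
            raise DataError(f"record {tid!r} has an empty sequence")
        yield TranscriptRecord(tid, component_of(tid, component_map), seq)


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _cigar_blocks(
    cigartuples: Sequence[tuple[int, int]], pos_1based: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Aligned (M/=/X) and deleted (D) reference blocks from CIGAR tuples."""
    # pysam op codes: 0=M 1=I 2=D 3=N 4=S 5=H 6=P 7== 8=X
    aligned: list[tuple[int, int]] = []
    deleted: list[tuple[int, int]] = []
    ref = pos_1based
    for op, n in cigartuples:
        if op in (0, 7, 8):
            if aligned and aligned[-1][1] == ref - 1:
                aligned[-1] = (aligned[-1][0], ref + n - 1)
            else:
                aligned.append((ref, ref + n - 1))
            ref += n
        elif op == 2:
            deleted.append((ref, ref + n - 1))
            ref += n
        elif op == 3:
            ref += n
        # I/S/H/P consume no reference
    return aligned, deleted


def _aligned_bases(cigartuples: Sequence[tuple[int, int]], seq: str) -> str:
    """Per-reference-position bases in block order (M/=/X only)."""
    out: list[str] = []
    q = 0
    for op, n in cigartuples:
        if op in (0, 7, 8):
            out.append(seq[q : q + n])
            q += n
        elif op in (1, 4):  # I, S consume query only
            q += n
    return "".join(out)


def read_sam_pairs(
    path: str | Path,
    *,
    with_bases: bool = False,
    drop_duplicates: bool = False,
    include_secondary: bool = True,
    warnings: SamWarnings | None = None,
) -> Iterator[PairMapping]:
    """Stream paired-end alignments from a text SAM file.

    Records with ``*`` CIGAR or with neither 0x40 nor 0x80 set are skipped
    and counted in *warnings*.  All alignment lines are kept by default
    (multi-mapped reads count everywhere they map); duplicates (FLAG 0x400)
    are dropped only when *drop_duplicates* is set.
    """
    warn = warnings if warnings is not None else SamWarnings()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_id < 0 or aln.cigartuples is None:
                # htslib downgrades a mapped record with `*` CIGAR to unmapped
                if aln.reference_id >= 0 and aln.cigartuples is None:
                    warn.missing_cigar += 1
                else:
                    warn.unmapped += 1
                continue
            if not (aln.is_read1 or aln.is_read2):
                warn.unpaired += 1
                continue
            if drop_duplicates and aln.is_duplicate:
                continue
            if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                continue
            pos = aln.reference_start + 1
            aligned, deleted = _cigar_blocks(aln.cigartuples, pos)
            bases: str | None = None
            if with_bases and aln.query_sequence:
                bases = _aligned_bases(aln.cigartuples, aln.query_sequence)
            yield PairMapping(
                transcript_id=fh.get_reference_name(aln.reference_id),
                read_id=aln.query_name,
                mate_rank="first_in_pair" if aln.is_read1 else "second_in_pair",
                strand="minus" if aln.is_reverse else "plus",
                start_1based=pos,
                aligned_ref_blocks=aligned,
                is_proper_pair=aln.is_proper_pair,
                is_duplicate=aln.is_duplicate,
                deleted_ref_blocks=deleted,
                aligned_bases=bases,
            )


def read_blast_tab(
    path: str | Path,
    db: str = "other",
    *,
    qlen_map: Mapping[str, int] | None = None,
    slen_map: Mapping[str, int] | None = None,
    taxon_map: Mapping[str, str] | None = None,
) -> list[HomologyHit]:
    """Parse BLAST outfmt-6 (12 columns) or outfmt-6 + qlen + slen (14).

    Query/subject lengths must come from columns 13-14 or from the sidecar
    maps; otherwise a :class:`DataError` is raised (coverage-proportion
    metrics are undefined without them).  Hit order is file order.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) not in (12, 14):
                raise DataError(f"{path}:{ln}: expected 12 or 14 columns, got {len(f)}")
            qid, sid = f[0], f[1]
            if len(f) == 14:
                q_len, s_len = int(f[12]), int(f[13])
            else:
                if qlen_map is None or slen_map is None or qid not in qlen_map or sid not in slen_map:
                    raise DataError(
                        f"{path}:{ln}: 12-column input needs qlen/slen sidecar maps "
                        f"covering {qid!r} and {sid!r}"
                    )
                q_len, s_len = qlen_map[qid], slen_map[sid]
            hits.append(
                HomologyHit(
                    query_id=qid,
                    subject_id=sid,
                    pident=float(f[2]),
                    q_start=int(f[6]),
                    q_end=int(f[7]),
                    s_start=int(f[8]),
                    s_end=int(f[9]),
                    evalue=float(f[10]),
                    bitscore=float(f[11]),
                    q_len=q_len,
                    s_len=s_len,
                    db=db,
                    subject_taxon=taxon_map.get(sid) if taxon_map else None,
                )
            )
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in the 14-column dialect (outfmt-6 + qlen + slen)."""
    with open(path, "w") as fh:
        for h in hits:
            aln_len = max(h.query_covered, h.subject_covered)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.pident:.2f}", aln_len, 0, 0,
                        h.q_start, h.q_end, h.s_start, h.s_end,
                        f"{h.evalue:.2e}", f"{h.bitscore:.1f}", h.q_len, h.s_len,
                    )
                )
                + "\n"
            )


def first_hits(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
    """Best hit per query: lowest e-value, ties broken by file order."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.evalue < cur.evalue:
            best[h.query_id] = h
    return best


# --- GFF3 / TSV report plumbing -------------------------------------------

_GFF_SOURCE = {"priority_external": "priority", "builtin_sixframe": "sixframe"}
_GFF_SOURCE_INV = {v: k for k, v in _GFF_SOURCE.items()}


def write_orfs_gff3(orfs: Iterable, path: str | Path) -> None:
    """Write ORF calls as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            attrs = (
                f"ID={o.orf_id};frame={o.frame};mode={o.mode};"
                f"partial={'true' if o.partial else 'false'}"
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        o.transcript_id,
                        _GFF_SOURCE.get(o.source, o.source),
                        "CDS",
                        o.start,
                        o.end,
                        ".",
                        "+" if o.strand == "plus" else "-",
                        "0",
                        attrs,
                    )
                )
                + "\n"
            )


def read_orfs_gff3(path: str | Path) -> list:
    """Read CDS features back into :class:`~ssfilter.orf_calling.OrfCall`."""
    from ssfilter.orf_calling import OrfCall

    out: list[OrfCall] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise DataError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(f)}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            out.append(
                OrfCall(
                    transcript_id=f[0],
                    start=int(f[3]),
                    end=int(f[4]),
                    strand="plus" if f[6] == "+" else "minus",
                    frame=int(attrs.get("frame", 0)),
                    source=_GFF_SOURCE_INV.get(f[1], f[1]),
                    mode=attrs.get("mode", "start_to_stop"),
                    partial=attrs.get("partial", "false") == "true",
                    orf_id=attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                )
            )
    return out


def write_report_tsv(rows: Iterable[Mapping[str, object]], path: str | Path, columns: Sequence[str] | None = None) -> None:
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t", lineterminator="\n")
        w.writeheader()
        for r in rows:
            w.writerow(r)


def read_report_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
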