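"""Seeded simulator for every input the triage pipeline consumes.

Emulates a dUTP strand-specific experiment end to end: multi-isoform
components with planted ORFs, exact reverse-complement "leakage" twins,
unstranded low-support contamination contigs, proper-pair alignments with
orientation leakage, planted substitution sites, tabular protein /
self-nucleotide hits, and two-pool counts with a planted global offset.

Mappings are generated directly (no external aligner), with a fixed
fragment size and uniform fragment starts — deliberately unrealistic but
sufficient for orientation and coverage statistics, and exact by
construction.  Because a leakage twin is the exact reverse complement of
its sense partner, every read pair of the partner also maps to the twin
in the flipped orientation (as a multi-match-tolerant aligner would
report), which is what gives twins their positive SSLR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ssfilter.io_formats import DataError, HomologyHit, TranscriptRecord, write_blast_tab
from ssfilter.leakage_filter import revcomp

__all__ = [
    "SimConfig",
    "TruthTables",
    "SnpTruth",
    "simulate_assembly",
    "simulate_pairs",
    "simulate_hits",
    "simulate_two_pool_counts",
    "simulate_all",
]

_NT = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in _NT
    for b in _NT
    for c in _NT
    if a + b + c not in _STOPS
)


@dataclass
class SimConfig:
    seed: int = 0
    n_components: int = 20
    isoforms_per_component: tuple[int, int] = (1, 1)
    transcript_len: tuple[int, int] = (600, 1500)
    coding_fraction: float = 1.0
    cds_fraction: float = 0.8
    leak_prob: float = 0.05
    twin_fraction: float = 0.0
    contamination_fraction: float = 0.0
    pairs_per_transcript: tuple[int, int] = (200, 300)
    contamination_pairs: tuple[int, int] = (2, 19)
    read_len: int = 100
    fragment_len: int = 250
    snp_sites_per_kb: float = 0.0
    snp_fractions: tuple[float, ...] = (0.3,)
    error_rate: float = 0.0
    de_offset: float = 0.0
    de_signal_fraction: float = 0.1
    de_mean_count: float = 300.0

    def __post_init__(self) -> None:
        for name in ("coding_fraction", "cds_fraction", "twin_fraction",
                     "contamination_fraction", "error_rate", "de_signal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.leak_prob <= 0.5:
            raise DataError("leak_prob must be in [0, 0.5]")
        for name in ("isoforms_per_component", "transcript_len",
                     "pairs_per_transcript", "contamination_pairs"):
            lo, hi = getattr(self, name)
            setattr(self, name, (int(lo), int(hi)))
            if lo > hi or lo < 0:
                raise DataError(f"{name} range ({lo},{hi}) is empty or negative")
        if self.isoforms_per_component[0] < 1:
            raise DataError("need at least one isoform per component")
        if self.coding_fraction > 0 and self.transcript_len[0] < 310:
            raise DataError("coding transcripts need transcript_len >= 310")
        if self.read_len < 1 or self.fragment_len < self.read_len:
            raise DataError("need 1 <= read_len <= fragment_len")
        if any(not 0.0 < f <= 1.0 for f in self.snp_fractions):
            raise DataError("snp_fractions must be in (0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("isoforms_per_component", "transcript_len",
                    "pairs_per_transcript", "contamination_pairs", "snp_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class SnpTruth:
    transcript_id: str
    position_1based: int
    ref_base: str
    alt_base: str
    fraction: float


@dataclass
class TruthTables:
    """Ground truth for everything the simulator planted."""

    labels: dict[str, str] = field(default_factory=dict)  # sense|leakage_antisense|contamination
    representative: dict[str, str] = field(default_factory=dict)  # component -> transcript
    orf_span: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    twin_of: dict[str, str] = field(default_factory=dict)  # twin -> sense partner
    fragment_of: dict[str, tuple[str, int]] = field(default_factory=dict)  # frag -> (full, offset0)
    snps: list[SnpTruth] = field(default_factory=list)
    de_offsets: dict[str, float] = field(default_factory=dict)
    de_global_offset: float = 0.0


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=n))


def _coding_sequence(
    rng: np.random.Generator, length: int, cds_fraction: float = 0.8
) -> tuple[str, int, int]:
    """A transcript of *length* bp with one planted plus-strand ORF.

    The 5' UTR ends with an in-frame TAA immediately before the ATG, so
    the planted ORF is exactly the maximal ATG-to-stop ORF in its frame.
    Returns (sequence, orf_start_1based, orf_end_1based).
    """
    target = max(300, int(round(cds_fraction * length)))
    orf_len = min(target, length - 9) // 3 * 3
    if orf_len < 300:
        raise DataError(f"transcript of {length} bp cannot carry a 300 bp ORF")
    n_mid = orf_len // 3 - 2  # codons between ATG and stop
    rest = length - orf_len
    utr5_len = 3 + int(rng.integers(0, rest - 3 + 1)) if rest > 3 else 3
    utr3_len = length - orf_len - utr5_len
    mid = "".join(
        _NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_mid)
    )
    stop = _STOPS[int(rng.integers(0, 3))]
    utr5 = _random_seq(rng, utr5_len - 3) + "TAA"
    utr3 = _random_seq(rng, utr3_len)
    seq = utr5 + "ATG" + mid + stop + utr3
    assert len(seq) == length
    return seq, utr5_len + 1, utr5_len + orf_len


def simulate_assembly(cfg: SimConfig) -> tuple[list[TranscriptRecord], TruthTables]:
    """Generate the putative-transcript FASTA records and the truth tables."""
    rng = np.random.default_rng(cfg.seed)
    truth = TruthTables()
    records: list[TranscriptRecord] = []

    def add(tid: str, seq: str, label: str) -> TranscriptRecord:
        rec = TranscriptRecord(tid, tid.rsplit("_seq", 1)[0], seq)
        records.append(rec)
        truth.labels[tid] = label
        return rec

    lo_len, hi_len = cfg.transcript_len
    lo_iso, hi_iso = cfg.isoforms_per_component
    for ci in range(1, cfg.n_components + 1):
        comp = f"comp{ci}_c0"
        length = int(rng.integers(lo_len, hi_len + 1))
        coding = rng.random() < cfg.coding_fraction
        if coding:
            seq, orf_s, orf_e = _coding_sequence(rng, length, cfg.cds_fraction)
        else:
            seq, orf_s, orf_e = _random_seq(rng, length), 0, 0
        full_id = f"{comp}_seq1"
        add(full_id, seq, "sense")
        if coding:
            truth.orf_span[full_id] = (orf_s, orf_e, "plus")
        truth.representative[comp] = full_id

        n_iso = int(rng.integers(lo_iso, hi_iso + 1))
        for k in range(2, n_iso + 1):
            frac = rng.uniform(0.3, 0.7)
            flen = max(50, int(round(frac * length)))
            off = int(rng.integers(0, length - flen + 1))
            fid = f"{comp}_seq{k}"
            add(fid, seq[off : off + flen], "sense")
            truth.fragment_of[fid] = (full_id, off)

        if rng.random() < cfg.twin_fraction:
            twin_id = f"comp{ci}_c1_seq1"
            add(twin_id, revcomp(seq), "leakage_antisense")
            truth.twin_of[twin_id] = full_id

        # plant substitution sites on the full-length isoform, away from
        # the coverage falloff at the transcript edges
        if cfg.snp_sites_per_kb > 0:
            n_snp = int(rng.poisson(cfg.snp_sites_per_kb * length / 1000.0))
            margin = min(cfg.fragment_len, length // 3)
            interior = np.arange(margin, length - margin)
            positions = sorted(
                int(p)
                for p in rng.choice(
                    interior, size=min(n_snp, len(interior)), replace=False
                )
            )
            for p0 in positions:
                ref = seq[p0]
                alt = _NT[(_NT.index(ref) + int(rng.integers(1, 4))) % 4]
                frac = float(cfg.snp_fractions[int(rng.integers(0, len(cfg.snp_fractions)))])
                truth.snps.append(SnpTruth(full_id, p0 + 1, ref, alt, frac))

    n_sense = sum(1 for v in truth.labels.values() if v == "sense")
    n_contam = int(round(cfg.contamination_fraction * n_sense))
    for j in range(1, n_contam + 1):
        tid = f"comp{cfg.n_components + j}_c0_seq1"
        length = int(rng.integers(80, 300))
        add(tid, _random_seq(rng, length), "contamination")
    return records, truth


def _sam_line(
    qname: str, flag: int, rname: str, pos1: int, cigar: str,
    pnext1: int, tlen: int, seq: str,
) -> str:
    return (
        f"{qname}\t{flag}\t{rname}\t{pos1}\t60\t{cigar}\t=\t{pnext1}\t{tlen}\t"
        f"{seq}\t{'I' * len(seq)}\n"
    )


def simulate_pairs(
    cfg: SimConfig,
    transcripts: Sequence[TranscriptRecord],
    truth: TruthTables,
    path: str | Path,
) -> None:
    """Write proper-pair alignments for every transcript as text SAM.

    Sense transcripts get FR pairs with the second-in-pair read on the
    plus strand, flipped with probability ``leak_prob``; contamination
    contigs get orientation-balanced pairs; each leakage twin receives
    the coordinate-mirrored copy of every pair of its sense partner.
    Planted substitution sites are injected at their exact fractions
    (rounded over the covering reads), after sequencing errors.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    snps_by_tid: dict[str, list[SnpTruth]] = {}
    for s in truth.snps:
        snps_by_tid.setdefault(s.transcript_id, []).append(s)
    twin_of_sense = {v: k for k, v in truth.twin_of.items()}

    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for t in transcripts:
            out.write(f"@SQ\tSN:{t.transcript_id}\tLN:{t.length_bp}\n")

        for t in transcripts:
            label = truth.labels[t.transcript_id]
            if label == "leakage_antisense":
                continue  # receives mirrored pairs from its partner
            L = t.length_bp
            frag = min(cfg.fragment_len, L)
            rlen = min(cfg.read_len, frag)
            if label == "contamination":
                lo, hi = cfg.contamination_pairs
            else:
                lo, hi = cfg.pairs_per_transcript
            n_pairs = int(rng.integers(lo, hi + 1))
            starts = rng.integers(0, L - frag + 1, size=n_pairs)
            if label == "contamination":
                flips = rng.random(n_pairs) < 0.5  # unstranded
            else:
                flips = rng.random(n_pairs) < cfg.leak_prob

            # reads[i]: (pair, rank, pos0) — left read is plus strand,
            # right read minus; rank 1 left iff the pair is flipped/leak
            reads: list[tuple[int, int, int]] = []
            for p in range(n_pairs):
                s0 = int(starts[p])
                left_rank = 1 if flips[p] else 2
                reads.append((p, left_rank, s0))
                reads.append((p, 3 - left_rank, s0 + frag - rlen))

            seqs: list[bytearray] = []
            for _, _, pos0 in reads:
                buf = bytearray(t.sequence[pos0 : pos0 + rlen], "ascii")
                if cfg.error_rate > 0:
                    errs = np.nonzero(rng.random(rlen) < cfg.error_rate)[0]
                    for e in errs:
                        buf[e] = ord(_NT[(_NT.index(chr(buf[e])) + int(rng.integers(1, 4))) % 4])
                seqs.append(buf)
            for snp in snps_by_tid.get(t.transcript_id, ()):
                p0 = snp.position_1based - 1
                cover = [i for i, (_, _, pos0) in enumerate(reads) if pos0 <= p0 < pos0 + rlen]
                n_alt = int(round(snp.fraction * len(cover)))
                carriers = set(
                    int(i) for i in rng.permutation(np.asarray(cover, dtype=np.int64))[:n_alt]
                )
                for i in cover:
                    _, _, pos0 = reads[i]
                    seqs[i][p0 - pos0] = ord(snp.alt_base if i in carriers else snp.ref_base)

            twin = twin_of_sense.get(t.transcript_id)
            cigar = f"{rlen}M"
            for p in range(n_pairs):
                li, ri = 2 * p, 2 * p + 1
                (_, lrank, lpos0), (_, rrank, rpos0) = reads[li], reads[ri]
                qname = f"{t.transcript_id}.p{p}"
                lflag = 0x1 | 0x2 | 0x20 | (0x40 if lrank == 1 else 0x80)
                rflag = 0x1 | 0x2 | 0x10 | (0x40 if rrank == 1 else 0x80)
                lseq, rseq = seqs[li].decode(), seqs[ri].decode()
                out.write(_sam_line(qname, lflag, t.transcript_id, lpos0 + 1, cigar,
                                    rpos0 + 1, frag, lseq))
                out.write(_sam_line(qname, rflag, t.transcript_id, rpos0 + 1, cigar,
                                    lpos0 + 1, -frag, rseq))
                if twin is not None:
                    # mirrored mapping: position L-pos0-rlen, strands swap
                    mlpos0, mrpos0 = L - rpos0 - rlen, L - lpos0 - rlen
                    mlflag = 0x1 | 0x2 | 0x20 | (0x40 if rrank == 1 else 0x80)
                    mrflag = 0x1 | 0x2 | 0x10 | (0x40 if lrank == 1 else 0x80)
                    out.write(_sam_line(qname, mlflag, twin, mlpos0 + 1, cigar,
                                        mrpos0 + 1, frag, revcomp(rseq)))
                    out.write(_sam_line(qname, mrflag, twin, mrpos0 + 1, cigar,
                                        mlpos0 + 1, -frag, revcomp(lseq)))


def _protein_hit(
    tid: str, t_len: int, subject: str, s_len_aa: int, cov_aa: int,
    q_from: int, q_to: int, db: str, minus: bool,
) -> HomologyHit:
    evalue = 10.0 ** (-min(180, max(1, cov_aa // 2)))
    q_start, q_end = (q_to, q_from) if minus else (q_from, q_to)
    return HomologyHit(
        query_id=tid, subject_id=subject, evalue=evalue,
        q_start=q_start, q_end=q_end, s_start=1, s_end=cov_aa,
        q_len=t_len, s_len=s_len_aa, db=db, bitscore=2.0 * cov_aa,
    )


def simulate_hits(
    cfg: SimConfig,
    transcripts: Sequence[TranscriptRecord],
    truth: TruthTables,
) -> tuple[list[HomologyHit], list[HomologyHit], list[HomologyHit]]:
    """Protein hit tables (uniref-like, nr-like) and the self-nucleotide table.

    Full-length coding isoforms hit a fictitious protein of matched
    length over ~100% of it; fragments hit it over the fraction of the
    CDS they contain; leakage twins hit it in the minus orientation.
    E-values are monotone in covered length.  Twin pairs appear in the
    self table as full-length reversed-orientation hits.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    uniref: list[HomologyHit] = []
    nr: list[HomologyHit] = []
    nucl: list[HomologyHit] = []

    def cds_portion(tid: str) -> tuple[str, int, int, int] | None:
        """(full_id, covered_cds_bp, cds_from_1, cds_to_1) on this transcript."""
        if tid in truth.orf_span:
            s, e, _ = truth.orf_span[tid]
            return tid, e - s + 1, s, e
        if tid in truth.fragment_of:
            full_id, off = truth.fragment_of[tid]
            if full_id not in truth.orf_span:
                return None
            s, e, _ = truth.orf_span[full_id]
            flen = by_id[tid].length_bp
            lo = max(s, off + 1)
            hi = min(e, off + flen)
            if hi - lo + 1 < 30:
                return None
            return full_id, hi - lo + 1, lo - off, hi - off
        return None

    for t in transcripts:
        tid = t.transcript_id
        label = truth.labels[tid]
        if label == "contamination":
            continue
        if label == "leakage_antisense":
            partner = truth.twin_of[tid]
            portion = cds_portion(partner)
            if portion is not None:
                full_id, cov, s, e = portion
                L = t.length_bp
                # CDS coordinates mirrored on the twin, minus orientation
                q_from, q_to = L - e + 1, L - s + 1
                s_len_aa = cov // 3
                for db, hits in (("uniref100", uniref), ("nr", nr)):
                    hits.append(_protein_hit(tid, L, f"{db[:2].upper()}_{full_id}",
                                             s_len_aa, s_len_aa, q_from, q_to, db, minus=True))
            # self-vs-self reversed full-length hit, both directions
            p = by_id[partner]
            for q, s in ((t, p), (p, t)):
                nucl.append(
                    HomologyHit(
                        query_id=q.transcript_id, subject_id=s.transcript_id,
                        evalue=1e-180, q_start=1, q_end=q.length_bp,
                        s_start=s.length_bp, s_end=1,
                        q_len=q.length_bp, s_len=s.length_bp,
                        db="nucl_self", bitscore=2.0 * q.length_bp,
                    )
                )
            continue
        portion = cds_portion(tid)
        if portion is None:
            continue
        full_id, cov, s, e = portion
        full_cds = truth.orf_span[full_id][1] - truth.orf_span[full_id][0] + 1
        s_len_aa = full_cds // 3
        cov_aa = max(1, cov // 3)
        for db, hits in (("uniref100", uniref), ("nr", nr)):
            hits.append(_protein_hit(tid, t.length_bp, f"{db[:2].upper()}_{full_id}",
                                     s_len_aa, cov_aa, s, e, db, minus=False))
    return uniref, nr, nucl


def simulate_two_pool_counts(
    cfg: SimConfig,
    transcripts: Sequence[TranscriptRecord],
    truth: TruthTables,
) -> tuple[dict[str, int], dict[str, int]]:
    """Two-pool read counts with a planted global log2 offset.

    Most transcripts are null (their expected log2 ratio equals
    ``de_offset``); a ``de_signal_fraction`` of them carry an extra
    per-transcript offset recorded in ``truth.de_offsets``.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    truth.de_global_offset = cfg.de_offset
    for t in transcripts:
        base = rng.lognormal(mean=math.log(cfg.de_mean_count), sigma=0.6)
        extra = 0.0
        if rng.random() < cfg.de_signal_fraction:
            extra = float(rng.normal(0.0, 3.0))
        truth.de_offsets[t.transcript_id] = extra
        delta = cfg.de_offset + extra
        lam_a = base * 2.0 ** (delta / 2.0)
        lam_b = base * 2.0 ** (-delta / 2.0)
        counts_a[t.transcript_id] = int(rng.poisson(lam_a))
        counts_b[t.transcript_id] = int(rng.poisson(lam_b))
    return counts_a, counts_b


def simulate_all(cfg: SimConfig, outdir: str | Path) -> TruthTables:
    """Generate the full artifact set under *outdir* (CLI entry point)."""
    from ssfilter.io_formats import write_fasta, write_report_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, truth = simulate_assembly(cfg)
    write_fasta(transcripts, outdir / "transcripts.fasta")
    simulate_pairs(cfg, transcripts, truth, outdir / "pairs.sam")
    uniref, nr, nucl = simulate_hits(cfg, transcripts, truth)
    write_blast_tab(uniref, outdir / "uniref_hits.tsv")
    write_blast_tab(nr, outdir / "nr_hits.tsv")
    write_blast_tab(nucl, outdir / "self_hits.tsv")
    counts_a, counts_b = simulate_two_pool_counts(cfg, transcripts, truth)
    write_report_tsv(
        ({"transcript_id": k, "count": v} for k, v in sorted(counts_a.items())),
        outdir / "counts_a.tsv", columns=["transcript_id", "count"],
    )
    write_report_tsv(
        ({"transcript_id": k, "count": v} for k, v in sorted(counts_b.items())),
        outdir / "counts_b.tsv", columns=["transcript_id", "count"],
    )
    write_report_tsv(
        ({"transcript_id": k, "label": v} for k, v in truth.labels.items()),
        outdir / "truth_labels.tsv", columns=["transcript_id", "label"],
    )
    write_report_tsv(
        ({"component_id": k, "transcript_id": v} for k, v in truth.representative.items()),
        outdir / "truth_representatives.tsv", columns=["component_id", "transcript_id"],
    )
    write_report_tsv(
        (
            {"transcript_id": k, "start": s, "end": e, "strand": st}
            for k, (s, e, st) in truth.orf_span.items()
        ),
        outdir / "truth_orfs.tsv", columns=["transcript_id", "start", "end", "strand"],
    )
    write_report_tsv(
        (asdict(s) for s in truth.snps),
        outdir / "truth_snps.tsv",
        columns=["transcript_id", "position_1based", "ref_base", "alt_base", "fraction"],
    )
    return truth
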