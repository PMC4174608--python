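"""The 19-metric weighted score and per-component representative selection.

Every metric is a bounded value in [-1, 1]; the aggregate is the
weight-weighted sum.  Normalizers phrased "in the component" (longest hit
length, longest transcript, max |SSLR|, max dips) are computed over the
transcripts of the same component that reached the scoring stage.
Missing evidence is neutral: a transcript with no hit gets 0 for that
database's metrics, one with no ORFs gets 0 for all B metrics, and every
0/0 is defined as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

from ssfilter.io_formats import DataError, HomologyHit, TranscriptRecord
from ssfilter.orf_calling import OrfCall

__all__ = [
    "ScoreWeights",
    "TranscriptEvidence",
    "ComponentContext",
    "ScoreBreakdown",
    "METRIC_NAMES",
    "score_transcript",
    "select_representatives",
    "lca_assign",
]

log = logging.getLogger(__name__)

METRIC_NAMES = tuple(
    [f"a{i}" for i in range(1, 13)] + [f"b{i}" for i in range(1, 7)] + ["c1"]
)


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the 19 metrics; defaults reproduce the published table."""

    a1: float = 10.0
    a2: float = 8.0
    a3: float = 7.0
    a4: float = 5.0
    a5: float = 4.0
    a6: float = 9.0
    a7: float = 7.0
    a8: float = 6.0
    a9: float = 4.0
    a10: float = 3.0
    a11: float = 7.0
    a12: float = 7.0
    b1: float = 10.0
    b2: float = 10.0
    b3: float = 8.0
    b4: float = 3.0
    b5: float = 8.0
    b6: float = 8.0
    c1: float = 10.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise DataError(f"weight {f.name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def from_overrides(cls, overrides: Mapping[str, float]) -> "ScoreWeights":
        unknown = set(overrides) - set(METRIC_NAMES)
        if unknown:
            raise DataError(f"unknown weight names: {sorted(unknown)}")
        return cls(**dict(overrides))


@dataclass
class TranscriptEvidence:
    """Everything score_transcript needs for one transcript."""

    first_uniref: HomologyHit | None = None
    first_nr: HomologyHit | None = None
    sslr: float = 0.0
    orfs: list[OrfCall] = field(default_factory=list)
    n_dips: int = 0


@dataclass
class ComponentContext:
    """Per-component maxima used as metric normalizers."""

    component_id: str
    longest_subject_hit_len: dict[str, int]
    longest_query_hit_len: dict[str, int]
    longest_transcript_len: int
    max_abs_sslr: float
    max_dips: int

    @classmethod
    def build(
        cls,
        component_id: str,
        members: Sequence[tuple[TranscriptRecord, TranscriptEvidence]],
    ) -> "ComponentContext":
        subj: dict[str, int] = {}
        qry: dict[str, int] = {}
        longest = 0
        max_sslr = 0.0
        max_dips = 0
        for rec, ev in members:
            longest = max(longest, rec.length_bp)
            max_sslr = max(max_sslr, abs(ev.sslr))
            max_dips = max(max_dips, ev.n_dips)
            for db, hit in (("uniref100", ev.first_uniref), ("nr", ev.first_nr)):
                if hit is not None:
                    subj[db] = max(subj.get(db, 0), hit.subject_covered)
                    qry[db] = max(qry.get(db, 0), hit.query_covered)
        return cls(component_id, subj, qry, longest, max_sslr, max_dips)


@dataclass
class ScoreBreakdown:
    transcript_id: str
    component_id: str
    metrics: dict[str, float]
    aggregate: float
    length_bp: int
    kept: bool = False
    reason: str = ""


def _div(num: float, den: float) -> float:
    return num / den if den else 0.0


def _hit_metrics(
    hit: HomologyHit | None,
    db: str,
    transcript_len: int,
    sslr: float,
    ctx: ComponentContext,
) -> tuple[float, float, float, float, float]:
    """The five per-database metrics (proportions, relative lengths, strand)."""
    if hit is None:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    m1 = _div(hit.subject_covered, hit.s_len)
    m2 = _div(hit.query_covered, transcript_len)
    m3 = _div(hit.subject_covered, ctx.longest_subject_hit_len.get(db, 0))
    m4 = _div(hit.query_covered, ctx.longest_query_hit_len.get(db, 0))
    sign = 1.0 if hit.query_strand == "plus" else -1.0
    m5 = sign * _div(-sslr, ctx.max_abs_sslr)
    return m1, m2, m3, m4, m5


def score_transcript(
    t: TranscriptRecord,
    evidence: TranscriptEvidence,
    ctx: ComponentContext,
    weights: ScoreWeights | None = None,
) -> ScoreBreakdown:
    """Evaluate the 19 metrics and the weighted aggregate for one transcript."""
    if ctx.component_id != t.component_id:
        raise DataError(
            f"context for component {ctx.component_id!r} used on {t.component_id!r}"
        )
    w = weights or ScoreWeights()
    m: dict[str, float] = {name: 0.0 for name in METRIC_NAMES}

    m["a1"], m["a2"], m["a3"], m["a4"], m["a5"] = _hit_metrics(
        evidence.first_uniref, "uniref100", t.length_bp, evidence.sslr, ctx
    )
    m["a6"], m["a7"], m["a8"], m["a9"], m["a10"] = _hit_metrics(
        evidence.first_nr, "nr", t.length_bp, evidence.sslr, ctx
    )
    m["a11"] = _div(-evidence.sslr, ctx.max_abs_sslr)
    m["a12"] = _div(t.length_bp, ctx.longest_transcript_len)

    orfs = evidence.orfs
    if orfs:
        best_subjects = {o.best_hit.subject_id for o in orfs if o.best_hit is not None}
        n_subj = len(best_subjects)
        m["b1"] = _div(1 - n_subj, n_subj)

        n_plus = sum(1 for o in orfs if o.strand == "plus")
        n_minus = len(orfs) - n_plus
        if n_plus and n_minus:
            ratio = -_div(min(n_plus, n_minus), max(n_plus, n_minus))
            plus_hit = any(o.best_hit is not None for o in orfs if o.strand == "plus")
            minus_hit = any(o.best_hit is not None for o in orfs if o.strand == "minus")
            if plus_hit and minus_hit:
                m["b2"] = ratio
            elif plus_hit or minus_hit:
                m["b3"] = ratio
            else:
                m["b4"] = ratio

        m["b5"] = _div(1 - len(orfs), len(orfs))
        orf_sign = 0.0 if (n_plus and n_minus) else (1.0 if n_plus else -1.0)
        m["b6"] = orf_sign * _div(-evidence.sslr, ctx.max_abs_sslr)

    m["c1"] = -_div(evidence.n_dips, ctx.max_dips)

    wd = w.as_dict()
    aggregate = sum(wd[k] * m[k] for k in METRIC_NAMES)
    return ScoreBreakdown(
        transcript_id=t.transcript_id,
        component_id=t.component_id,
        metrics=m,
        aggregate=aggregate,
        length_bp=t.length_bp,
    )


def select_representatives(
    scored: Mapping[str, Sequence[ScoreBreakdown]],
    min_score: float = 14.0,
) -> dict[str, ScoreBreakdown]:
    """Pick at most one transcript per component.

    The max-aggregate member wins (ties: longer transcript, then
    lexicographically smaller ID) and is kept only if its aggregate
    strictly exceeds *min_score*.  Marks ``kept``/``reason`` on every
    breakdown; returns the kept winner per component.
    """
    kept: dict[str, ScoreBreakdown] = {}
    for comp, breakdowns in scored.items():
        if not breakdowns:
            continue
        winner = sorted(
            breakdowns, key=lambda b: (-b.aggregate, -b.length_bp, b.transcript_id)
        )[0]
        for b in breakdowns:
            if b is winner:
                if b.aggregate > min_score:
                    b.kept, b.reason = True, "representative"
                    kept[comp] = b
                else:
                    b.kept, b.reason = False, "low_score"
            else:
                b.kept, b.reason = False, "not_best_in_component"
    return kept


def lca_assign(
    hits: Iterable[HomologyHit],
    parent: Mapping[str, str],
) -> str | None:
    """Lowest common ancestor of the taxa of all best-e-value hits.

    Hits with an e-value worse than the minimum are ignored; hits whose
    taxon is absent from the parent map are dropped with a warning.  The
    parent map is rooted: the root maps to itself (or has no entry).
    Returns ``None`` when no usable hit remains.
    """

    def lineage(taxon: str) -> list[str] | None:
        path = [taxon]
        seen = {taxon}
        node = taxon
        while node in parent and parent[node] != node:
            node = parent[node]
            if node in seen:
                raise DataError(f"cycle in taxonomy at {node!r}")
            seen.add(node)
            path.append(node)
        return path

    hits = [h for h in hits if h.subject_taxon is not None]
    if not hits:
        return None
    best_e = min(h.evalue for h in hits)
    taxa: list[str] = []
    for h in hits:
        if h.evalue != best_e:
            continue
        if h.subject_taxon not in parent and all(
            p != h.subject_taxon for p in parent.values()
        ):
            log.warning("taxon %r absent from parent map; hit dropped", h.subject_taxon)
            continue
        taxa.append(h.subject_taxon)
    if not taxa:
        return None
    paths = [lineage(t) for t in dict.fromkeys(taxa)]
    ancestor_sets = [set(p) for p in paths[1:]]
    for node in paths[0]:
        if all(node in s for s in ancestor_sets):
            return node
    return None
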