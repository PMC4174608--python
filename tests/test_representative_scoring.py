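import numpy as np
import pytest

from ssfilter.io_formats import DataError, HomologyHit, TranscriptRecord
from ssfilter.orf_calling import OrfCall
from ssfilter.representative_scoring import (
    ComponentContext,
    METRIC_NAMES,
    ScoreBreakdown,
    ScoreWeights,
    TranscriptEvidence,
    lca_assign,
    score_transcript,
    select_representatives,
)

from oracles import score_bruteforce


def _hit(db, q_start, q_end, s_start, s_end, q_len, s_len, subject="S", evalue=1e-50):
    return HomologyHit("t", subject, evalue, q_start, q_end, s_start, s_end, q_len, s_len, db=db)


def _ideal_bundle():
    """Both hits full coverage, single plus ORF, sslr = -max, 0 dips."""
    t = TranscriptRecord("comp1_c0_seq1", "comp1_c0", "A" * 900)
    orf = OrfCall("comp1_c0_seq1", 1, 900, "plus", 0)
    orf.best_hit = _hit("nr", 1, 900, 1, 300, 900, 300)
    ev = TranscriptEvidence(
        first_uniref=_hit("uniref100", 1, 900, 1, 300, 900, 300),
        first_nr=_hit("nr", 1, 900, 1, 300, 900, 300),
        sslr=-2.0,
        orfs=[orf],
        n_dips=0,
    )
    ctx = ComponentContext.build("comp1_c0", [(t, ev)])
    return t, ev, ctx


class TestWeights:
    def test_defaults_match_published_table(self):
        w = ScoreWeights().as_dict()
        assert [w[f"a{i}"] for i in range(1, 13)] == [10, 8, 7, 5, 4, 9, 7, 6, 4, 3, 7, 7]
        assert [w[f"b{i}"] for i in range(1, 7)] == [10, 10, 8, 3, 8, 8]
        assert w["c1"] == 10

    def test_override_subset(self):
        w = ScoreWeights.from_overrides({"a1": 0.0})
        assert w.a1 == 0.0 and w.a2 == 8.0

    def test_unknown_override_rejected(self):
        with pytest.raises(DataError):
            ScoreWeights.from_overrides({"zz": 1.0})

    def test_negative_weight_rejected(self):
        with pytest.raises(DataError):
            ScoreWeights(a1=-1.0)


class TestScoreTranscript:
    def test_ideal_transcript_scores_85(self):
        t, ev, ctx = _ideal_bundle()
        b = score_transcript(t, ev, ctx)
        for name in [f"a{i}" for i in range(1, 13)] + ["b6"]:
            assert b.metrics[name] == pytest.approx(1.0), name
        for name in ("b1", "b2", "b3", "b4", "b5", "c1"):
            assert b.metrics[name] == 0.0, name
        assert b.aggregate == pytest.approx(85.0)

    def test_hitless_orfless_best_scores_14(self):
        t = TranscriptRecord("comp1_c0_seq1", "comp1_c0", "A" * 900)
        ev = TranscriptEvidence(sslr=-2.0)
        ctx = ComponentContext.build("comp1_c0", [(t, ev)])
        b = score_transcript(t, ev, ctx)
        assert b.metrics["a11"] == 1.0 and b.metrics["a12"] == 1.0
        assert b.aggregate == pytest.approx(14.0)
        # and the strict >14 rule excludes it
        kept = select_representatives({"comp1_c0": [b]})
        assert kept == {} and b.reason == "low_score"

    def test_opposite_strand_orfs_with_nr_hits(self):
        t = TranscriptRecord("comp1_c0_seq1", "comp1_c0", "A" * 900)
        o1 = OrfCall("t", 1, 300, "plus", 0)
        o1.best_hit = _hit("nr", 1, 300, 1, 100, 900, 100, subject="S1")
        o2 = OrfCall("t", 400, 699, "minus", 0)
        o2.best_hit = _hit("nr", 699, 400, 1, 100, 900, 100, subject="S2")
        ev = TranscriptEvidence(sslr=0.0, orfs=[o1, o2])
        ctx = ComponentContext.build("comp1_c0", [(t, ev)])
        b = score_transcript(t, ev, ctx)
        # b2 x (-1) = -10 and b1 x ((1-2)/2) = -5
        assert b.metrics["b2"] == -1.0
        assert b.metrics["b1"] == -0.5
        assert b.metrics["b3"] == 0.0 and b.metrics["b4"] == 0.0

    def test_context_component_mismatch_is_error(self):
        t, ev, _ = _ideal_bundle()
        ctx = ComponentContext("other_c0", {}, {}, 900, 2.0, 0)
        with pytest.raises(DataError):
            score_transcript(t, ev, ctx)

    def test_no_hits_neutral(self):
        t = TranscriptRecord("comp1_c0_seq1", "comp1_c0", "A" * 100)
        ev = TranscriptEvidence(sslr=0.0)
        ctx = ComponentContext.build("comp1_c0", [(t, ev)])
        b = score_transcript(t, ev, ctx)
        # only a12 can be nonzero (max_abs_sslr is 0 -> a11 guarded to 0)
        assert b.aggregate == pytest.approx(7.0)

    def test_monotone_in_uniref_subject_coverage(self):
        t = TranscriptRecord("comp1_c0_seq1", "comp1_c0", "A" * 900)
        prev = None
        for cov in (50, 100, 200, 300):
            ev = TranscriptEvidence(
                first_uniref=_hit("uniref100", 1, 900, 1, cov, 900, 300),
                sslr=-1.0,
            )
            ctx = ComponentContext.build("comp1_c0", [(t, ev)])
            # hold normalizers fixed so only the proportion changes
            ctx.longest_subject_hit_len["uniref100"] = 300
            ctx.longest_query_hit_len["uniref100"] = 900
            agg = score_transcript(t, ev, ctx).aggregate
            if prev is not None:
                assert agg >= prev
            prev = agg


def _random_bundle(rng):
    comp = "comp1_c0"
    length = int(rng.integers(200, 3000))
    t = TranscriptRecord("comp1_c0_seq1", comp, "A" * length)
    ev = TranscriptEvidence(sslr=float(rng.normal(0, 3)), n_dips=int(rng.integers(0, 4)))
    for db in ("uniref100", "nr"):
        if rng.random() < 0.8:
            s_len = int(rng.integers(50, 800))
            scov = int(rng.integers(1, s_len + 1))
            qcov = int(rng.integers(1, length + 1))
            q0 = int(rng.integers(1, length - qcov + 2))
            minus = rng.random() < 0.5
            hit = HomologyHit(
                "t", f"S{int(rng.integers(0, 5))}", 10.0 ** -int(rng.integers(10, 100)),
                q0 + qcov - 1 if minus else q0, q0 if minus else q0 + qcov - 1,
                1, scov, length, s_len, db=db,
            )
            if db == "uniref100":
                ev.first_uniref = hit
            else:
                ev.first_nr = hit
    for _ in range(int(rng.integers(0, 4))):
        s = int(rng.integers(1, max(2, length - 100)))
        e = min(length, s + int(rng.integers(59, 400)))
        o = OrfCall("t", s, e, "plus" if rng.random() < 0.5 else "minus", 0)
        if rng.random() < 0.6:
            o.best_hit = _hit("nr", s, e, 1, 50, length, 60, subject=f"S{int(rng.integers(0, 5))}")
        ev.orfs.append(o)
    # random co-members so normalizers vary
    members = [(t, ev)]
    for k in range(int(rng.integers(0, 3))):
        t2 = TranscriptRecord(f"comp1_c0_seq{k + 2}", comp, "A" * int(rng.integers(200, 3000)))
        ev2 = TranscriptEvidence(sslr=float(rng.normal(0, 3)), n_dips=int(rng.integers(0, 4)))
        members.append((t2, ev2))
    ctx = ComponentContext.build(comp, members)
    return t, ev, ctx


def test_oracle_equivalence_on_random_bundles():
    rng = np.random.default_rng(99)
    w = ScoreWeights()
    for _ in range(200):
        t, ev, ctx = _random_bundle(rng)
        got = score_transcript(t, ev, ctx, w).aggregate
        want = score_bruteforce(t, ev, ctx, w)
        assert got == pytest.approx(want, abs=1e-9)


def test_aggregate_bounded_by_85():
    rng = np.random.default_rng(123)
    for _ in range(300):
        t, ev, ctx = _random_bundle(rng)
        assert score_transcript(t, ev, ctx).aggregate <= 85.0 + 1e-9


class TestSelectRepresentatives:
    def _bd(self, tid, comp, agg, length):
        return ScoreBreakdown(tid, comp, {}, agg, length)

    def test_argmax_kept(self):
        a = self._bd("t1", "c", 85.0, 900)
        b = self._bd("t2", "c", 40.0, 900)
        kept = select_representatives({"c": [a, b]})
        assert kept["c"] is a and a.kept and not b.kept

    def test_exactly_14_excluded(self):
        a = self._bd("t1", "c", 14.0, 900)
        assert select_representatives({"c": [a]}) == {}

    def test_tie_broken_by_length(self):
        a = self._bd("t1", "c", 30.0, 900)
        b = self._bd("t2", "c", 30.0, 1200)
        assert select_representatives({"c": [a, b]})["c"] is b

    def test_tie_broken_by_id(self):
        a = self._bd("t2", "c", 30.0, 900)
        b = self._bd("t1", "c", 30.0, 900)
        assert select_representatives({"c": [a, b]})["c"] is b

    def test_stable_under_permutation(self):
        rng = np.random.default_rng(8)
        bds = [self._bd(f"t{i}", "c", float(rng.integers(10, 80)), 500 + i) for i in range(6)]
        base = select_representatives({"c": list(bds)})["c"].transcript_id
        for _ in range(5):
            rng.shuffle(bds)
            assert select_representatives({"c": list(bds)})["c"].transcript_id == base

    def test_at_most_one_per_component(self):
        bds = {
            "c1": [self._bd("a", "c1", 50.0, 1), self._bd("b", "c1", 60.0, 1)],
            "c2": [self._bd("c", "c2", 5.0, 1)],
        }
        kept = select_representatives(bds)
        assert set(kept) == {"c1"}


TAXO = {
    "root": "root",
    "Bacteria": "root",
    "Eukaryota": "root",
    "G": "Eukaryota",
    "sp_x": "G",
    "sp_y": "G",
    "E_coli": "Bacteria",
}


def _tax_hit(subject, taxon, evalue):
    return HomologyHit("q", subject, evalue, 1, 10, 1, 10, 100, 100, subject_taxon=taxon)


class TestLcaAssign:
    def test_single_best_hit(self):
        assert lca_assign([_tax_hit("s1", "sp_x", 1e-50)], TAXO) == "sp_x"

    def test_sibling_species_collapse_to_genus(self):
        # path-intersection on the toy tree: sp_x and sp_y meet at G
        hits = [_tax_hit("s1", "sp_x", 1e-50), _tax_hit("s2", "sp_y", 1e-50)]
        assert lca_assign(hits, TAXO) == "G"

    def test_disjoint_kingdoms_hit_root(self):
        hits = [_tax_hit("s1", "sp_x", 1e-50), _tax_hit("s2", "E_coli", 1e-50)]
        assert lca_assign(hits, TAXO) == "root"

    def test_worse_evalue_ignored(self):
        hits = [_tax_hit("s1", "sp_x", 1e-50), _tax_hit("s2", "E_coli", 1e-40)]
        assert lca_assign(hits, TAXO) == "sp_x"

    def test_unknown_taxon_dropped(self):
        hits = [_tax_hit("s1", "martian", 1e-50), _tax_hit("s2", "sp_x", 1e-50)]
        assert lca_assign(hits, TAXO) == "sp_x"

    def test_all_dropped_unassigned(self):
        assert lca_assign([_tax_hit("s1", "martian", 1e-50)], TAXO) is None
        assert lca_assign([], TAXO) is None
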