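import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virotriage.io_formats import AlignmentRecord, Contig
from virotriage.triage import (
    CATEGORIES,
    TriageThresholds,
    best_hsp_per_pair,
    classify_contig,
    hit_category,
    hit_metrics,
    length_filter,
    tally_known_viruses,
)

from _oracles import triage_region_oracle


def _rec(qacc="q", sacc="s", pident=90.0, align_len=1000, evalue=1e-20,
         bitscore=100.0, qlen=1000):
    return AlignmentRecord(qacc, sacc, pident, align_len, evalue, bitscore, qlen)


def _contig(cid, length):
    return Contig(cid, "A" * length)


class TestLengthFilter:
    def test_one_kb_boundary_is_inclusive(self):
        contigs = [_contig("a", 999), _contig("b", 1000), _contig("c", 5000)]
        assert [c.id for c in length_filter(contigs)] == ["b", "c"]

    def test_empty_input(self):
        assert length_filter([]) == []

    def test_noop_when_all_long_preserves_order(self):
        contigs = [_contig("z", 2000), _contig("a", 3000)]
        assert length_filter(contigs) == contigs


class TestHitMetrics:
    @pytest.mark.parametrize(
        "pident,align_len,qlen,ani,cov",
        [
            (90.0, 1000, 1000, 0.9, 1.0),
            (100.0, 500, 1000, 0.5, 0.5),
            (0.0, 800, 1000, 0.0, 0.8),
        ],
    )
    def test_formulas(self, pident, align_len, qlen, ani, cov):
        rec = _rec(pident=pident, align_len=align_len, qlen=qlen)
        assert hit_metrics(rec) == (ani, cov)

    def test_gapped_alignment_coverage_can_exceed_one(self):
        ani, cov = hit_metrics(_rec(pident=80.0, align_len=1200, qlen=1000))
        assert cov == 1.2
        assert ani == 0.96


class TestBestHspPerPair:
    def test_highest_bitscore_wins(self):
        low = _rec(bitscore=50.0)
        high = _rec(bitscore=100.0)
        assert best_hsp_per_pair([low, high]) == [high]

    def test_unique_pairs_unchanged(self):
        recs = [_rec(sacc="s1"), _rec(sacc="s2")]
        assert best_hsp_per_pair(recs) == recs

    def test_tie_breaks_by_evalue_then_first_occurrence(self):
        first = _rec(evalue=1e-10)
        better_e = _rec(evalue=1e-20)
        assert best_hsp_per_pair([first, better_e]) == [better_e]
        same = _rec(evalue=1e-10)
        assert best_hsp_per_pair([first, same])[0] is first

    @given(st.lists(st.tuples(st.sampled_from("ab"), st.sampled_from("xy"),
                              st.floats(1, 500)), max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_exactly_one_record_per_pair(self, triples):
        recs = [_rec(qacc=q, sacc=s, bitscore=b) for q, s, b in triples]
        reduced = best_hsp_per_pair(recs)
        pairs = [(r.qacc, r.sacc) for r in reduced]
        assert len(pairs) == len(set(pairs)) == len({(r.qacc, r.sacc) for r in recs})


class TestHitCategory:
    @pytest.mark.parametrize(
        "ani,cov,expected",
        [
            (0.90, 0.85, "known_known"),
            (0.90, 0.60, "known_unknown_1"),
            (0.60, 0.90, "known_unknown_2"),
            (0.30, 0.30, None),
            # boundary mass falls downward: thresholds strict as printed
            (0.85, 0.9, "known_unknown_2"),  # ani exactly at the kk bound
        ],
    )
    def test_examples(self, ani, cov, expected):
        assert hit_category(ani, cov, TriageThresholds()) == expected

    def test_coverage_exactly_point_eight_is_known_unknown_1(self):
        assert hit_category(0.9, 0.8, TriageThresholds()) == "known_unknown_1"


class TestClassifyContig:
    @pytest.mark.parametrize(
        "ani,cov,expected",
        [
            (0.90, 0.95, "known_known"),
            (0.60, 0.90, "known_unknown_2"),
            (0.30, 0.90, "unknown_unknown"),
        ],
    )
    def test_single_hit_categories(self, ani, cov, expected):
        # realize (ani, cov) through a record: pident = 100*ani/cov
        qlen = 1000
        rec = _rec(pident=100.0 * ani / cov, align_len=int(cov * qlen), qlen=qlen)
        assert classify_contig("c", [rec]).category == expected

    def test_no_hits_is_unknown_unknown_with_no_best_subject(self):
        res = classify_contig("c", [])
        assert res.category == "unknown_unknown"
        assert res.best_sacc is None
        assert res.ani is None

    def test_hits_above_evalue_cutoff_ignored(self):
        rec = _rec(evalue=0.01)  # above default 1e-3
        res = classify_contig("c", [rec])
        assert res.category == "unknown_unknown"
        assert res.best_sacc is None

    def test_strict_all_vs_all_cutoff_configurable(self):
        th = TriageThresholds(max_evalue=1e-10)
        rec = _rec(evalue=1e-5)
        assert classify_contig("c", [rec], th).best_sacc is None

    def test_best_category_over_hits_wins(self):
        ku2 = _rec(sacc="weak", pident=70.0, align_len=900, bitscore=500.0)
        kk = _rec(sacc="strong", pident=95.0, align_len=1000, bitscore=400.0)
        res = classify_contig("c", [ku2, kk])
        assert res.category == "known_known"
        assert res.best_sacc == "strong"

    def test_nonqualifying_hit_still_reported_as_best_subject(self):
        rec = _rec(sacc="far", pident=20.0)
        res = classify_contig("c", [rec])
        assert res.category == "unknown_unknown"
        assert res.best_sacc == "far"

    @given(
        ani=st.floats(0, 1), cov=st.floats(0.05, 1.2),
        bump_ani=st.floats(0, 0.2), bump_cov=st.floats(0, 0.2),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_monotonicity_raising_ani_or_coverage_never_demotes(
        self, ani, cov, bump_ani, bump_cov
    ):
        th = TriageThresholds()
        rank = {c: i for i, c in enumerate(CATEGORIES)}
        base = hit_category(ani, cov, th) or "unknown_unknown"
        # raising ani at fixed coverage
        better = hit_category(min(ani + bump_ani, cov), cov, th) or "unknown_unknown"
        if min(ani + bump_ani, cov) >= ani:
            assert rank[better] <= rank[base]

    def test_categories_partition_every_grid_point(self):
        th = TriageThresholds()
        grid = [round(0.05 * i, 2) for i in range(25)]
        for ani in grid:
            for cov in grid:
                got = hit_category(ani, cov, th) or "unknown_unknown"
                assert got in CATEGORIES


class TestTallyKnownViruses:
    def _results(self):
        from virotriage.triage import TriageResult

        return [
            TriageResult("c1", "known_known", "A", 0.9, 0.9),
            TriageResult("c2", "known_known", "A", 0.9, 0.9),
            TriageResult("c3", "known_known", "B", 0.9, 0.9),
            TriageResult("c4", "unknown_unknown"),
        ]

    def test_counts_known_knowns_only(self):
        assert tally_known_viruses(self._results()) == [("A", 2), ("B", 1)]

    def test_all_unknown_gives_empty(self):
        from virotriage.triage import TriageResult

        assert tally_known_viruses([TriageResult("c", "unknown_unknown")]) == []

    def test_ties_sorted_by_subject_id(self):
        from virotriage.triage import TriageResult

        results = [
            TriageResult(f"c{i}", "known_known", s, 0.9, 0.9)
            for i, s in enumerate("edcba")
        ]
        assert tally_known_viruses(results) == [(s, 1) for s in "abcde"]


class TestRegionOracleAgreement:
    def test_hit_category_matches_independent_oracle_on_grid(self):
        """Spot version of the full acceptance grid comparison."""
        th = TriageThresholds()
        for i in range(25):
            for j in range(25):
                ani, cov = 0.05 * i, 0.05 * j
                got = hit_category(ani, cov, th) or "unknown_unknown"
                assert got == triage_region_oracle(ani, cov), (ani, cov)
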