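import numpy as np
import pytest

from virotriage.io_formats import Contig
from virotriage.kmer_taxonomy import (
    KmerIndex,
    Taxonomy,
    build_index,
    canonical_kmer,
    classify_sequence,
    lca,
    read_index,
    reverse_complement,
    select_references,
    write_index,
)
from virotriage.synthetic import mutate_contig, random_sequence, simulate_taxonomy

from _oracles import lca_oracle


class TestTaxonomy:
    def test_rejects_missing_root(self):
        with pytest.raises(ValueError):
            Taxonomy.from_nodes({2: (1, "x", "x")})

    def test_rejects_cycle(self):
        nodes = {1: (1, "root", "r"), 2: (3, "a", "a"), 3: (2, "b", "b")}
        with pytest.raises(ValueError):
            Taxonomy.from_nodes(nodes)

    def test_leaves(self, small_taxonomy):
        assert small_taxonomy.leaves() == [100, 101, 102]


class TestLca:
    def test_identity(self, small_taxonomy):
        assert lca(small_taxonomy, 101, 101) == 101

    def test_siblings_under_genus(self, small_taxonomy):
        assert lca(small_taxonomy, 100, 101) == 10

    def test_cross_genus_resolves_to_root(self, small_taxonomy):
        assert lca(small_taxonomy, 100, 102) == 1

    def test_ancestor_of_descendant(self, small_taxonomy):
        assert lca(small_taxonomy, 10, 101) == 10

    def test_unknown_taxid_raises(self, small_taxonomy):
        with pytest.raises(KeyError):
            lca(small_taxonomy, 999, 100)

    def test_agrees_with_brute_force_on_all_pairs(self, small_taxonomy):
        nodes = small_taxonomy.nodes
        for a in nodes:
            for b in nodes:
                assert lca(small_taxonomy, a, b) == lca_oracle(
                    nodes, small_taxonomy.root, a, b
                )


class TestBuildIndex:
    def test_private_kmer_maps_to_its_reference_taxid(self, small_taxonomy):
        seq = random_sequence(100, np.random.default_rng(0))
        index = build_index([(Contig("r", seq), 100)], small_taxonomy, k=32)
        assert set(index.entries.values()) == {100}

    def test_shared_kmer_maps_to_sibling_parent(self, small_taxonomy):
        shared = random_sequence(32, np.random.default_rng(1))
        a = shared + random_sequence(40, np.random.default_rng(2))
        b = shared + random_sequence(40, np.random.default_rng(3))
        index = build_index(
            [(Contig("a", a), 100), (Contig("b", b), 101)], small_taxonomy, k=32
        )
        assert index.entries[canonical_kmer(shared)] == 10  # MRCA of the siblings

    def test_reference_shorter_than_k_contributes_nothing(self, small_taxonomy):
        index = build_index([(Contig("tiny", "A" * 31), 100)], small_taxonomy, k=32)
        assert index.entries == {}

    def test_ambiguous_bases_skipped(self, small_taxonomy):
        seq = "A" * 20 + "N" + "C" * 20  # every 32-mer crosses the N
        index = build_index([(Contig("r", seq), 100)], small_taxonomy, k=32)
        assert index.entries == {}

    def test_unknown_taxid_raises(self, small_taxonomy):
        with pytest.raises(KeyError):
            build_index([(Contig("r", "A" * 40), 999)], small_taxonomy)

    def test_sampling_stride_reduces_entries(self, small_taxonomy):
        seq = random_sequence(500, np.random.default_rng(4))
        full = build_index([(Contig("r", seq), 100)], small_taxonomy, k=32)
        strided = build_index(
            [(Contig("r", seq), 100)], small_taxonomy, k=32, sampling_stride=10
        )
        assert 0 < len(strided.entries) < len(full.entries)

    def test_every_entry_is_ancestor_or_self_of_all_sources(self, small_taxonomy):
        """Brute-force check of the MRCA invariant on a shared+private mix."""
        rng = np.random.default_rng(5)
        core = random_sequence(60, rng)
        refs = [
            (Contig("a", core + random_sequence(50, rng)), 100),
            (Contig("b", core + random_sequence(50, rng)), 101),
            (Contig("c", random_sequence(110, rng)), 102),
        ]
        index = build_index(refs, small_taxonomy, k=32)
        for kmer, assigned in index.entries.items():
            sources = [
                taxid for contig, taxid in refs
                if any(
                    canonical_kmer(contig.sequence[i : i + 32]) == kmer
                    for i in range(len(contig.sequence) - 31)
                )
            ]
            assert sources
            for taxid in sources:
                assert assigned in small_taxonomy.path_to_root(taxid)


class TestClassifySequence:
    def _index_for(self, taxonomy, assignments: dict[str, int], k: int = 32):
        return KmerIndex(k=k, entries={canonical_kmer(m): t for m, t in assignments.items()})

    def test_all_kmers_on_one_leaf_gives_probability_one(self, small_taxonomy):
        rng = np.random.default_rng(6)
        seq = random_sequence(80, rng)
        index = build_index([(Contig("r", seq), 100)], small_taxonomy, k=32)
        call = classify_sequence(index, small_taxonomy, Contig("q", seq))
        assert call.best_taxid == 100
        assert call.probability == 1.0
        assert call.total_indexed_kmers == len(seq) - 31

    def test_tie_between_sibling_leaves_resolves_to_parent(self, small_taxonomy):
        rng = np.random.default_rng(7)
        k1 = random_sequence(32, rng)
        k2 = random_sequence(32, rng)
        index = self._index_for(small_taxonomy, {k1: 100, k2: 101})
        contig = Contig("q", k1 + k2)  # junction k-mers miss the index
        call = classify_sequence(index, small_taxonomy, contig, min_probability=0.1)
        assert call.best_taxid == 10
        assert call.probability == 0.5

    def test_no_indexed_kmers_is_unclassified(self, small_taxonomy):
        index = self._index_for(small_taxonomy, {})
        call = classify_sequence(index, small_taxonomy, Contig("q", "A" * 50))
        assert call.best_taxid is None
        assert call.total_indexed_kmers == 0
        assert call.probability == 0.0

    def test_below_min_probability_reported_unclassified(self, small_taxonomy):
        rng = np.random.default_rng(8)
        kmers = {random_sequence(32, rng): t for t in (100, 101, 102)}
        index = self._index_for(small_taxonomy, kmers)
        contig = Contig("q", "".join(kmers))
        call = classify_sequence(index, small_taxonomy, contig, min_probability=0.9)
        assert call.best_taxid is None
        assert call.path_scores  # scores still returned

    def test_invariant_under_reverse_complement(self, small_taxonomy):
        rng = np.random.default_rng(9)
        seq = random_sequence(120, rng)
        index = build_index([(Contig("r", seq), 100)], small_taxonomy, k=32)
        fwd = classify_sequence(index, small_taxonomy, Contig("q", seq))
        rev = classify_sequence(
            index, small_taxonomy, Contig("q", reverse_complement(seq))
        )
        assert (fwd.best_taxid, fwd.probability, fwd.total_indexed_kmers) == (
            rev.best_taxid, rev.probability, rev.total_indexed_kmers
        )

    def test_max_leaf_path_score_equals_reported_probability(self, small_taxonomy):
        rng = np.random.default_rng(10)
        seq = random_sequence(200, rng)
        refs = [(Contig("a", seq[:120]), 100), (Contig("b", seq[60:]), 101)]
        index = build_index(refs, small_taxonomy, k=32)
        call = classify_sequence(index, small_taxonomy, Contig("q", seq))
        leaf_scores = [
            s for t, s in call.path_scores.items() if t in (100, 101, 102)
        ]
        assert max(leaf_scores) / call.total_indexed_kmers == call.probability
        assert all(s <= call.total_indexed_kmers for s in leaf_scores)

    def test_mutated_contig_recovers_source_leaf(self):
        """1% point mutation: the call is the source species leaf."""
        taxonomy, refs = simulate_taxonomy(6, seed=3, ref_length=5000)
        index = build_index(refs, taxonomy, k=32)
        rng = np.random.default_rng(12)
        for trial in range(20):
            ref, taxid = refs[trial % len(refs)]
            contig, _ = mutate_contig(
                ref, 0.99, 0.2, seed=int(rng.integers(0, 2**31)), contig_id="q"
            )
            call = classify_sequence(index, taxonomy, contig)
            assert call.best_taxid == taxid


class TestSelectReferences:
    def _contig(self, n, length=300, seed=0):
        return Contig(f"c{n}", random_sequence(length, np.random.default_rng(seed + n)))

    def test_sample_exceeding_population_keeps_all(self):
        refs = [(self._contig(i), 100, False) for i in range(2)]
        assert len(select_references(refs, n_per_species=3, seed=1)) == 2

    def test_segmented_exact_duplicates_deduplicated(self):
        c = self._contig(0, length=500)
        refs = [(c, 100, True), (Contig("c1", c.sequence), 100, True)]
        kept = select_references(refs, seed=1)
        assert len(kept) == 1

    def test_segmented_distinct_sequences_kept(self):
        refs = [(self._contig(i, length=500, seed=50) , 100, True) for i in range(2)]
        refs[1] = (self._contig(1, length=500, seed=99), 100, True)
        kept = select_references(refs, dedup_distance=0.05, seed=1)
        assert len(kept) == 2

    def test_seeded_sampling_is_deterministic(self):
        refs = [(self._contig(i), 100, False) for i in range(10)]
        a = select_references(refs, n_per_species=3, seed=42)
        b = select_references(refs, n_per_species=3, seed=42)
        assert [c.id for c, _ in a] == [c.id for c, _ in b]
        assert len(a) == 3


class TestIndexSerialization:
    def test_roundtrip(self, small_taxonomy, tmp_path):
        seq = random_sequence(100, np.random.default_rng(13))
        index = build_index([(Contig("r", seq), 100)], small_taxonomy, k=32,
                            sampling_stride=2)
        p = tmp_path / "index.tsv"
        write_index(index, p)
        back = read_index(p)
        assert back.entries == index.entries
        assert (back.k, back.sampling_stride) == (32, 2)
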