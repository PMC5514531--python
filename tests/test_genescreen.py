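"""20-mer indexing, greedy read assignment, category binning, Fisher test."""

import math

import pytest

from strainsieve import (Thresholds, assign_read, assign_read_pair,
                         bin_categories, build_index, canonical_kmers,
                         compare_category_presence, reverse_complement,
                         simulate_gene_db, simulate_gene_reads)
from strainsieve.genescreen import CategoryTable


class TestIndex:
    def test_kmer_counts_by_length(self):
        idx = build_index([("g20", "A" * 10 + "C" * 10), ("g100", "ACGT" * 25)])
        assert len(canonical_kmers("A" * 10 + "C" * 10, 20)) == 1
        # L - k + 1 = 81 k-mers before dedup; dedup may shrink
        assert len(idx.kmers["g100"]) <= 81

    def test_reverse_complement_gene_same_kmers(self):
        genes, _ = simulate_gene_db(1, 200, seed=1)
        gid, seq = genes[0]
        idx = build_index([(gid, seq), ("rc", reverse_complement(seq))])
        assert idx.kmers[gid] == idx.kmers["rc"]

    def test_short_gene_excluded_with_warning(self):
        idx = build_index([("tiny", "ACGTACGT")])
        assert "tiny" not in idx.kmers

    def test_duplicate_ids_rejected(self):
        with pytest.raises(Exception):
            build_index([("g", "A" * 30), ("g", "C" * 30)])

    def test_n_containing_kmers_skipped(self):
        assert canonical_kmers("A" * 19 + "N" + "C" * 19, 20) == frozenset()


@pytest.fixture(scope="module")
def index():
    genes, catmap = simulate_gene_db(6, 400, seed=7)
    return build_index(genes, catmap), genes


class TestAssignment:

    def test_exact_substring_fully_matches(self, index, thresholds):
        idx, genes = index
        gid, seq = genes[0]
        a = assign_read(("r", seq[50:250]), idx, thresholds)
        assert a.gene_id == gid and a.matched_fraction == 1.0

    def test_strand_invariance(self, index, thresholds):
        idx, genes = index
        read = genes[2][1][10:170]
        a1 = assign_read(("f", read), idx, thresholds)
        a2 = assign_read(("r", reverse_complement(read)), idx, thresholds)
        assert (a1.gene_id, a1.matched_fraction) == (a2.gene_id, a2.matched_fraction)

    def test_low_identity_read_unassigned(self, index, thresholds):
        idx, genes = index
        reads = simulate_gene_reads(genes, identity=0.85, n_reads=30,
                                    read_length=200, seed=3)
        fracs = [assign_read(("r", r.seq), idx, thresholds).matched_fraction
                 for r in reads]
        # at 85% identity k-mer survival is ~0.85^20 ~= 3.9%, far below 90%
        assert all(f < 0.9 for f in fracs)

    def test_short_read_unassigned_with_reason(self, index, thresholds):
        idx, _ = index
        a = assign_read(("r", "ACGTACGT"), idx, thresholds)
        assert a.gene_id is None and "shorter" in a.reason

    def test_tie_breaks_to_lexicographically_smaller_gene(self, thresholds):
        seq = "ACGTAGCTAGGATCCTAGCATCGATCGGATATC"
        idx = build_index([("geneB", seq), ("geneA", seq)])
        a = assign_read(("r", seq[:25]), idx, thresholds)
        assert a.gene_id == "geneA"

    def test_paired_reads_scored_jointly(self, index, thresholds):
        idx, genes = index
        gid, seq = genes[1]
        a = assign_read_pair("p", seq[:120], reverse_complement(seq[200:320]),
                             idx, thresholds)
        assert a.gene_id == gid
        assert a.n_query_kmers > len(canonical_kmers(seq[:120], 20))

    def test_true_source_is_best_match_at_95_identity(self, index, thresholds):
        # 10 substitutions in a 200 bp read disrupt most overlapping 20-mers
        # (expected survival ~(190/200 choose ...) ~ 36%), so such reads fall
        # below the 90% matching requirement — but the true source gene must
        # still be the top-scoring candidate for essentially every read.
        idx, genes = index
        reads = simulate_gene_reads(genes, identity=0.95, n_reads=300,
                                    read_length=200, seed=11)
        top_correct = 0
        for r in reads:
            fracs = {g: len(canonical_kmers(r.seq, 20) & k) / max(
                len(canonical_kmers(r.seq, 20)), 1) for g, k in idx.kmers.items()}
            top_correct += max(fracs, key=fracs.get) == r.source_gene
        assert top_correct / len(reads) >= 0.99

    def test_fully_matching_reads_always_assigned(self, index, thresholds):
        idx, genes = index
        reads = simulate_gene_reads(genes, identity=1.0, n_reads=200,
                                    read_length=200, seed=12)
        for r in reads:
            a = assign_read((r.read_id, r.seq), idx, thresholds)
            assert a.gene_id == r.source_gene and a.matched_fraction == 1.0


class TestCategories:
    def test_counts_accumulate_per_category(self, thresholds):
        genes, _ = simulate_gene_db(2, 100, seed=1)
        idx = build_index(genes, {"gene001": ("beta_lactam",)})
        reads = [("r%d" % i, genes[0][1][:40]) for i in range(10)]
        assignments = [assign_read(r, idx, thresholds) for r in reads]
        table = bin_categories(assignments, idx)
        assert table.counts["beta_lactam"] == 10
        assert table.genes["beta_lactam"] == {"gene001"}

    def test_gene_in_two_categories_double_binned(self, thresholds):
        genes, _ = simulate_gene_db(1, 100, seed=2)
        idx = build_index(genes, {"gene001": ("efflux_pump", "beta_lactam")})
        assignments = [assign_read(("r%d" % i, genes[0][1][10:70]), idx, thresholds)
                       for i in range(5)]
        table = bin_categories(assignments, idx)
        assert table.counts == {"efflux_pump": 5, "beta_lactam": 5}

    def test_unmapped_gene_is_uncategorized(self, thresholds):
        genes, _ = simulate_gene_db(1, 100, seed=3)
        idx = build_index(genes, {})
        a = assign_read(("r", genes[0][1][:50]), idx, thresholds)
        table = bin_categories([a], idx)
        assert table.counts == {"uncategorized": 1}

    def test_no_assignments_empty_table(self):
        genes, _ = simulate_gene_db(1, 100, seed=4)
        idx = build_index(genes)
        assert bin_categories([], idx).counts == {}


class TestFisher:
    def _table(self, sample, cats):
        t = CategoryTable(sample_id=sample)
        t.counts = {c: 1 for c in cats}
        return t

    def test_identical_patterns_p_one(self):
        a = self._table("a", ["x", "y", "z"])
        b = self._table("b", ["x", "y", "z"])
        assert compare_category_presence(a, b) == pytest.approx(1.0)

    def test_complete_split_matches_hypergeometric_enumeration(self):
        # a detects all 10 union categories, b none -> 2x2 [[10,0],[0,10]];
        # exactly 2 of C(20,10) tables are as extreme under the null
        cats = [f"c{i}" for i in range(10)]
        a = self._table("a", cats)
        b = self._table("b", [])
        b.counts = {c: 0 for c in cats}
        p = compare_category_presence(a, b)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_symmetric_in_sample_order(self):
        a = self._table("a", ["x", "y"])
        a.counts["w"] = 0
        b = self._table("b", ["x"])
        b.counts.update({"y": 0, "w": 0})
        assert compare_category_presence(a, b) == pytest.approx(
            compare_category_presence(b, a))

    def test_empty_union_rejected(self):
        with pytest.raises(Exception):
            compare_category_presence(CategoryTable("a"), CategoryTable("b"))
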