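"""Engine unit and property tests: profiles, distances, length matching,
candidate pruning and the ortholog search itself."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdsortho import (
    GeneSet,
    MatchParams,
    candidate_scan,
    dinucleotide_profile,
    find_orthologs,
    find_orthologs_combined,
    gene_distance,
    match_lengths,
    profile_distance,
)

from _reference import exhaustive_match, naive_profile, naive_tv
from conftest import make_gene, random_gene_set

dna = st.text(alphabet="ACGT", min_size=2, max_size=60)
dna_n = st.text(alphabet="ACGTN", min_size=0, max_size=60)


class TestDinucleotideProfile:
    @pytest.mark.parametrize(
        "exon,expected",
        [
            ("AAAA", {"AA": 1.0}),
            ("ACGT", {"AC": 1 / 3, "CG": 1 / 3, "GT": 1 / 3}),
        ],
    )
    def test_known_profiles(self, exon, expected):
        order = [a + b for a in "ACGT" for b in "ACGT"]
        profile = dinucleotide_profile(exon)
        for k, d in enumerate(order):
            assert profile[k] == pytest.approx(expected.get(d, 0.0))

    @pytest.mark.parametrize("exon", ["ANA", "A", "", "NNNN"])
    def test_degenerate_exons_give_all_zero(self, exon):
        assert not dinucleotide_profile(exon).any()

    @given(dna_n)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_substring_counting_oracle(self, exon):
        np.testing.assert_allclose(
            dinucleotide_profile(exon), naive_profile(exon), atol=1e-12
        )

    @given(dna)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_profiles_sum_to_one(self, exon):
        assert dinucleotide_profile(exon).sum() == pytest.approx(1.0)


class TestProfileDistance:
    def test_identical_profiles_are_distance_zero(self):
        p = dinucleotide_profile("ACGTACGT")
        assert profile_distance(p, p) == 0.0

    def test_disjoint_support_is_distance_one(self):
        assert profile_distance(
            dinucleotide_profile("AAAA"), dinucleotide_profile("TTTT")
        ) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # ACGT: three bigrams at 1/3 each; AAAA: all mass on AA
        d = profile_distance(dinucleotide_profile("ACGT"), dinucleotide_profile("AAAA"))
        assert d == pytest.approx((1 / 3 * 3 + 1) / 2)

    @given(dna, dna)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, a, b):
        p, q = dinucleotide_profile(a), dinucleotide_profile(b)
        d = profile_distance(p, q)
        assert d == pytest.approx(profile_distance(q, p))
        assert 0 <= d <= 1 + 1e-12
        assert d == pytest.approx(naive_tv(list(p), list(q)))


def genes_from_lengths(ql, sl):
    q = make_gene("a", "qa", tuple("A" * L for L in ql))
    s = make_gene("b", "sb", tuple("A" * L for L in sl))
    return q, s


class TestMatchLengths:
    def test_close_requires_exact_length_lists(self):
        q, s = genes_from_lengths([90, 150, 60], [90, 150, 60])
        pairing = match_lengths(q, s, MatchParams("close"))
        assert pairing is not None and pairing.n_events == 0
        q, s = genes_from_lengths([10, 20, 30], [10, 21, 30])
        assert match_lengths(q, s, MatchParams("close")) is None

    def test_distant_allows_fusion_event(self):
        q, s = genes_from_lengths([90, 150, 60], [240, 60])
        pairing = match_lengths(q, s, MatchParams("distant"))
        assert pairing is not None
        assert pairing.n_events == 1
        assert pairing.units[0] == ((0, 1), (0,))

    def test_region_count_gap_over_budget_is_rejected(self):
        q, s = genes_from_lengths([10, 10, 10, 10], [40])
        assert match_lengths(q, s, MatchParams("distant")) is None

    def test_event_budget_is_enforced(self):
        # three splits needed -> over the two-event budget
        q, s = genes_from_lengths([4, 4, 4, 4, 4, 4], [8, 8, 8])
        assert match_lengths(q, s, MatchParams("distant")) is None
        q, s = genes_from_lengths([8, 8, 4, 4], [8, 8, 8])
        pairing = match_lengths(q, s, MatchParams("distant"))
        assert pairing is not None and pairing.n_events == 1

    @given(
        st.lists(st.integers(2, 12), min_size=1, max_size=7),
        st.lists(st.integers(2, 12), min_size=1, max_size=7),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_greedy_agrees_with_exhaustive_search(self, ql, sl):
        """The greedy in-order scan accepts exactly what exhaustive
        enumeration of merge pairings accepts (merge runs are forced by the
        sum constraint, so greedy is complete)."""
        q, s = genes_from_lengths(ql, sl)
        params = MatchParams("distant")
        greedy = match_lengths(q, s, params)
        exhaustive = exhaustive_match(tuple(ql), tuple(sl), params.max_diff_regions)
        assert (greedy is None) == (exhaustive is None)
        if greedy is not None:
            assert list(greedy.units) == exhaustive

    @given(st.lists(st.integers(2, 20), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_close_acceptance_implies_distant_acceptance(self, ql):
        q, s = genes_from_lengths(ql, ql)
        close = match_lengths(q, s, MatchParams("close"))
        distant = match_lengths(q, s, MatchParams("distant"))
        assert close is not None and distant is not None
        assert distant.n_events == 0


class TestGeneDistance:
    def test_gene_vs_itself_is_zero(self):
        g = make_gene("a", "g1", ("ACGTACGTAC", "GGGCCCATA"))
        g2 = make_gene("b", "g1b", g.cds_seqs)
        pairing = match_lengths(g, g2, MatchParams("close"))
        assert gene_distance(g, g2, pairing) == 0.0

    def test_single_exon_distance_equals_profile_distance(self):
        q = make_gene("a", "q", ("ACGT",))
        s = make_gene("b", "s", ("AAAA",))
        pairing = match_lengths(q, s, MatchParams("close"))
        assert gene_distance(q, s, pairing) == pytest.approx(1.0)

    def test_mean_over_units(self):
        q = make_gene("a", "q", ("ACGTACGT", "AAAATTTT"))
        s = make_gene("b", "s", ("ACGTACGT", "AAAAAAAA"))
        pairing = match_lengths(q, s, MatchParams("close"))
        d_exon2 = profile_distance(
            dinucleotide_profile("AAAATTTT"), dinucleotide_profile("AAAAAAAA")
        )
        assert gene_distance(q, s, pairing) == pytest.approx(d_exon2 / 2)

    def test_merge_unit_compares_concatenation(self):
        q = make_gene("a", "q", ("ACGTAC", "GTACGTAC"))  # 6 + 8
        s = make_gene("b", "s", ("ACGTACGTACGTAC",))  # 14
        pairing = match_lengths(q, s, MatchParams("distant"))
        assert pairing.n_events == 1
        assert gene_distance(q, s, pairing) == 0.0

    def test_all_n_unit_is_skipped_with_warning(self):
        q = make_gene("a", "q", ("NNNN", "ACGTACGT"))
        s = make_gene("b", "s", ("NNNN", "ACGTACGT"))
        pairing = match_lengths(q, s, MatchParams("close"))
        with pytest.warns(UserWarning, match="no countable bigrams"):
            assert gene_distance(q, s, pairing) == 0.0

    def test_incomparable_genes_get_infinite_distance(self):
        q = make_gene("a", "q", ("NNNN",))
        s = make_gene("b", "s", ("ACGT",))
        pairing = match_lengths(q, s, MatchParams("close"))
        with pytest.warns(UserWarning):
            assert math.isinf(gene_distance(q, s, pairing))


class TestCandidateScan:
    def test_window_on_sorted_counts(self):
        subjects = GeneSet(
            "b",
            tuple(
                make_gene("b", f"g{n}", tuple("ACGT" for _ in range(n)))
                for n in range(1, 10)
            ),
        )
        query = make_gene("a", "q", tuple("ACGT" for _ in range(5)))
        counts = sorted(g.n_cds for g in candidate_scan(query, subjects))
        assert counts == [3, 4, 5, 6, 7]

    def test_empty_window(self):
        subjects = GeneSet(
            "b", tuple(make_gene("b", f"g{k}", ("ACGT",) * 9) for k in range(4))
        )
        query = make_gene("a", "q", ("ACGT",))
        assert list(candidate_scan(query, subjects)) == []

    def test_equals_brute_force_filter(self, rng):
        subjects = random_gene_set(rng, "b", 80)
        for query in random_gene_set(rng, "a", 15):
            got = {g.gene_id for g in candidate_scan(query, subjects)}
            want = {g.gene_id for g in subjects if abs(g.n_cds - query.n_cds) <= 2}
            assert got == want


class TestFindOrthologs:
    def test_self_recovery_at_distance_zero(self, small_fixture):
        ga = small_fixture.genes_a
        relabeled = GeneSet(
            "mirror",
            tuple(
                make_gene("mirror", g.gene_id + "_m", g.cds_seqs) for g in ga
            ),
        )
        pairs = find_orthologs(ga, relabeled, MatchParams("close"))
        assert len(pairs) == len(ga)
        assert all(p.distance == 0.0 for p in pairs)
        assert all(p.subject.gene_id == p.query.gene_id + "_m" for p in pairs)

    def test_no_length_overlap_yields_no_pairs(self):
        qa = GeneSet("a", (make_gene("a", "q", ("ACGT" * 5,)),))
        sb = GeneSet("b", (make_gene("b", "s", ("ACGT" * 6,)),))
        assert find_orthologs(qa, sb, MatchParams("distant")) == []

    def test_same_species_rejected(self, small_fixture):
        with pytest.raises(ValueError, match="different species"):
            find_orthologs(small_fixture.genes_a, small_fixture.genes_a)

    def test_empty_gene_set_warns(self, small_fixture):
        empty = GeneSet("x", ())
        with pytest.warns(UserWarning, match="empty"):
            assert find_orthologs(small_fixture.genes_a, empty) == []

    def test_reported_distances_within_threshold(self, small_fixture):
        params = MatchParams("close")
        pairs = find_orthologs(small_fixture.genes_a, small_fixture.genes_b, params)
        assert pairs
        assert all(0 <= p.distance <= params.threshold for p in pairs)

    def test_threshold_monotonicity(self, rng):
        qa = random_gene_set(rng, "a", 40)
        sb = random_gene_set(rng, "b", 40)
        lo = find_orthologs(qa, sb, MatchParams("distant", 0.3))
        hi = find_orthologs(qa, sb, MatchParams("distant", 0.6))
        assert {p.query.gene_id for p in lo} <= {p.query.gene_id for p in hi}

    def test_parallel_run_is_result_invariant(self, small_fixture):
        serial = find_orthologs(small_fixture.genes_a, small_fixture.genes_b)
        parallel = find_orthologs(
            small_fixture.genes_a, small_fixture.genes_b, n_jobs=3
        )
        assert serial == parallel

    def test_reciprocal_filter_is_a_subset(self, rng):
        qa = random_gene_set(rng, "a", 50)
        sb = random_gene_set(rng, "b", 50)
        plain = find_orthologs(qa, sb, MatchParams("distant", 0.5))
        recip = find_orthologs(qa, sb, MatchParams("distant", 0.5), reciprocal=True)
        plain_keys = {(p.query.gene_id, p.subject.gene_id) for p in plain}
        assert {(p.query.gene_id, p.subject.gene_id) for p in recip} <= plain_keys


class TestCombinedSetting:
    def test_union_with_close_precedence(self, structural_fixture):
        fx = structural_fixture
        close = find_orthologs(fx.genes_a, fx.genes_b, MatchParams("close"))
        distant = find_orthologs(fx.genes_a, fx.genes_b, MatchParams("distant"))
        combined = find_orthologs_combined(fx.genes_a, fx.genes_b)
        close_q = {p.query.gene_id for p in close}
        combined_map = {p.query.gene_id: p for p in combined}
        for p in close:
            assert combined_map[p.query.gene_id].setting == "close"
        for p in distant:
            assert p.query.gene_id in combined_map
        assert len(combined) >= max(len(close), len(distant))
        # distant-only queries keep their distant pair
        for p in distant:
            if p.query.gene_id not in close_q:
                assert combined_map[p.query.gene_id] == p

    def test_both_settings_empty_gives_empty(self):
        qa = GeneSet("a", (make_gene("a", "q", ("AC" * 10,)),))
        sb = GeneSet("b", (make_gene("b", "s", ("AC" * 11,)),))
        assert find_orthologs_combined(qa, sb) == []
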