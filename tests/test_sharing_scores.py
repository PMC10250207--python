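import itertools

import numpy as np
import pytest

from clonelineage.counts_calls import CallerParams, SiteCounts
from clonelineage.io_model import GenomicSite
from clonelineage.sharing_scores import (
    FALSE_POSITIVE,
    GERMLINE,
    HIGH_FREQ_MOSAIC,
    MOSAIC,
    PairwiseCallTable,
    ScoreThresholds,
    VariantScore,
    build_pair_table,
    classify_variants,
    score_all,
    score_variant,
    sharing_sets,
)

SITE = GenomicSite("chr1", 100, "A", "T")


def table_from_pattern(n, pairs, supported):
    return PairwiseCallTable(
        unit_ids=[f"u{i}" for i in range(n)],
        called_pairs={SITE: frozenset(pairs)},
        support={SITE: frozenset(supported)},
    )


def brute_force_scores(n, pairs, supported):
    """Independent re-derivation of M and G from first principles."""
    a = {i for i, _ in pairs}
    b = set(range(n)) - a
    if a and b:
        m = sum(1 for i in a for j in b if (i, j) in pairs) / (len(a) * len(b))
    else:
        m = 0.0
    g = sum(1 for _, j in pairs if j in supported) / len(pairs) if pairs else 0.0
    return m, g


class TestScoreVariant:
    def test_perfect_bipartition_is_clean_mosaic(self):
        # carriers {0,1}, every (carrier, non-carrier) pair called
        pairs = {(0, 2), (0, 3), (1, 2), (1, 3)}
        t = table_from_pattern(4, pairs, supported={0, 1})
        sc = score_variant(t, SITE)
        assert sc.mosaic_score == 1.0
        assert sc.germline_score == 0.0
        assert sc.carriers == {"u0", "u1"}

    def test_all_controls_supported_is_germline(self):
        pairs = {(0, 1), (0, 2)}
        t = table_from_pattern(3, pairs, supported={0, 1, 2})
        sc = score_variant(t, SITE)
        assert sc.germline_score == 1.0

    def test_carriers_everywhere_scores_zero_mosaic(self):
        # A = all units -> B empty -> M = 0 by definition
        pairs = {(0, 1), (1, 0), (2, 0)}
        t = table_from_pattern(3, pairs, supported=set())
        sc = score_variant(t, SITE)
        assert sc.mosaic_score == 0.0

    def test_exhaustive_three_unit_patterns_match_brute_force(self):
        all_pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
        rng = np.random.default_rng(1)
        for bits in range(1, 2 ** 6):
            pairs = {p for k, p in enumerate(all_pairs) if bits >> k & 1}
            supported = set(np.nonzero(rng.random(3) < 0.5)[0].tolist())
            t = table_from_pattern(3, pairs, supported)
            sc = score_variant(t, SITE)
            m, g = brute_force_scores(3, pairs, supported)
            assert sc.mosaic_score == pytest.approx(m)
            assert sc.germline_score == pytest.approx(g)

    @pytest.mark.parametrize("n", [4, 5])
    def test_random_patterns_match_brute_force(self, n):
        rng = np.random.default_rng(n)
        all_pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        for _ in range(300):
            k = int(rng.integers(1, len(all_pairs)))
            idx = rng.choice(len(all_pairs), size=k, replace=False)
            pairs = {all_pairs[i] for i in idx}
            supported = set(np.nonzero(rng.random(n) < 0.5)[0].tolist())
            t = table_from_pattern(n, pairs, supported)
            sc = score_variant(t, SITE)
            m, g = brute_force_scores(n, pairs, supported)
            assert sc.mosaic_score == pytest.approx(m)
            assert sc.germline_score == pytest.approx(g)

    def test_mosaic_score_invariant_under_unit_relabeling(self):
        rng = np.random.default_rng(8)
        n = 5
        all_pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        idx = rng.choice(len(all_pairs), size=8, replace=False)
        pairs = {all_pairs[i] for i in idx}
        perm = rng.permutation(n)
        permuted = {(int(perm[i]), int(perm[j])) for i, j in pairs}
        sc1 = score_variant(table_from_pattern(n, pairs, set()), SITE)
        sc2 = score_variant(table_from_pattern(n, permuted, set()), SITE)
        assert sc1.mosaic_score == pytest.approx(sc2.mosaic_score)

    def test_germline_score_monotone_in_supported_controls(self):
        pairs = {(0, 1), (0, 2), (0, 3)}
        g_values = []
        for supported in [set(), {1}, {1, 2}, {1, 2, 3}]:
            sc = score_variant(table_from_pattern(4, pairs, supported), SITE)
            g_values.append(sc.germline_score)
        assert g_values == sorted(g_values)


class TestClassify:
    def make(self, m, g, n_carriers, n_units=10):
        return VariantScore(
            site=SITE, carriers=frozenset(f"u{i}" for i in range(n_carriers)),
            n_units=n_units, mosaic_score=m, germline_score=g)

    def test_high_frequency_mosaic(self):
        (sc,) = classify_variants([self.make(1.0, 0.0, 9)])
        assert sc.label == HIGH_FREQ_MOSAIC

    def test_low_scores_are_false_positive(self):
        (sc,) = classify_variants([self.make(0.3, 0.1, 2)])
        assert sc.label == FALSE_POSITIVE

    def test_germline_dominates_mosaic(self):
        (sc,) = classify_variants([self.make(0.9, 0.5, 2)])
        assert sc.label == GERMLINE

    def test_ordinary_mosaic(self):
        (sc,) = classify_variants([self.make(0.9, 0.1, 3)])
        assert sc.label == MOSAIC

    def test_thresholds_configurable(self):
        (sc,) = classify_variants([self.make(0.7, 0.1, 3)],
                                  ScoreThresholds(m_min=0.6))
        assert sc.label == MOSAIC


class TestSharingSets:
    def test_only_mosaic_classes_emitted(self):
        scores = classify_variants([
            VariantScore(SITE, frozenset({"u0"}), 4, 1.0, 0.0),
            VariantScore(GenomicSite("chr1", 200, "A", "G"),
                         frozenset({"u0", "u1", "u2", "u3"}), 4, 0.0, 0.9),
        ])
        out = sharing_sets(scores)
        assert list(out) == [SITE]

    def test_empty_input_empty_mapping(self):
        assert sharing_sets([]) == {}


class TestBuildPairTable:
    def unit(self, name, site_alt):
        counts = {s: (20, a) for s, a in site_alt.items()}
        return SiteCounts(sample=name, counts=counts, mean_coverage=20)

    def test_ordered_pair_count(self):
        s = {SITE: 0}
        units = [self.unit(f"u{i}", s) for i in range(3)]
        units[0].counts[SITE] = (20, 10)
        table = build_pair_table(units, CallerParams())
        # variant in u0 only: called with u0 as case vs u1 and u2
        assert table.called_pairs[SITE] == {(0, 1), (0, 2)}

    def test_restriction_excludes_site(self):
        other = GenomicSite("chr1", 500, "C", "G")
        units = [self.unit("a", {SITE: 10, other: 10}),
                 self.unit("b", {SITE: 0, other: 0})]
        table = build_pair_table(units, CallerParams(), restrict_sites=[other])
        assert SITE not in table.called_pairs
        assert other in table.called_pairs

    def test_postfilter_drops_low_vaf_case(self):
        low = GenomicSite("chr1", 7, "A", "C")
        units = [self.unit("a", {low: 4}), self.unit("b", {low: 0})]  # VAF 0.2
        filtered = build_pair_table(units, CallerParams())
        raw = build_pair_table(units, CallerParams(), apply_postfilter=False)
        assert low not in filtered.called_pairs
        assert low in raw.called_pairs

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            build_pair_table([self.unit("a", {SITE: 5})], CallerParams())


def test_founder_mutations_recover_true_carrier_sets(small_truth):
    """With deep per-line data, mosaic variants shared by >= 2 lines are
    classified mosaic with exactly the true carrier set."""
    from clonelineage.simulate import simulate_sequencing

    lines = [lid for lid, l in sorted(small_truth.lines.items()) if l.clonal][:8]
    universe = small_truth.site_universe()
    units = [simulate_sequencing(small_truth, lid, 40.0, sites=universe)[0]
             for lid in lines]
    table = build_pair_table(units, CallerParams())
    scored = classify_variants(score_all(table))
    sharing = sharing_sets(scored)

    true_carriers = {}
    for node, muts in small_truth.edge_mutations.items():
        carriers = frozenset(
            lid for lid in lines
            if small_truth.lines[lid].founder.startswith(node))
        for s in muts:
            true_carriers[s] = carriers
    checkable = {
        s: c for s, c in true_carriers.items()
        if 2 <= len(c) < len(lines)
        and (s.vclass == "SNV" or s.indel_len <= 9)
    }
    correct = sum(1 for s, c in checkable.items() if sharing.get(s) == c)
    assert correct / len(checkable) >= 0.95
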