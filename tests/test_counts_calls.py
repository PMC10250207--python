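import numpy as np
import pytest
from scipy import stats

from clonelineage.counts_calls import (
    CallerParams,
    SiteCounts,
    build_pseudobulk,
    call_pair,
    downsample_counts,
    postfilter,
    read_counts,
    sum_counts,
    write_counts,
)
from clonelineage.io_model import GenomeMask, GenomicSite, MutationCall


def site(pos, ref="A", alt="T"):
    return GenomicSite("chr1", pos, ref, alt)


def sc(sample, counts, cov=None):
    if cov is None:
        cov = float(np.mean([d for d, _ in counts.values()])) if counts else 0.0
    return SiteCounts(sample=sample, counts=counts, mean_coverage=cov)


class TestDownsample:
    def test_target_equal_to_mean_is_identity(self):
        counts = sc("a", {site(i): (10, 5) for i in range(1, 50)}, cov=10)
        out = downsample_counts(counts, 10, seed=1)
        assert out.counts == counts.counts

    def test_upsampling_refused(self):
        counts = sc("a", {site(1): (5, 2)}, cov=5)
        with pytest.raises(ValueError):
            downsample_counts(counts, 10, seed=1)

    def test_zero_depth_stays_zero(self):
        counts = sc("a", {site(1): (0, 0)}, cov=50)
        out = downsample_counts(counts, 5, seed=1)
        assert out.counts[site(1)] == (0, 0)

    def test_mean_depth_matches_binomial_expectation(self):
        # mean 50 -> target 5 keeps each read with p = 0.1
        n = 10_000
        counts = sc("a", {site(i): (50, 25) for i in range(1, n + 1)}, cov=50)
        out = downsample_counts(counts, 5, seed=3)
        depths = np.array([d for d, _ in out.counts.values()])
        se = np.sqrt(50 * 0.1 * 0.9 / n)
        assert abs(depths.mean() - 5.0) < 3 * se

    def test_sequential_thinning_equals_product_probability(self):
        # thin 40x->20x->5x vs 40x->5x: same marginal distribution
        n = 10_000
        counts = sc("a", {site(i): (40, 20) for i in range(1, n + 1)}, cov=40)
        twice = downsample_counts(downsample_counts(counts, 20, seed=5), 5, seed=6)
        once = downsample_counts(counts, 5, seed=7)
        d2 = np.array([d for d, _ in twice.counts.values()])
        d1 = np.array([d for d, _ in once.counts.values()])
        assert stats.ks_2samp(d1, d2).pvalue > 1e-3
        a2 = np.array([a for _, a in twice.counts.values()])
        a1 = np.array([a for _, a in once.counts.values()])
        assert stats.ks_2samp(a1, a2).pvalue > 1e-3

    def test_deterministic_under_seed(self):
        counts = sc("a", {site(i): (30, 12) for i in range(1, 200)}, cov=30)
        assert downsample_counts(counts, 5, seed=9).counts == \
            downsample_counts(counts, 5, seed=9).counts


class TestSumCounts:
    def test_sitewise_additivity(self):
        a = sc("a", {site(1): (5, 2)})
        b = sc("b", {site(1): (5, 3), site(2): (4, 0)})
        out = sum_counts([a, b])
        assert out.counts[site(1)] == (10, 5)
        assert out.counts[site(2)] == (4, 0)
        assert out.mean_coverage == a.mean_coverage + b.mean_coverage

    def test_single_input_identity(self):
        a = sc("a", {site(1): (5, 2)})
        assert sum_counts([a]).counts == a.counts

    def test_commutativity(self):
        many = [sc(f"s{i}", {site(j): (i + j, j % (i + 1)) for j in range(1, 9)})
                for i in range(1, 4)]
        fwd = sum_counts(many)
        rev = sum_counts(many[::-1])
        assert fwd.counts == rev.counts

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sum_counts([])


class TestPseudobulk:
    def test_depth_accumulates_and_role_is_control(self):
        clones = [sc(f"c{i}", {site(1): (8, 0)}) for i in range(4)]
        pb = build_pseudobulk(clones)
        assert pb.counts[site(1)] == (32, 0)
        assert pb.role == "control"

    def test_private_variant_diluted(self):
        # variant at VAF .5 in one of four equal clones -> ~1/8 alt fraction
        clones = [sc(f"c{i}", {site(1): (100, 50 if i == 0 else 0)}) for i in range(4)]
        pb = build_pseudobulk(clones)
        d, a = pb.counts[site(1)]
        assert a / d == pytest.approx(0.125)

    def test_germline_never_called_against_pseudobulk(self, small_truth):
        """Variants carried by all clones poison their own control."""
        from clonelineage.simulate import simulate_sequencing

        universe = small_truth.site_universe()
        lines = sorted(small_truth.lines)[:4]
        counts = [simulate_sequencing(small_truth, l, 30.0, sites=universe)[0]
                  for l in lines]
        pb = build_pseudobulk(counts[1:])
        calls = call_pair(counts[0], pb, CallerParams())
        germline_called = {c.site for c in calls} & set(small_truth.germline_sites)
        assert not germline_called


class TestCallPair:
    params = CallerParams()

    def test_supported_clean_site_called(self):
        case = sc("t", {site(1): (5, 3)})
        ctrl = sc("n", {site(1): (10, 0)})
        calls = call_pair(case, ctrl, self.params)
        assert len(calls) == 1 and calls[0].vaf == pytest.approx(0.6)

    def test_below_three_reads_not_called(self):
        case = sc("t", {site(1): (5, 2)})
        ctrl = sc("n", {site(1): (10, 0)})
        assert call_pair(case, ctrl, self.params) == []

    def test_insufficient_control_depth_not_called(self):
        case = sc("t", {site(1): (5, 3)})
        ctrl = sc("n", {site(1): (3, 0)})
        assert call_pair(case, ctrl, self.params) == []

    def test_control_alt_reads_block_call(self):
        case = sc("t", {site(1): (5, 3)})
        ctrl = sc("n", {site(1): (10, 1)})
        assert call_pair(case, ctrl, self.params) == []

    def test_site_outside_mask_not_called(self):
        mask = GenomeMask.from_intervals({"chr1": [(100, 200)]})
        params = CallerParams(mask=mask)
        case = sc("t", {site(1): (5, 3), site(150): (5, 3)})
        ctrl = sc("n", {site(1): (10, 0), site(150): (10, 0)})
        calls = call_pair(case, ctrl, params)
        assert [c.site.pos for c in calls] == [150]

    def test_sensitivity_monotone_in_case_depth(self):
        """Analytic call probability rises with coverage at fixed VAF 0.5."""
        def call_prob(coverage):
            # depth ~ Poisson(cov), called iff alt >= 3, alt ~ Binom(d, .5)
            p = 0.0
            for d in range(0, 200):
                pd = stats.poisson.pmf(d, coverage)
                if pd < 1e-12:
                    continue
                p += pd * stats.binom.sf(2, d, 0.5)
            return p

        probs = [call_prob(c) for c in (2, 5, 10, 20, 40)]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_cluster_sum_beats_any_single_member(self, small_truth):
        """Summing redundant 5x lines detects more founder mutations."""
        from clonelineage.simulate import simulate_sequencing

        # find a founder group with >= 3 clonal lines
        groups: dict[str, list[str]] = {}
        for lid, line in small_truth.lines.items():
            if line.clonal:
                groups.setdefault(line.founder, []).append(lid)
        founder, members = max(groups.items(), key=lambda kv: len(kv[1]))
        founder_sites = small_truth.founder_set(founder)
        universe = sorted(founder_sites)
        per_line = [
            simulate_sequencing(small_truth, lid, 5.0, sites=universe)[0]
            for lid in members
        ]
        merged = sum_counts(per_line)

        def n_detected(counts):
            return sum(1 for s in founder_sites if counts.alt(s) >= 3)

        best_single = max(n_detected(c) for c in per_line)
        assert n_detected(merged) > best_single


class TestPostfilter:
    params = CallerParams()

    def make(self, alt_count, depth, ref="A", alt="T"):
        return MutationCall.from_counts(site(1, ref, alt), "s", alt_count, depth)

    def test_vaf_boundary(self):
        low = self.make(29, 100)
        high = self.make(31, 100)
        exact = self.make(30, 100)
        kept = postfilter([low, high, exact], self.params)
        assert low not in kept and high in kept and exact in kept

    def test_indel_length_boundary(self):
        nine = self.make(50, 100, ref="A", alt="A" + "T" * 9)
        ten = self.make(50, 100, ref="A", alt="A" + "T" * 10)
        kept = postfilter([nine, ten], self.params)
        assert nine in kept and ten not in kept

    def test_high_vaf_snv_kept(self):
        c = self.make(95, 100)
        assert postfilter([c], self.params) == [c]


def test_counts_tsv_round_trip(tmp_path):
    counts = sc("a", {site(i): (10 + i, i) for i in range(1, 6)}, cov=12)
    path = tmp_path / "c.tsv"
    write_counts(counts, path)
    (back,) = read_counts(path, mean_coverage=12)
    assert back.sample == "a" and back.counts == counts.counts
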