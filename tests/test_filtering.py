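import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import clopper_pearson_lower_bisect
from poolsel import (BiallelicVariantTable, FilterConfig, PooledCountsTable,
                     allele_frequencies, binomial_ci_lower, call_biallelic,
                     coverage_filters, filter_pipeline, high_confidence_filter,
                     lower_quantile, make_design, merge_varref,
                     third_allele_threshold)


def counts_table(per_sample_counts, pos=None):
    """Build a PooledCountsTable from a list of (n_sites, 6) count arrays."""
    counts = np.asarray(per_sample_counts)
    n_sites = counts.shape[1]
    sites = pd.DataFrame({
        "arm": ["2L"] * n_sites,
        "pos": pos if pos is not None else np.arange(1, n_sites + 1),
        "ref": ["A"] * n_sites,
    })
    return PooledCountsTable(sites=sites, counts=counts,
                             samples=[f"s{i}" for i in
                                      range(counts.shape[0])])


class TestMergeVarref:
    def test_single_sample_is_identity(self):
        t = counts_table([[[3, 0, 1, 0, 0, 0]]])
        merged, _ = merge_varref(t)
        assert np.array_equal(merged, [[3, 0, 1, 0, 0, 0]])

    def test_counts_add_elementwise(self):
        t = counts_table([[[3, 0, 0, 0, 0, 0]], [[1, 2, 0, 0, 0, 0]]])
        merged, _ = merge_varref(t)
        assert np.array_equal(merged, [[4, 2, 0, 0, 0, 0]])

    def test_mismatched_site_sets_error_names_sites(self):
        a = counts_table([[[3, 0, 0, 0, 0, 0]]], pos=[10])
        b = counts_table([[[3, 0, 0, 0, 0, 0]]], pos=[20])
        with pytest.raises(ValueError, match="2L:(10|20)"):
            merge_varref([a, b])

    def test_merged_median_exceeds_per_sample_median(self, small_experiment):
        # 12 pooled samples merge to far deeper coverage than any one
        table, _, _, _ = small_experiment
        _, merged_median = merge_varref(table)
        per_sample = np.median(table.counts.sum(axis=2), axis=1)
        assert merged_median > 10 * per_sample.max() / 2


class TestThirdAlleleThreshold:
    def test_strictly_biallelic_sites_give_zero(self):
        varref = np.array([[50, 10, 0, 0, 0, 0], [7, 3, 0, 0, 0, 0]])
        assert third_allele_threshold(varref) == 0

    def test_hand_enumerated_quantile(self):
        # third-largest counts {0, 0, 1, 3, 5}; lower 0.75-quantile is 3
        thirds = [0, 0, 1, 3, 5]
        varref = np.array([[100, 50, t, 0, 0, 0] for t in thirds])
        assert third_allele_threshold(varref, 0.75) == 3

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=50),
           st.floats(0.05, 0.95))
    @settings(deadline=None, max_examples=50)
    def test_lower_quantile_is_an_order_statistic(self, values, q):
        res = lower_quantile(np.array(values), q)
        assert res in values
        assert (np.sort(values)[: max(int(np.ceil(q * len(values))), 1)]
                <= res).all()


class TestCallBiallelic:
    def test_third_allele_above_threshold_drops_site(self):
        t = counts_table([[[100, 4, 10, 0, 0, 0]]])
        merged, _ = merge_varref(t)
        assert call_biallelic(t, merged, 3).n_sites == 0

    def test_kept_site_ref_alt_and_depth(self):
        t = counts_table([[[100, 50, 3, 0, 0, 0]]])
        merged, _ = merge_varref(t)
        out = call_biallelic(t, merged, 3)
        assert out.n_sites == 1
        assert out.sites.loc[0, "ref"] == "A"
        assert out.sites.loc[0, "alt"] == "T"
        assert out.depths[0, 0] == 150      # third-allele reads excluded

    def test_minor_count_must_exceed_threshold(self):
        t = counts_table([[[100, 3, 0, 0, 0, 0]]])
        merged, _ = merge_varref(t)
        assert call_biallelic(t, merged, 3).n_sites == 0

    def test_ref_slot_follows_reference_base_when_minor(self):
        # reference base A is the *minor* allele: still takes the ref slot
        t = counts_table([[[30, 100, 0, 0, 0, 0]]])
        merged, _ = merge_varref(t)
        out = call_biallelic(t, merged, 3)
        assert out.sites.loc[0, "ref"] == "A"
        assert out.sites.loc[0, "alt"] == "T"
        assert out.alt_counts[0, 0] == 100


def design_2gen():
    return make_design([f"s{i}" for i in range(4)],
                       ["selected", "control"] * 2, [1, 1, 2, 2],
                       [4, 4, 17, 17], 200)


class TestCoverageFilters:
    def make(self, depths):
        depths = np.asarray(depths)
        alt = np.minimum(5, depths)
        sites = pd.DataFrame({"arm": "2L",
                              "pos": np.arange(1, depths.shape[1] + 1),
                              "ref": "A", "alt": "T"})
        return BiallelicVariantTable(sites=sites, alt_counts=alt,
                                     depths=depths,
                                     samples=[f"s{i}" for i in range(4)])

    def test_global_depth_rule_is_strict(self):
        # merged depth exactly 10 fails "over 10x"
        t = self.make([[2, 100], [3, 100], [2, 100], [3, 100]])
        out, _ = coverage_filters(t, design_2gen(),
                                  FilterConfig(per_sample_min_depth=1))
        assert out.sites["pos"].tolist() == [2]

    def test_equal_depths_survive_high_coverage_rule(self):
        t = self.make(np.full((4, 5), 50))
        out, cut = coverage_filters(t, design_2gen(),
                                    FilterConfig(per_sample_min_depth=1))
        assert out.n_sites == 5
        assert cut == 200

    def test_cohort_low_coverage_needs_failure_in_all_samples(self):
        # covered >=10x in a single sample per cohort: retained
        t = self.make([[50, 5], [5, 5], [50, 5], [5, 5]])
        out, _ = coverage_filters(t, design_2gen(), FilterConfig())
        assert out.sites["pos"].tolist() == [1]


class TestBinomialCi:
    def test_zero_minor_gives_zero_bound(self):
        assert binomial_ci_lower(0, 100) == 0.0

    def test_full_minor_bound_above_point_eight(self):
        assert binomial_ci_lower(50, 50) > 0.8

    @pytest.mark.parametrize("minor,depth", [(5, 100), (1, 30), (12, 40),
                                             (50, 50), (3, 1000)])
    def test_matches_tail_bisection_oracle(self, minor, depth):
        ours = float(binomial_ci_lower(minor, depth, 0.9973))
        oracle = clopper_pearson_lower_bisect(minor, depth, 0.9973)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci_lower(0, 0)

    def test_wilson_and_wald_options(self):
        w = binomial_ci_lower(10, 100, 0.95, method="wilson")
        a = binomial_ci_lower(10, 100, 0.95, method="wald")
        assert 0 < a < w < 0.1
        # a Wald 3-sigma bound excludes low-count sites that exact CP keeps
        assert binomial_ci_lower(1, 80, 0.9973, method="wald") == 0.0
        assert binomial_ci_lower(1, 80, 0.9973) > 0.0


class TestHighConfidence:
    def make(self, alt, dep):
        alt, dep = np.asarray(alt), np.asarray(dep)
        sites = pd.DataFrame({"arm": "2L",
                              "pos": np.arange(1, alt.shape[1] + 1),
                              "ref": "A", "alt": "T"})
        return BiallelicVariantTable(
            sites=sites, alt_counts=alt, depths=dep,
            samples=[f"s{i}" for i in range(alt.shape[0])])

    def test_zero_minor_everywhere_dropped(self):
        t = self.make([[0], [0]], [[50], [60]])
        assert high_confidence_filter(t).n_sites == 0

    def test_single_strong_sample_suffices(self):
        t = self.make([[0], [10]], [[50], [20]])
        assert high_confidence_filter(t).n_sites == 1


class TestFrequenciesAndPipeline:
    def test_allele_frequency_values(self):
        sites = pd.DataFrame({"arm": ["2L"], "pos": [1], "ref": ["A"],
                              "alt": ["T"]})
        t = BiallelicVariantTable(sites=sites, alt_counts=np.array([[5], [0]]),
                                  depths=np.array([[50], [40]]),
                                  samples=["a", "b"])
        freq = allele_frequencies(t)
        assert freq[0, 0] == 0.10
        assert freq[1, 0] == 0.0

    def test_pipeline_idempotent_with_frozen_thresholds(self,
                                                        small_experiment):
        table, design, _, _ = small_experiment
        bial, report = filter_pipeline(table, design)
        # rebuild a counts table holding only the retained ref/alt reads
        base_order = {b: i for i, b in
                      enumerate(["A", "T", "C", "G", "N", "del"])}
        counts = np.zeros((len(bial.samples), bial.n_sites, 6), dtype=int)
        ref_i = bial.sites["ref"].map(base_order).to_numpy()
        alt_i = bial.sites["alt"].map(base_order).to_numpy()
        rng_sites = np.arange(bial.n_sites)
        for j in range(len(bial.samples)):
            counts[j, rng_sites, alt_i] = bial.alt_counts[j]
            counts[j, rng_sites, ref_i] = bial.depths[j] - bial.alt_counts[j]
        rebuilt = PooledCountsTable(
            sites=bial.sites[["arm", "pos", "ref"]].copy(), counts=counts,
            samples=bial.samples)
        again, _ = filter_pipeline(rebuilt, design, frozen=report)
        assert again.n_sites == bial.n_sites
        assert np.array_equal(again.alt_counts, bial.alt_counts)
        assert np.array_equal(again.depths, bial.depths)

    def test_each_retained_site_unique_with_distinct_alleles(
            self, small_filtered):
        bial, _, _ = small_filtered
        assert not bial.sites.duplicated(["arm", "pos"]).any()
        assert (bial.sites["ref"] != bial.sites["alt"]).all()

    def test_error_free_simulation_keeps_true_variants(self):
        from poolsel import SimulationConfig, generate_experiment
        cfg = SimulationConfig(n_loci=200, ne=120, arms=(("2L", 400_000),),
                               depth_mean=60.0, error_rate=0.0,
                               pool_individuals=80,
                               free_recombination=True, seed=31)
        table, design, truth, founders = generate_experiment(cfg)
        varref, _ = merge_varref(table)
        thr = third_allele_threshold(varref)
        assert thr == 0
        bial, report = filter_pipeline(table, design)
        # no site with merged minor count above threshold and adequate
        # coverage is lost
        classes = np.sort(varref[:, [0, 1, 2, 3, 5]], axis=1)
        minor = classes[:, -2]
        depth = varref[:, [0, 1, 2, 3, 5]].sum(axis=1)
        expected = ((minor > thr) & (depth > 10)
                    & (depth <= report.high_cov_cutoff))
        kept = np.isin(founders.positions, bial.sites["pos"])
        assert (kept == expected).all()

    def test_sync_round_trip(self, tmp_path, small_experiment):
        table, _, _, _ = small_experiment
        p = tmp_path / "x.sync"
        table.write_sync(p)
        back = PooledCountsTable.read_sync(p, samples=table.samples)
        assert np.array_equal(back.counts, table.counts)
        assert back.sites["pos"].tolist() == table.sites["pos"].tolist()

    def test_biallelic_tsv_round_trip(self, tmp_path, small_filtered):
        bial, _, _ = small_filtered
        p = tmp_path / "v.tsv"
        bial.write_tsv(p)
        back = BiallelicVariantTable.read_tsv(p)
        assert np.array_equal(back.alt_counts, bial.alt_counts)
        assert np.array_equal(back.depths, bial.depths)
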