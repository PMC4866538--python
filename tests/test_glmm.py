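import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import glmm_oracle
from poolsel import (enumerate_permutations, fit_glmm_batch, fit_site_glmm,
                     permutation_fdr, run_divergence_scan)

TREAT = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


class TestSiteFit:
    def test_exchangeable_groups_give_null_fit(self):
        fit = fit_site_glmm(np.full(6, 25.0), np.full(6, 50.0), TREAT)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-6)
        assert fit.p == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_negates_beta_and_keeps_p(self):
        alt = np.array([40.0, 38, 42, 20, 22, 18])
        dep = np.full(6, 50.0)
        a = fit_site_glmm(alt, dep, TREAT)
        b = fit_site_glmm(alt, dep, 1 - TREAT)
        assert b.beta1 == pytest.approx(-a.beta1, rel=1e-8)
        assert b.p == pytest.approx(a.p, rel=1e-8)

    def test_matches_dense_grid_likelihood_oracle(self):
        alt = np.array([40.0, 38, 42, 20, 22, 18])
        dep = np.full(6, 50.0)
        fit = fit_site_glmm(alt, dep, TREAT)
        oracle = glmm_oracle(alt, dep, TREAT)
        # agreement to 3 significant figures on the p-value
        assert fit.p == pytest.approx(oracle["p"], rel=1e-3)
        assert fit.beta1 == pytest.approx(oracle["theta"][1], abs=1e-5)
        assert fit.loglik == pytest.approx(oracle["loglik"], abs=1e-6)

    def test_overdispersed_site_matches_oracle(self):
        alt = np.array([45.0, 20, 38, 20, 10, 30])
        dep = np.full(6, 60.0)
        fit = fit_site_glmm(alt, dep, TREAT)
        oracle = glmm_oracle(alt, dep, TREAT)
        assert fit.sigma_u == pytest.approx(oracle["theta"][2], abs=1e-4)
        assert fit.p == pytest.approx(oracle["p"], rel=1e-3)

    def test_wald_p_reproducible_from_z(self):
        alt = np.array([30.0, 28, 35, 22, 25, 20])
        fit = fit_site_glmm(alt, np.full(6, 50.0), TREAT)
        assert not fit.separated
        assert fit.p == pytest.approx(2 * stats.norm.sf(abs(fit.z)), rel=1e-12)
        assert fit.z == pytest.approx(fit.beta1 / fit.se1, rel=1e-12)

    def test_sigma_boundary_matches_plain_binomial_glm(self):
        # identical replicate counts force sigma to 0; the Wald test then
        # equals a fixed-effects binomial GLM (independent statsmodels fit)
        import statsmodels.api as sm
        alt = np.array([40.0, 40, 40, 25, 25, 25])
        dep = np.full(6, 50.0)
        fit = fit_site_glmm(alt, dep, TREAT)
        assert fit.sigma_u < 1e-3
        X = sm.add_constant(TREAT)
        glm = sm.GLM(np.column_stack([alt, dep - alt]), X,
                     family=sm.families.Binomial()).fit()
        assert fit.beta1 == pytest.approx(glm.params[1], rel=1e-6)
        assert fit.se1 == pytest.approx(glm.bse[1], rel=1e-4)

    def test_separation_flagged_with_lrt_fallback(self):
        fit = fit_site_glmm(np.array([50.0, 50, 50, 0, 0, 0]),
                            np.full(6, 50.0), TREAT)
        assert fit.separated
        # the LRT is damped by the null model's free random-effect variance
        # (it can absorb separated counts by inflating sigma), so the
        # fallback p is small but nowhere near the naive GLM value
        assert 0 < fit.p < 0.05

    def test_too_few_samples_per_group_rejected(self):
        with pytest.raises(ValueError, match="two samples per treatment"):
            fit_site_glmm(np.array([1.0, 2]), np.array([10.0, 10]),
                          np.array([1.0, 0.0]))

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="positive depth"):
            fit_site_glmm(np.zeros(6), np.array([0.0, 9, 9, 9, 9, 9]), TREAT)


class TestPermutations:
    @pytest.mark.parametrize("k,expected", [(1, 0), (2, 2), (3, 9), (4, 34)])
    def test_relabeling_count_is_half_central_binomial_minus_one(
            self, k, expected):
        treat = np.array([1] * k + [0] * k, dtype=float)
        scheme = enumerate_permutations(treat)
        assert scheme.n == expected

    def test_no_relabeling_equals_observed_partition(self):
        scheme = enumerate_permutations(TREAT)
        obs = frozenset(np.where(TREAT > 0)[0])
        for lab in scheme.relabelings:
            part = frozenset(np.where(lab)[0])
            assert part != obs
            assert frozenset(range(6)) - part != obs

    def test_relabelings_are_distinct_partitions(self):
        scheme = enumerate_permutations(TREAT)
        parts = {min(tuple(sorted(np.where(lab)[0])),
                     tuple(sorted(np.where(~lab)[0])))
                 for lab in scheme.relabelings}
        assert len(parts) == 9

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            enumerate_permutations(np.array([1, 1, 1, 1, 0, 0], dtype=float))

    def test_relabeling_equals_column_permutation(self):
        # refitting under a relabeling is the same as permuting sample
        # columns and refitting with the observed labels
        rng = np.random.default_rng(5)
        alt = rng.binomial(50, 0.4, size=(20, 6)).astype(float)
        dep = np.full((20, 6), 50.0)
        lab = enumerate_permutations(TREAT).relabelings[3].astype(float)
        direct = fit_glmm_batch(alt, dep, lab)["p"].to_numpy()
        order = np.concatenate([np.where(lab > 0)[0], np.where(lab == 0)[0]])
        permuted = fit_glmm_batch(alt[:, order], dep[:, order],
                                  TREAT)["p"].to_numpy()
        assert np.allclose(direct, permuted, rtol=1e-8)


class TestPermutationFdr:
    def test_hand_counted_example(self):
        # 10 variants at p=.001 and 90 at .5; two relabelings contribute
        # one and zero p-values below .01 -> FDR(.01) = 0.5/10 = 0.05
        p_obs = np.array([0.001] * 10 + [0.5] * 90)
        p_perm = np.vstack([
            np.array([0.005] + [0.6] * 99),
            np.full(100, 0.7),
        ])
        curve, _, _ = permutation_fdr(p_obs, p_perm, alpha=0.05,
                                      grid=np.array([0.01]))
        assert curve.fdr[0] == pytest.approx(0.05)

    def test_clean_permutations_give_zero_fdr(self):
        p_obs = np.array([0.001, 0.2, 0.9])
        p_perm = np.full((9, 3), 0.95)
        curve, threshold, sdv = permutation_fdr(p_obs, p_perm)
        assert (curve.fdr[curve.s_obs > 0] == 0).all()
        assert threshold == pytest.approx(0.9)
        assert sdv.sum() == 2  # strict "<" excludes the largest p itself

    def test_exchangeable_permutations_give_fdr_near_one(self, rng):
        p_obs = rng.uniform(size=2000)
        p_perm = rng.uniform(size=(9, 2000))
        curve, _, _ = permutation_fdr(p_obs, p_perm)
        mid = (curve.grid > 0.2) & (curve.grid < 0.8)
        assert np.nanmedian(curve.fdr[mid]) == pytest.approx(1.0, abs=0.1)

    def test_selected_threshold_controls_fdr_by_construction(self, rng):
        p_obs = np.concatenate([rng.uniform(0, 1e-4, 50),
                                rng.uniform(size=500)])
        p_perm = rng.uniform(size=(9, 550))
        curve, threshold, sdv = permutation_fdr(p_obs, p_perm, alpha=0.05)
        assert threshold is not None
        at = curve.grid == threshold
        assert curve.fdr[at][0] < 0.05
        assert sdv.sum() == int((p_obs < threshold).sum())

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            permutation_fdr(np.array([]), np.zeros((9, 0)))


class TestScan:
    @pytest.mark.parametrize("seed", [5, 11])
    def test_spiked_common_drivers_rank_in_top_percentile(self, seed):
        # six unlinked drivers at s=0.2 placed on common standing variants
        # (founder frequency >= 0.2, the regime where 17 generations of
        # selection produce a detectable shift): every driver that survives
        # QC ranks in the top 1% of GLMM p-values
        from poolsel import (SimulationConfig, build_founders,
                             filter_pipeline, generate_experiment)
        base = SimulationConfig(
            n_loci=1200, ne=1000, arms=(("2L", 12_000_000),),
            free_recombination=True, founder_mode="linkage_equilibrium",
            sfs="uniform", depth_mean=80.0, pool_individuals=100, seed=seed)
        streams = np.random.SeedSequence(seed).spawn(7)
        preview = build_founders(base, np.random.default_rng(streams[0]))
        common = np.where(preview.founder_frequencies >= 0.2)[0]
        drivers = tuple((int(i), 0.2, 0.5)
                        for i in common[::len(common) // 6][:6])
        config = SimulationConfig(**{**base.__dict__,
                                     "driver_loci": drivers})
        table, design, truth, founders = generate_experiment(config)
        bial, _ = filter_pipeline(table, design)
        pos = {s: j for j, s in enumerate(bial.samples)}
        late = design[design["generation"] == 17]
        idx = [pos[s] for s in late["sample"]]
        treat = (late["treatment"] == "selected").to_numpy().astype(float)
        fits = fit_glmm_batch(bial.alt_counts[idx].T, bial.depths[idx].T,
                              treat)
        driver_pos = set(founders.positions[truth.driver_sites].tolist())
        is_driver = bial.sites["pos"].isin(driver_pos).to_numpy()
        assert is_driver.sum() >= 4            # most drivers survive QC
        rank = fits["p"].rank(pct=True).to_numpy()
        assert (rank[is_driver] <= 0.01).all()

    def test_scan_smoke_with_mask(self, small_filtered):
        bial, _, design = small_filtered
        mask = pd.DataFrame({"arm": ["2L"], "start": [0], "end": [100_000]})
        scan = run_divergence_scan(bial, design, mask=mask)
        res = scan.results
        assert {"beta1", "p", "sdv", "masked"} <= set(res.columns)
        assert res["masked"].sum() > 0
        assert not (res["sdv"] & res["masked"]).any()
        assert [f"p_perm{j}" for j in range(1, 10)] == \
            [c for c in res.columns if c.startswith("p_perm")]

    def test_unbalanced_design_fails_with_guidance(self, small_filtered):
        bial, _, design = small_filtered
        design = design[design["sample"] != "S1_g17"]
        with pytest.raises(ValueError, match="balanced"):
            run_divergence_scan(bial, design)
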