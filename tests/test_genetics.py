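import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hervkit.genetics import (
    GenotypeStudy,
    _tmm_pair,
    call_ehervs,
    cis_scan,
    enrichment_test,
    expand_gwas_ld,
    factor_count_schedule,
    genotype_pcs,
    hidden_factors,
    hwe_pvalue,
    inverse_normal,
    inverse_normal_rows,
    ld_r2,
    mask_expression,
    matched_background,
    permutation_pass,
    presence_from_contigs,
    prune_ld,
    site_variant_filter,
    tmm_factors,
    variant_qc,
)


def study(dosage, chrom="chr1", positions=None):
    dosage = np.asarray(dosage, dtype=float)
    n_var = dosage.shape[0]
    positions = positions if positions is not None else list(range(100, 100 + 100 * n_var, 100))
    return GenotypeStudy(
        dosage=dosage,
        variants=pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n_var)],
                "chrom": chrom,
                "pos": positions,
                "ref": "A",
                "alt": "G",
            }
        ),
        individuals=[f"I{j}" for j in range(dosage.shape[1])],
    )


class TestPresence:
    def test_unique_contig_present(self):
        calls = presence_from_contigs({("L1", "I1"): [True]})
        assert calls[("L1", "I1")] == "present"

    def test_only_multimapping_absent(self):
        calls = presence_from_contigs({("L1", "I1"): [False, False, False]})
        assert calls[("L1", "I1")] == "absent"

    def test_no_contigs_absent(self):
        calls = presence_from_contigs({}, loci=["L1"], individuals=["I1"])
        assert calls[("L1", "I1")] == "absent"

    def test_mask_expression(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["L1"], columns=["I1", "I2"])
        masked = mask_expression(expr, {("L1", "I1"): "absent", ("L1", "I2"): "present"})
        assert np.isnan(masked.loc["L1", "I1"])
        assert masked.loc["L1", "I2"] == 2.0


class TestVariantQc:
    def test_exact_hwe_kept(self):
        dosage = np.array([[0] * 25 + [1] * 50 + [2] * 25])
        assert hwe_pvalue(25, 50, 25) == pytest.approx(1.0)
        assert list(variant_qc(study(dosage))) == [0]

    def test_extreme_hwe_dropped(self):
        # AA=50, aa=50: chi2 = sum((O-E)^2/E) with E=(25,50,25) -> 100
        p = hwe_pvalue(50, 0, 50)
        chi2 = (50 - 25) ** 2 / 25 + 50 + (50 - 25) ** 2 / 25
        assert chi2 == 100
        assert p == pytest.approx(stats.chi2.sf(100, 1))
        dosage = np.array([[0] * 50 + [2] * 50])
        assert len(variant_qc(study(dosage))) == 0

    def test_missingness_boundary(self):
        row = np.array([0, 1, 2, 1, 0, 1, 2, 1, 0, 1] * 10, dtype=float)
        row6 = row.copy()
        row6[:6] = np.nan  # 6% missing -> dropped
        row4 = row.copy()
        row4[:4] = np.nan  # 4% missing -> kept
        keep = variant_qc(study(np.vstack([row6, row4])))
        assert list(keep) == [1]

    def test_monomorphic_dropped(self):
        dosage = np.zeros((1, 50))
        assert len(variant_qc(study(dosage))) == 0

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            variant_qc(study(np.zeros((1, 5))))


class TestSiteVariantFilter:
    def test_ten_carriers_kept(self):
        row = np.array([1] * 10 + [0] * 190, dtype=float)
        assert list(site_variant_filter(study(row[None, :]))) == [0]

    def test_nine_carriers_dropped(self):
        row = np.array([1] * 9 + [0] * 191, dtype=float)
        assert len(site_variant_filter(study(row[None, :]))) == 0

    def test_low_maf_dropped(self):
        row = np.array([1] * 10 + [0] * 990, dtype=float)  # MAF 0.005
        assert len(site_variant_filter(study(row[None, :]))) == 0

    def test_ref_minor_counted(self):
        row = np.array([2] * 90 + [1] * 10, dtype=float)  # ref allele is minor
        assert list(site_variant_filter(study(row[None, :]))) == [0]


class TestTmm:
    def test_identical_columns_unit_factors(self, rng):
        counts = pd.DataFrame(np.tile(rng.integers(1, 500, size=50)[:, None], (1, 4)))
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_depth_only_difference_unit_factors(self, rng):
        base = rng.integers(10, 500, size=100)
        counts = pd.DataFrame({"A": base, "B": base * 3})
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_constant_m_gives_2_to_m(self, rng):
        # all M-values equal m=1 -> weighted trimmed mean is exactly 1
        ref = rng.integers(10, 500, size=200).astype(float)
        obs = ref * 2
        lib = float(ref.sum()) * 10
        f = _tmm_pair(obs, ref, lib, lib)
        assert f == pytest.approx(1.0, abs=1e-12)

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 800, size=(300, 6)))
        factors = tmm_factors(counts)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_sample_errors(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(counts)


class TestInverseNormal:
    def test_n3_quantiles(self):
        out = inverse_normal(np.array([5.0, 1.0, 3.0]))
        expected = stats.norm.ppf([5 / 6, 1 / 6, 3 / 6])
        np.testing.assert_allclose(out, expected, atol=1e-4)
        assert out[1] == pytest.approx(-0.9674, abs=1e-4)

    def test_rank_preserving(self, rng):
        v = rng.random(50)
        out = inverse_normal(v)
        assert (np.argsort(out) == np.argsort(v)).all()

    def test_idempotent_on_ranks(self, rng):
        v = rng.random(30)
        once = inverse_normal(v)
        twice = inverse_normal(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_missing_preserved(self):
        out = inverse_normal(np.array([1.0, np.nan, 3.0, 2.0]))
        assert np.isnan(out[1])
        assert not np.isnan(out[[0, 2, 3]]).any()

    def test_all_equal_maps_to_zero(self):
        np.testing.assert_array_equal(inverse_normal(np.array([2.0, 2.0, 2.0])), 0.0)

    def test_ties_get_average_ranks(self):
        out = inverse_normal(np.array([1.0, 1.0, 5.0, 9.0]))
        assert out[0] == out[1]


class TestLd:
    def test_identical_vectors_r2_one(self):
        d = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
        assert ld_r2(d, d) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(11)
        d1 = rng.binomial(2, 0.3, size=10_000).astype(float)
        d2 = rng.binomial(2, 0.3, size=10_000).astype(float)
        assert ld_r2(d1, d2) < 0.01

    def test_constant_vector_zero(self):
        assert ld_r2(np.ones(10), np.arange(10.0)) == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ld_r2(np.array([1.0, np.nan, 2.0]), np.array([1.0, 2.0, np.nan]))

    def test_prune_perfect_pair_keeps_one(self, rng):
        d = rng.binomial(2, 0.4, size=50).astype(float)
        g = study(np.vstack([d, d]))
        kept = prune_ld(g)
        assert kept == ["v0"]  # later-positioned variant dropped

    def test_prune_keeps_unlinked(self, rng):
        d1 = rng.binomial(2, 0.4, size=200).astype(float)
        d2 = rng.binomial(2, 0.4, size=200).astype(float)
        g = study(np.vstack([d1, d2]))
        assert prune_ld(g) == ["v0", "v1"]


class TestGenotypePcs:
    def _two_cluster_study(self, rng, n_per=30, n_var=100):
        freqs_a = rng.uniform(0.1, 0.4, size=n_var)
        freqs_b = np.clip(freqs_a + 0.4, 0, 1)
        a = rng.binomial(2, freqs_a[:, None], size=(n_var, n_per))
        b = rng.binomial(2, freqs_b[:, None], size=(n_var, n_per))
        return study(np.hstack([a, b]).astype(float)), n_per

    def test_pc1_separates_clusters(self, rng):
        g, n_per = self._two_cluster_study(rng)
        scores = genotype_pcs(g, k=3)
        pc1 = scores["PC1"].to_numpy()
        lo, hi = pc1[:n_per], pc1[n_per:]
        assert max(lo.max(), hi.max()) > min(lo.min(), hi.min())
        assert (lo.max() < hi.min()) or (hi.max() < lo.min())

    def test_scores_orthogonal(self, rng):
        g, _ = self._two_cluster_study(rng)
        scores = genotype_pcs(g, k=3).to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_duplicated_variants_scale_scores(self, rng):
        g, _ = self._two_cluster_study(rng)
        doubled = study(np.vstack([g.dosage, g.dosage]))
        s1 = genotype_pcs(g, k=2).to_numpy()
        s2 = genotype_pcs(doubled, k=2).to_numpy()
        np.testing.assert_allclose(s2, s1 * math.sqrt(2), rtol=1e-8)

    def test_k_too_large(self, rng):
        g = study(rng.integers(0, 3, size=(5, 4)).astype(float))
        with pytest.raises(ValueError):
            genotype_pcs(g, k=4)

    def test_missing_mean_imputed(self, rng):
        g, _ = self._two_cluster_study(rng)
        g.dosage[0, 0] = np.nan
        scores = genotype_pcs(g, k=2)
        assert np.isfinite(scores.to_numpy()).all()


class TestFactorSchedule:
    @pytest.mark.parametrize(
        "n,k", [(10, 15), (149, 15), (150, 30), (249, 30), (250, 45), (349, 45), (350, 60), (1000, 60)]
    )
    def test_schedule(self, n, k):
        assert factor_count_schedule(n) == k

    def test_hidden_factors_clipped(self, rng):
        expr = pd.DataFrame(rng.random((30, 10)))
        factors = hidden_factors(expr)
        assert factors.shape[1] <= 9


def _qtl_fixture(seed=5, n=100, n_var=10, beta=1.0, maf=0.3, planted=0):
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, maf, size=(n_var, n)).astype(float)
    g = study(dosage, positions=[500_000 + 1000 * i for i in range(n_var)])
    y = rng.normal(size=n)
    if beta:
        y = y + beta * dosage[planted]
    expr = pd.DataFrame([y], index=["L1"], columns=g.individuals)
    tss_map = {"L1": ("chr1", 500_000)}
    return expr, tss_map, g


class TestCisScan:
    def test_planted_beta_recovered(self):
        expr, tss_map, g = _qtl_fixture(beta=1.0)
        res = cis_scan(inverse_normal_rows(expr), tss_map, g)
        best = res.loc[res["p_nominal"].idxmin()]
        assert best["variant_id"] == "v0"
        # INT compresses the effect; beta=1 raw with unit noise ~0.55 INT units
        assert abs(best["beta"]) > 2 * best["se"]

    def test_window_boundary(self):
        rng = np.random.default_rng(3)
        dosage = rng.binomial(2, 0.3, size=(2, 50)).astype(float)
        g = study(dosage, positions=[1_500_000, 1_500_001])  # tss 500_000
        expr = pd.DataFrame([rng.normal(size=50)], index=["L1"], columns=g.individuals)
        res = cis_scan(expr, {"L1": ("chr1", 500_000)}, g, min_obs=20)
        assert set(res["variant_id"]) == {"v0"}  # exactly 1 Mb included, +1 excluded

    def test_null_p_uniform(self):
        rng = np.random.default_rng(17)
        pvals = []
        for i in range(100):
            dosage = rng.binomial(2, 0.3, size=(20, 150)).astype(float)
            g = study(dosage, positions=[400_000 + 1000 * j for j in range(20)])
            expr = pd.DataFrame(
                [rng.normal(size=150)], index=["L1"], columns=g.individuals
            )
            res = cis_scan(expr, {"L1": ("chr1", 500_000)}, g)
            pvals.extend(res["p_nominal"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_covariate_residualization(self):
        # expression driven entirely by a covariate: no association remains
        rng = np.random.default_rng(23)
        dosage = rng.binomial(2, 0.3, size=(5, 200)).astype(float)
        g = study(dosage, positions=[500_000 + i for i in range(5)])
        confound = rng.normal(size=200)
        expr = pd.DataFrame([5 * confound + rng.normal(size=200) * 0.1], index=["L1"], columns=g.individuals)
        cov = pd.DataFrame({"c1": confound}, index=g.individuals)
        res_with = cis_scan(expr, {"L1": ("chr1", 500_000)}, g, covariates=cov)
        assert (res_with["p_nominal"] > 0.001).all()


class TestPermutationPass:
    def test_exhaustive_matches_bruteforce_oracle(self):
        """n=5 samples, all 120 permutations: empirical p equals the add-one
        exhaustive rank computed by an independent regression oracle."""
        rng = np.random.default_rng(9)
        n = 5
        dosage = np.array(
            [[0, 1, 2, 1, 0], [2, 1, 0, 0, 1], [1, 1, 0, 2, 0]], dtype=float
        )
        g = study(dosage, positions=[499_000, 500_000, 501_000])
        y = rng.normal(size=n)
        expr = pd.DataFrame([y], index=["L1"], columns=g.individuals)
        tss_map = {"L1": ("chr1", 500_000)}
        res = permutation_pass(expr, tss_map, g, n_perm=0, exhaustive=True, min_obs=3)
        # oracle: min nominal p over variants for every permutation
        def min_p(y_perm):
            ps = []
            for row in dosage:
                fit = stats.linregress(row, y_perm)
                ps.append(fit.pvalue)
            return min(ps)

        obs = min_p(y)
        count = sum(
            1
            for perm in itertools.permutations(range(n))
            if min_p(y[list(perm)]) <= obs + 1e-12
        )
        expected = (1 + count) / (1 + math.factorial(n))
        assert res.iloc[0]["p_perm"] == pytest.approx(expected)

    def test_null_empirical_p_not_tiny(self):
        expr, tss_map, g = _qtl_fixture(seed=31, beta=0.0)
        res = permutation_pass(expr, tss_map, g, n_perm=200, seed=1)
        assert res.iloc[0]["p_perm"] >= 1 / 201

    def test_strong_qtl_minimal_p_and_called(self):
        expr, tss_map, g = _qtl_fixture(seed=13, beta=2.0)
        res = permutation_pass(inverse_normal_rows(expr), tss_map, g, n_perm=500, seed=2)
        assert res.iloc[0]["p_perm"] == pytest.approx(1 / 501)
        called = call_ehervs(res)
        assert bool(called.iloc[0]["is_eherv"]) is True

    def test_masking_equivalent_to_removal(self):
        expr, tss_map, g = _qtl_fixture(seed=41, beta=1.0)
        masked = expr.copy()
        masked.iloc[0, :10] = np.nan
        res_masked = permutation_pass(masked, tss_map, g, n_perm=100, seed=3, min_obs=10)
        g_sub = GenotypeStudy(
            dosage=g.dosage[:, 10:], variants=g.variants, individuals=g.individuals[10:]
        )
        res_removed = permutation_pass(
            expr[g.individuals[10:]], tss_map, g_sub, n_perm=100, seed=3, min_obs=10
        )
        assert res_masked.iloc[0]["p_perm"] == res_removed.iloc[0]["p_perm"]
        assert res_masked.iloc[0]["p_nominal_min"] == pytest.approx(
            res_removed.iloc[0]["p_nominal_min"]
        )


class TestMatchedBackground:
    def _variants(self, rng, n, prefix, chrom="chr1"):
        return pd.DataFrame(
            {
                "variant_id": [f"{prefix}{i}" for i in range(n)],
                "chrom": chrom,
                "pos": rng.integers(0, 2_000_000, size=n),
                "maf": rng.uniform(0.01, 0.5, size=n),
            }
        )

    def test_shifted_copy_matches_all(self, rng):
        targets = self._variants(rng, 50, "t")
        pool = targets.copy()
        pool["variant_id"] = [f"p{i}" for i in range(50)]
        tss = {"chr1": [0, 1_000_000, 2_000_000]}
        matched, kept = matched_background(targets, pool, tss, seed=0)
        assert len(matched) == len(kept) == 50

    def test_maf_distribution_reproduced(self):
        rng = np.random.default_rng(6)
        targets = self._variants(rng, 500, "t")
        pool = self._variants(rng, 20_000, "p")
        tss = {"chr1": [0, 500_000, 1_000_000, 1_500_000, 2_000_000]}
        matched, kept = matched_background(targets, pool, tss, seed=0)
        maf_by_id = dict(zip(pool["variant_id"], pool["maf"]))
        matched_maf = [maf_by_id[v] for v in matched]
        kept_maf = dict(zip(targets["variant_id"], targets["maf"]))
        target_maf = [kept_maf[v] for v in kept]
        ks = stats.ks_2samp(matched_maf, target_maf)
        assert ks.pvalue > 0.05

    def test_seed_determinism_and_variation(self, rng):
        targets = self._variants(rng, 100, "t")
        pool = self._variants(rng, 5000, "p")
        tss = {"chr1": [0, 1_000_000]}
        m1, _ = matched_background(targets, pool, tss, seed=1)
        m1b, _ = matched_background(targets, pool, tss, seed=1)
        m2, _ = matched_background(targets, pool, tss, seed=2)
        assert m1 == m1b
        assert m1 != m2

    def test_pool_overlap_rejected(self, rng):
        targets = self._variants(rng, 10, "t")
        with pytest.raises(ValueError):
            matched_background(targets, targets, {"chr1": [0]}, seed=0)


class TestEnrichment:
    def test_cross_product_or(self):
        annotation = {}
        targets, background = [], []
        for i in range(100):
            vid = f"t{i}"
            targets.append(vid)
            annotation[vid] = {"cat"} if i < 10 else {"other"}
        for i in range(100):
            vid = f"b{i}"
            background.append(vid)
            annotation[vid] = {"cat"} if i < 1 else {"other"}
        res = enrichment_test(targets, background, annotation)
        row = res[res.category == "cat"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(11.0)

    def test_p_matches_hypergeometric_oracle(self):
        """Two-tailed Fisher p equals the sum of hypergeometric point
        probabilities <= the observed one (margins fixed)."""
        rng = np.random.default_rng(19)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 40, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n = a + b + c + d
            k_total = a + c
            row1 = a + b
            p_obs = stats.hypergeom.pmf(a, n, k_total, row1)
            p_two = sum(
                stats.hypergeom.pmf(k, n, k_total, row1)
                for k in range(max(0, k_total - (c + d)), min(row1, k_total) + 1)
                if stats.hypergeom.pmf(k, n, k_total, row1) <= p_obs * (1 + 1e-7)
            )
            scipy_p = stats.fisher_exact([[a, b], [c, d]])[1]
            assert scipy_p == pytest.approx(min(p_two, 1.0), rel=1e-6)

    def test_identical_frequencies_null(self):
        annotation = {f"t{i}": {"cat"} for i in range(10)}
        annotation.update({f"b{i}": {"cat"} for i in range(10)})
        annotation.update({f"t{i}": {"x"} for i in range(10, 20)})
        annotation.update({f"b{i}": {"x"} for i in range(10, 20)})
        res = enrichment_test(
            [f"t{i}" for i in range(20)], [f"b{i}" for i in range(20)], annotation
        )
        row = res[res.category == "cat"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_drop_categories_absent_from_output(self):
        annotation = {
            "t0": {"splicing", "intronic"},
            "b0": {"stopgain", "intronic"},
        }
        res = enrichment_test(
            ["t0"], ["b0"], annotation, drop_categories=["splicing", "stopgain", "stoploss", "ncRNA_splicing"]
        )
        assert set(res["category"]) == {"intronic"}

    def test_zero_cell_continuity_correction(self):
        annotation = {f"t{i}": {"cat"} for i in range(5)}
        annotation.update({f"b{i}": {"other"} for i in range(5)})
        res = enrichment_test([f"t{i}" for i in range(5)], [f"b{i}" for i in range(5)], annotation)
        row = res[res.category == "cat"].iloc[0]
        assert np.isfinite(row["odds_ratio"])
        assert row["odds_ratio"] == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(["a"], ["a"], {"a": {"x"}})


class TestExpandGwasLd:
    def test_linked_neighbour_included(self, rng):
        d = rng.binomial(2, 0.4, size=100).astype(float)
        g = study(np.vstack([d, d, rng.binomial(2, 0.4, size=100)]))
        hits = pd.DataFrame({"variant_id": ["v0"], "p": [1e-9]})
        out = expand_gwas_ld(hits, g)
        assert "v0" in out and "v1" in out and "v2" not in out

    def test_exact_threshold_excluded(self, rng):
        d = rng.binomial(2, 0.4, size=100).astype(float)
        g = study(d[None, :])
        hits = pd.DataFrame({"variant_id": ["v0"], "p": [5e-8]})
        assert expand_gwas_ld(hits, g) == []

    def test_r2_below_threshold_excluded(self):
        rng = np.random.default_rng(77)
        d1 = rng.binomial(2, 0.5, size=2000).astype(float)
        noise = rng.random(2000) < 0.25
        d2 = np.where(noise, rng.binomial(2, 0.5, size=2000), d1).astype(float)
        r2 = ld_r2(d1, d2)
        assert r2 < 0.8  # construction check
        g = study(np.vstack([d1, d2]))
        hits = pd.DataFrame({"variant_id": ["v0"], "p": [1e-10]})
        assert expand_gwas_ld(hits, g) == ["v0"]

    def test_absent_hit_kept_without_expansion(self, rng):
        g = study(rng.binomial(2, 0.4, size=(1, 50)).astype(float))
        hits = pd.DataFrame({"variant_id": ["rs_missing"], "p": [1e-9]})
        assert expand_gwas_ld(hits, g) == ["rs_missing"]
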