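import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hlase.eqtl import (QcThresholds, choose_covariate_count, cis_scan,
                        compute_pcs, fdr_select, gene_permutation_p, hwe_test,
                        interaction_test, inverse_normal_transform, ld_r2, pi1,
                        pi1_grid, qc_filter_variants, residualize)
from hlase.io import GenotypeMatrix

from test_io import _toy_matrix


def exact_hwe_p(n_rr, n_ra, n_aa):
    """Exact Hardy-Weinberg oracle: enumerate every heterozygote count
    compatible with the allele counts, order outcomes by the goodness-of-fit
    statistic, and return the mid-p tail (half weight on the observed
    outcome class) — the exact-test variant whose behavior matches an
    asymptotic test without the discreteness bias of the full tail."""
    n = n_rr + n_ra + n_aa
    n_a = n_ra + 2 * n_aa  # condition on the alt-allele count
    from math import lgamma

    def logprob(het):
        hom_a = (n_a - het) // 2
        hom_r = n - het - hom_a
        return (lgamma(n + 1) - lgamma(hom_r + 1) - lgamma(het + 1)
                - lgamma(hom_a + 1) + het * math.log(2)
                + lgamma(n_a + 1) + lgamma(2 * n - n_a + 1) - lgamma(2 * n + 1))

    def chi2(het):
        hom_a = (n_a - het) // 2
        hom_r = n - het - hom_a
        p = (2 * hom_r + het) / (2 * n)
        q = 1.0 - p
        exp = [n * p * p, 2 * n * p * q, n * q * q]
        return sum((o - e) ** 2 / e for o, e in zip([hom_r, het, hom_a], exp))

    hets = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    obs = chi2(n_ra)
    gt = sum(math.exp(logprob(h)) for h in hets if chi2(h) > obs + 1e-12)
    eq = sum(math.exp(logprob(h)) for h in hets if abs(chi2(h) - obs) <= 1e-12)
    return min(1.0, gt + 0.5 * eq)


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_complete_het_deficit(self):
        # chi-square equals n; p = sf(100, df=1)
        p = hwe_test(50, 0, 50)
        assert p == pytest.approx(stats.chi2.sf(100, 1), rel=1e-9)
        assert p < 1e-22

    def test_monomorphic_p_one(self):
        assert hwe_test(100, 0, 0) == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)

    def test_within_twofold_of_exact_enumeration(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 50:
            n = int(rng.integers(20, 200))
            q = rng.uniform(0.1, 0.5)
            geno = rng.binomial(2, q, size=n)
            counts = [(geno == k).sum() for k in (0, 1, 2)]
            if counts[1] == 0 or min(counts[0] + counts[1], counts[1] + counts[2]) == 0:
                continue
            p_chi = hwe_test(*counts)
            p_exact = exact_hwe_p(*counts)
            if p_exact < 1e-4:
                continue
            assert 0.5 < p_chi / p_exact < 2.0
            checked += 1


class TestQcFilter:
    def _matrix(self):
        rng = np.random.default_rng(1)
        n = 200
        cols = []
        # passing variant, HWE, MAF 0.3
        cols.append(rng.binomial(2, 0.3, n).astype(float))
        # MAF 0.005: one het among 200 -> removed "maf"
        v = np.zeros(n); v[0] = 1.0; cols.append(v)
        # missingness 0.03 -> removed "missing"
        v = rng.binomial(2, 0.4, n).astype(float); v[:6] = np.nan; cols.append(v)
        # HWE catastrophe: no hets at 50/50 -> removed "hwe"
        v = np.array([0.0] * 100 + [2.0] * 100); cols.append(v)
        return _toy_matrix(np.column_stack(cols))

    def test_fates(self):
        gm = self._matrix()
        kept, fate = qc_filter_variants(gm, QcThresholds())
        assert fate["fate"].tolist() == ["pass", "maf", "missing", "hwe"]
        assert kept.n_variants == 1

    def test_matches_per_rule_oracle(self):
        rng = np.random.default_rng(2)
        n, m = 150, 100
        dosages = rng.binomial(2, rng.uniform(0.0, 0.5, m), size=(n, m)).astype(float)
        dosages[rng.random((n, m)) < 0.02] = np.nan
        gm = _toy_matrix(dosages)
        thr = QcThresholds()
        kept, fate = qc_filter_variants(gm, thr)
        for j in range(m):
            col = dosages[:, j]
            ok = ~np.isnan(col)
            af = col[ok].mean() / 2 if ok.any() else np.nan
            maf = min(af, 1 - af) if not np.isnan(af) else np.nan
            counts = [(col[ok] == k).sum() for k in (0, 1, 2)]
            expected_pass = (not np.isnan(maf) and maf >= thr.maf_min
                             and (~ok).mean() <= thr.missing_max
                             and hwe_test(*counts) >= thr.hwe_p_min)
            assert (fate.loc[j, "fate"] == "pass") == expected_pass

    def test_idempotent(self):
        gm = self._matrix()
        kept, _ = qc_filter_variants(gm)
        kept2, fate2 = qc_filter_variants(kept)
        assert (fate2["fate"] == "pass").all()
        np.testing.assert_array_equal(kept.dosages, kept2.dosages)


class TestNormalization:
    def test_closed_form_n3(self):
        out = inverse_normal_transform([10.0, 2.0, 5.0])
        expected = stats.norm.ppf([5 / 6, 1 / 6, 3 / 6])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[1] == pytest.approx(-0.9674, abs=1e-4)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        np.testing.assert_allclose(inverse_normal_transform(x),
                                   inverse_normal_transform(np.exp(x)), atol=1e-12)

    def test_standardized_output(self):
        rng = np.random.default_rng(4)
        out = inverse_normal_transform(rng.normal(size=500))
        assert abs(out.mean()) < 0.01
        assert abs(out.std() - 1.0) < 0.02

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([1.0, 1.0, 1.0])


class TestResidualize:
    def test_orthogonal_covariates_center_only(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to linear trend
        np.testing.assert_allclose(residualize(y, c), y - y.mean(), atol=1e-12)

    def test_phenotype_in_span(self):
        rng = np.random.default_rng(5)
        C = rng.normal(size=(30, 2))
        y = 2.0 + C @ np.array([1.5, -0.5])
        np.testing.assert_allclose(residualize(y, C), 0.0, atol=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(6)
        C = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        X = np.column_stack([np.ones(40), C])
        oracle = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(residualize(y, C), oracle, atol=1e-10)

    def test_rank_deficiency_rejected(self):
        C = np.ones((10, 1))  # collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            residualize(np.arange(10.0), C)


class TestComputePcs:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(7)
        u = rng.normal(size=50)
        X = np.outer(u, rng.normal(size=20))
        scores = compute_pcs(X, 1)
        r = np.corrcoef(scores[:, 0], u)[0, 1]
        assert abs(r) > 0.9999

    def test_planted_orthogonal_directions(self):
        rng = np.random.default_rng(8)
        u1, u2 = rng.normal(size=(2, 200))
        u2 -= u2 @ u1 / (u1 @ u1) * u1
        X = (3.0 * np.outer(u1, rng.normal(size=30))
             + 1.0 * np.outer(u2, rng.normal(size=30))
             + 0.01 * rng.normal(size=(200, 30)))
        scores = compute_pcs(X, 2)
        assert abs(np.corrcoef(scores[:, 0], u1)[0, 1]) > 0.99
        assert abs(np.corrcoef(scores[:, 1], u2)[0, 1]) > 0.99

    def test_k_zero_and_k_too_large(self):
        X = np.zeros((5, 3))
        assert compute_pcs(X, 0).shape == (5, 0)
        with pytest.raises(ValueError):
            compute_pcs(X, 4)

    def test_scores_standardized(self):
        rng = np.random.default_rng(9)
        scores = compute_pcs(rng.normal(size=(60, 10)), 3)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(scores.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestCisScan:
    def test_phenotype_equal_to_dosage(self):
        rng = np.random.default_rng(10)
        dos = rng.binomial(2, 0.4, 100).astype(float)
        gm = _toy_matrix(dos[:, None])
        table, best = cis_scan(dos, gm, "6", 100)
        assert best.r2 == pytest.approx(1.0)
        assert best.nominal_p < 1e-100

    def test_null_p_uniform(self):
        rng = np.random.default_rng(11)
        dosages = rng.binomial(2, 0.3, size=(200, 500)).astype(float)
        gm = _toy_matrix(dosages)
        y = rng.normal(size=200)
        table, _ = cis_scan(y, gm, "6", 25_000)
        _, p = stats.kstest(table["nominal_p"], "uniform")
        assert p > 0.01

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(12)
        dosages = rng.binomial(2, 0.3, size=(80, 5)).astype(float)
        gm = _toy_matrix(dosages)
        y = rng.normal(size=80) + dosages[:, 2]
        table, _ = cis_scan(y, gm, "6", 300)
        for j in range(5):
            r = np.corrcoef(dosages[:, j], y)[0, 1]
            assert table.loc[j, "r2"] == pytest.approx(r ** 2, abs=1e-12)

    def test_tie_break_by_distance_then_id(self):
        dos = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0] * 10)
        dosages = np.column_stack([dos, dos])  # identical -> tied p
        gm = _toy_matrix(dosages, positions=[100, 400])
        y = dos + 0.1
        _, best = cis_scan(y, gm, "6", 350)  # 400 is 50 away, 100 is 250 away
        assert best.variant_id == "6:400:A:G"

    def test_empty_window(self):
        gm = _toy_matrix(np.zeros((10, 1)), positions=[100])
        with pytest.raises(ValueError, match="no variants"):
            cis_scan(np.zeros(10), gm, "7", 100)

    def test_planted_variant_variance_explained(self):
        # r^2 = 2pq b^2 / (2pq b^2 + sigma^2) = 0.5; a single n=2000 draw
        # has MC SD ~0.016, so measure the mean over replicates
        n, beta = 2000, math.sqrt(2.0)
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            dos = rng.binomial(2, 0.5, n).astype(float)
            y = beta * dos + rng.normal(size=n)
            _, best = cis_scan(y, _toy_matrix(dos[:, None]), "6", 100)
            r2s.append(best.r2)
        assert np.mean(r2s) == pytest.approx(0.50, abs=0.02)


class TestGenePermutationP:
    def test_single_variant_gene_p_close_to_nominal(self):
        rng = np.random.default_rng(14)
        dos = rng.binomial(2, 0.4, 120).astype(float)
        y = 0.22 * dos + rng.normal(size=120)
        gm = _toy_matrix(dos[:, None])
        res = gene_permutation_p(y, gm, "6", 100, R=1000, rng=rng)
        se = math.sqrt(res.nominal_p * (1 - res.nominal_p) / 1000)
        assert abs(res.empirical_p - res.nominal_p) < max(4 * se, 0.02)

    def test_null_calibration(self):
        # under a global null the empirical gene-level p is uniform on its
        # support: P(p <= alpha) ~ alpha
        rng = np.random.default_rng(15)
        dosages = rng.binomial(2, 0.3, size=(60, 20)).astype(float)
        gm = _toy_matrix(dosages)
        ps = []
        for seed in range(200):
            y = np.random.default_rng(1000 + seed).normal(size=60)
            res = gene_permutation_p(y, gm, "6", 1000, R=100,
                                     rng=np.random.default_rng(seed))
            ps.append(res.empirical_p)
        ps = np.array(ps)
        for alpha in (0.1, 0.25, 0.5):
            rate = (ps <= alpha).mean()
            assert abs(rate - alpha) < 0.12

    def test_beta_p_tracks_empirical_p(self):
        rng = np.random.default_rng(16)
        dosages = rng.binomial(2, 0.3, size=(100, 30)).astype(float)
        gm = _toy_matrix(dosages)
        checked = 0
        for seed in range(30):
            g = np.random.default_rng(seed)
            y = 0.17 * dosages[:, 0] + g.normal(size=100)
            res = gene_permutation_p(y, gm, "6", 1500, R=1000,
                                     rng=np.random.default_rng(seed))
            if 0.01 <= res.empirical_p <= 0.5:
                assert 0.7 < res.beta_p / res.empirical_p < 1.3
                checked += 1
        assert checked >= 5

    def test_small_r_rejected(self):
        gm = _toy_matrix(np.zeros((10, 1)))
        with pytest.raises(ValueError, match="R"):
            gene_permutation_p(np.zeros(10), gm, "6", 100, R=10)


class TestFdrSelect:
    def test_all_tiny_p_selected(self):
        genes, _ = fdr_select({f"g{i}": 1e-10 for i in range(100)})
        assert len(genes) == 100

    def test_uniform_null_selects_none(self):
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = pd.Series(rng.uniform(size=1000),
                          index=[f"g{i}" for i in range(1000)])
            genes, _ = fdr_select(p)
            hits.append(len(genes))
        assert sorted(hits)[int(0.95 * len(hits)) - 1] <= 2

    def test_worked_example_matches_step_up_oracle(self):
        p = {"a": 0.001, "b": 0.008, "c": 0.039, "d": 0.041, "e": 0.9}
        genes, thr = fdr_select(p, level=0.05)
        assert set(genes) == {"a", "b"}

        def bh_oracle(pvals, alpha):
            s = sorted(pvals.items(), key=lambda kv: kv[1])
            m = len(s)
            kmax = 0
            for i, (_, pv) in enumerate(s, start=1):
                if pv <= alpha * i / m:
                    kmax = i
            return {k for k, _ in s[:kmax]}

        rng = np.random.default_rng(17)
        for _ in range(20):
            pvals = {f"g{i}": float(v) for i, v in
                     enumerate(rng.uniform(size=50) ** rng.uniform(1, 3))}
            genes, _ = fdr_select(pvals, level=0.05)
            assert set(genes) == bh_oracle(pvals, 0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_select({})


class TestInteraction:
    def _paired(self, seed, n, b_unstim, b_stim, sigma=1.0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.4, n).astype(float)
        u = rng.normal(size=n)  # per-individual baseline
        ids = [f"S{i}" for i in range(n)]
        yu = pd.Series(u + b_unstim * g + sigma * rng.normal(size=n), index=ids)
        ys = pd.Series(u + 0.5 + b_stim * g + sigma * rng.normal(size=n), index=ids)
        return yu, ys, pd.Series(g, index=ids)

    def test_type_i_error_calibrated(self):
        # exact paired t reference at n=55; 1000 replicates keep the MC SD
        # of the rejection rate (~0.7pp) well inside the 5% +/- 2pp band
        rejections = 0
        for seed in range(1000):
            yu, ys, g = self._paired(seed, 55, 0.4, 0.4)
            res = interaction_test(yu, ys, g)
            rejections += res.interaction_p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_power_for_doubled_slope(self):
        hits = 0
        for seed in range(50):
            yu, ys, g = self._paired(seed, 200, 0.5, 1.0, sigma=0.7)
            res = interaction_test(yu, ys, g)
            hits += (res.interaction_effect > 0) and (res.interaction_p < 0.05)
        assert hits >= 40

    def test_per_condition_slopes_consistent(self):
        yu, ys, g = self._paired(0, 100, 0.3, 0.9)
        res = interaction_test(yu, ys, g)
        assert res.slope_stim - res.slope_unstim == pytest.approx(
            res.interaction_effect, abs=1e-10)
        assert res.genotype_effect == res.slope_unstim

    def test_constant_genotype_rejected(self):
        ids = ["S0", "S1", "S2"]
        y = pd.Series([1.0, 2.0, 3.0], index=ids)
        g = pd.Series([1.0, 1.0, 1.0], index=ids)
        with pytest.raises(ValueError, match="constant"):
            interaction_test(y, y, g)

    def test_unpaired_dropped(self):
        yu, ys, g = self._paired(1, 30, 0.4, 0.8)
        res = interaction_test(yu.iloc[:-3], ys, g)
        assert res.n_pairs == 27 and res.n_dropped == 3


class TestPi1:
    def test_pure_null(self):
        rng = np.random.default_rng(18)
        est = pi1(rng.uniform(size=10_000))
        assert abs(est.pi1) <= 0.03

    def test_pure_alternative(self):
        est = pi1(np.full(100, 1e-7))
        assert est.pi1 == 1.0

    @pytest.mark.parametrize("f", [0.2, 0.34, 0.5])
    def test_mixture_recovery(self, f):
        rng = np.random.default_rng(int(f * 100))
        m = 10_000
        k = int(f * m)
        p = np.concatenate([rng.uniform(0, 1e-4, size=k),
                            rng.uniform(size=m - k)])
        est = pi1(p)
        assert est.pi1 == pytest.approx(f, abs=0.05)

    def test_grid_close_to_single_lambda(self):
        rng = np.random.default_rng(19)
        p = np.concatenate([rng.uniform(0, 1e-4, 3000), rng.uniform(size=7000)])
        assert pi1_grid(p).pi1 == pytest.approx(pi1(p).pi1, abs=0.05)

    def test_too_few_pvalues(self):
        with pytest.raises(ValueError):
            pi1(np.linspace(0.1, 0.9, 10))


class TestLdR2:
    def test_identical_vectors(self):
        rng = np.random.default_rng(20)
        dos = rng.binomial(2, 0.3, 50).astype(float)
        gm = _toy_matrix(np.column_stack([dos, dos]))
        assert ld_r2(gm, "6:100:A:G", "6:200:A:G") == pytest.approx(1.0)

    def test_independent_variants(self):
        rng = np.random.default_rng(21)
        gm = _toy_matrix(rng.binomial(2, 0.4, size=(10_000, 2)).astype(float))
        assert ld_r2(gm, "6:100:A:G", "6:200:A:G") <= 0.01

    def test_haplotype_fixture_matches_d_squared_identity(self):
        # draw chromosomes from 4 two-marker haplotypes with known
        # frequencies; r^2 of dosages must match D^2/(p1 q1 p2 q2)
        rng = np.random.default_rng(22)
        hap_freqs = {(1, 1): 0.35, (1, 0): 0.15, (0, 1): 0.10, (0, 0): 0.40}
        haps = list(hap_freqs)
        idx = rng.choice(4, size=(10_000, 2), p=list(hap_freqs.values()))
        chrom = np.array(haps)[idx]  # (n, 2 copies, 2 markers)
        dosages = chrom.sum(axis=1).astype(float)
        gm = _toy_matrix(dosages)
        # oracle from realized chromosome-level frequencies
        flat = chrom.reshape(-1, 2)
        p1, p2 = flat.mean(axis=0)
        p11 = float(np.mean((flat[:, 0] == 1) & (flat[:, 1] == 1)))
        D = p11 - p1 * p2
        oracle = D ** 2 / (p1 * (1 - p1) * p2 * (1 - p2))
        assert ld_r2(gm, "6:100:A:G", "6:200:A:G") == pytest.approx(oracle, abs=0.02)

    def test_monomorphic_rejected(self):
        gm = _toy_matrix(np.column_stack([np.zeros(10), np.arange(10) % 3]).astype(float))
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(gm, "6:100:A:G", "6:200:A:G")


class TestChooseCovariateCount:
    def _tss(self, genes):
        return pd.DataFrame({"gene": genes, "chrom": "6",
                             "tss": 5000, "strand": "+"}).set_index("gene")

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(23)
        gm = _toy_matrix(rng.binomial(2, 0.3, size=(40, 3)).astype(float))
        pheno = pd.DataFrame(rng.normal(size=(2, 40)), index=["g1", "g2"],
                             columns=gm.sample_ids)
        k, counts = choose_covariate_count(pheno, gm, self._tss(["g1", "g2"]),
                                           [2], R=100, rng=0)
        assert k == 2 and set(counts) == {2}

    def test_confounder_removal_increases_egenes(self):
        rng = np.random.default_rng(24)
        n, genes = 80, 8
        dosages = rng.binomial(2, 0.4, size=(n, 4)).astype(float)
        gm = _toy_matrix(dosages)
        confounder = rng.normal(size=n)
        pheno = {}
        for i in range(genes):
            signal = 0.8 * dosages[:, i % 4]
            pheno[f"g{i}"] = signal + 2.5 * confounder + 0.5 * rng.normal(size=n)
        pheno = pd.DataFrame(pheno).T
        pheno.columns = gm.sample_ids
        k, counts = choose_covariate_count(pheno, gm, self._tss(list(pheno.index)),
                                           [0, 1], R=200, rng=1)
        assert counts[1] > counts[0]
        assert k == 1

    def test_pure_noise_prefers_smallest_k(self):
        rng = np.random.default_rng(25)
        gm = _toy_matrix(rng.binomial(2, 0.3, size=(50, 3)).astype(float))
        pheno = pd.DataFrame(rng.normal(size=(5, 50)),
                             index=[f"g{i}" for i in range(5)],
                             columns=gm.sample_ids)
        k, counts = choose_covariate_count(pheno, gm, self._tss(list(pheno.index)),
                                           [0, 1, 2], R=100, rng=2)
        assert k == min(counts, key=lambda kk: (-counts[kk], kk))
        if len(set(counts.values())) == 1:
            assert k == 0
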