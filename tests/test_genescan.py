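"""Marker filtering, association scan, epistasis, segregation test, G-BLUP."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wheatpheno import genescan, simulate as sim
from wheatpheno.core import GenotypeMatrix, TraitArchitecture


def make_matrix(dose, positions=None):
    dose = np.asarray(dose, dtype=float)
    n, m = dose.shape
    markers = pd.DataFrame(
        {"marker": [f"m{j}" for j in range(m)], "chrom": "chr1",
         "pos_cm": positions if positions is not None else np.arange(m, dtype=float)}
    )
    return GenotypeMatrix([f"L{i}" for i in range(n)], markers, dose)


class TestFilterMarkers:
    def test_threshold_rules(self):
        n = 100
        rng = np.random.default_rng(1)
        good = rng.choice([0.0, 2.0], size=n)
        low_maf = np.concatenate([np.full(9, 2.0), np.zeros(n - 9)])  # MAF 0.09
        missing = good.copy()
        missing[:31] = np.nan  # 31% missing
        het = good.copy()
        het[:7] = 1.0  # 7% het
        G = make_matrix(np.column_stack([good, low_maf, missing, het]))
        Gf, report = genescan.filter_markers(G)
        assert Gf.marker_ids == ["m0"]
        assert report["removed_maf"] == 1
        assert report["removed_missing"] == 1
        assert report["removed_het"] == 1

    def test_matches_brute_force(self, ril_population):
        rng = np.random.default_rng(2)
        dose = ril_population.dose.copy()
        mask = rng.uniform(size=dose.shape) < 0.1
        dose[mask] = np.nan
        G = GenotypeMatrix(ril_population.line_ids, ril_population.markers, dose)
        Gf, _ = genescan.filter_markers(G)
        kept = set(Gf.marker_ids)
        for j, mid in enumerate(G.marker_ids):
            col = dose[:, j]
            obs = col[~np.isnan(col)]
            f = obs.sum() / (2 * obs.size)
            expect = (
                min(f, 1 - f) >= 0.1
                and np.isnan(col).mean() <= 0.30
                and (obs == 1).mean() <= 0.06
            )
            assert (mid in kept) == expect

    def test_idempotent(self, ril_population):
        G1, _ = genescan.filter_markers(ril_population)
        G2, rep2 = genescan.filter_markers(G1)
        assert G1.marker_ids == G2.marker_ids
        assert rep2["n_retained"] == rep2["n_input"]
        assert np.array_equal(G1.dose, G2.dose, equal_nan=True)


class TestMarkerScan:
    def test_perfect_signal(self):
        rng = np.random.default_rng(3)
        dose = rng.choice([0.0, 2.0], size=(60, 5))
        y = 2.0 * dose[:, 2]
        res = genescan.marker_scan(y, make_matrix(dose))
        assert res.loc[2, "p"] < 1e-20
        assert res.loc[2, "effect"] == pytest.approx(2.0)
        assert res.loc[2, "significant"]

    def test_pvalues_match_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        dose = rng.choice([0.0, 2.0], size=(40, 6))
        y = 0.8 * dose[:, 1] + rng.normal(0, 1, 40)
        res = genescan.marker_scan(y, make_matrix(dose))
        for j in range(6):
            fit = sm.OLS(y, sm.add_constant(dose[:, j])).fit()
            assert res.loc[j, "p"] == pytest.approx(fit.pvalues[1], rel=1e-8)
            assert res.loc[j, "effect"] == pytest.approx(fit.params[1], rel=1e-8)
            assert res.loc[j, "se"] == pytest.approx(fit.bse[1], rel=1e-8)

    def test_monomorphic_marker_flagged(self):
        rng = np.random.default_rng(5)
        dose = np.column_stack([np.zeros(40), rng.choice([0.0, 2.0], 40)])
        y = rng.normal(size=40)
        res = genescan.marker_scan(y, make_matrix(dose))
        assert res.loc[0, "p"] == 1.0
        assert np.isnan(res.loc[0, "effect"])

    def test_het_policies(self):
        dose = np.array([[0.0], [1.0], [2.0]] * 10)
        y = dose[:, 0].copy()
        res_mid = genescan.marker_scan(y, make_matrix(dose), het="midpoint")
        assert res_mid.loc[0, "n"] == 30
        res_miss = genescan.marker_scan(y, make_matrix(dose), het="missing")
        assert res_miss.loc[0, "n"] == 20


class TestBonferroni:
    def test_values(self):
        assert genescan.bonferroni_threshold(0.05, 8237) == pytest.approx(6.07e-6, rel=1e-3)
        assert genescan.bonferroni_threshold(0.05, 1) == 0.05
        ms = [1, 10, 100, 1000]
        ths = [genescan.bonferroni_threshold(0.05, m) for m in ms]
        assert ths == sorted(ths, reverse=True)

    def test_rejects_zero_tests(self):
        with pytest.raises(ValueError):
            genescan.bonferroni_threshold(0.05, 0)


class TestEpistasis:
    def test_pure_interaction_detected(self):
        # oracle: two-way layout where y != 0 only when both loci carry allele B
        rng = np.random.default_rng(6)
        n = 200
        dose = rng.choice([0.0, 2.0], size=(n, 4))
        xa, xb = dose[:, 0] / 2, dose[:, 1] / 2
        y = 3.0 * xa * xb + rng.normal(0, 0.5, n)
        res = genescan.epistasis_scan(y, make_matrix(dose), [0, 1, 2, 3])
        pair = res[(res["index_j"] == 0) & (res["index_k"] == 1)].iloc[0]
        assert pair["significant"]
        assert pair["lod"] > 10
        other = res[(res["index_j"] == 2) & (res["index_k"] == 3)].iloc[0]
        assert not other["significant"]

    def test_interaction_matches_anova_class_means(self):
        # noise-free: interaction coefficient from the four class means
        dose = np.array([[0, 0], [0, 2], [2, 0], [2, 2]] * 25, dtype=float)
        xa, xb = dose[:, 0] - 1, dose[:, 1] - 1
        y = 1.0 + 0.5 * xa + 0.25 * xb + 0.75 * xa * xb
        res = genescan.epistasis_scan(y, make_matrix(dose), [0, 1])
        row = res.iloc[0]
        assert row["epsilon"] == pytest.approx(0.75, abs=1e-10)
        assert row["alpha_j"] == pytest.approx(0.5, abs=1e-10)
        assert row["beta_k"] == pytest.approx(0.25, abs=1e-10)

    def test_lod_zero_when_no_interaction_improvement(self):
        dose = np.array([[0, 0], [0, 2], [2, 0], [2, 2]] * 10, dtype=float)
        y = dose[:, 0] + dose[:, 1]  # purely additive, noise-free
        res = genescan.epistasis_scan(y, make_matrix(dose), [0, 1])
        assert res.iloc[0]["lod"] == pytest.approx(0.0, abs=1e-8)

    def test_additive_trait_interaction_p_uniformish(self):
        # permutation-flavored check: additive signal, noise -> interaction p
        # should not be systematically small
        rng = np.random.default_rng(7)
        ps = []
        for s in range(40):
            dose = rng.choice([0.0, 2.0], size=(120, 2))
            y = dose[:, 0] + dose[:, 1] + rng.normal(0, 1, 120)
            res = genescan.epistasis_scan(y, make_matrix(dose), [0, 1])
            ps.append(res.iloc[0]["p_interaction"])
        assert np.mean(np.array(ps) < 0.05) < 0.2
        assert np.mean(ps) > 0.3

    def test_collinear_pair_skipped(self):
        dose = np.tile(np.array([[0.0], [2.0]]), (10, 2))
        y = np.arange(20.0)
        res = genescan.epistasis_scan(y, make_matrix(np.column_stack([dose[:, 0], dose[:, 0]])), [0, 1])
        assert res.iloc[0]["skipped"]


class TestSegregation:
    def test_exact_three_to_one(self):
        chi2, p = genescan.segregation_test(225, 75)
        assert chi2 == 0.0 and p == 1.0

    def test_even_split_statistic(self):
        # oracle: sum (O-E)^2/E with E = (225, 75): 75^2/225 + 75^2/75 = 100
        chi2, p = genescan.segregation_test(150, 150)
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-20

    def test_dominant_epistasis_enumeration(self):
        assert genescan.dominant_epistasis_proportions() == (0.75, 0.25)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            genescan.segregation_test(0, 0)


class TestGBLUP:
    def test_matches_hand_linear_algebra(self):
        # 5 lines, 3 markers: predict line 4 from the rest with fixed lambda
        dose = np.array(
            [[0, 2, 0], [2, 0, 0], [2, 2, 2], [0, 0, 2], [2, 0, 2]], dtype=float
        )
        y = np.array([1.0, 2.0, 3.0, 1.5, 2.5])
        G = make_matrix(dose)
        K = genescan.genomic_relationship(G)
        # oracle built from definitions, independently of gblup_solve
        freq = dose.mean(axis=0) / 2
        W = dose - 2 * freq
        K_hand = W @ W.T / (2 * np.sum(freq * (1 - freq)))
        assert np.allclose(K, K_hand)
        train = np.array([0, 1, 2, 4])
        lam = 0.7
        A = K_hand[np.ix_(train, train)] + lam * np.eye(4)
        Ai = np.linalg.inv(A)
        mu = (np.ones(4) @ Ai @ y[train]) / (np.ones(4) @ Ai @ np.ones(4))
        g_hand = mu + K_hand[:, train] @ Ai @ (y[train] - mu)
        pred = genescan.gblup_solve(K, y[train], train, lam)
        assert np.allclose(pred, g_hand, atol=1e-10)

    def test_near_perfect_trait_predicts_well(self, ril_population):
        arch = TraitArchitecture(polygenic_var=1.0, intercept=0.0)
        y = sim.genetic_values(ril_population, arch, seed=31)  # heritability 1
        cv = genescan.genomic_prediction_cv(y, ril_population, reps=15, seed=2)
        assert cv.mean_r > 0.8

    def test_h2_half_polygenic_ratio_plausible(self, ril_population):
        rng = np.random.default_rng(8)
        arch = TraitArchitecture(polygenic_var=1.0, intercept=0.0)
        g = sim.genetic_values(ril_population, arch, seed=32)
        y = g + rng.normal(0, 1.0, g.size)  # h2 = 0.5
        cv = genescan.genomic_prediction_cv(y, ril_population, reps=30, seed=3)
        assert 0.0 < cv.variance_modeled < 1.0
        assert 0.2 < cv.h2 < 0.8

    def test_small_population_rejected(self):
        dose = np.random.default_rng(0).choice([0.0, 2.0], size=(10, 4))
        with pytest.raises(ValueError):
            genescan.genomic_prediction_cv(np.zeros(10), make_matrix(dose))

    def test_unknown_method_rejected(self, ril_population):
        with pytest.raises(ValueError):
            genescan.genomic_prediction_cv(np.zeros(300), ril_population, method="bayesA")


def test_interaction_hides_main_effect_in_dummy_coding(ril_population):
    """A locus acting only in the presence of the major locus's allele shows a
    marginal main effect in the genome scan, but its main term vanishes once
    the interaction is modeled with presence/absence coding (the two-locus
    conditional-effect signature)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(9)
    dose = ril_population.dose
    a_idx, c_idx = 10, 50  # different chromosomes
    za = (dose[:, a_idx] == 2).astype(float)
    zc = (dose[:, c_idx] == 2).astype(float)
    y = -2.4 * za * zc + rng.normal(0, 0.5, dose.shape[0])
    scan = genescan.marker_scan(y, ril_population)
    assert scan.loc[c_idx, "significant"]  # marginal effect detected
    X = sm.add_constant(np.column_stack([za, zc, za * zc]))
    fit = sm.OLS(y, X).fit()
    assert fit.pvalues[3] < 1e-10  # interaction term strongly significant
    assert fit.pvalues[2] > 0.01  # main effect of the conditional locus gone
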