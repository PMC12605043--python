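"""Association scans: calibration, oracle equality, multi-locus behaviour."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import toy_geno
from mangogp.gwas import (
    blink_scan,
    bonferroni_threshold,
    farmcpu_scan,
    genotype_class_contrast,
    glm_scan,
    mlmm_scan,
    reliable_snps,
)
from mangogp.relmat import bend, vanraden_grm
from mangogp.simdata import SimConfig, simulate_phenotype, simulate_structured_genotypes


def unstructured(n=300, m=800, seed=0):
    return simulate_structured_genotypes(
        SimConfig(
            n_subpop1=n // 2,
            n_subpop2=n - n // 2,
            fst=0.0,
            n_snps=m,
            n_founder_haps=40,
            switch_rate=5e-4,
            seed=seed,
        )
    )


@pytest.fixture(scope="module")
def major_qtl_panel():
    res = simulate_structured_genotypes(SimConfig(n_snps=1500, seed=11))
    pheno, truth = simulate_phenotype(
        res.geno,
        res.labels,
        n_qtl=20,
        target_h2=0.7,
        major_qtl_variance_fraction=0.36,
        seed=11,
    )
    return res, pheno, truth


class TestBonferroni:
    def test_study_scale_threshold(self):
        assert bonferroni_threshold(2_016_911, 0.05) == pytest.approx(7.61, abs=0.005)

    def test_single_test(self):
        assert bonferroni_threshold(1, 0.05) == pytest.approx(1.301, abs=5e-4)

    def test_twenty_tests(self):
        assert bonferroni_threshold(20, 0.05) == pytest.approx(
            -np.log10(0.0025), abs=1e-12
        )

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestGLMScan:
    def test_matches_nested_f_test_oracle(self):
        rng = np.random.default_rng(1)
        n, m = 40, 15
        D = rng.integers(0, 3, size=(n, m)).astype(float)
        C = rng.normal(size=(n, 2))
        y = rng.normal(size=n) + D[:, 3] * 0.8
        res = glm_scan(y, toy_geno(D), covariates=C)
        # oracle: explicit nested-model F-test per marker
        X0 = np.c_[np.ones(n), C]
        for j in range(m):
            X1 = np.c_[X0, D[:, j]]
            rss0 = np.linalg.lstsq(X0, y, rcond=None)[1][0]
            rss1 = np.linalg.lstsq(X1, y, rcond=None)[1][0]
            df = n - X1.shape[1]
            F = (rss0 - rss1) / (rss1 / df)
            p_oracle = scipy.stats.f.sf(F, 1, df)
            assert res.table.p.iloc[j] == pytest.approx(p_oracle, abs=1e-10)

    def test_type_one_error_calibrated(self):
        rates = []
        for seed in range(5):
            res = unstructured(seed=seed)
            y = np.random.default_rng(seed + 100).normal(size=300)
            scan = glm_scan(y, res.geno)
            rates.append(float((scan.table.p < 0.05).mean()))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.015)

    def test_affine_rescaling_leaves_p_unchanged(self):
        res = unstructured(n=100, m=200, seed=2)
        y = np.random.default_rng(2).normal(size=100)
        p1 = glm_scan(y, res.geno).table.p
        p2 = glm_scan(3.0 * y + 7.0, res.geno).table.p
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_collinear_marker_listed_and_skipped(self):
        rng = np.random.default_rng(3)
        D = rng.integers(0, 3, size=(50, 5)).astype(float)
        D[:, 2] = 1.0  # constant: collinear with the intercept
        res = glm_scan(rng.normal(size=50), toy_geno(D))
        assert res.skipped == ["chr1_3"]
        assert np.isnan(res.table.p.iloc[2])

    def test_permuted_trait_rarely_beats_bonferroni(self, major_qtl_panel):
        res, pheno, truth = major_qtl_panel
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(10):
            y = rng.permutation(pheno.to_numpy())
            scan = glm_scan(y, res.geno)
            if -np.log10(scan.table.p.min()) >= scan.threshold_neglog10:
                hits += 1
        assert hits <= 1

    def test_major_qtl_is_top_hit(self, major_qtl_panel):
        res, pheno, truth = major_qtl_panel
        scan = glm_scan(pheno.to_numpy(), res.geno)
        top = scan.table.sort_values("p").iloc[0]
        col_top = res.geno.marker_index([top.marker])[0]
        col_qtl = res.geno.marker_index([truth.major_qtl_id])[0]
        link = np.corrcoef(
            res.geno.dosages[:, col_top], res.geno.dosages[:, col_qtl]
        )[0, 1] ** 2
        assert link > 0.8


class TestMLMMScan:
    def test_zero_steps_is_single_locus_mixed_scan(self, major_qtl_panel):
        res, pheno, truth = major_qtl_panel
        grm = bend(vanraden_grm(res.geno))
        one = mlmm_scan(pheno, res.geno, grm, max_steps=0)
        assert one.pseudo_qtns == []
        assert one.table.p.notna().sum() > 0

    def test_null_trait_selects_no_pseudo_qtns(self):
        for seed in range(3):
            res = unstructured(n=200, m=400, seed=seed + 20)
            y = pd.Series(
                np.random.default_rng(seed + 200).normal(size=200),
                index=res.geno.ids,
            )
            grm = bend(vanraden_grm(res.geno))
            scan = mlmm_scan(y, res.geno, grm, max_steps=5)
            assert scan.pseudo_qtns == []

    def test_two_large_qtls_both_selected(self):
        found = 0
        for seed in range(3):
            res = unstructured(n=400, m=600, seed=seed + 30)
            rng = np.random.default_rng(seed + 300)
            q1, q2 = 100, 400
            g = res.geno.dosages[:, q1] * 1.0 + res.geno.dosages[:, q2] * 1.0
            y = pd.Series(
                g + rng.normal(scale=g.std(ddof=1) * 0.6, size=400),
                index=res.geno.ids,
            )
            grm = bend(vanraden_grm(res.geno))
            scan = mlmm_scan(y, res.geno, grm, max_steps=5)
            ids = set(scan.pseudo_qtns)
            m_ids = res.geno.marker_ids
            if m_ids[q1] in ids and m_ids[q2] in ids:
                found += 1
        assert found >= 2


class TestFarmCPUScan:
    def test_null_trait_falls_back_to_glm(self):
        res = unstructured(n=200, m=400, seed=40)
        y = np.random.default_rng(40).normal(size=200)
        f = farmcpu_scan(y, res.geno)
        g = glm_scan(y, res.geno)
        assert f.pseudo_qtns == []
        np.testing.assert_allclose(
            f.table.p.to_numpy(), g.table.p.to_numpy(), atol=0, equal_nan=True
        )

    def test_pseudo_qtn_set_is_a_fixed_point(self, major_qtl_panel):
        res, pheno, truth = major_qtl_panel
        a = farmcpu_scan(pheno.to_numpy(), res.geno, max_iter=8)
        b = farmcpu_scan(pheno.to_numpy(), res.geno, max_iter=9)
        assert set(a.pseudo_qtns) == set(b.pseudo_qtns)

    def test_finds_at_least_as_many_qtls_as_glm(self):
        wins = 0
        for seed in range(3):
            res = simulate_structured_genotypes(
                SimConfig(n_snps=2000, seed=seed + 50)
            )
            pheno, truth = simulate_phenotype(
                res.geno, res.labels, n_qtl=10, target_h2=0.6, seed=seed + 500
            )
            y = pheno.to_numpy()
            f = farmcpu_scan(y, res.geno)
            g = glm_scan(y, res.geno)
            truth_cols = res.geno.marker_index(truth.qtl_ids)

            def true_hits(scan):
                sig = set(scan.significant())
                hits = 0
                for c in truth_cols:
                    x = res.geno.dosages[:, c]
                    for s in sig:
                        sc = res.geno.marker_index([s])[0]
                        if np.corrcoef(x, res.geno.dosages[:, sc])[0, 1] ** 2 > 0.8:
                            hits += 1
                            break
                return hits

            if true_hits(f) >= true_hits(g):
                wins += 1
        assert wins >= 2

    def test_empty_bin_grid_rejected(self, major_qtl_panel):
        res, pheno, _ = major_qtl_panel
        with pytest.raises(ValueError):
            farmcpu_scan(pheno.to_numpy(), res.geno, bin_sizes=())


class TestBLINKScan:
    def test_null_trait_falls_back_to_glm(self):
        res = unstructured(n=200, m=400, seed=60)
        y = np.random.default_rng(60).normal(size=200)
        b = blink_scan(y, res.geno)
        g = glm_scan(y, res.geno)
        assert b.pseudo_qtns == []
        np.testing.assert_allclose(
            b.table.p.to_numpy(), g.table.p.to_numpy(), atol=0, equal_nan=True
        )

    def test_perfect_ld_pair_yields_single_pseudo_qtn(self):
        res = unstructured(n=400, m=300, seed=61)
        D = res.geno.dosages.copy()
        D[:, 150] = D[:, 50]  # perfect LD duplicate of a QTL
        geno = type(res.geno)(res.geno.ids, res.geno.markers, D)
        rng = np.random.default_rng(61)
        g = D[:, 50]
        y = g + rng.normal(scale=g.std(ddof=1) * 0.5, size=400)
        scan = blink_scan(y, geno)
        pair = {geno.marker_ids[50], geno.marker_ids[150]}
        assert len(pair & set(scan.pseudo_qtns)) <= 1

    def test_major_qtl_significant(self, major_qtl_panel):
        res, pheno, truth = major_qtl_panel
        scan = blink_scan(pheno.to_numpy(), res.geno)
        sig = set(scan.significant())
        col_qtl = res.geno.marker_index([truth.major_qtl_id])[0]
        linked = False
        for s in sig:
            sc = res.geno.marker_index([s])[0]
            if np.corrcoef(
                res.geno.dosages[:, sc], res.geno.dosages[:, col_qtl]
            )[0, 1] ** 2 > 0.8:
                linked = True
        assert linked

    def test_invalid_ld_threshold_rejected(self, major_qtl_panel):
        res, pheno, _ = major_qtl_panel
        with pytest.raises(ValueError, match="ld_r2"):
            blink_scan(pheno.to_numpy(), res.geno, ld_r2=1.5)


class TestReliableSnps:
    def make(self, method, sig_markers):
        table = pd.DataFrame(
            dict(
                marker=["m1", "m2", "m3"],
                chrom="chr1",
                pos=[1, 2, 3],
                maf=0.3,
                effect=1.0,
                p=[1e-12 if m in sig_markers else 0.5 for m in ["m1", "m2", "m3"]],
            )
        )
        from mangogp.gwas import GWASResult

        return GWASResult(method=method, table=table, threshold_neglog10=7.61)

    def test_two_method_vote(self):
        results = [
            self.make("blink", {"m1"}),
            self.make("farmcpu", {"m1", "m2"}),
            self.make("glm", {"m1"}),
        ]
        out = reliable_snps(results, 2)
        assert out.marker_ids == ["m1"]
        assert set(out.methods_by_marker["m1"]) == {"blink", "farmcpu", "glm"}

    def test_single_method_hit_excluded(self):
        results = [self.make("farmcpu", {"m2"}), self.make("glm", set())]
        assert reliable_snps(results, 2).marker_ids == []

    def test_min_methods_one_is_union(self):
        results = [self.make("farmcpu", {"m2"}), self.make("glm", {"m3"})]
        assert reliable_snps(results, 1).marker_ids == ["m2", "m3"]

    def test_empty_input_empty_set(self):
        assert reliable_snps([], 2).marker_ids == []


class TestGenotypeClassContrast:
    def test_additive_marker_gives_monotone_class_means(self, major_qtl_panel):
        res, pheno, truth = major_qtl_panel
        out = genotype_class_contrast(
            truth.true_breeding_values, res.geno, truth.major_qtl_id
        )
        j = truth.qtl_ids.index(truth.major_qtl_id)
        means = [out["class_means"][c] for c in sorted(out["class_means"])]
        diffs = np.diff(means)
        assert (diffs > 0).all() if truth.qtl_effects[j] > 0 else (diffs < 0).all()

    def test_single_class_rejected(self):
        geno = toy_geno(np.ones((6, 2)))
        with pytest.raises(ValueError, match="two genotype classes"):
            genotype_class_contrast(np.arange(6.0), geno, "chr1_1")

    def test_null_marker_p_values_not_extreme(self):
        res = unstructured(n=300, m=50, seed=70)
        rng = np.random.default_rng(70)
        vals = rng.normal(size=300)
        ps = []
        for marker in res.geno.marker_ids[:20]:
            try:
                out = genotype_class_contrast(vals, res.geno, marker)
            except ValueError:
                continue
            ps.extend(out["pairwise_p"].values())
        assert min(ps) > 1e-4  # no spurious strong separation
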