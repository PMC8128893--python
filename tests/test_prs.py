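import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

from crosstwas.config import SimulationConfig
from crosstwas.prs import (
    DEFAULT_THRESHOLD_GRID,
    build_profiles,
    evaluate_incremental_r2,
    gwas_prs,
    impute_expression,
    prs_multiplicity,
    train_gene_effects,
    training_covariates,
    validate_grid,
)
from crosstwas.simulate import Genotypes, simulate_study
from crosstwas.weights import train_cross_tissue


def _tiny_genotypes(X, a1="A", a2="G"):
    m = X.shape[1]
    snps = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(m)],
            "chr": 1, "pos": np.arange(m) * 100 + 1,
            "a1": a1, "a2": a2, "maf": 0.3, "gene_id": "g",
        }
    )
    return Genotypes(X=X.astype(np.int8), snps=snps)


class TestGrid:
    def test_default_grid_is_the_17_published_cutoffs(self):
        assert len(DEFAULT_THRESHOLD_GRID) == 17
        assert DEFAULT_THRESHOLD_GRID[0] == 1.0
        assert DEFAULT_THRESHOLD_GRID[-1] == 5e-8
        assert all(a > b for a, b in zip(DEFAULT_THRESHOLD_GRID, DEFAULT_THRESHOLD_GRID[1:]))

    def test_non_decreasing_grid_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            validate_grid((0.5, 0.5))
        with pytest.raises(ValueError, match="empty"):
            validate_grid(())


class TestImpute:
    def test_unit_weight_recovers_standardized_dosage(self, rng):
        X = rng.integers(0, 3, size=(50, 3))
        geno = _tiny_genotypes(X)
        w = pd.DataFrame(
            [{"gene_id": "g", "tissue_id": "t", "snp_id": "s1",
              "effect_allele": "A", "other_allele": "G", "weight": 1.0}]
        )
        e = impute_expression(geno, w)
        np.testing.assert_allclose(e["g"], geno.standardized()[:, 1])

    def test_swapped_alleles_flip_sign(self, rng):
        X = rng.integers(0, 3, size=(50, 1))
        geno = _tiny_genotypes(X)
        w = pd.DataFrame(
            [{"gene_id": "g", "tissue_id": "t", "snp_id": "s0",
              "effect_allele": "G", "other_allele": "A", "weight": 1.0}]
        )
        e = impute_expression(geno, w)
        np.testing.assert_allclose(e["g"], -geno.standardized()[:, 0])

    def test_constant_snp_excluded(self):
        X = np.column_stack([np.ones(30), np.arange(30) % 3])
        geno = _tiny_genotypes(X)
        w = pd.DataFrame(
            [{"gene_id": "g", "tissue_id": "t", "snp_id": "s0",
              "effect_allele": "A", "other_allele": "G", "weight": 5.0},
             {"gene_id": "g", "tissue_id": "t", "snp_id": "s1",
              "effect_allele": "A", "other_allele": "G", "weight": 1.0}]
        )
        e = impute_expression(geno, w)
        np.testing.assert_allclose(e["g"], geno.standardized()[:, 1])

    def test_oracle_weights_track_genetic_expression(self, base_study):
        s = base_study
        e = impute_expression(s.ref.genotypes, s.weights, tissue_id="tissue0")
        Xs = s.ref.genotypes.standardized()
        for gi, gene in enumerate(s.annotation["gene_id"][:5]):
            cols = s.ref.genotypes.gene_columns(gene)
            genetic = Xs[:, cols] @ s.truth.eqtl_effects[gene][:, 0]
            assert np.corrcoef(e[gene], genetic)[0, 1] > 0.999
            # against total expression: ~ sqrt(cis_h2)
            r = np.corrcoef(e[gene], s.expression[0, :, gi])[0, 1]
            assert abs(r - np.sqrt(0.3)) < 0.12


class TestTrainEffects:
    def _cov(self, n, rng):
        return pd.DataFrame({"age": rng.standard_normal(n), "sex": rng.integers(0, 2, n).astype(float)})

    def test_null_gene_p_uniform(self):
        rng = np.random.default_rng(0)
        n = 120
        ps = []
        for _ in range(500):
            cov = self._cov(n, rng)
            y = 0.2 * cov["age"].to_numpy() + rng.standard_normal(n)
            e = pd.DataFrame({"g": rng.standard_normal(n)})
            ps.append(train_gene_effects(y, e, training_covariates(cov))["p"].iloc[0])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_effect_recovery(self):
        rng = np.random.default_rng(1)
        n = 2000
        cov = self._cov(n, rng)
        e = pd.DataFrame({"g": rng.standard_normal(n)})
        y = 2.0 * e["g"].to_numpy() + rng.standard_normal(n)
        out = train_gene_effects(y, e, training_covariates(cov))
        assert out["beta"].iloc[0] == pytest.approx(2.0, abs=0.1)

    def test_covariate_only_phenotype_gives_null_effect(self):
        rng = np.random.default_rng(2)
        n = 3000
        cov = self._cov(n, rng)
        y = 0.5 * cov["age"].to_numpy() - 0.3 * cov["sex"].to_numpy() + rng.standard_normal(n)
        e = pd.DataFrame({"g": rng.standard_normal(n)})
        out = train_gene_effects(y, e, training_covariates(cov))
        assert abs(out["beta"].iloc[0]) < 0.08

    def test_total_volume_covariate_accepted(self):
        rng = np.random.default_rng(3)
        n = 500
        cov = self._cov(n, rng)
        tv = rng.standard_normal(n)
        e = pd.DataFrame({"g": rng.standard_normal(n)})
        y = tv + rng.standard_normal(n)
        out = train_gene_effects(y, e, training_covariates(cov), total_volume=tv)
        assert len(out) == 1

    def test_constant_expression_skipped(self):
        rng = np.random.default_rng(4)
        n = 100
        cov = self._cov(n, rng)
        e = pd.DataFrame({"g": np.ones(n)})
        out = train_gene_effects(rng.standard_normal(n), e, training_covariates(cov))
        assert out.empty

    def test_too_small_cohort_rejected(self):
        rng = np.random.default_rng(5)
        cov = training_covariates(self._cov(6, rng))
        with pytest.raises(ValueError, match="too small"):
            train_gene_effects(np.zeros(6), pd.DataFrame({"g": np.zeros(6)}), cov)


class TestProfiles:
    def test_default_grid_yields_17_profiles(self, rng):
        e = pd.DataFrame({"g1": rng.standard_normal(40), "g2": rng.standard_normal(40)})
        eff = pd.DataFrame({"gene_id": ["g1", "g2"], "beta": [1.0, -0.5], "p": [0.03, 0.4]})
        prof = build_profiles(e, eff)
        assert prof.shape[1] == 17

    def test_hand_computed_weighted_sum(self):
        e = pd.DataFrame({"g1": [1.0, 2.0], "g2": [0.5, -1.0]})
        eff = pd.DataFrame({"gene_id": ["g1", "g2"], "beta": [2.0, -1.0], "p": [0.005, 0.3]})
        prof = build_profiles(e, eff, grid=(1.0, 0.01))
        np.testing.assert_allclose(prof[1.0], [2 * 1.0 - 0.5, 2 * 2.0 + 1.0])
        np.testing.assert_allclose(prof[0.01], [2.0, 4.0])  # only g1 passes

    def test_no_gene_passes_gives_flagged_zero_profile(self, rng):
        e = pd.DataFrame({"g1": rng.standard_normal(10)})
        eff = pd.DataFrame({"gene_id": ["g1"], "beta": [1.0], "p": [0.5]})
        prof = build_profiles(e, eff, grid=(1.0, 5e-8))
        assert not prof[5e-8].any()
        assert prof.attrs["empty_thresholds"] == [5e-8]


class TestEvaluate:
    def _setup(self, rng, n=400):
        cov = pd.DataFrame({"age": rng.standard_normal(n), "sex": rng.integers(0, 2, n).astype(float)})
        s = rng.standard_normal(n)
        y = 0.4 * s + 0.3 * cov["age"].to_numpy() + rng.standard_normal(n)
        return cov, s, y

    def test_zero_profile_gives_exactly_zero_increment(self, rng):
        cov, _, y = self._setup(rng)
        prof = pd.DataFrame({1.0: np.zeros(len(y))})
        ev = evaluate_incremental_r2(y, prof, cov)
        assert ev["incr_twas"].iloc[0] == 0.0

    def test_duplicated_prs_adds_nothing(self, rng):
        cov, s, y = self._setup(rng)
        prof = pd.DataFrame({1.0: s})
        ev = evaluate_incremental_r2(y, prof, cov, gwas_prs=s)
        assert abs(ev["incr_twas_given_gwas"].iloc[0]) < 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nested_model_invariants(self, seed):
        rng = np.random.default_rng(seed)
        cov, s, y = self._setup(rng)
        g = 0.5 * s + rng.standard_normal(len(s))
        prof = pd.DataFrame({1.0: s, 0.5: rng.standard_normal(len(s))})
        ev = evaluate_incremental_r2(y, prof, cov, gwas_prs=g)
        assert (ev["r2_m4"] >= ev["r2_m2"] - 1e-10).all()
        assert (ev["r2_m3"] >= ev["r2_m1"] - 1e-10).all()
        assert (ev["incr_joint"] >= ev[["incr_twas", "incr_gwas"]].max(axis=1) - 1e-10).all()
        assert (ev[["incr_twas", "incr_gwas", "incr_joint"]] >= -1e-10).all().all()

    def test_constant_phenotype_rejected(self, rng):
        cov, s, _ = self._setup(rng)
        with pytest.raises(ValueError, match="constant"):
            evaluate_incremental_r2(np.ones(len(s)), pd.DataFrame({1.0: s}), cov)

    def test_leaking_test_data_inflates_increment(self):
        # honest training on train only vs training on train+test
        cfg = SimulationConfig(
            n_ref=200, n_gwas=50, n_train=800, n_test=300, n_genes=30,
            snps_per_gene=6, n_tissues=2, cis_h2=0.3,
            mediated_h2=0.0, direct_h2=0.0, seed=55,
        )
        s = simulate_study(cfg)
        e_tr = impute_expression(s.train.genotypes, s.weights, tissue_id="tissue0")
        e_te = impute_expression(s.test.genotypes, s.weights, tissue_id="tissue0")
        honest_eff = train_gene_effects(
            s.train.phenotype, e_tr, training_covariates(s.train.covariates)
        )
        leaked_eff = train_gene_effects(
            np.concatenate([s.train.phenotype, s.test.phenotype]),
            pd.concat([e_tr, e_te], ignore_index=True),
            training_covariates(pd.concat([s.train.covariates, s.test.covariates], ignore_index=True)),
        )
        prof_h = build_profiles(e_te, honest_eff)
        prof_l = build_profiles(e_te, leaked_eff)
        ev_h = evaluate_incremental_r2(s.test.phenotype, prof_h, s.test.covariates)
        ev_l = evaluate_incremental_r2(s.test.phenotype, prof_l, s.test.covariates)
        assert ev_l["incr_twas"].max() > ev_h["incr_twas"].max()


class TestMultiplicity:
    def test_published_counts(self):
        n_tests, thr = prs_multiplicity(101, 4, 110, 3)
        assert n_tests == 734
        assert thr == 0.05 / 734

    def test_trivial_case(self):
        assert prs_multiplicity(1, 1, 1, 1) == (2, 0.025)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(1, 50, 4))
        n_tests, thr = prs_multiplicity(a, b, c, d, alpha=0.04)
        assert n_tests == a * b + c * d
        assert thr == 0.04 / (a * b + c * d)

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            prs_multiplicity(0, 1, 1, 1)


class TestGwasPrs:
    def test_no_passing_snp_gives_zero_vector(self, base_study):
        out = gwas_prs(base_study.test.genotypes, base_study.gwas, p_threshold=1e-300)
        assert not out.any()

    def test_score_correlates_with_phenotype_under_signal(self, base_study):
        s = base_study
        out = gwas_prs(s.test.genotypes, s.gwas, p_threshold=1e-4)
        r = np.corrcoef(out, s.test.phenotype)[0, 1]
        assert r > 0.05


class TestPanelSizeEffect:
    def test_larger_reference_panels_predict_better(self):
        sizes = [30, 150, 600]
        means = []
        for n_ref in sizes:
            vals = []
            for seed in (1, 2, 3):
                cfg = SimulationConfig(
                    n_ref=n_ref, n_gwas=50, n_train=3000, n_test=1000, n_genes=6,
                    snps_per_gene=15, n_tissues=3, cis_h2=0.25,
                    n_causal_eqtl_per_gene=5, mediated_h2=0.15, direct_h2=0.0, seed=seed,
                )
                s = simulate_study(cfg)
                panel, _ = train_cross_tissue(
                    s.expression, s.ref.genotypes, s.annotation, 0.05, 0.05,
                    max_iter=300, tol=1e-6,
                )
                e_tr = impute_expression(s.train.genotypes, panel, tissue_id="tissue0")
                e_te = impute_expression(s.test.genotypes, panel, tissue_id="tissue0")
                eff = train_gene_effects(
                    s.train.phenotype, e_tr, training_covariates(s.train.covariates)
                )
                prof = build_profiles(e_te[list(eff["gene_id"])], eff)
                ev = evaluate_incremental_r2(s.test.phenotype, prof, s.test.covariates)
                vals.append(ev["incr_twas"].max())
            means.append(np.mean(vals))
        assert spearmanr(sizes, means).statistic > 0
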