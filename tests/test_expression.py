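import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossmeth import diagnostics, expression, simulate


def design12():
    return simulate.expression_design("speciesA", n_replicates=3)


class TestDesign:
    def test_full_factorial_terms_and_rank(self):
        X, terms = expression.build_design(design12(), ["tissue", "treatment"])
        assert X.shape == (12, 4)
        assert set(terms) == {"Intercept", "tissue", "treatment", "tissue:treatment"}

    def test_three_factor_interactions(self):
        d = simulate.expression_design(["a", "b", "c"], n_replicates=2)
        X, terms = expression.build_design(d, ["species", "tissue", "treatment"])
        assert "species:tissue:treatment" in terms
        assert X.shape[1] == 12  # 1 + 2 + 1 + 1 + 2 + 2 + 1 + 2
        assert np.linalg.matrix_rank(X) == 12


class TestRpkm:
    def test_basic_value(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        out = expression.rpkm(
            counts, pd.Series({"g1": 1000}), pd.Series({"s1": 1_000_000})
        )
        assert out.loc["g1", "s1"] == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(60)
        counts = pd.DataFrame(rng.poisson(50, (20, 4)),
                              index=[f"g{i}" for i in range(20)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 5000, 20), index=counts.index)
        lib = counts.sum(axis=0)
        r1 = expression.rpkm(counts, lengths, lib)
        r2 = expression.rpkm(counts * 7, lengths, lib * 7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_matches_direct_recount(self):
        rng = np.random.default_rng(61)
        counts = pd.DataFrame(rng.poisson(30, (10, 3)),
                              index=[f"g{i}" for i in range(10)],
                              columns=list("xyz"))
        lengths = pd.Series(rng.integers(500, 3000, 10), index=counts.index)
        lib = counts.sum(axis=0)
        out = expression.rpkm(counts, lengths, lib)
        g, s = "g3", "y"
        expect = 1e9 * counts.loc[g, s] / (lib[s] * lengths[g])
        assert out.loc[g, s] == pytest.approx(expect)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g1"])
        with pytest.raises(ValueError):
            expression.rpkm(counts, pd.Series({"g1": 100}), pd.Series({"s1": 0}))


class TestExpressedFilter:
    def test_boundary_inclusive(self):
        r = pd.DataFrame([[3.0, 3.0, 3.0] + [0.0] * 9], index=["g1"])
        assert expression.expressed_filter(r).loc["g1"]

    def test_below_threshold_everywhere(self):
        r = pd.DataFrame([[2.9] * 12], index=["g1"])
        assert not expression.expressed_filter(r).loc["g1"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(62)
        r = pd.DataFrame(rng.gamma(2, 2, (100, 12)))
        lo = expression.expressed_filter(r, min_rpkm=2)
        hi = expression.expressed_filter(r, min_rpkm=5)
        assert not (hi & ~lo).any()


class TestDispersion:
    def test_poisson_counts_give_small_dispersion(self):
        r = diagnostics.dispersion_recovery(0.0, n_genes=200, seed=63)
        assert r["dispersion_median_estimate"] < 0.05

    def test_nb_dispersion_recovered(self):
        r = diagnostics.dispersion_recovery(0.4, n_genes=300, seed=64)
        assert 0.2 <= r["dispersion_median_estimate"] <= 0.6

    def test_all_zero_gene_skipped(self):
        counts, _ = simulate.simulate_expression(20, design12(), seed=65)
        counts.iloc[0] = 0
        disp = expression.estimate_dispersion(counts, design12())
        assert np.isnan(disp.iloc[0]) and np.isfinite(disp.iloc[1:]).all()

    def test_floor_applied_on_degenerate_input(self):
        # duplicated samples: zero within-cell variance
        base = np.tile(np.array([[100, 200, 150, 120]]), (10, 3)).astype(float)
        counts = pd.DataFrame(base[:, :12])
        disp = expression.estimate_dispersion(counts, design12())
        assert (disp >= expression.DISPERSION_FLOOR - 1e-15).all()


class TestFitAndTest:
    def test_deviance_nesting(self):
        counts, _ = simulate.simulate_expression(100, design12(), seed=66)
        y = counts.to_numpy(float)
        X, terms = expression.build_design(design12(), ["tissue", "treatment"])
        phi = np.full(100, 0.1)
        offset = np.log(y.sum(axis=0))
        full = expression.fit_nb_glm(y, X, phi, offset)
        keep = [i for i in range(X.shape[1]) if i not in terms["tissue:treatment"]]
        red = expression.fit_nb_glm(y, X[:, keep], phi, offset)
        assert (red.deviance >= full.deviance - 1e-6).all()

    def test_null_type_one_error_calibrated(self):
        r = diagnostics.glm_null_type1(n_genes=800, seed=67)
        for term, frac in r.items():
            assert 0.02 <= frac <= 0.08, (term, frac)

    def test_power_on_injected_tissue_effect(self):
        counts, truth = simulate.simulate_expression(
            300, design12(), dispersion=0.1,
            effects={"tissue": (100, 2.0)}, seed=68,
        )
        disp = expression.estimate_dispersion(counts, design12())
        fits = expression.fit_and_test(counts, design12(), disp)
        de = truth.de_genes["tissue"]
        power = (fits.loc[de, "p_tissue"] < 0.05).mean()
        assert power > 0.9

    def test_poisson_limit_matches_poisson_glm(self):
        # dispersion -> 0: NB deviance test converges to the Poisson one
        counts, _ = simulate.simulate_expression(
            50, design12(), dispersion=0.0, seed=69,
            baseline_log_mean=(4.0, 4.0),
        )
        disp_tiny = np.full(50, 1e-10)
        fits = expression.fit_and_test(counts, design12(), disp_tiny)
        # independent route: statsmodels Poisson GLM per gene
        import statsmodels.api as sm

        X, terms = expression.build_design(design12(), ["tissue", "treatment"])
        y = counts.to_numpy(float)
        offset = np.log(y.sum(axis=0))
        keep = [i for i in range(X.shape[1]) if i not in terms["tissue"]]
        for g in [0, 7, 23]:
            full = sm.GLM(y[g], X, family=sm.families.Poisson(),
                          offset=offset).fit()
            red = sm.GLM(y[g], X[:, keep], family=sm.families.Poisson(),
                         offset=offset).fit()
            p_sm = stats.chi2.sf(red.deviance - full.deviance, 1)
            assert fits["p_tissue"].iloc[g] == pytest.approx(p_sm, abs=1e-3)

    def test_tissue_only_effects_recovered_by_tissue_term(self):
        counts, truth = simulate.simulate_expression(
            400, design12(), dispersion=0.1,
            effects={"tissue": (120, 1.5)}, seed=70,
        )
        disp = expression.estimate_dispersion(counts, design12())
        fits = expression.fit_and_test(counts, design12(), disp)
        n_tissue = (fits["p_tissue"] < 0.01).sum()
        n_treat = (fits["p_treatment"] < 0.01).sum()
        assert n_tissue > 5 * max(n_treat, 1)


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        genes = [f"g{i}" for i in range(20)]
        assoc = pd.DataFrame(
            {"gene_id": genes, "feature": "exon", "meth_value": [1.0] * 10 + [-1.0] * 10}
        )
        lfc = pd.Series([-2.0] * 10 + [2.0] * 10, index=genes)
        out = expression.methylation_expression_correlation(assoc, lfc)
        assert out.loc[out["feature"] == "exon", "rho"].iloc[0] == pytest.approx(-1.0)

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(71)
        genes = [f"g{i}" for i in range(1000)]
        assoc = pd.DataFrame(
            {"gene_id": genes, "feature": "exon",
             "meth_value": rng.choice([-1.0, 1.0], 1000)}
        )
        lfc = pd.Series(rng.normal(size=1000), index=genes)
        out = expression.methylation_expression_correlation(assoc, lfc)
        assert abs(out["rho"].iloc[0]) < 0.1

    def test_small_classes_unavailable(self):
        assoc = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "feature": "intron", "meth_value": [1.0, -1.0]}
        )
        lfc = pd.Series([0.5, -0.5], index=["g1", "g2"])
        out = expression.methylation_expression_correlation(assoc, lfc)
        assert np.isnan(out["rho"].iloc[0]) and out["n_genes"].iloc[0] == 2

    def test_midrank_ties_match_independent_ranking(self):
        rng = np.random.default_rng(72)
        genes = [f"g{i}" for i in range(50)]
        vals = rng.choice([-1.0, 0.0, 1.0], 50)
        lfc = pd.Series(rng.normal(size=50).round(1), index=genes)
        assoc = pd.DataFrame(
            {"gene_id": genes, "feature": "exon", "meth_value": vals}
        )
        out = expression.methylation_expression_correlation(assoc, lfc)
        # independent midrank route: Pearson on rankdata
        rx = stats.rankdata(vals)
        ry = stats.rankdata(lfc.to_numpy())
        expect = np.corrcoef(rx, ry)[0, 1]
        assert out["rho"].iloc[0] == pytest.approx(expect, abs=1e-12)
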