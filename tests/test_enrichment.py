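import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwasct import ctd as ctd_mod
from gwasct import enrichment as enr


def _gene_table(gene_z, gene_ids=None, rng=None):
    n = len(gene_z)
    rng = rng or np.random.default_rng(0)
    n_snps = rng.integers(1, 20, size=n)
    length = rng.integers(2_000, 100_000, size=n)
    return pd.DataFrame({
        "gene_id": gene_ids or [f"G{i:05d}" for i in range(n)],
        "n_snps": n_snps,
        "gene_p": stats.norm.sf(gene_z),
        "gene_z": gene_z,
        "gene_length": length,
        "log_n_snps": np.log(n_snps),
        "log_gene_length": np.log(length),
    })


class TestOlsOneSided:
    def test_matches_statsmodels(self):
        """Analytic slope/SE/one-sided p agree with the reference OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 80
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        cov = rng.standard_normal((n, 3))
        fit = enr.ols_one_sided(y, x, cov)
        covn = (cov - cov.mean(0)) / cov.std(0)
        ref = sm.OLS(y, np.column_stack([np.ones(n), covn, x])).fit()
        assert fit.beta == pytest.approx(ref.params[-1], rel=1e-10)
        assert fit.se == pytest.approx(ref.bse[-1], rel=1e-10)
        t = ref.params[-1] / ref.bse[-1]
        assert fit.p_one_sided == pytest.approx(stats.t.sf(t, ref.df_resid), rel=1e-10)

    def test_single_gene_set_closed_form_toy(self):
        """5-gene toy, no covariates: slope is the group-mean contrast."""
        y = np.array([3.0, 0.5, -0.2, 0.8, -1.1])
        x = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        fit = enr.ols_one_sided(y, x, None)
        assert fit.beta == pytest.approx(y[0] - y[1:].mean(), rel=1e-12)

    def test_one_sided_orientation(self):
        """Negating the response maps each p to 1 - p."""
        rng = np.random.default_rng(2)
        y = rng.standard_normal(60)
        x = rng.standard_normal(60)
        p_pos = enr.ols_one_sided(y, x, None).p_one_sided
        p_neg = enr.ols_one_sided(-y, x, None).p_one_sided
        assert p_pos + p_neg == pytest.approx(1.0, abs=1e-10)

    def test_constant_x_degenerate(self):
        fit = enr.ols_one_sided(np.random.default_rng(0).standard_normal(40),
                                np.ones(40), None)
        assert fit.degenerate and np.isnan(fit.p_one_sided)


def _spec_fixture(n_genes=120, k=4, seed=0):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rng.gamma(2, 1, size=(n_genes, 1)) *
                         np.ones((1, 8 * k)) + 0.2)
    labels = [f"T{i}" for i in range(k) for _ in range(8)]
    cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(8 * k)],
                          "supercluster": labels})
    return ctd_mod.compute_specificity(counts, cells, "supercluster")


class TestEnrichmentModes:
    def test_planted_linear_signal_recovered(self, sc_small, spec_super):
        rng = np.random.default_rng(3)
        target = "Microglia"
        z = 3.0 * spec_super.specificity[target].to_numpy() + rng.standard_normal(len(spec_super.genes))
        table = _gene_table(z, gene_ids=list(spec_super.genes))
        res = enr.linear_enrichment(table, spec_super)
        best = res.loc[res["p"].idxmin()]
        assert best["cell_type"] == target and best["beta"] > 0

    def test_top10_planted_signal_recovered(self, sc_small, spec_super):
        rng = np.random.default_rng(4)
        sets = ctd_mod.top_decile_sets(spec_super)
        target = "Macrophage"
        member = spec_super.specificity.index.isin(sets[target])
        z = 2.0 * member + rng.standard_normal(len(member))
        table = _gene_table(z, gene_ids=list(spec_super.genes))
        res = enr.top10_enrichment(table, sets)
        best = res.loc[res["p"].idxmin()]
        assert best["cell_type"] == target and best["beta"] > 0

    def test_linear_vs_statsmodels_full_path(self, spec_super):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        table = _gene_table(rng.standard_normal(len(spec_super.genes)),
                            gene_ids=list(spec_super.genes))
        res = enr.linear_enrichment(table, spec_super)
        t = spec_super.cell_types[0]
        x = spec_super.quantile_bins[t].to_numpy(float) / spec_super.n_bins
        cov = table[list(enr.DEFAULT_COVARIATES)].to_numpy(float)
        covn = (cov - cov.mean(0)) / cov.std(0)
        ref = sm.OLS(table["gene_z"].to_numpy(),
                     np.column_stack([np.ones(len(x)), covn, x])).fit()
        row = res[res["cell_type"] == t].iloc[0]
        assert row["beta"] == pytest.approx(ref.params[-1], rel=1e-8)
        assert row["se"] == pytest.approx(ref.bse[-1], rel=1e-8)

    def test_identical_specificity_flagged_degenerate(self):
        spec = _spec_fixture()
        spec.quantile_bins["T0"] = 7  # constant covariate for one type
        rng = np.random.default_rng(6)
        table = _gene_table(rng.standard_normal(len(spec.genes)),
                            gene_ids=list(spec.genes))
        res = enr.linear_enrichment(table, spec)
        assert bool(res.loc[res["cell_type"] == "T0", "degenerate"].iloc[0])
        assert not res.loc[res["cell_type"] != "T0", "degenerate"].any()

    def test_empty_and_full_sets_degenerate(self):
        spec = _spec_fixture()
        rng = np.random.default_rng(7)
        table = _gene_table(rng.standard_normal(len(spec.genes)),
                            gene_ids=list(spec.genes))
        sets = {"none": set(), "all": set(spec.genes), "ok": set(list(spec.genes)[:10])}
        res = enr.top10_enrichment(table, sets)
        assert res.set_index("cell_type")["degenerate"].to_dict() == {
            "none": True, "all": True, "ok": False}

    def test_too_few_shared_genes_raises(self, spec_super):
        table = _gene_table(np.zeros(10), gene_ids=list(spec_super.genes[:10]))
        with pytest.raises(ValueError, match="shared"):
            enr.linear_enrichment(table, spec_super)

    def test_noise_covariate_barely_moves_p(self, spec_super):
        rng = np.random.default_rng(8)
        table = _gene_table(rng.standard_normal(len(spec_super.genes)),
                            gene_ids=list(spec_super.genes))
        base = enr.linear_enrichment(table, spec_super)
        noisy = table.assign(noise=rng.standard_normal(len(table)))
        with_noise = enr.linear_enrichment(
            noisy, spec_super, covariate_list=enr.DEFAULT_COVARIATES + ("noise",))
        diff = np.abs(base["p"].to_numpy() - with_noise["p"].to_numpy())
        assert np.all(diff < 0.1)


class TestBonferroni:
    def test_threshold_54_tests(self):
        res = pd.DataFrame({"p": np.linspace(0.001, 0.9, 54)})
        out = enr.bonferroni(res, alpha=0.05)
        thr = out["alpha_corrected"].iloc[0]
        assert thr == pytest.approx(9.259e-4, abs=1e-6)
        # consistent with a printed two-significant-figure 9.2e-4
        assert 9.2e-4 <= thr < 9.3e-4

    def test_single_test(self):
        out = enr.bonferroni(pd.DataFrame({"p": [0.03]}), alpha=0.05)
        assert out["alpha_corrected"].iloc[0] == 0.05
        assert bool(out["significant"].iloc[0])

    def test_p_equal_to_threshold_not_significant(self):
        res = pd.DataFrame({"p": [0.05 / 10] + [0.5] * 9})
        out = enr.bonferroni(res, alpha=0.05)
        assert not bool(out["significant"].iloc[0])  # strict <

    def test_nan_p_never_significant(self):
        out = enr.bonferroni(pd.DataFrame({"p": [np.nan, 1e-9]}), alpha=0.05)
        assert out["significant"].tolist() == [False, True]

    def test_empty_family_raises(self):
        with pytest.raises(ValueError):
            enr.bonferroni(pd.DataFrame({"p": []}))
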