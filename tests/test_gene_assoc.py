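import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwasct import gene_assoc as ga
from gwasct.gtf import GeneModel
from gwasct.simulate import ar1_matrix


def _records(positions, chrom="1", z=None):
    n = len(positions)
    z = np.ones(n) if z is None else np.asarray(z)
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": [chrom] * n,
        "pos": positions,
        "z": z,
        "p": 2 * stats.norm.sf(np.abs(z)),
    })


class TestSnpToGeneMapping:
    GM_PLUS = GeneModel("GP", "1", "+", 100_000, 120_000, [(100_000, 120_000)])
    GM_MINUS = GeneModel("GM", "1", "-", 100_000, 120_000, [(100_000, 120_000)])

    def test_snp_in_gene_body_always_mapped(self):
        rec = _records([110_000])
        m = ga.map_snps_to_genes(rec, [self.GM_PLUS], window=(0, 0))
        assert list(m["GP"]) == [0]

    def test_zero_window_boundary(self):
        rec = _records([99_999, 100_000, 120_000, 120_001])
        m = ga.map_snps_to_genes(rec, [self.GM_PLUS], window=(0, 0))
        assert sorted(m["GP"]) == [1, 2]

    def test_strand_mirroring(self):
        # 20 kb 3'-ward of tx_start for a minus-strand gene = 20 kb below
        # tx_start in coordinates; covered by the 35 kb upstream arm only
        # after mirroring (the downstream arm is 10 kb).
        rec = _records([80_000, 132_000, 110_000])
        m_minus = ga.map_snps_to_genes(rec, [self.GM_MINUS], window=(35_000, 10_000))
        # 80 kb (20 kb below start) is 3' of a minus gene: only the 10 kb arm
        # reaches there, so it is excluded; 132 kb (12 kb above end) sits in
        # the mirrored 35 kb upstream arm and is included.
        assert sorted(m_minus["GM"]) == [1, 2]
        m_plus = ga.map_snps_to_genes(rec, [self.GM_PLUS], window=(35_000, 10_000))
        # + strand: 35 kb arm is below tx_start (catches 80 kb), 10 kb arm
        # above tx_end (132 kb excluded)
        assert sorted(m_plus["GP"]) == [0, 2]

    def test_enumerated_interval_oracle(self):
        """Mapping agrees with direct interval arithmetic at every position."""
        up, down = 3_000, 1_000
        models = [
            GeneModel("P", "1", "+", 50_000, 60_000, [(50_000, 60_000)]),
            GeneModel("M", "1", "-", 50_000, 60_000, [(50_000, 60_000)]),
        ]
        positions = np.arange(45_000, 65_001, 250)
        rec = _records(positions)
        m = ga.map_snps_to_genes(rec, models, window=(up, down))
        got_p = set(positions[sorted(m.get("P", []))])
        got_m = set(positions[sorted(m.get("M", []))])
        want_p = {p for p in positions if 50_000 - up <= p <= 60_000 + down}
        want_m = {p for p in positions if 50_000 - down <= p <= 60_000 + up}
        assert got_p == want_p
        assert got_m == want_m

    def test_snp_can_map_to_multiple_genes(self):
        overlapping = [
            GeneModel("A", "1", "+", 100, 1000, [(100, 1000)]),
            GeneModel("B", "1", "+", 500, 2000, [(500, 2000)]),
        ]
        m = ga.map_snps_to_genes(_records([700]), overlapping, window=(0, 0))
        assert set(m) == {"A", "B"}

    def test_no_mapping_raises_with_diagnostics(self):
        with pytest.raises(ValueError, match="no SNP maps"):
            ga.map_snps_to_genes(_records([1], chrom="9"), [self.GM_PLUS])


class TestGenePvalue:
    def test_single_snp_reduces_to_two_sided_p(self):
        for z in (0.5, 1.96, 3.3):
            p = ga.gene_pvalue(np.array([z]))
            assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)

    def test_perfect_ld_reduces_to_single_snp(self):
        """R = all-ones has rank 1: any n behaves as one SNP."""
        z = np.full(7, 2.1)
        p = ga.gene_pvalue(z, np.ones((7, 7)))
        assert p == pytest.approx(2 * stats.norm.sf(2.1), rel=1e-10)

    def test_identity_ld_exact_chi_square(self):
        z = np.linspace(0.1, 2.0, 20)
        p = ga.gene_pvalue(z, np.eye(20))
        assert p == pytest.approx(stats.chi2.sf(np.sum(z ** 2), 20), rel=1e-12)

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_exact_matches_monte_carlo_oracle(self, rho):
        """Weighted-chi-square tail within 2 MC SEs of the empirical null."""
        n, draws = 10, 400_000
        R = ar1_matrix(n, rho)
        rng = np.random.default_rng(17)
        L = np.linalg.cholesky(R)
        q_null = np.sum((rng.standard_normal((draws, n)) @ L.T) ** 2, axis=1)
        for q in (6.0, 12.0, 22.0):
            p_mc = (1 + np.sum(q_null >= q)) / (draws + 1)
            se = np.sqrt(p_mc * (1 - p_mc) / draws)
            p_exact = ga.weighted_chi2_sf(q, np.linalg.eigvalsh(R))
            assert abs(p_exact - p_mc) <= 2 * se

    def test_montecarlo_method_agrees_with_exact(self):
        R = ar1_matrix(6, 0.5)
        z = np.array([1.0, -0.5, 2.0, 0.3, -1.2, 0.8])
        p_mc = ga.gene_pvalue(z, R, method="montecarlo", mc_draws=200_000,
                              rng=np.random.default_rng(3))
        p_ex = ga.gene_pvalue(z, R)
        assert abs(p_mc - p_ex) < 3 * np.sqrt(p_ex * (1 - p_ex) / 200_000)

    def test_satterthwaite_close_to_exact_in_bulk(self):
        R = ar1_matrix(8, 0.5)
        z = np.linalg.cholesky(R) @ np.random.default_rng(4).standard_normal(8)
        p_sat = ga.gene_pvalue(z, R, method="satterthwaite")
        p_ex = ga.gene_pvalue(z, R)
        assert abs(p_sat - p_ex) < 0.02

    def test_monotone_in_signal(self):
        """Inflating every |z| weakly decreases the gene p."""
        R = ar1_matrix(5, 0.4)
        z = np.array([0.2, -1.0, 0.7, 1.5, -0.3])
        ps = [ga.gene_pvalue(c * z, R) for c in (1.0, 1.5, 2.0, 3.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_deep_tail_is_finite_and_monotone(self):
        R = ar1_matrix(5, 0.6)
        lam = np.linalg.eigvalsh(R)
        ps = [ga.weighted_chi2_sf(q, lam) for q in (50, 100, 200, 400)]
        assert all(p > 0 for p in ps)
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_errors(self):
        with pytest.raises(ValueError):
            ga.gene_pvalue(np.array([]))
        with pytest.raises(ValueError, match="dimension"):
            ga.gene_pvalue(np.ones(3), np.eye(2))
        with pytest.raises(ValueError, match="diagonal"):
            ga.gene_pvalue(np.ones(2), 2 * np.eye(2))
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError):
            ga.gene_pvalue(np.ones(2), bad, method="exact")


class TestGeneZscores:
    def test_probit_relation_and_covariates(self, sc_small, null_gene_table):
        t = null_gene_table
        np.testing.assert_allclose(t["gene_z"], stats.norm.isf(t["gene_p"]), rtol=1e-9)
        assert (t["n_snps"] >= 1).all()
        np.testing.assert_allclose(t["log_n_snps"], np.log(t["n_snps"]))
        lengths = {g.gene_id: g.length for g in sc_small.gene_models}
        assert all(t.set_index("gene_id")["gene_length"][g] == lengths[g]
                   for g in t["gene_id"])

    def test_null_p_uniform(self, null_gene_table):
        assert stats.kstest(null_gene_table["gene_p"], "uniform").pvalue > 0.01

    def test_gene_without_snps_absent(self):
        models = [GeneModel("A", "1", "+", 100, 200, [(100, 200)]),
                  GeneModel("B", "2", "+", 100, 200, [(100, 200)])]
        rec = _records([150])  # chrom 1 only
        out = ga.gene_zscores(rec, models, window=(0, 0))
        assert out["gene_id"].tolist() == ["A"]

    def test_planted_signal_is_top_gene(self):
        rng = np.random.default_rng(6)
        models = [GeneModel(f"G{i}", "1", "+", 10_000 * (1 + 4 * i),
                            10_000 * (1 + 4 * i) + 5_000,
                            [(10_000 * (1 + 4 * i), 10_000 * (1 + 4 * i) + 5_000)])
                  for i in range(50)]
        pos, zs = [], []
        for i, m in enumerate(models):
            shift = 4.0 if i == 7 else 0.0
            for k in range(3):
                pos.append(m.tx_start + 100 * k)
                zs.append(rng.standard_normal() + shift)
        out = ga.gene_zscores(_records(pos, z=zs), models, window=(0, 0))
        assert out.loc[out["gene_z"].idxmax(), "gene_id"] == "G7"
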