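import logging

import numpy as np
import pandas as pd
import pytest

from gwasct import epr
from gwasct.gtf import GeneModel


def _gm(gene_id, exons, chrom="1"):
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    return GeneModel(gene_id, chrom, "+", lo, hi, exons)


class TestExonUnionLengths:
    def test_overlapping_transcripts(self):
        out = epr.exon_union_lengths([_gm("G", [(100, 200), (150, 300)])])
        assert out["G"] == 201

    def test_disjoint_exons(self):
        out = epr.exon_union_lengths([_gm("G", [(100, 200), (300, 400)])])
        assert out["G"] == 202

    def test_random_models_match_bitmap_oracle(self):
        rng = np.random.default_rng(7)
        models = []
        expected = {}
        for i in range(50):
            n = rng.integers(1, 10)
            starts = rng.integers(1, 3000, size=n)
            ends = starts + rng.integers(0, 500, size=n)
            exons = list(zip(starts.tolist(), ends.tolist()))
            models.append(_gm(f"G{i}", exons))
            occ = np.zeros(int(ends.max()) + 2, dtype=bool)
            for s, e in exons:
                occ[s:e + 1] = True
            expected[f"G{i}"] = int(occ.sum())
        out = epr.exon_union_lengths(models)
        assert out.to_dict() == expected

    def test_no_exons_raises(self):
        gm = _gm("G", [(1, 10)])
        gm.exons = []
        with pytest.raises(ValueError, match="G"):
            epr.exon_union_lengths([gm])


class TestCountsToTpm:
    def test_closed_form_toy(self):
        counts = np.array([[10], [10]])
        tpm = epr.counts_to_tpm(counts, np.array([1000.0, 2000.0]))
        np.testing.assert_allclose(tpm[:, 0], [666_666.666667, 333_333.333333], rtol=1e-9)

    def test_equal_counts_equal_lengths_symmetry(self):
        G = 8
        tpm = epr.counts_to_tpm(np.full((G, 3), 5), np.full(G, 100.0))
        np.testing.assert_allclose(tpm, 1e6 / G)

    def test_scale_invariance_per_cell(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(20, 4)).astype(float)
        counts[0] += 1
        lengths = rng.uniform(200, 5000, size=20)
        a = epr.counts_to_tpm(counts, lengths)
        doubled = counts.copy()
        doubled[:, 2] *= 2
        b = epr.counts_to_tpm(doubled, lengths)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_nonzero_cells_sum_to_million(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.3, size=(50, 30))
        tpm = epr.counts_to_tpm(counts, rng.uniform(100, 9000, size=50))
        sums = tpm.sum(axis=0)
        nz = counts.sum(axis=0) > 0
        np.testing.assert_allclose(sums[nz], 1e6, rtol=1e-3)
        assert np.all(sums[~nz] == 0)

    def test_missing_length_raises(self):
        lengths = pd.Series({"A": 100.0})
        with pytest.raises(ValueError, match="B"):
            epr.counts_to_tpm(np.ones((2, 1)), lengths, genes=["A", "B"])

    def test_nonpositive_length_raises(self):
        with pytest.raises(ValueError):
            epr.counts_to_tpm(np.ones((2, 1)), np.array([100.0, 0.0]))


class TestPercentileRanks:
    def test_four_gene_toy(self):
        tpm = np.array([[0.0], [5.0], [10.0], [20.0]])
        ranks = epr.percentile_ranks(tpm)
        np.testing.assert_allclose(ranks[:, 0], [25, 50, 75, 100])

    def test_tie_sharing_at_zero(self):
        """19 of 20 genes at zero: all zeros share rank 95."""
        tpm = np.zeros((20, 1))
        tpm[0, 0] = 3.0
        ranks = epr.percentile_ranks(tpm)
        assert ranks[0, 0] == 100
        np.testing.assert_allclose(ranks[1:, 0], 95.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        tpm = rng.gamma(1.0, 5.0, size=(40, 6))
        a = epr.percentile_ranks(tpm)
        b = epr.percentile_ranks(np.log1p(tpm) ** 3)
        np.testing.assert_allclose(a, b)

    def test_ranks_in_range_and_monotone_in_tpm(self):
        rng = np.random.default_rng(3)
        tpm = np.round(rng.gamma(0.5, 10.0, size=(30, 5)), 1)
        ranks = epr.percentile_ranks(tpm)
        assert np.all((ranks > 0) & (ranks <= 100))
        for j in range(tpm.shape[1]):
            order = np.argsort(tpm[:, j])
            assert np.all(np.diff(ranks[order, j]) >= 0)


class TestClassify:
    @pytest.mark.parametrize("value, expected", [
        (0.0, "off"), (9.999, "off"),
        (10.0, "low"),  # off requires strictly below 10
        (50.0, "low"), (90.0, "low"),  # high requires strictly above 90
        (90.001, "high"), (100.0, "high"),
    ])
    def test_boundaries(self, value, expected):
        assert epr.classify_epr(value) == expected


class TestEprSummary:
    def _cells(self, labels):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(labels))],
                             "supercluster": labels})

    def test_top_gene_everywhere_is_high(self):
        rng = np.random.default_rng(4)
        tpm = rng.uniform(1, 10, size=(10, 6))
        tpm[3] = 100.0  # top in every cell
        out = epr.epr_summary(tpm, self._cells(["A"] * 3 + ["B"] * 3),
                              ["G00003"], ["A", "B"],
                              genes=[f"G{i:05d}" for i in range(10)])
        assert (out["mean_epr"] == 100.0).all()
        assert (out["epr_class"] == "high").all()

    def test_zero_adjusted_class_vs_raw_rank(self):
        """An unexpressed gene reports the raw tie rank but classes as off."""
        tpm = np.zeros((20, 4))
        tpm[0] = 3.0
        out = epr.epr_summary(tpm, self._cells(["A"] * 4), ["G00001"], ["A"],
                              genes=[f"G{i:05d}" for i in range(20)])
        row = out.iloc[0]
        assert row["mean_epr"] == pytest.approx(95.0)  # raw ECDF tie rank
        assert row["epr_class"] == "off"               # zero-adjusted statistic
        raw = epr.epr_summary(tpm, self._cells(["A"] * 4), ["G00001"], ["A"],
                              genes=[f"G{i:05d}" for i in range(20)],
                              zero_adjusted_class=False)
        assert raw.iloc[0]["epr_class"] == "high"

    def test_every_row_gets_exactly_one_class(self):
        rng = np.random.default_rng(5)
        tpm = rng.gamma(0.4, 20, size=(30, 12))
        genes = [f"G{i:05d}" for i in range(30)]
        out = epr.epr_summary(tpm, self._cells(["A"] * 6 + ["B"] * 6),
                              genes[:8], ["A", "B"], genes=genes)
        assert len(out) == 16
        assert out["epr_class"].isin(["off", "low", "high"]).all()

    def test_median_statistic_option(self):
        tpm = np.array([[1.0, 9.0], [2.0, 1.0], [3.0, 2.0], [4.0, 3.0]])
        genes = ["a", "b", "c", "d"]
        out = epr.epr_summary(tpm, self._cells(["A", "A"]), ["a"], ["A"],
                              genes=genes, class_statistic="median")
        assert out.iloc[0]["median_epr"] == pytest.approx((25 + 100) / 2)

    def test_errors(self):
        tpm = np.ones((4, 2))
        genes = list("abcd")
        with pytest.raises(ValueError, match="absent"):
            epr.epr_summary(tpm, self._cells(["A", "A"]), ["zz"], ["A"], genes=genes)
        with pytest.raises(ValueError, match="no cells"):
            epr.epr_summary(tpm, self._cells(["A", "A"]), ["a"], ["B"], genes=genes)
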