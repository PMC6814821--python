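import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.composite import (
    assign_genes,
    empirical_selection_probability,
    gene_scores,
    ifxd_sites,
    parametric_selection_probability,
    window_scan,
)
from sweepscan.core import GeneTable


def genes_df(rows):
    return GeneTable(
        pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    )


class TestSelectionProbability:
    def test_rank_probabilities_direction_high(self):
        np.testing.assert_allclose(
            empirical_selection_probability([1, 5, 9], "high"), [0.25, 0.5, 0.75]
        )

    def test_direction_low_reverses(self):
        np.testing.assert_allclose(
            empirical_selection_probability([1, 5, 9], "low"), [0.75, 0.5, 0.25]
        )

    def test_ties_average(self):
        with pytest.warns(UserWarning, match="identical"):
            np.testing.assert_allclose(
                empirical_selection_probability([2, 2], "high"), [0.5, 0.5]
            )

    def test_absolute_direction(self):
        ps = empirical_selection_probability([-9, 1, 5], "absolute")
        np.testing.assert_allclose(ps, [0.75, 0.25, 0.5])

    def test_missing_values_stay_missing(self):
        ps = empirical_selection_probability([1.0, np.nan, 3.0], "high")
        assert np.isnan(ps[1])
        np.testing.assert_allclose(ps[[0, 2]], [1 / 3, 2 / 3])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_open_interval_and_half_mean(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=rng.integers(2, 200))
        ps = empirical_selection_probability(vals, "high")
        assert ((ps > 0) & (ps < 1)).all()
        assert np.mean(ps) == pytest.approx(0.5, abs=1e-9)  # tie-free marginal


class TestIFXD:
    def test_odds_identities(self):
        ifxd, _, _ = ifxd_sites(np.array([[0.5, 0.5, 0.5], [0.9, 0.9, 0.9]]))
        np.testing.assert_allclose(ifxd, [1.0, 729.0], rtol=1e-12)

    def test_single_method(self):
        ifxd, _, _ = ifxd_sites(np.array([[0.75]]))
        assert ifxd[0] == pytest.approx(3.0)

    def test_log_equals_sum_of_logits(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0.01, 0.99, size=(10_000, 3))
        ifxd, log_ifxd, _ = ifxd_sites(ps)
        expected = np.log(ps / (1 - ps)).sum(axis=1)
        np.testing.assert_allclose(log_ifxd, expected, rtol=1e-12)
        np.testing.assert_allclose(np.log(ifxd), expected, rtol=1e-9)

    def test_strictly_increasing_in_each_component(self):
        base = np.array([0.3, 0.6, 0.2])
        f0 = ifxd_sites(base[None, :])[0][0]
        for i in range(3):
            up = base.copy()
            up[i] += 0.05
            assert ifxd_sites(up[None, :])[0][0] > f0

    def test_missing_method_skips_site(self):
        ifxd, _, skipped = ifxd_sites(np.array([[0.5, np.nan], [0.5, 0.5]]))
        assert np.isnan(ifxd[0]) and ifxd[1] == pytest.approx(1.0)
        assert skipped == 1

    def test_out_of_range_ps_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            ifxd_sites(np.array([[0.0, 0.5]]))

    def test_parametric_conversion_monotone_and_clipped(self):
        ps = parametric_selection_probability([-50.0, 0.0, 50.0])
        assert 0 < ps[0] < ps[1] < ps[2] < 1
        assert ps[1] == pytest.approx(0.5)


class TestGeneScores:
    def make_stats(self):
        return pd.DataFrame(
            {
                "chromosome": ["1"] * 4,
                "position": [150, 180, 250, 950],
                "ifxd": [1.0, 3.0, 5.0, 2.0],
                "fst": [0.1, 0.4, 0.2, 0.3],
                "xpehh_std": [2.5, -1.0, 0.0, 3.0],
            }
        )

    def test_mean_rank_and_summaries(self):
        genes = genes_df(
            [("gA", "1", 100, 200), ("gB", "1", 200, 300), ("gC", "1", 400, 500)]
        )
        scored, report = gene_scores(self.make_stats(), genes)
        ga = scored[scored.gene_id == "gA"].iloc[0]
        assert ga.ifxd_mean == pytest.approx(2.0)  # mean of {1, 3}
        assert ga.n_snps == 2 and ga.fst_max == pytest.approx(0.4)
        assert ga.xpehh_sig_num == 1
        gb = scored[scored.gene_id == "gB"].iloc[0]
        assert gb.ifxd_mean == pytest.approx(5.0) and gb["rank"] == 1
        assert report["top_genes"] == ["gB", "gA"]
        assert report["n_genes_omitted"] == 1  # gC has no SNPs
        assert sorted(scored["rank"]) == [1, 2]

    def test_membership_is_strict_interval(self):
        # BED gene 100..200 covers 1-based 101..200: position 100 outside,
        # 101 and 200 inside, 201 outside
        genes = genes_df([("g", "1", 100, 200)])
        stats = pd.DataFrame(
            {
                "chromosome": ["1"] * 4,
                "position": [100, 101, 200, 201],
                "ifxd": [1.0] * 4,
            }
        )
        assigned = assign_genes(stats, genes)
        assert assigned.notna().tolist() == [False, True, True, False]

    def test_empty_gene_table_rejected(self):
        genes = GeneTable(
            pd.DataFrame(columns=["gene_id", "chromosome", "start", "end"])
        )
        with pytest.raises(ValueError, match="empty"):
            gene_scores(self.make_stats(), genes)


class TestWindowScan:
    def make_stats(self, positions, values, chrom="1"):
        return pd.DataFrame(
            {"chromosome": chrom, "position": positions, "stat": values}
        )

    def test_constant_values_all_windows_tie_at_max_p(self):
        stats = self.make_stats(np.arange(1, 300_001, 1000), 1.0)
        w = window_scan(stats, "stat", size=50_000, step=25_000)
        n = len(w)
        assert n > 1
        np.testing.assert_allclose(w["empirical_p"], n / (n + 1))

    def test_single_extreme_window_p(self):
        # 99 windows, one strictly above all others -> p = 1/100
        positions = np.arange(99) * 25_000 + 10_000
        values = np.zeros(99)
        values[42] = 5.0
        stats = self.make_stats(positions, values)
        w = window_scan(stats, "stat", size=25_000, step=25_000)
        assert len(w) == 99
        top = w.loc[w["mean_stat"].idxmax()]
        assert top["empirical_p"] == pytest.approx(1 / 100)
        assert top["neg_log10_p"] == pytest.approx(2.0)

    def test_windows_tile_with_step(self):
        stats = self.make_stats([60_000], [1.0])
        w = window_scan(stats, "stat", size=50_000, step=25_000)
        # the SNP at 60 kb falls in windows starting at 25 kb and 50 kb
        assert w["start"].tolist() == [25_000, 50_000]

    def test_permutation_leaves_rank_distribution_uniform(self):
        rng = np.random.default_rng(0)
        positions = np.arange(50) * 25_000 + 5_000
        values = rng.normal(size=50)
        ranks = []
        for _ in range(200):
            perm = rng.permutation(values)
            stats = self.make_stats(positions, perm)
            w = window_scan(stats, "stat", size=25_000, step=25_000)
            ranks.append(w.loc[0, "empirical_p"])
        # empirical p of a fixed window under permutation ~ uniform on
        # {1/(N+1) ... N/(N+1)}: mean 0.5, checked within Monte-Carlo error
        assert np.mean(ranks) == pytest.approx(0.5, abs=0.06)

    def test_bad_window_parameters(self):
        stats = self.make_stats([100], [1.0])
        with pytest.raises(ValueError):
            window_scan(stats, "stat", size=0, step=25_000)
        with pytest.raises(ValueError):
            window_scan(stats, "stat", size=10_000, step=25_000)
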