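import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ehh_pairs, ihh_pairs, xpehh_pairs
from sweepscan.haplotype import (
    EHHCurve,
    UninformativeCoreError,
    ehh_curve,
    ihs_scan,
    integrated_hh,
    standardize_by_daf,
    xpehh_scan,
)


def _single_pop(hapset_factory, alleles, positions=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    return hapset_factory(alleles, positions=positions, pops=["P"] * alleles.shape[0])


class TestEHHCurve:
    def test_core_value_is_one_for_allele_groups(self, hapset_factory):
        alleles = np.array([[1, 0], [1, 1], [0, 0], [0, 1]])
        hs = _single_pop(hapset_factory, alleles)
        curve = ehh_curve(hs, "P", 0, "derived")
        assert curve.left[0] == (0, 1.0) and curve.right[0] == (0, 1.0)

    def test_identical_carriers_stay_at_one(self, hapset_factory):
        alleles = np.tile([1, 0, 1, 0, 1], (4, 1))
        hs = _single_pop(hapset_factory, alleles)
        curve = ehh_curve(hs, "P", 2, "derived")
        assert all(e == 1.0 for _, e in curve.left + curve.right)

    def test_partition_2_1_1_gives_one_sixth(self, hapset_factory):
        # 4 derived carriers of core 0 split into extended-haplotype
        # groups {2,1,1} two sites to the right: EHH = C(2,2)/C(4,2) = 1/6
        alleles = np.array(
            [
                [1, 0, 0],
                [1, 0, 0],
                [1, 0, 1],
                [1, 1, 0],
                [0, 0, 0],
                [0, 0, 0],
            ],
            dtype=np.int8,
        )
        hs = _single_pop(hapset_factory, alleles)
        curve = ehh_curve(hs, "P", 0, "derived")
        # at distance 2 sites right: partitions {2,1,1}
        assert curve.right[2][1] == pytest.approx(1 / 6)
        assert curve.right[2][1] == pytest.approx(
            ehh_pairs(alleles, [0, 1, 2, 3], 0, 2)
        )

    def test_monotone_non_increasing(self, hapset_factory):
        rng = np.random.default_rng(3)
        alleles = rng.integers(0, 2, size=(20, 40)).astype(np.int8)
        alleles[:, 20] = np.repeat([0, 1], 10)
        hs = _single_pop(hapset_factory, alleles)
        for group in ("ancestral", "derived", "all"):
            curve = ehh_curve(hs, "P", 20, group)
            for side in (curve.left, curve.right):
                ehhs = [e for _, e in side]
                assert all(a >= b - 1e-12 for a, b in zip(ehhs, ehhs[1:]))

    def test_uninformative_core(self, hapset_factory):
        alleles = np.array([[1, 0], [0, 0], [0, 1], [0, 0]], dtype=np.int8)
        hs = _single_pop(hapset_factory, alleles)
        with pytest.raises(UninformativeCoreError, match="uninformative"):
            ehh_curve(hs, "P", 0, "derived")


class TestIntegratedHH:
    def test_rectangle(self):
        curve = EHHCurve(
            core_index=0,
            group="derived",
            left=[(0, 1.0), (1000, 1.0), (1100, 0.0)],
            right=[(0, 1.0), (1000, 1.0), (1100, 0.0)],
        )
        ihh, edge = integrated_hh(curve, cutoff=0.05)
        # each side: 1000 of EHH=1 plus the decay trapezoid 0.5*100
        assert ihh == pytest.approx(2 * (1000 + 50))
        assert not edge

    def test_immediate_decay_single_trapezoid(self):
        curve = EHHCurve(
            core_index=0, group="derived",
            left=[(0, 1.0)],
            right=[(0, 1.0), (500, 0.01)],
        )
        ihh, edge = integrated_hh(curve, cutoff=0.05)
        assert ihh == pytest.approx(0.5 * (1.0 + 0.01) * 500)
        assert edge  # left side never decayed before the chromosome end

    def test_piecewise_linear_hand_summed(self):
        right = [(0, 1.0), (200, 0.6), (500, 0.3), (900, 0.02)]
        left = [(0, 1.0), (100, 0.5), (300, 0.04)]
        curve = EHHCurve(core_index=0, group="derived", left=left, right=right)
        expected = (
            0.5 * (1.0 + 0.6) * 200 + 0.5 * (0.6 + 0.3) * 300 + 0.5 * (0.3 + 0.02) * 400
            + 0.5 * (1.0 + 0.5) * 100 + 0.5 * (0.5 + 0.04) * 200
        )
        ihh, edge = integrated_hh(curve, cutoff=0.05)
        assert ihh == pytest.approx(expected)
        assert not edge


class TestScansAgainstNaiveReference:
    """iHS / XP-EHH agree with direct quadratic-time pair counting."""

    @pytest.mark.parametrize("seed", [0, 1])
    def test_ihs_raw_matches_reference(self, hapset_factory, seed):
        rng = np.random.default_rng(seed)
        n_hap, n_site = 30, 80
        alleles = (rng.random((n_hap, n_site)) < rng.random(n_site)).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 100_000), n_site, replace=False))
        hs = hapset_factory(alleles, positions=positions, pops=["P"] * n_hap)
        res = ihs_scan(hs, "P", maf_min=0.05, min_per_bin=5)
        for j in range(n_site):
            if np.isnan(res["ihs_raw"].iloc[j]):
                continue
            anc = [i for i in range(n_hap) if alleles[i, j] == 0]
            der = [i for i in range(n_hap) if alleles[i, j] == 1]
            ihh_a, _ = ihh_pairs(alleles, positions, anc, j, 0.05, 200_000, False)
            ihh_d, _ = ihh_pairs(alleles, positions, der, j, 0.05, 200_000, False)
            assert res["ihs_raw"].iloc[j] == pytest.approx(
                np.log(ihh_a / ihh_d), abs=1e-10
            )

    def test_xpehh_raw_matches_reference(self, hapset_factory):
        rng = np.random.default_rng(2)
        n_hap, n_site = 24, 60
        alleles = (rng.random((n_hap, n_site)) < rng.random(n_site)).astype(np.int8)
        positions = np.arange(1, n_site + 1) * 700
        pops = ["A"] * 12 + ["B"] * 12
        hs = hapset_factory(alleles, positions=positions, pops=pops)
        res = xpehh_scan(hs, "A", "B")
        rows_a, rows_b = list(range(12)), list(range(12, 24))
        n_checked = 0
        for j in range(n_site):
            if np.isnan(res["xpehh_raw"].iloc[j]):
                continue
            ihh_a, ihh_b, edge = xpehh_pairs(
                alleles, positions, rows_a, rows_b, j, 0.05, 200_000
            )
            assert not edge
            assert res["xpehh_raw"].iloc[j] == pytest.approx(
                np.log(ihh_a / ihh_b), abs=1e-10
            )
            n_checked += 1
        assert n_checked > 10


class TestIHS:
    def test_mirror_structures_give_zero(self, hapset_factory):
        # ancestral and derived carriers have identical flank structure;
        # flanks fully decay (all carriers distinct) before the edges
        wings = np.array(
            [[0, 0, 0, 0], [0, 1, 0, 1], [1, 0, 1, 0], [1, 1, 1, 1]], dtype=np.int8
        )
        core = np.array([[0], [0], [0], [0], [1], [1], [1], [1]], dtype=np.int8)
        flank = np.vstack([wings, wings])
        alleles = np.hstack([flank[:, :2], core, flank[:, 2:]])
        hs = _single_pop(hapset_factory, alleles)
        res = ihs_scan(hs, "P", maf_min=0.0, min_per_bin=1)
        assert res["ihs_raw"].iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_standardization_zero_mean_unit_sd_per_bin(self):
        rng = np.random.default_rng(8)
        raw = rng.normal(size=500)
        daf = rng.uniform(0.05, 0.95, size=500)
        std = standardize_by_daf(raw, daf, n_bins=5, min_per_bin=20)
        for b in range(5):
            sel = (daf >= b / 5) & (daf < (b + 1) / 5)
            assert np.nanmean(std[sel]) == pytest.approx(0.0, abs=1e-8)
            assert np.nanstd(std[sel]) == pytest.approx(1.0, abs=1e-8)


class TestXPEHH:
    def test_identical_populations_zero(self, hapset_factory):
        # 12 haplotypes per pop: the pooled-EHH floor from twin pairs,
        # 1/(2n-1), then sits below the decay cutoff
        rng = np.random.default_rng(4)
        block = rng.integers(0, 2, size=(12, 30)).astype(np.int8)
        alleles = np.vstack([block, block])
        hs = hapset_factory(alleles, pops=["A"] * 12 + ["B"] * 12)
        res = xpehh_scan(hs, "A", "B")
        ok = res["xpehh_raw"].notna()
        assert ok.any()
        np.testing.assert_allclose(res.loc[ok, "xpehh_raw"], 0.0, atol=1e-12)

    def test_population_swap_antisymmetry(self, hapset_factory):
        rng = np.random.default_rng(6)
        alleles = rng.integers(0, 2, size=(24, 40)).astype(np.int8)
        hs = hapset_factory(alleles, pops=["A"] * 12 + ["B"] * 12)
        ab = xpehh_scan(hs, "A", "B")["xpehh_raw"]
        ba = xpehh_scan(hs, "B", "A")["xpehh_raw"]
        np.testing.assert_allclose(ab.to_numpy(), -ba.to_numpy(), atol=1e-12)


def test_max_gap_truncates_integration(hapset_factory):
    # core at the right edge of a cluster: the left flank decays, the
    # right neighbour sits beyond max_gap, so integration stops there
    alleles = np.array(
        [
            [0, 1, 0, 1],  # site 0
            [0, 1, 1, 0],  # site 1: splits both carrier groups
            [1, 1, 0, 0],  # site 2: the core
            [0, 1, 0, 1],  # site 3: across the gap
        ],
        dtype=np.int8,
    ).T
    positions = np.array([1000, 2000, 3000, 300_000])
    hs = hapset_factory(alleles, positions=positions, pops=["P"] * 4)
    res = ihs_scan(hs, "P", maf_min=0.0, min_per_bin=1, max_gap=200_000)
    assert res.attrs["n_gap_truncated"] >= 1
    assert np.isfinite(res["ihs_raw"].iloc[2])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_ehh_monotone_property(seed):
    """EHH never increases with distance, for random small matrices."""
    from conftest import make_hapset

    rng = np.random.default_rng(seed)
    n_hap = int(rng.integers(4, 16)) * 2
    n_site = int(rng.integers(5, 30))
    alleles = rng.integers(0, 2, size=(n_hap, n_site)).astype(np.int8)
    core = int(rng.integers(0, n_site))
    if alleles[:, core].sum() < 2:
        alleles[:2, core] = 1
    hs = make_hapset(alleles, pops=["P"] * n_hap)
    curve = ehh_curve(hs, "P", core, "derived")
    for side in (curve.left, curve.right):
        ehhs = [e for _, e in side]
        assert all(a >= b - 1e-12 for a, b in zip(ehhs, ehhs[1:]))
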