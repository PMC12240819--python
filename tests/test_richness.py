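import numpy as np
import pandas as pd
import pytest

from coretrans import (
    core_richness_test, decompose_richness, default_core_sectors,
    weighted_variance_partition,
)
from coretrans.errors import ValidationError


def classification_from(presences):
    """presences: list of (species_id, cell_id, characteristic, origin)."""
    return pd.DataFrame(
        presences,
        columns=["species_id", "cell_id", "characteristic", "origin_module"])


class TestDecomposition:
    def test_centred_and_pool_arithmetic(self):
        # region with 6 characteristic species; cells with char richness 3 and 5
        rows = [(f"s{i}", "c1", True, pd.NA) for i in (0, 1, 2)]
        rows += [(f"s{i}", "c2", True, pd.NA) for i in (1, 2, 3, 4, 5)]
        cls = classification_from(rows)
        regions = pd.Series({"c1": "M", "c2": "M"})
        dec = decompose_richness(cls, regions).set_index("cell_id")
        assert dec.loc["c1", "centred_char"] == pytest.approx(-1.0)
        assert dec.loc["c2", "centred_char"] == pytest.approx(1.0)
        assert (dec["pool_size"] == 6).all()  # distinct characteristic species

    def test_richness_identity(self, small_partitioned):
        cls = small_partitioned["classification"]
        regions = small_partitioned["partition"].cell_modules
        dec = decompose_richness(cls, regions)
        per_cell = cls.groupby("cell_id").size()
        assert (dec.set_index("cell_id")["S"].reindex(per_cell.index)
                == per_cell).all()

    def test_centred_columns_sum_to_zero(self, small_partitioned):
        cls = small_partitioned["classification"]
        regions = small_partitioned["partition"].cell_modules
        dec = decompose_richness(cls, regions)
        sums = dec.groupby("region")[["centred_char", "centred_nonchar"]].sum()
        assert np.allclose(sums.to_numpy(), 0.0, atol=1e-9)

    def test_no_spill_means_zero_nonchar(self):
        rows = [(f"s{i}", f"c{j}", True, pd.NA)
                for i in range(4) for j in range(i + 1)]
        cls = classification_from(rows)
        regions = pd.Series({f"c{j}": "M" for j in range(4)})
        dec = decompose_richness(cls, regions)
        assert (dec["centred_nonchar"] == 0).all()


class TestVariancePartition:
    def _design(self, rng, n=200, n_regions=4):
        region = rng.integers(0, n_regions, n)
        pool = np.array([30.0, 60.0, 90.0, 120.0])[region]
        cc = rng.normal(size=n)
        nc = rng.normal(size=n)
        df = pd.DataFrame({
            "region": region, "pool_size": pool,
            "centred_char": cc - pd.Series(cc).groupby(region).transform("mean"),
            "centred_nonchar": nc - pd.Series(nc).groupby(region).transform("mean"),
        })
        df["region_size"] = df.groupby("region")["region"].transform("size")
        return df

    def test_pool_driven_response(self):
        rng = np.random.default_rng(0)
        dec = self._design(rng)
        dec["S"] = dec["pool_size"]
        out = weighted_variance_partition(dec, weighting="none")
        assert out["r2_full"] == pytest.approx(1.0, abs=1e-9)
        assert out["fractions"]["pool_size"] > 0.9

    def test_orthogonal_fractions_equal_marginal_r2(self):
        # exactly orthogonal predictors: individual fraction = marginal R^2
        n = 64
        t = np.arange(n)
        x1 = np.where(t % 2 == 0, 1.0, -1.0)
        x2 = np.where((t // 2) % 2 == 0, 1.0, -1.0)
        x3 = np.where((t // 4) % 2 == 0, 1.0, -1.0)
        y = 2 * x1 + 1 * x2 + 0.5 * x3
        dec = pd.DataFrame({
            "pool_size": x1, "centred_char": x2, "centred_nonchar": x3,
            "S": y, "region_size": 1.0, "region": 0})
        out = weighted_variance_partition(dec, weighting="none")
        tss = ((y - y.mean()) ** 2).sum()
        for col, x in [("pool_size", x1), ("centred_char", x2), ("centred_nonchar", x3)]:
            beta = (x @ y) / (x @ x)
            marginal = (beta * x) @ (beta * x) / tss
            assert out["fractions"][col] == pytest.approx(marginal, abs=1e-9)

    def test_constant_response_zero_fractions(self):
        rng = np.random.default_rng(1)
        dec = self._design(rng)
        dec["S"] = 7.0
        out = weighted_variance_partition(dec, weighting="none")
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in out["fractions"].values())

    def test_unweighted_equals_equal_weights(self):
        rng = np.random.default_rng(2)
        dec = self._design(rng)
        dec["S"] = dec["pool_size"] + 3 * dec["centred_char"] + rng.normal(size=len(dec))
        dec["region_size"] = 50  # equal region sizes -> equal weights
        a = weighted_variance_partition(dec, weighting="none")
        b = weighted_variance_partition(dec, weighting="inverse-region-size")
        assert a["r2_full"] == pytest.approx(b["r2_full"], abs=1e-12)
        for k in a["fractions"]:
            assert a["fractions"][k] == pytest.approx(b["fractions"][k], abs=1e-12)

    def test_single_region_pool_collinear(self):
        rng = np.random.default_rng(3)
        dec = self._design(rng)
        dec["pool_size"] = 42.0
        dec["S"] = rng.normal(size=len(dec))
        out = weighted_variance_partition(dec)
        assert np.isnan(out["fractions"]["pool_size"])
        assert "collinear" in out["reasons"]["pool_size"]

    def test_fractions_nonnegative_random_designs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            dec = self._design(rng, n=60)
            dec["S"] = rng.normal(size=60)
            out = weighted_variance_partition(dec)
            assert all((v >= 0) or np.isnan(v) for v in out["fractions"].values())
            assert all((np.isnan(v)) or (v <= out["r2_full"] + 1e-9)
                       for v in out["fractions"].values())

    def test_too_few_cells(self):
        dec = pd.DataFrame({
            "pool_size": [1.0], "centred_char": [0.0], "centred_nonchar": [0.0],
            "S": [1.0], "region_size": [1], "region": [0]})
        with pytest.raises(ValidationError):
            weighted_variance_partition(dec)


class TestCoreTest:
    def _setup(self):
        # 6 cells; species "rare" lives only in core cells c0, c1
        rows = []
        for c in range(6):
            rows.append(("common", f"c{c}", True, pd.NA))
        rows += [("rare", "c0", True, pd.NA), ("rare", "c1", True, pd.NA)]
        cls = classification_from(rows)
        sectors = pd.Series({f"c{i}": (1 if i < 2 else 2) for i in range(6)})
        return cls, sectors, [f"c{i}" for i in range(6)]

    def test_unbeatable_core_minimum_p(self):
        cls, sectors, cells = self._setup()
        out = core_richness_test(cls, sectors, cells, core_sectors=[1],
                                 n_perm=200, seed=0)
        assert out["observed"] == 2
        # permuted cores sometimes miss the rare species -> p < 1
        assert out["p_value"] < 1.0
        assert out["p_value"] >= 1 / 201

    def test_degenerate_core(self):
        cls, sectors, cells = self._setup()
        out = core_richness_test(cls, sectors, cells, core_sectors=[1, 2],
                                 n_perm=10, seed=0)
        assert out["degenerate"]
        assert out["p_value"] == 1.0

    def test_zero_permutations_rejected(self):
        cls, sectors, cells = self._setup()
        with pytest.raises(ValidationError):
            core_richness_test(cls, sectors, cells, [1], n_perm=0)

    def test_null_p_uniformity(self):
        """Random sector labels: p approximately uniform across replicates."""
        rng = np.random.default_rng(5)
        n_cells, n_sp, n_rep = 15, 10, 300
        ps = []
        for rep in range(n_rep):
            rows = []
            for s in range(n_sp):
                occ = rng.choice(n_cells, size=rng.integers(1, 5), replace=False)
                rows += [(f"s{s}", f"c{c}", True, pd.NA) for c in occ]
            cls = classification_from(pd.DataFrame(rows).drop_duplicates(
                [0, 1]).values.tolist())
            labels = rng.permutation(np.repeat([1, 2, 3], 5))
            sectors = pd.Series(labels, index=[f"c{i}" for i in range(n_cells)])
            out = core_richness_test(cls, sectors, list(sectors.index), [1],
                                     n_perm=39, seed=int(rng.integers(2**31)))
            ps.append(out["p_value"])
        ps = np.asarray(ps)
        # mean of a uniform p-value is 1/2 (discreteness inflates it slightly)
        assert 0.40 < ps.mean() < 0.65
        assert (ps < 0.25).mean() > 0.10  # low tail populated


def test_default_core_sectors_reach_target_share():
    sectors = pd.Series([1] * 10 + [2] * 20 + [3] * 70)
    chosen = default_core_sectors(sectors, centroid_order=[1, 2, 3],
                                  target_share=0.3)
    assert chosen == [1, 2]
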