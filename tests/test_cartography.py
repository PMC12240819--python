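import statistics

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from coretrans import (
    OccurrenceDataset, aspect_correlations, build_bipartite, cell_aspects,
    detect_bioregions, filter_modules, species_aspects,
)
from coretrans.bioregions import ModulePartition
from coretrans.cartography import ASPECT_COLUMNS
from coretrans.errors import ValidationError


def graph_with_partition(pairs, cell_mod, sp_mod):
    g = build_bipartite(OccurrenceDataset(
        taxon="t", records=pd.DataFrame(pairs, columns=["species_id", "cell_id"])))
    part = ModulePartition(
        cell_modules=pd.Series(cell_mod), species_modules=pd.Series(sp_mod),
        codelength=1.0, backend="truth")
    return g, filter_modules(part, g)


def brute_force_aspects(pairs, cell_mod, sp_mod):
    """Independent per-node recomputation with plain python loops."""
    links = list(pairs)
    retained = {}
    modules = set(cell_mod.values()) | set(sp_mod.values())
    I_c = {c: sum(1 for s, cc in links if cc == c and sp_mod[s] == cell_mod[c])
           for c in cell_mod}
    L_c = {c: sum(1 for s, cc in links if cc == c) for c in cell_mod}
    I_s = {s: sum(1 for ss, c in links if ss == s and cell_mod[c] == sp_mod[s])
           for s in sp_mod}
    L_s = {s: sum(1 for ss, c in links if ss == s) for s in sp_mod}
    for m in modules:
        cells = [c for c in cell_mod if cell_mod[c] == m]
        sps = [s for s in sp_mod if sp_mod[s] == m]
        ok = (cells and sps
              and len(set(I_c[c] for c in cells)) > 1
              and len(set(I_s[s] for s in sps)) > 1)
        retained[m] = ok
    sp_rows = {}
    for m in modules:
        if not retained[m]:
            continue
        sps = [s for s in sp_mod if sp_mod[s] == m]
        mean = statistics.mean(I_s[s] for s in sps)
        sd = statistics.stdev(I_s[s] for s in sps)
        for s in sps:
            sp_rows[s] = {"z_spp": (I_s[s] - mean) / sd,
                          "C_endem": I_s[s] / L_s[s]}
    cell_rows = {}
    for m in modules:
        if not retained[m]:
            continue
        cells = [c for c in cell_mod if cell_mod[c] == m]
        mean = statistics.mean(I_c[c] for c in cells)
        sd = statistics.stdev(I_c[c] for c in cells)
        for c in cells:
            present = [s for s, cc in links if cc == c and sp_mod[s] == m]
            row = {
                "relative_richness": (I_c[c] - mean) / sd,
                "biota_overlap": (L_c[c] - I_c[c]) / L_c[c] if L_c[c] else None,
                "valid": bool(present),
            }
            if present:
                row["endemicity"] = statistics.median(
                    sp_rows[s]["C_endem"] for s in present)
                row["relative_occupancy"] = statistics.median(
                    sp_rows[s]["z_spp"] for s in present)
            cell_rows[c] = row
    return sp_rows, cell_rows


def random_instance(rng, max_nodes=50):
    """Random bipartite graph + random partition with retained modules."""
    while True:
        n_cells = rng.integers(4, max_nodes // 2)
        n_sp = rng.integers(4, max_nodes - n_cells)
        n_mod = rng.integers(1, 4)
        cell_mod = {f"c{i}": int(rng.integers(n_mod)) for i in range(n_cells)}
        sp_mod = {f"s{i}": int(rng.integers(n_mod)) for i in range(n_sp)}
        pairs = set()
        for s in sp_mod:
            # species link mostly inside their module
            own = [c for c in cell_mod if cell_mod[c] == sp_mod[s]]
            other = [c for c in cell_mod if cell_mod[c] != sp_mod[s]]
            k = rng.integers(1, max(2, len(own)))
            pairs.update((s, c) for c in rng.choice(own, size=min(k, len(own)),
                                                    replace=False)) if own else None
            if other and rng.random() < 0.5:
                pairs.add((s, str(rng.choice(other))))
        pairs = sorted(pairs)
        used_cells = {c for _, c in pairs}
        used_sp = {s for s, _ in pairs}
        if used_cells == set(cell_mod) and used_sp == set(sp_mod) and pairs:
            return pairs, cell_mod, sp_mod


class TestHandExamples:
    def test_species_aspects_arithmetic(self):
        # module M: s1 fully inside (endemic), s2 with one link outside
        pairs = [("s1", "c1"), ("s1", "c2"), ("s2", "c1"), ("s2", "c2"),
                 ("s2", "c6"), ("s2", "c4"), ("s3", "c1"),
                 # second module N
                 ("t1", "c3"), ("t1", "c4"), ("t2", "c4"), ("t2", "c5"),
                 ("t3", "c3"), ("t3", "c4"), ("t3", "c5")]
        cell_mod = {"c1": "M", "c2": "M", "c6": "M",
                    "c3": "N", "c4": "N", "c5": "N"}
        sp_mod = {"s1": "M", "s2": "M", "s3": "M", "t1": "N", "t2": "N", "t3": "N"}
        g, part = graph_with_partition(pairs, cell_mod, sp_mod)
        spp = species_aspects(g, part).set_index("species_id")
        assert spp.loc["s1", "C_endem"] == pytest.approx(1.0)  # endemic
        # s2: I_s=3 (c1,c2,c6 in M), L_s=4
        assert spp.loc["s2", "I_s"] == 3 and spp.loc["s2", "L_s"] == 4
        assert spp.loc["s2", "C_endem"] == pytest.approx(0.75)
        # s2's I_s equals the module mean of {2,2,1} -> no; check z identity instead
        m_mean = spp.loc[["s1", "s2", "s3"], "I_s"].mean()
        sd = spp.loc[["s1", "s2", "s3"], "I_s"].std(ddof=1)
        assert spp.loc["s3", "z_spp"] == pytest.approx((1 - m_mean) / sd)

    def test_species_at_module_mean_has_zero_z(self):
        pairs = [("s1", "c1"), ("s2", "c1"), ("s2", "c2"),
                 ("s3", "c1"), ("s3", "c2"), ("s3", "c3")]
        cell_mod = {"c1": "M", "c2": "M", "c3": "M"}
        sp_mod = {"s1": "M", "s2": "M", "s3": "M"}
        g, part = graph_with_partition(pairs, cell_mod, sp_mod)
        spp = species_aspects(g, part).set_index("species_id")
        assert spp.loc["s2", "z_spp"] == pytest.approx(0.0)  # I_s = mean{1,2,3}

    def test_biota_overlap_fraction(self):
        # cell with 10 links, 4 to outside species -> 0.4
        pairs = [(f"in{i}", "c0") for i in range(6)]
        pairs += [(f"out{i}", "c0") for i in range(4)]
        pairs += [(f"in{i}", "c1") for i in range(3)]
        pairs += [(f"in{i}", "c2") for i in range(5)]
        pairs += [(f"out{i}", "d0") for i in range(4)]
        pairs += [(f"out{i}", "d1") for i in range(3)]
        cell_mod = {"c0": "M", "c1": "M", "c2": "M", "d0": "X", "d1": "X"}
        sp_mod = {f"in{i}": "M" for i in range(6)}
        sp_mod.update({f"out{i}": "X" for i in range(4)})
        g, part = graph_with_partition(pairs, cell_mod, sp_mod)
        cells = cell_aspects(g, part).set_index("cell_id")
        assert cells.loc["c0", "biota_overlap"] == pytest.approx(0.4)
        assert cells.loc["c1", "biota_overlap"] == pytest.approx(0.0)

    def test_relative_richness_sample_sd(self):
        # module cells with I = {2, 4, 6}: the I=6 cell has z = 1 (sample sd = 2)
        pairs = [(f"s{i}", "c2") for i in range(6)]
        pairs += [(f"s{i}", "c1") for i in range(4)]
        pairs += [(f"s{i}", "c0") for i in range(2)]
        cell_mod = {"c0": "M", "c1": "M", "c2": "M"}
        sp_mod = {f"s{i}": "M" for i in range(6)}
        g, part = graph_with_partition(pairs, cell_mod, sp_mod)
        cells = cell_aspects(g, part).set_index("cell_id")
        assert cells.loc["c2", "relative_richness"] == pytest.approx(1.0)


class TestOracle:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(123)
        checked = 0
        for _ in range(10):
            pairs, cell_mod, sp_mod = random_instance(rng)
            g, part = graph_with_partition(pairs, cell_mod, sp_mod)
            spp = species_aspects(g, part).set_index("species_id")
            cells = cell_aspects(g, part, spp.reset_index()).set_index("cell_id")
            oracle_sp, oracle_cells = brute_force_aspects(pairs, cell_mod, sp_mod)
            for s, exp in oracle_sp.items():
                assert spp.loc[s, "z_spp"] == pytest.approx(exp["z_spp"], abs=1e-10)
                assert spp.loc[s, "C_endem"] == pytest.approx(exp["C_endem"], abs=1e-12)
            for c, exp in oracle_cells.items():
                got = cells.loc[c]
                assert got["relative_richness"] == pytest.approx(
                    exp["relative_richness"], abs=1e-10)
                assert got["biota_overlap"] == pytest.approx(
                    exp["biota_overlap"], abs=1e-12)
                assert bool(got["valid"]) == exp["valid"]
                if exp["valid"]:
                    assert got["endemicity"] == pytest.approx(exp["endemicity"], abs=1e-12)
                    assert got["relative_occupancy"] == pytest.approx(
                        exp["relative_occupancy"], abs=1e-10)
                checked += 1
        assert checked > 20


class TestInvariants:
    def test_richness_z_standardized_within_module(self, small_partitioned):
        cells = small_partitioned["aspects"]
        for m, grp in cells.groupby("module"):
            z = grp["relative_richness"]
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_bounds(self, small_partitioned):
        cells = small_partitioned["aspects"]
        valid = cells[cells["valid"]]
        assert valid["biota_overlap"].between(0, 1).all()
        assert (valid["endemicity"] > 0).all()
        assert (valid["endemicity"] <= 1).all()

    def test_core_to_transition_gradients(self, small_partitioned):
        """The four aspects grade with distance from the regional hotspot."""
        truth = small_partitioned["truth"]
        cells = small_partitioned["aspects"]
        valid = cells[cells["valid"]].set_index("cell_id")
        dist = truth.cells.set_index("cell_id").loc[valid.index, "distance_to_hotspot"]
        assert spearmanr(dist, valid["relative_richness"]).statistic < 0
        assert spearmanr(dist, valid["endemicity"]).statistic < 0
        assert spearmanr(dist, valid["biota_overlap"]).statistic > 0
        assert spearmanr(dist, valid["relative_occupancy"]).statistic > 0


class TestAspectCorrelations:
    def test_independent_aspects_uncorrelated(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list(ASPECT_COLUMNS))
        frame["valid"] = True
        out = aspect_correlations(frame)
        assert (out["pearson_r"].abs() < 0.2).all()
        assert not out["flagged"].any()

    def test_threshold_flags_boundary(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=500)
        frame = pd.DataFrame({
            "relative_richness": x,
            "biota_overlap": 0.9 * x + rng.normal(scale=0.2, size=500),
            "endemicity": rng.normal(size=500),
            "relative_occupancy": rng.normal(size=500),
            "valid": True,
        })
        out = aspect_correlations(frame).set_index(["aspect_a", "aspect_b"])
        assert bool(out.loc[("relative_richness", "biota_overlap"), "flagged"])
        others = out.drop(index=("relative_richness", "biota_overlap"))
        assert not others["flagged"].any()

    def test_constant_aspect_flagged_undefined(self):
        frame = pd.DataFrame({
            "relative_richness": [1.0, 2.0, 3.0, 4.0],
            "biota_overlap": 0.5,
            "endemicity": [0.9, 0.8, 0.7, 0.6],
            "relative_occupancy": [0.1, 0.4, 0.2, 0.3],
            "valid": True,
        })
        out = aspect_correlations(frame).set_index(["aspect_a", "aspect_b"])
        row = out.loc[("relative_richness", "biota_overlap")]
        assert np.isnan(row["pearson_r"]) and bool(row["flagged"])

    def test_too_few_cells(self):
        frame = pd.DataFrame(np.ones((2, 4)), columns=list(ASPECT_COLUMNS))
        frame["valid"] = True
        with pytest.raises(ValidationError):
            aspect_correlations(frame)
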