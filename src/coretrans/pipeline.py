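"""End-to-end orchestration: simulate/load -> bioregions -> aspects ->
sectors -> adjacency / environment / beta / richness, with a provenance
manifest.

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master).spawn(...)`` in a fixed order
(simulation per taxon, bioregion trials, taxon-specific clustering, general
clustering, richness permutations), so every stage can be re-run in
isolation with identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adjacency import adjacency_counts, neighbor_tests
from .beta import multisite_sorensen_partition, nestedness_summary, sector_site_matrix
from .bioregions import (
    build_bipartite, classify_presences, detect_bioregions, filter_modules,
)
from .cartography import ASPECT_COLUMNS, aspect_correlations, cell_aspects, species_aspects
from .clustering import general_sectors, taxon_specific_sectors
from .envmodels import region_environment_tests
from .errors import ConfigError
from .io import read_env, read_grid, read_occurrences, write_sector_map
from .richness import (
    core_richness_test, decompose_richness, default_core_sectors,
    weighted_variance_partition,
)
from .synthetic import EnvGradient, LandscapeConfig, generate_landscape

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML or JSON."""

    # either a simulate block ...
    simulate: LandscapeConfig | None = None
    n_taxa: int = 1
    # ... or input paths
    occurrences: str | None = None
    grid: str | None = None
    env: str | None = None

    backend: str = "mapeq"
    n_trials: int = 20
    k_range_taxon: tuple[int, int] = (2, 30)
    k_range_general: tuple[int, int] = (2, 14)
    restarts: int = 100
    weight_by_taxon: bool = False
    scheme: str = "queen"
    alpha: float = 0.05
    min_n: int = 30
    covariates: list[str] = field(default_factory=lambda: ["temperature", "precipitation"])
    weighting: str = "inverse-region-size"
    n_perm: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and (self.occurrences is None or self.grid is None):
            raise ConfigError(
                "config needs either a simulate block or occurrences+grid paths"
            )
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        if sim is not None:
            env = sim.pop("env", None)
            if env is not None:
                env = EnvGradient(**{**env, "variables": tuple(env.get("variables", ("temperature", "precipitation")))})
                sim["env"] = env
            sim = LandscapeConfig(**sim)
        for key in ("k_range_taxon", "k_range_general"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(simulate=sim, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence(master).spawn(stage + 1)[stage].generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage in order and return the artifact bundle.

    The bundle maps stage names to DataFrames / objects; with ``outdir``
    given, flat CSV outputs and a JSON provenance manifest are written.
    """
    config.validate()
    bundle: dict = {"per_taxon": {}}
    manifest: dict = {
        "version": "0.1.0",
        "seed": config.seed,
        "backend": config.backend,
        "n_trials": config.n_trials,
        "stages": [],
    }

    # --- stage: inputs -------------------------------------------------
    taxa_data = []
    if config.simulate is not None:
        for t in range(config.n_taxa):
            cfg = dataclasses.replace(
                config.simulate,
                seed=_stage_seed(config.seed, 0) + t,
                taxon=(config.simulate.taxon if config.n_taxa == 1
                       else f"{config.simulate.taxon}{t}"),
            )
            taxa_data.append(generate_landscape(cfg))
        manifest["stages"].append({"stage": "simulate", "n_taxa": config.n_taxa})
    else:
        dataset = read_occurrences(config.occurrences)
        grid = read_grid(config.grid)
        env = read_env(config.env) if config.env else None
        taxa_data.append((dataset, grid, env, None))
        manifest["stages"].append({"stage": "load", "occurrences": config.occurrences})

    # --- stages per taxon: bioregions, metrics -------------------------
    all_aspects = []
    for dataset, grid, env, truth in taxa_data:
        graph = build_bipartite(dataset)
        truth_labels = None
        if config.backend == "truth":
            if truth is None:
                raise ConfigError("truth backend requires simulated data")
            truth_labels = pd.concat([
                truth.cells.set_index("cell_id")["region_id"],
                truth.species.set_index("species_id")["origin_region"],
            ])
        partition = detect_bioregions(
            graph, backend=config.backend, n_trials=config.n_trials,
            seed=_stage_seed(config.seed, 1), truth_labels=truth_labels,
        )
        partition = filter_modules(partition, graph)
        classification = classify_presences(graph, partition)
        spp = species_aspects(graph, partition)
        aspects = cell_aspects(graph, partition, spp)
        bundle["per_taxon"][dataset.taxon] = {
            "dataset": dataset, "grid": grid, "env": env, "truth": truth,
            "graph": graph, "partition": partition,
            "classification": classification, "species_aspects": spp,
            "aspects": aspects,
        }
        all_aspects.append(aspects[aspects["valid"]])
        manifest["stages"].append({
            "stage": "bioregions", "taxon": dataset.taxon,
            "codelength": partition.codelength,
            "n_modules": len(partition.modules),
            "n_retained": len(partition.retained_modules()),
        })
    aspects_all = pd.concat(all_aspects, ignore_index=True)

    # --- stage: sectors -------------------------------------------------
    taxon_parts = {}
    for i, (taxon, info) in enumerate(bundle["per_taxon"].items()):
        sub = aspects_all[aspects_all["taxon"] == taxon]
        taxon_parts[taxon] = taxon_specific_sectors(
            sub, k_range=config.k_range_taxon, restarts=config.restarts,
            seed=_stage_seed(config.seed, 2) + i,
        )
    assignment = general_sectors(
        aspects_all, taxon_parts, k_range=config.k_range_general,
        restarts=config.restarts, seed=_stage_seed(config.seed, 3),
        weight_by_taxon=config.weight_by_taxon,
    )
    bundle["assignment"] = assignment
    bundle["aspects"] = aspects_all
    manifest["stages"].append({
        "stage": "sectors", "k_general": assignment.k,
        "k_taxon": {t: p.k for t, p in taxon_parts.items()},
    })

    # --- downstream stages ---------------------------------------------
    adjacency_results = []
    adjacency_counts_all = []
    beta_rows = []
    decomps = []
    core_rows = []
    env_rows = []
    centroid_order = list(assignment.centroids.index)
    for taxon, info in bundle["per_taxon"].items():
        sectors = assignment.sectors_of(taxon)
        regions = info["partition"].cell_modules
        counts = adjacency_counts(info["grid"], sectors, regions, scheme=config.scheme)
        counts.insert(0, "taxon", taxon)
        adjacency_counts_all.append(counts)
        res, _ = neighbor_tests(
            counts, alpha=config.alpha, min_n=config.min_n,
        )
        res.insert(0, "taxon", taxon)
        adjacency_results.append(res)

        if info["env"] is not None:
            adf = pd.DataFrame({
                "cell_id": sectors.index,
                "region": regions.loc[sectors.index].to_numpy(),
                "sector": sectors.to_numpy(),
            })
            covs = [c for c in config.covariates if c in info["env"].table.columns]
            if covs:
                er = region_environment_tests(adf, info["env"].table, covs)
                er.insert(0, "taxon", taxon)
                env_rows.append(er)

        cls = info["classification"]
        for region in info["partition"].retained_modules():
            mat = sector_site_matrix(cls, sectors, regions, region, "characteristic")
            if mat is not None:
                r = multisite_sorensen_partition(mat)
                beta_rows.append((taxon, region, "characteristic",
                                  r.beta_sor, r.beta_sim, r.beta_sne, r.nestedness_ratio))
            origins = cls.loc[
                (~cls["characteristic"]) & (cls["cell_id"].map(regions) == region),
                "origin_module",
            ].dropna().unique()
            for origin in origins:
                mat = sector_site_matrix(cls, sectors, regions, region,
                                         "non-characteristic", origin=origin)
                if mat is not None:
                    r = multisite_sorensen_partition(mat)
                    beta_rows.append((taxon, region, f"non-characteristic:{origin}",
                                      r.beta_sor, r.beta_sim, r.beta_sne, r.nestedness_ratio))

            region_cells = list(regions.index[regions == region])
            present = sectors.reindex(region_cells).dropna()
            if len(present) == 0:
                continue
            core = default_core_sectors(present, centroid_order)
            if core:
                ct = core_richness_test(
                    cls, sectors, region_cells, core,
                    n_perm=config.n_perm, seed=_stage_seed(config.seed, 4),
                )
                core_rows.append((taxon, region, str(core), ct["observed"],
                                  ct["core_fraction"], ct["p_value"]))

        dec = decompose_richness(cls, regions)
        dec.insert(0, "taxon", taxon)
        decomps.append(dec)

    bundle["adjacency_counts"] = pd.concat(adjacency_counts_all, ignore_index=True)
    bundle["neighbor_tests"] = pd.concat(adjacency_results, ignore_index=True)
    tested = bundle["neighbor_tests"][bundle["neighbor_tests"]["tested"]]
    if len(tested):
        freq = (
            tested.groupby(["sector_a", "sector_b"])
            .agg(n_regions=("region", "size"), n_significant=("significant", "sum"))
            .reset_index()
        )
        freq["frequency"] = freq["n_significant"] / freq["n_regions"]
    else:
        freq = pd.DataFrame(columns=["sector_a", "sector_b", "n_regions", "n_significant", "frequency"])
    bundle["pair_frequency"] = freq
    bundle["env_models"] = (
        pd.concat(env_rows, ignore_index=True) if env_rows
        else pd.DataFrame(columns=["taxon", "region", "delta_aicc", "pseudo_r2", "significant", "reason"])
    )
    bundle["beta_partition"] = pd.DataFrame(
        beta_rows,
        columns=["taxon", "region", "group", "beta_sor", "beta_sim", "beta_sne", "nestedness_ratio"],
    )
    bundle["core_tests"] = pd.DataFrame(
        core_rows,
        columns=["taxon", "region", "core_sectors", "observed_richness", "core_fraction", "p_value"],
    )
    decomp_all = pd.concat(decomps, ignore_index=True)
    bundle["richness_decomposition"] = decomp_all
    bundle["variance_partition"] = weighted_variance_partition(
        decomp_all, weighting=config.weighting
    )
    bundle["manifest"] = manifest

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aspects_all.to_csv(outdir / "aspects.csv", index=False)
        sector_frame = assignment.frame.copy()
        sector_frame["bioregion"] = [
            bundle["per_taxon"][t]["partition"].cell_modules.get(c)
            for t, c in zip(sector_frame["taxon"], sector_frame["cell_id"])
        ]
        sector_frame.to_csv(outdir / "sectors.csv", index=False)
        assignment.ami_table.to_csv(outdir / "ami_table.csv", index=False)
        bundle["neighbor_tests"].to_csv(outdir / "neighbor_tests.csv", index=False)
        bundle["pair_frequency"].to_csv(outdir / "pair_frequency.csv", index=False)
        bundle["env_models"].to_csv(outdir / "multinom_results.csv", index=False)
        bundle["beta_partition"].to_csv(outdir / "beta_partition.csv", index=False)
        bundle["core_tests"].to_csv(outdir / "core_test.csv", index=False)
        vp = bundle["variance_partition"]
        pd.DataFrame([
            {"term": k, "fraction": v} for k, v in vp["fractions"].items()
        ] + [{"term": "r2_full", "fraction": vp["r2_full"]}]).to_csv(
            outdir / "variance_partition.csv", index=False
        )
        first_taxon = next(iter(bundle["per_taxon"]))
        info = bundle["per_taxon"][first_taxon]
        write_sector_map(
            sector_frame[sector_frame["taxon"] == first_taxon],
            info["grid"], outdir / "sectors.geojson",
        )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return bundle


def report(bundle: dict) -> str:
    """Human-readable summary of an artifact bundle."""
    lines = []
    asg = bundle.get("assignment")
    aspects = bundle.get("aspects")
    if asg is None or aspects is None:
        return "incomplete bundle: no sector assignment\n"
    lines.append(f"General biogeographical sectors: k = {asg.k}")
    lines.append("")
    lines.append("Aspect medians by sector (1 = most core-like):")
    merged = aspects.merge(asg.frame, on=["taxon", "cell_id"])
    summ = merged.groupby("sector")[list(ASPECT_COLUMNS)].median().round(3)
    lines.append(summ.to_string())
    lines.append("")
    try:
        corr = aspect_correlations(aspects)
        flagged = corr[corr["flagged"]]
        lines.append("Aspect correlation screen (|r| >= 0.7 flagged):")
        lines.append(corr.round(3).to_string(index=False))
        if len(flagged) == 0:
            lines.append("no strongly correlated aspect pairs")
    except Exception as exc:  # noqa: BLE001
        lines.append(f"correlation screen unavailable: {exc}")
    lines.append("")
    freq = bundle.get("pair_frequency")
    if freq is not None and len(freq):
        lines.append("Higher-than-expected neighbouring (share of regions):")
        lines.append(freq.round(3).to_string(index=False))
    else:
        lines.append("neighbouring frequency table omitted: no testable pairs")
    lines.append("")
    em = bundle.get("env_models")
    if em is not None and len(em):
        ok = em[em["reason"] == ""]
        if len(ok):
            lines.append(
                f"Environment models: {int(ok['significant'].sum())}/{len(ok)} regions "
                f"significant (median pseudo-R2 = {ok['pseudo_r2'].median():.3f})"
            )
    bp = bundle.get("beta_partition")
    if bp is not None and len(bp):
        char = bp[bp["group"] == "characteristic"].dropna(subset=["nestedness_ratio"])
        if len(char):
            lines.append(
                f"Nestedness > turnover in {(char['nestedness_ratio'] > 0.5).mean():.0%} "
                f"of regions (characteristic species)"
            )
    vp = bundle.get("variance_partition")
    if vp is not None:
        fr = vp["fractions"]
        lines.append(
            "Richness variance fractions: "
            + ", ".join(f"{k}={v:.3f}" if v == v else f"{k}=NA" for k, v in fr.items())
            + f" (R2 full = {vp['r2_full']:.3f})"
        )
    return "\n".join(lines) + "\n"
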