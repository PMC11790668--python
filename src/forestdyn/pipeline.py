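"""End-to-end orchestration: biomass → topography → diversity → drivers.

``run_pipeline`` reads the input file set (censuses, species table,
phylogeny, corner elevations, habitat map), validates it, and writes all
intermediate tables, the driver results and a provenance record to the
output directory. Outputs carry no timestamps, so identical inputs and
configuration reproduce byte-identical files.
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

from . import __version__, io
from .biomass import delta_agb, impute_wood_density, quadrat_agb
from .diversity import NullModelSpec, change_values, diversity_profile, trait_dendrogram, INDEX_NAMES
from .drivers import run_driver_analysis, wilcoxon_compare
from .errors import ForestdynError
from .simulate import phylo_distance_matrix
from .topography import assign_habitats, quadrat_topography

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths plus every module default, in one place."""

    census_path: str = "censuses.csv"
    species_path: str = "species.csv"
    phylogeny_path: str = "phylogeny.nwk"
    elevation_path: str = "elevation.csv"
    habitat_path: str = "habitat.csv"
    out_dir: str = "out"
    quadrat_side: float = 20.0            # m; quadrat area is its square
    null_scheme: str = "taxa-shuffle"
    null_iterations: int = 999
    vif_threshold: float = 5.0
    max_exhaustive: int = 15
    simpson_gini: bool = True             # Gini–Simpson (1 - sum p^2) vs dominance form
    abundance_weighted: bool = False      # abundance-weighted SES metrics
    aspect_transform: str = "raw"         # "raw" degrees or "northness" = cos(aspect)
    wilcoxon_paired: bool = False
    strata: tuple = ("whole", "H1", "H2", "H3")
    intervals: tuple | None = None        # e.g. ("1-2",); None = all consecutive
    min_stratum_n: int = 10
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ForestdynError(f"unknown config keys: {sorted(unknown)}")
        if "strata" in data:
            data["strata"] = tuple(data["strata"])
        if "intervals" in data and data["intervals"] is not None:
            data["intervals"] = tuple(data["intervals"])
        return cls(**data)


def load_inputs(config: PipelineConfig, base: Path | str = ".") -> dict:
    """Read and cross-validate the study bundle."""
    base = Path(base)

    def p(name):
        q = Path(getattr(config, name))
        return q if q.is_absolute() else base / q

    censuses = io.read_census(p("census_path"))
    pool = io.read_species(p("species_path"))
    tree = io.read_tree(p("phylogeny_path")) if p("phylogeny_path").exists() else None
    corner = io.read_elevation(p("elevation_path"))
    habitat = io.read_habitat(p("habitat_path"))
    tree = io.validate_bundle(censuses, pool, tree)
    pool.tree = tree
    return dict(censuses=censuses, pool=pool, corner=corner, habitat=habitat)


def compute_results(censuses: pd.DataFrame, pool, corner: np.ndarray,
                    habitat: pd.Series, config: PipelineConfig) -> dict:
    """All pipeline stages on in-memory inputs; returns a results dict."""

    def stage(name, fn):
        try:
            return fn()
        except ForestdynError:
            raise
        except Exception as e:  # pragma: no cover - defensive tagging
            raise ForestdynError(f"stage {name!r} failed: {e}") from e

    pool = stage("biomass", lambda: impute_wood_density(pool))

    topo = stage("topography", lambda: assign_habitats(
        quadrat_topography(corner, config.quadrat_side), habitat))
    quadrats = topo.index

    area = config.quadrat_side**2
    agb = stage("biomass", lambda: quadrat_agb(censuses, pool, area, quadrats=quadrats))
    dagb = stage("biomass", lambda: delta_agb(agb))

    phylo_d = stage("diversity", lambda: phylo_distance_matrix(pool.tree).loc[pool.species, pool.species])
    dendro_d, gower = stage("diversity", lambda: trait_dendrogram(pool))
    null = NullModelSpec(scheme=config.null_scheme, n_iterations=config.null_iterations,
                         seed=config.seed)
    profile = stage("diversity", lambda: diversity_profile(
        censuses, pool, phylo_d, dendro_d, gower, null=null, quadrats=quadrats,
        abundance_weighted=config.abundance_weighted, gini=config.simpson_gini))
    changes = stage("diversity", lambda: change_values(profile))

    wilcox = stage("drivers", lambda: wilcoxon_compare(agb, strata=topo["habitat"],
                                                       paired=config.wilcoxon_paired))

    covariates = stage("drivers", lambda: _covariate_table(dagb, topo, profile, changes, config))
    intervals = list(config.intervals) if config.intervals else None
    results = stage("drivers", lambda: run_driver_analysis(
        covariates, strata=config.strata, intervals=intervals,
        vif_threshold=config.vif_threshold, max_exhaustive=config.max_exhaustive,
        min_n=config.min_stratum_n))

    return dict(pool=pool, topography=topo, agb=agb, delta_agb=dagb, profile=profile,
                changes=changes, wilcoxon=wilcox, covariates=covariates, drivers=results)


def _covariate_table(dagb, topo, profile, changes, config) -> pd.DataFrame:
    topo_cols = topo[["elevation", "slope", "aspect", "convexity"]].copy()
    if config.aspect_transform == "northness":
        topo_cols["aspect"] = np.cos(np.radians(topo_cols["aspect"]))
    wide = profile.set_index(["quadrat", "census"])
    frames = []
    for interval in dagb.columns:
        c1 = interval.split("-")[0]
        initial = wide.xs(type(profile["census"].iloc[0])(c1), level="census")[INDEX_NAMES]
        ch = changes[changes["interval"] == interval].set_index("quadrat").drop(columns="interval")
        block = pd.concat(
            [dagb[interval].rename("delta_agb"), topo_cols,
             initial.reindex(dagb.index), ch.reindex(dagb.index)], axis=1)
        block.insert(0, "interval", interval)
        block.insert(1, "habitat", topo["habitat"].reindex(dagb.index))
        frames.append(block.reset_index())
    return pd.concat(frames, ignore_index=True)


def write_outputs(results: dict, config: PipelineConfig, out_dir=None) -> Path:
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = io.config_hash(config)
    s = config.seed
    io.write_csv(results["agb"], out / "agb.csv", "agb", s, h)
    io.write_csv(results["delta_agb"], out / "delta_agb.csv", "delta_agb", s, h)
    io.write_csv(results["topography"], out / "topography.csv", "topography", s, h)
    io.write_csv(results["profile"], out / "diversity.csv", "diversity", s, h, index=False)
    io.write_csv(results["changes"], out / "change_values.csv", "change_values", s, h, index=False)
    io.write_csv(results["covariates"], out / "covariates.csv", "covariates", s, h, index=False)
    io.write_csv(results["wilcoxon"], out / "wilcoxon.csv", "wilcoxon", s, h, index=False)

    coef_rows = []
    for r in results["drivers"]:
        tab = r.model.coefficients.copy()
        tab.insert(0, "stratum", r.stratum)
        tab.insert(0, "interval", r.interval)
        tab["relative_importance"] = r.partition["relative_importance"].reindex(tab.index)
        coef_rows.append(tab.reset_index(names="predictor"))
    if coef_rows:
        io.write_csv(pd.concat(coef_rows, ignore_index=True), out / "driver_coefficients.csv",
                     "driver_coefficients", s, h, index=False)
    summary = {"cells": [r.summary() for r in results["drivers"]],
               "n_cells": len(results["drivers"]), "seed": s, "config_hash": h}
    (out / "driver_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    prov = {"config": dataclasses.asdict(config), "config_hash": h, "seed": s,
            "package_version": __version__}
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True, default=str))
    return out


def run_pipeline(config: PipelineConfig, base: Path | str = ".") -> dict:
    """Read inputs, run every stage, write the output bundle."""
    inputs = load_inputs(config, base)
    results = compute_results(inputs["censuses"], inputs["pool"], inputs["corner"],
                              inputs["habitat"], config)
    write_outputs(results, config)
    log.info("pipeline complete: %d driver cells", len(results["drivers"]))
    return results
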