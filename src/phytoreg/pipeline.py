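"""End-to-end orchestration: synthetic data → gridding → turnover →
districts/MRPP → NMDS → predictor selection → envfit → exclusive species
and tracks, with every intermediate artifact written to disk and a
reproducibility manifest (seeds, config hash, package version).

The configuration is a plain nested dataclass loadable from YAML; all
defaults transcribe the standard settings of the workflow (0.25° cells,
minimum five records per cell, 999 permutations, two final districts cut
from eight groups).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import environment as env_mod
from . import gridding, ordination, regionalization, ret_tracks, synthetic, turnover
from ._geo import read_feature_collection

__all__ = ["PipelineConfig", "StageError", "simulate", "run_pipeline", "default_config"]

STAGES = ("grid", "turnover", "cluster", "mrpp", "nmds", "env_select", "envfit", "tracks")


@dataclass
class GridConfig:
    origin: tuple[float, float] = (-102.0, 17.0)
    cell_size: float = 0.25
    min_records: int = 5
    search_radius: int = 2


@dataclass
class ClusteringConfig:
    k_groups: int = 8
    k_final: int = 2


@dataclass
class NmdsConfig:
    k: int = 2
    restarts: int = 20
    max_iter: int = 500
    tol: float = 1e-7
    seed: int = 11


@dataclass
class RdaConfig:
    collinearity_threshold: float = 0.8
    alpha: float = 0.05
    permutations: int = 999
    seed: int = 13


@dataclass
class MrppConfig:
    permutations: int = 999
    seed: int = 12


@dataclass
class EnvfitConfig:
    permutations: int = 999
    seed: int = 14


@dataclass
class SyntheticConfig:
    seed: int = 1
    landscape: synthetic.LandscapeSpec = field(default_factory=synthetic.LandscapeSpec)
    community: synthetic.CommunitySpec = field(default_factory=synthetic.CommunitySpec)
    layers: tuple = synthetic.DEFAULT_ENV_LAYERS


@dataclass
class PathsConfig:
    occurrences: str = "occurrences.csv"
    env: str = "env.csv"
    region: str | None = None
    truth: str | None = "truth.csv"
    outdir: str = "results"


@dataclass
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    nmds: NmdsConfig = field(default_factory=NmdsConfig)
    rda: RdaConfig = field(default_factory=RdaConfig)
    mrpp: MrppConfig = field(default_factory=MrppConfig)
    envfit: EnvfitConfig = field(default_factory=EnvfitConfig)
    synthetic: SyntheticConfig | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, values in raw.items():
            if not hasattr(cfg, section):
                raise ValueError(f"unknown config section {section!r}")
            target = getattr(cfg, section)
            if target is None and section == "synthetic":
                target = SyntheticConfig()
                cfg.synthetic = target
            for key, val in (values or {}).items():
                if not hasattr(target, key):
                    raise ValueError(f"unknown key {key!r} in section {section!r}")
                setattr(target, key, tuple(val) if isinstance(val, list) else val)
        return cfg


def default_config(outdir: str = "results", seed: int = 1) -> PipelineConfig:
    """Synthetic-preset configuration: all stage seeds derived from one seed."""
    cfg = PipelineConfig()
    cfg.paths.outdir = outdir
    cfg.synthetic = SyntheticConfig(seed=seed)
    cfg.synthetic.community = synthetic.CommunitySpec(seed=seed + 1)
    cfg.nmds.seed = seed + 2
    cfg.mrpp.seed = seed + 3
    cfg.rda.seed = seed + 4
    cfg.envfit.seed = seed + 5
    return cfg


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def simulate(config: PipelineConfig, outdir: str | Path | None = None) -> dict[str, Path]:
    """Generate the synthetic dataset on disk (occurrences, env, truth,
    cell polygons) and return the file paths."""
    if config.synthetic is None:
        raise ValueError("config has no synthetic section")
    out = Path(outdir if outdir is not None else config.paths.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.synthetic

    landscape = synthetic.generate_landscape(sc.landscape, seed=sc.seed)
    records = synthetic.generate_occurrences(landscape, sc.community)
    env = synthetic.generate_env_table(landscape, sc.layers, seed=sc.seed + 1000)

    paths = {
        "occurrences": out / "occurrences.csv",
        "env": out / "env.csv",
        "truth": out / "truth.csv",
        "cells": out / "cells.geojson",
    }
    synthetic.write_occurrences_csv(records, paths["occurrences"])
    synthetic.write_env_csv(env, paths["env"])
    synthetic.write_truth_csv(landscape, paths["truth"])
    synthetic.write_cells_geojson(landscape, paths["cells"])

    config.paths.occurrences = str(paths["occurrences"])
    config.paths.env = str(paths["env"])
    config.paths.truth = str(paths["truth"])
    # grid origin must match the landscape so env cell ids line up
    config.grid.origin = (sc.landscape.extent[0], sc.landscape.extent[1])
    config.grid.cell_size = sc.landscape.cell_size
    return paths


def run_pipeline(config: PipelineConfig, progress: bool = False) -> dict:
    """Run all stages in workflow order, writing artifacts under
    ``config.paths.outdir``; returns the in-memory results bundle."""
    out = Path(config.paths.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "package": "phytoreg",
        "version": __import__("phytoreg").__version__,
        "config_hash": config.config_hash(),
        "seeds": {
            "nmds": config.nmds.seed,
            "mrpp": config.mrpp.seed,
            "rda": config.rda.seed,
            "envfit": config.envfit.seed,
            "synthetic": config.synthetic.seed if config.synthetic else None,
        },
        "stages": {},
        "log": {},
    }

    def log(stage: str, **counts) -> None:
        manifest["log"][stage] = counts
        if progress:
            print(f"[{stage}] " + ", ".join(f"{k}={v}" for k, v in counts.items()))

    def record(stage: str, *files: Path) -> None:
        manifest["stages"][stage] = [str(f) for f in files]
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
            fh.write("\n")

    # --- stage: grid -----------------------------------------------------
    try:
        region = None
        if config.paths.region:
            geoms = [g for g, _ in read_feature_collection(config.paths.region)]
            region = geoms[0]
            for g in geoms[1:]:
                region = region.union(g)
        raw = gridding.read_occurrences_csv(config.paths.occurrences)
        curated, report = gridding.curate_records(raw, region_polygon=region)
        grid = gridding.GridSpec(
            origin=tuple(config.grid.origin),
            cell_size=config.grid.cell_size,
            region_polygon=region,
        )
        table0 = gridding.assign_to_grid(curated, grid)
        table = gridding.filter_and_merge(
            table0, min_records=config.grid.min_records, search_radius=config.grid.search_radius
        )
        incidence = gridding.incidence_matrix(table)
        table.write_long_csv(out / "cells_species.csv")
        table.write_geojson(out / "cell_polygons.geojson")
        table.merge_log.to_csv(out / "merge_log.csv", index=False)
        results.update(
            curation_report=report, cells_prefilter=table0, cells=table, incidence=incidence
        )
        log(
            "grid",
            records_in=len(raw),
            records_curated=len(curated),
            cells_original=len(table0.cells),
            cells_retained=len(table.cells),
            cells_merged=len(table.merge_log),
        )
        record("grid", out / "cells_species.csv", out / "cell_polygons.geojson", out / "merge_log.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("grid", e) from e

    # --- stage: turnover -------------------------------------------------
    try:
        dm = turnover.turnover_matrix(incidence)
        turnover.write_matrix_csv(dm, out / "betasim.csv")
        results["turnover"] = dm
        log("turnover", cells=len(dm.ids), mean_beta_sim=round(float(dm.condensed_form().mean()), 4))
        record("turnover", out / "betasim.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("turnover", e) from e

    # --- stage: cluster --------------------------------------------------
    try:
        dendro = regionalization.wpgma(dm)
        groups = regionalization.cut_tree(dendro, config.clustering.k_groups)
        assignment = regionalization.consolidate_districts(
            groups, dendro, k_final=config.clustering.k_final
        )
        dendro.write_newick(out / "dendrogram.nwk")
        assignment.write_csv(out / "assignment.csv")
        results.update(dendrogram=dendro, groups=groups, assignment=assignment)
        log(
            "cluster",
            k_groups=config.clustering.k_groups,
            k_final=config.clustering.k_final,
            reassigned=int((assignment.assignment["provenance"] == "reassigned").sum()),
        )
        record("cluster", out / "dendrogram.nwk", out / "assignment.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", e) from e

    # --- stage: mrpp -----------------------------------------------------
    try:
        mrpp_res = regionalization.mrpp(
            dm, assignment, permutations=config.mrpp.permutations, seed=config.mrpp.seed
        )
        with open(out / "mrpp.json", "w") as fh:
            json.dump(mrpp_res.to_dict(), fh, indent=1)
            fh.write("\n")
        results["mrpp"] = mrpp_res
        log("mrpp", delta=round(mrpp_res.observed_delta, 4), p=mrpp_res.p_value, A=round(mrpp_res.a_statistic, 4))
        record("mrpp", out / "mrpp.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("mrpp", e) from e

    # --- stage: nmds -----------------------------------------------------
    try:
        ord_res = ordination.nmds(
            dm,
            k=config.nmds.k,
            restarts=config.nmds.restarts,
            max_iter=config.nmds.max_iter,
            tol=config.nmds.tol,
            seed=config.nmds.seed,
        )
        ord_res.write_csv(out / "nmds_scores.csv")
        with open(out / "nmds.json", "w") as fh:
            json.dump(ord_res.to_report(), fh, indent=1)
            fh.write("\n")
        ordination.axis_maps(
            ord_res,
            assignment,
            cells=table.cells,
            grid=grid,
            geojson_path=out / "nmds_axes.geojson",
        )
        results["ordination"] = ord_res
        log("nmds", stress=round(ord_res.stress, 4), label=ordination.stress_quality(ord_res.stress))
        record("nmds", out / "nmds_scores.csv", out / "nmds.json", out / "nmds_axes.geojson")
    except Exception as e:  # noqa: BLE001
        raise StageError("nmds", e) from e

    # --- stage: env_select -----------------------------------------------
    try:
        env_raw = pd.read_csv(config.paths.env)
        if "cell_id" in env_raw.columns:
            env_table = env_raw.set_index("cell_id")
        else:
            env_table, _missing = env_mod.aggregate_pixels(env_raw, grid)
        env_table = env_table.reindex(incidence.index)
        if env_table.isna().any().any():
            missing = env_table.index[env_table.isna().any(axis=1)].tolist()
            raise ValueError(f"no environmental data for cells {missing}")
        env_pruned, prune_report = env_mod.prune_collinear(
            env_table, threshold=config.rda.collinearity_threshold
        )
        env_z, env_means, env_sds = env_mod.standardize(env_pruned)
        Yz, *_ = env_mod.standardize(
            incidence.loc[:, incidence.std(ddof=1) > 0].astype(float)
        )
        rda_full = env_mod.rda(Yz, env_z)
        fs = env_mod.forward_select(
            Yz,
            env_z,
            permutations=config.rda.permutations,
            alpha=config.rda.alpha,
            seed=config.rda.seed,
        )
        prune_report.to_csv(out / "pruning_report.csv", index=False)
        fs.write_csv(out / "rda_steps.csv")
        with open(out / "rda.json", "w") as fh:
            json.dump({"full_model": rda_full.to_dict(), "forward_selection": fs.to_dict()}, fh, indent=1)
            fh.write("\n")
        results.update(env=env_z, rda_full=rda_full, forward_selection=fs, prune_report=prune_report)
        log(
            "env_select",
            variables_in=env_table.shape[1],
            pruned=len(prune_report),
            selected=len(fs.selected),
            proportion_explained=round(fs.proportion_explained, 4),
        )
        record("env_select", out / "pruning_report.csv", out / "rda_steps.csv", out / "rda.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("env_select", e) from e

    # --- stage: envfit ---------------------------------------------------
    try:
        fit_vars = fs.selected if fs.selected else list(env_z.columns)
        ef = ret_tracks.envfit(
            ord_res.scores,
            env_z[fit_vars],
            permutations=config.envfit.permutations,
            seed=config.envfit.seed,
        )
        ef.to_csv(out / "envfit.csv", float_format="%.6g")
        results["envfit"] = ef
        log("envfit", variables=len(ef), significant=int((ef["p"] <= 0.001).sum()))
        record("envfit", out / "envfit.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("envfit", e) from e

    # --- stage: tracks ---------------------------------------------------
    try:
        excl = ret_tracks.exclusive_species(table.species_sets(), assignment)
        rows = [(d, sp) for d, spp in excl.items() for sp in spp]
        pd.DataFrame(rows, columns=["district", "species"]).to_csv(
            out / "exclusive_species.csv", index=False
        )
        tracks = []
        for district, spp in excl.items():
            recs = table.records[table.records["species"].isin(spp)]
            if recs[["lon", "lat"]].drop_duplicates().shape[0] >= 2:
                tracks.append(ret_tracks.mst_track(recs, district))
        ret_tracks.write_tracks_geojson(tracks, out / "tracks.geojson")
        results.update(exclusive=excl, tracks=tracks)
        log(
            "tracks",
            **{f"exclusive_{d}": len(spp) for d, spp in excl.items()},
            tracks=len(tracks),
        )
        record("tracks", out / "exclusive_species.csv", out / "tracks.geojson")
    except Exception as e:  # noqa: BLE001
        raise StageError("tracks", e) from e

    results["manifest"] = manifest
    return results
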