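"""End-to-end study orchestration.

``run_study`` executes the whole in-memory analysis on one landscape:
generate (or accept) layers and occurrence records, filter records, build
the doubling scale series, tile and fill sampling grids, resample the
environment to each grain, partition each qualifying grid's compositional
variance into the four variable groups, and aggregate to per-scale
summaries.  ``run_pipeline`` is the file-writing wrapper behind the CLI: it
resolves a :class:`RunConfig`, runs the study, and writes every stage table
as CSV next to a copy of the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import environment as env_mod
from . import gridding, occurrences, ordination, scaling_analysis, synthetic_data
from .environment import EnvironmentalLayer, VariableGroup, default_variable_groups

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    scales: list[gridding.ScaleSpec]
    partitions: list[ordination.PartitionResult]
    partition_df: pd.DataFrame
    grid_df: pd.DataFrame
    cv_df: pd.DataFrame
    grid_cv_df: pd.DataFrame
    summaries: list[scaling_analysis.ScaleSummary]
    summary_df: pd.DataFrame
    n_records: int
    groups: list[VariableGroup]


def _coarse_layers(
    fine: dict[str, EnvironmentalLayer],
    cell_side: float,
    class_names: dict[int, str],
) -> dict[str, EnvironmentalLayer]:
    """All analysis variables at one grain, on the scale's global cell lattice.

    Continuous variables take the cell mean, the LULC mosaic becomes one
    percent-cover layer per class, and elevation range is the cell
    max − min of the fine elevation layer.
    """
    out: dict[str, EnvironmentalLayer] = {}
    for name, layer in fine.items():
        if name == "lulc":
            out.update(env_mod.lattice_percent_cover(layer, cell_side, class_names))
        else:
            out[name] = env_mod.aggregate_to_lattice(layer, cell_side, how="mean")
    out["elevation_range"] = env_mod.aggregate_to_lattice(
        fine["elevation"], cell_side, how="range"
    )
    return out


def run_study(
    config: synthetic_data.LandscapeConfig,
    group_affinity: dict[str, float],
    seed: int,
    n_species: int = 24,
    n_target: int = 100000,
    base_grain: float | None = None,
    n_scales: int = 3,
    cv_convention: str = "sd_mean",
    min_nonsingleton_cells: int = gridding.MIN_NONSINGLETON_CELLS,
    min_species: int = gridding.MIN_SPECIES,
    tolerance_fraction: float = 0.15,
    layers: dict[str, EnvironmentalLayer] | None = None,
    records: pd.DataFrame | None = None,
) -> StudyResult:
    """Run the full synthetic multi-scale analysis for one landscape.

    All randomness derives from ``seed`` (landscape, species pool and
    occurrence sampling get independent child seeds).  Pre-built ``layers``
    and/or ``records`` bypass the corresponding generator stage.
    """
    s_land, s_pool, s_occ = (
        int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(3)
    )
    if layers is None:
        config = dataclasses.replace(config, seed=s_land)
        layers = synthetic_data.generate_landscape(config)
    if records is None:
        niches = synthetic_data.generate_species_pool(
            n_species,
            group_affinity,
            layers,
            seed=s_pool,
            tolerance_fraction=tolerance_fraction,
        )
        records = synthetic_data.sample_occurrences(layers, niches, n_target, seed=s_occ)
    records = occurrences.filter_precision(records)

    base = base_grain if base_grain is not None else config.pixel_area
    scales = gridding.build_scale_series(base, n_scales)
    class_names = config.class_names
    groups = default_variable_groups(
        tuple(class_names[k] for k in sorted(class_names))
    )

    ref = next(iter(layers.values()))
    study_bounds = ref.bounds

    partitions: list[ordination.PartitionResult] = []
    scale_of: dict[str, int] = {}
    all_grids: list[gridding.SamplingGrid] = []
    cv_frames: list[pd.DataFrame] = []
    for scale in scales:
        coarse = _coarse_layers(layers, scale.cell_side, class_names)
        grids = gridding.tile_grids(study_bounds, scale)
        for grid in grids:
            gridding.aggregate_occurrences(records, grid)
            ok, _reason = gridding.qualify_grid(
                grid, min_nonsingleton_cells, min_species
            )
            all_grids.append(grid)
            if not ok:
                continue
            env = env_mod.extract_environment(coarse, grid)
            part = ordination.partition_variance(
                grid.community, env, groups, grid_id=grid.grid_id
            )
            partitions.append(part)
            scale_of[grid.grid_id] = scale.index
            cv_frames.append(
                env_mod.cv_table(env, grid.grid_id, scale.index, cv_convention)
            )

    cv_df = (
        pd.concat(cv_frames, ignore_index=True)
        if cv_frames
        else pd.DataFrame(columns=["grid_id", "scale", "variable", "cv", "convention"])
    )
    grid_cv_df = scaling_analysis.group_cv_per_grid(
        cv_df, {g.name: g.members for g in groups}
    )
    summaries = []
    for scale in scales:
        parts_k = [p for p in partitions if scale_of[p.grid_id] == scale.index]
        s = scaling_analysis.summarize_scale(parts_k, grid_cv_df, scale.index)
        if s is not None:
            summaries.append(s)

    return StudyResult(
        scales=scales,
        partitions=partitions,
        partition_df=ordination.partition_table(partitions, scale_of),
        grid_df=gridding.grid_summary(all_grids),
        cv_df=cv_df,
        grid_cv_df=grid_cv_df,
        summaries=summaries,
        summary_df=scaling_analysis.summary_table(summaries),
        n_records=len(records),
        groups=groups,
    )


# ---------------------------------------------------------------------------
# File-based pipeline (CLI backend)
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative run configuration (YAML-serializable).

    Exactly one occurrence source must be given: a ``synthetic`` block (the
    generator settings) or an ``occurrences_csv`` path together with
    ``layers_dir`` holding ASCII-grid rasters.
    """

    out_dir: str
    synthetic: dict | None = None
    occurrences_csv: str | None = None
    layers_dir: str | None = None
    whitelist_file: str | None = None
    base_grain: float | None = None
    n_scales: int = 3
    n_species: int = 24
    n_target: int = 100000
    group_affinity: dict[str, float] = field(
        default_factory=lambda: {"climate": 1.0, "lulc": 1.0}
    )
    min_decimals: int = 3
    min_nonsingleton_cells: int = gridding.MIN_NONSINGLETON_CELLS
    min_species: int = gridding.MIN_SPECIES
    cv_convention: str = "sd_mean"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _load_layers(layers_dir: str) -> dict[str, EnvironmentalLayer]:
    layers = {}
    for p in sorted(Path(layers_dir).glob("*.asc")):
        name = p.stem
        kind = "categorical" if name == "lulc" else "continuous"
        layers[name] = env_mod.read_ascii_grid(p, name=name, kind=kind)
    if not layers:
        raise ValueError(f"no .asc layers found in {layers_dir}")
    if "lulc" not in layers:
        raise ValueError("layers_dir must contain a categorical 'lulc.asc' layer")
    return layers


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured study and write all stage outputs as CSV.

    Returns the output directory.  The resolved configuration is written
    next to the outputs so every run is reproducible from its own artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("scalepart")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if config.synthetic is None and config.occurrences_csv is None:
            raise ValueError(
                "config must provide an occurrence source: either a 'synthetic' "
                "generator block or an 'occurrences_csv' path (with 'layers_dir')"
            )

        land_cfg = synthetic_data.LandscapeConfig(**(config.synthetic or {}))
        layers = records = None
        if config.occurrences_csv is not None:
            if config.layers_dir is None:
                raise ValueError("'occurrences_csv' requires 'layers_dir'")
            layers = _load_layers(config.layers_dir)
            records = occurrences.read_occurrences(config.occurrences_csv)
            records = occurrences.filter_precision(records, config.min_decimals)
            if config.whitelist_file:
                wl = occurrences.SpeciesWhitelist.from_file(config.whitelist_file)
                records = occurrences.filter_whitelist(records, wl)

        result = run_study(
            land_cfg,
            group_affinity=config.group_affinity,
            seed=config.seed,
            n_species=config.n_species,
            n_target=config.n_target,
            base_grain=config.base_grain,
            n_scales=config.n_scales,
            cv_convention=config.cv_convention,
            min_nonsingleton_cells=config.min_nonsingleton_cells,
            min_species=config.min_species,
            layers=layers,
            records=records,
        )

        result.grid_df.to_csv(out / "grids.csv", index=False)
        result.partition_df.to_csv(out / "partitions.csv", index=False)
        result.cv_df.to_csv(out / "cv.csv", index=False)
        result.grid_cv_df.to_csv(out / "group_cv.csv", index=False)
        result.summary_df.to_csv(out / "scale_summary.csv", index=False)

        regs = []
        for g in result.groups:
            try:
                regs.append(
                    scaling_analysis.regress_variance_on_cv(result.summaries, g.name)
                )
            except ValueError as exc:
                logger.info("regression skipped for %s: %s", g.name, exc)
        scaling_analysis.regression_table(regs).to_csv(
            out / "regressions.csv", index=False
        )

        config.to_yaml(out / "config.resolved.yaml")
        counts = {
            "n_records": result.n_records,
            "n_grids": int(len(result.grid_df)),
            "n_qualified": int(result.grid_df["qualified"].fillna(False).sum()),
            "scales_used": [s.scale_index for s in result.summaries],
        }
        (out / "summary.json").write_text(json.dumps(counts, indent=2))
        logger.info("pipeline finished: %s", json.dumps(counts))
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
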