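"""Pipeline orchestration: one config in, a full report bundle out.

The bundle mirrors how such survey reports are assembled: per-element
descriptive statistics, the area-mean indicator summary, per-site indices,
interpolated HQ/PLI/Zc/B rasters with hazard-class area shares, the
correlation/PCA tables, and a machine-readable run log recording package
version, parameters and every default that filled a config gap.  Identical
config and seed give byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import platform
import sys
import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import indices as idx
from . import multivariate as mv
from . import spatial
from . import synthetic_data as synth
from .reference import pavlodar_registry
from .sample_io import read_reference_table, read_sample_table, validate_dataset, write_sample_table


@dataclass
class PipelineConfig:
    """Everything a reproduction run needs, loadable from one TOML file."""

    samples: str | None = None
    refs: str | None = None
    dialect: str = "csv"
    simulate_preset: str | None = None
    n_sites: int = synth.DEFAULT_N_SITES
    seed: int = 0
    out_dir: str = "soilrisk_out"
    cell_size: float = spatial.DEFAULT_CELL_SIZE
    padding: float = spatial.DEFAULT_PADDING
    levels: int = spatial.DEFAULT_LEVELS
    initial_lattice: int = spatial.DEFAULT_INITIAL_LATTICE
    mask: str | None = None
    zc_variant: str = "literal"
    run_indices: bool = True
    run_spatial: bool = True
    run_multivariate: bool = True
    run_figures: bool = False
    scales: dict = dc_field(default_factory=dict)
    defaults_used: list[str] = dc_field(default_factory=list)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        inp = raw.get("input", {})
        cfg.samples = inp.get("samples")
        cfg.refs = inp.get("refs")
        cfg.dialect = inp.get("dialect", cfg.dialect)
        sim = raw.get("simulate", {})
        cfg.simulate_preset = sim.get("preset")
        cfg.n_sites = sim.get("n_sites", cfg.n_sites)
        cfg.seed = raw.get("seed", sim.get("seed", cfg.seed))
        grid = raw.get("grid", {})
        for key, attr in (("cell_size", "cell_size"), ("padding", "padding"),
                          ("levels", "levels"), ("initial_lattice", "initial_lattice")):
            if key in grid:
                setattr(cfg, attr, grid[key])
            else:
                cfg.defaults_used.append(f"grid.{key}={getattr(cfg, attr)}")
        stages = raw.get("stages", {})
        cfg.run_indices = stages.get("indices", True)
        cfg.run_spatial = stages.get("spatial", True)
        cfg.run_multivariate = stages.get("multivariate", True)
        cfg.run_figures = stages.get("figures", False)
        cfg.mask = raw.get("mask")
        cfg.zc_variant = raw.get("zc_variant", cfg.zc_variant)
        out = raw.get("output", {})
        cfg.out_dir = out.get("dir", cfg.out_dir)
        for name, spec_ in raw.get("scales", {}).items():
            cfg.scales[name] = idx.ClassificationScale(
                name=name,
                breakpoints=tuple(spec_["breakpoints"]),
                labels=tuple(spec_["labels"]),
            )
        return cfg

    def resolve_scales(self) -> dict[str, idx.ClassificationScale]:
        scales = dict(idx.DEFAULT_SCALES)
        for name in scales:
            if name not in self.scales:
                self.defaults_used.append(f"scales.{name}=default")
        scales.update(self.scales)
        return scales


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all enabled stages; returns the manifest of written artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    scales = config.resolve_scales()

    def emit(name: str, path: Path) -> None:
        manifest[name] = str(path)

    # --- load or simulate the sample table
    try:
        if config.samples:
            table = read_sample_table(config.samples, dialect=config.dialect)
        elif config.simulate_preset:
            scenario = synth.preset(
                config.simulate_preset, n_sites=config.n_sites, seed=config.seed
            )
            table, _ = synth.generate_field(scenario)
            sim_path = out_dir / "simulated_samples.csv"
            write_sample_table(table, sim_path)
            emit("simulated_samples", sim_path)
        else:
            raise ValueError("config provides neither input.samples nor simulate.preset")
        registry = read_reference_table(config.refs) if config.refs else pavlodar_registry()
        if not config.refs:
            config.defaults_used.append("refs=builtin pavlodar registry")
        report = validate_dataset(table, registry)
        if not report.ok:
            raise ValueError("validation failed: " + "; ".join(report.errors))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        raise PipelineError("load", exc) from exc

    site_table = None
    if config.run_indices:
        try:
            stats = idx.descriptive_stats(table, registry)
            stats.rename_axis("element").to_csv(out_dir / "descriptive_stats.csv")
            emit("descriptive_stats", out_dir / "descriptive_stats.csv")
            summary = idx.area_mean_indices(table, registry, zc_variant=config.zc_variant)
            per_el = summary["per_element"].copy()
            per_el.rename_axis("element").to_csv(out_dir / "summary_per_element.csv")
            emit("summary_per_element", out_dir / "summary_per_element.csv")
            agg = {k: summary[k] for k in ("pli", "n_pli", "zc", "n_zc", "d", "df", "b_score")}
            pd.DataFrame([agg]).to_csv(out_dir / "summary_aggregates.csv", index=False)
            emit("summary_aggregates", out_dir / "summary_aggregates.csv")
            site_table = idx.site_indices(table, registry, scales, zc_variant=config.zc_variant)
            site_table.rename_axis("site_id").to_csv(out_dir / "site_indices.csv")
            emit("site_indices", out_dir / "site_indices.csv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("indices", exc) from exc

    if config.run_spatial:
        try:
            if site_table is None:
                site_table = idx.site_indices(table, registry, scales, zc_variant=config.zc_variant)
            grid_spec = spatial.make_grid_spec(
                table.bbox, cell_size=config.cell_size, padding=config.padding
            )
            mask = spatial.read_mask_geojson(config.mask) if config.mask else None
            points = table.coords
            for el in table.elements:
                hq = (table.conc[el] / registry[el].mpc).to_numpy()
                grid = spatial.fit_mbs_surface(
                    points, hq, grid_spec, config.levels, config.initial_lattice
                )
                spatial.write_ascii_grid(grid, out_dir / f"hq_{el}.asc")
                emit(f"hq_raster_{el}", out_dir / f"hq_{el}.asc")
            for name in ("pli", "zc", "b_score"):
                grid = spatial.fit_mbs_surface(
                    points, site_table[name].to_numpy(), grid_spec,
                    config.levels, config.initial_lattice,
                )
                spatial.write_ascii_grid(grid, out_dir / f"{name}.asc")
                emit(f"{name}_raster", out_dir / f"{name}.asc")
                scale = scales.get(name if name != "b_score" else "b")
                if scale is not None:
                    class_grid = spatial.classify_raster(grid, scale)
                    shares = spatial.area_shares(class_grid, scale, mask=mask)
                    shares.to_csv(out_dir / f"area_shares_{name}.csv")
                    emit(f"area_shares_{name}", out_dir / f"area_shares_{name}.csv")
                    mid_levels = list(scale.breakpoints)
                    contours = spatial.extract_contours(grid, mid_levels)
                    spatial.write_contours_geojson(contours, out_dir / f"contours_{name}.geojson")
                    emit(f"contours_{name}", out_dir / f"contours_{name}.geojson")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("spatial", exc) from exc

    if config.run_multivariate:
        try:
            corr = mv.pearson_matrix(table)
            corr.matrix.rename_axis("element").to_csv(out_dir / "correlation.csv")
            emit("correlation", out_dir / "correlation.csv")
            pca = mv.run_pca(table)
            pca.loadings.rename_axis("element").to_csv(out_dir / "pca_loadings.csv")
            pd.DataFrame(
                {"explained_variance_ratio": pca.explained_variance_ratio},
                index=pca.loadings.columns,
            ).rename_axis("component").to_csv(out_dir / "pca_variance.csv")
            pca.scores.rename_axis("site_id").to_csv(out_dir / "pca_scores.csv")
            emit("pca_loadings", out_dir / "pca_loadings.csv")
            emit("pca_variance", out_dir / "pca_variance.csv")
            emit("pca_scores", out_dir / "pca_scores.csv")
            if site_table is None:
                site_table = idx.site_indices(table, registry, scales, zc_variant=config.zc_variant)
            joint = mv.joint_index_correlation(pca, site_table, table)
            joint.matrix.rename_axis("variable").to_csv(out_dir / "joint_correlation.csv")
            emit("joint_correlation", out_dir / "joint_correlation.csv")
            if config.run_figures:
                _figures(corr, pca, out_dir, manifest)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("multivariate", exc) from exc

    log = {
        "soilrisk_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": {
            "cell_size": config.cell_size,
            "padding": config.padding,
            "levels": config.levels,
            "initial_lattice": config.initial_lattice,
            "zc_variant": config.zc_variant,
        },
        "defaults_used": config.defaults_used,
        "artifacts": sorted(manifest),
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    manifest["run_log"] = str(out_dir / "run_log.json")
    return manifest


def _figures(corr, pca, out_dir: Path, manifest: dict) -> None:
    # Presentation artifacts only; nothing numeric depends on them.
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.matrix)), corr.matrix.columns, rotation=90)
    ax.set_yticks(range(len(corr.matrix)), corr.matrix.index)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(out_dir / "correlation_heatmap.svg")
    plt.close(fig)
    manifest["correlation_heatmap"] = str(out_dir / "correlation_heatmap.svg")

    fig, ax = plt.subplots()
    ratios = pca.explained_variance_ratio
    ax.plot(range(1, len(ratios) + 1), ratios, "o-")
    ax.set_xlabel("principal component")
    ax.set_ylabel("explained variance ratio")
    fig.tight_layout()
    fig.savefig(out_dir / "scree.svg")
    plt.close(fig)
    manifest["scree"] = str(out_dir / "scree.svg")
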