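"""Interchange formats, pipeline configuration and the pipeline driver.

Formats
-------
* Sample tables: CSV with columns ``sample_id, station_id, lon, lat,
  depth_m`` then one column per species (cells L⁻¹); species columns
  are auto-detected as everything after ``depth_m``.
* Matrices (exposure, connectivity, dissimilarity): CSV, comma
  separated, UTF-8, '.' decimal, row labels in column 1, header row of
  column labels.
* Gridded fields (velocity, tracer snapshots): NetCDF-style files via
  xarray with the scipy backend (dims ``y, x`` [, ``tracer``],
  variables ``u``, ``v``, ``phi``).
* Configs: YAML; every output directory gets a JSON manifest with the
  config hash and all seeds so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .community_stats import (
    REQUIRED_COLUMNS,
    DissimilarityMatrix,
    Ordination2D,
    SampleTable,
    anosim,
    bray_curtis,
    nmds2,
)
from .connectivity import DISSIMILARITY_TRANSFORM, connectivity_to_dissimilarity
from .linkage import assign_domains, explainers_table, filter_by_depth
from .synth import (
    Scenario,
    build_scenario,
    default_community_model,
    run_connectivity,
    synth_communities,
)

logger = logging.getLogger("oceanconn")

__all__ = [
    "PipelineConfig",
    "read_sample_table",
    "write_sample_table",
    "read_matrix_csv",
    "write_matrix_csv",
    "write_gridded_field",
    "read_gridded_field",
    "describe_samples",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full pipeline run."""

    scenario: str = "barrier_jet"
    overrides: dict = field(default_factory=dict)
    sample_table: str | None = None
    depth_cutoff: float = 20.0
    nmds_restarts: int = 20
    n_perm: int = 9999
    seed: int = 0
    samples_per_domain: int = 6
    sigma: float = 0.6
    community_mode: str = "connectivity"
    outdir: str = "oceanconn_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Tables and matrices

def read_sample_table(path: str | Path) -> SampleTable:
    """Read and validate a sample table CSV.

    Species columns are all columns after ``depth_m``.  Schema
    violations (missing columns, negative or non-numeric abundances)
    raise with the offending column or row named.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    species = list(df.columns[df.columns.get_loc("depth_m") + 1 :])
    if not species:
        raise ValueError(f"{path}: no species columns found after depth_m")
    for col in species + ["lon", "lat", "depth_m"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0]}"
            )
        df[col] = vals
    for col in species:
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValueError(
                f"{path}: negative abundance in column {col!r}, row {neg[0]}"
            )
    return SampleTable(data=df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def write_matrix_csv(
    M: np.ndarray, labels: list[str], path: str | Path, index_name: str = "label"
) -> None:
    df = pd.DataFrame(np.asarray(M), index=labels, columns=labels)
    df.index.name = index_name
    df.to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row labels do not match column labels")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


# ---------------------------------------------------------------------------
# Gridded fields (NetCDF-style via the scipy backend)

def write_gridded_field(
    path: str | Path,
    grid,
    *,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
    phi: np.ndarray | None = None,
    tracer_labels: list[str] | None = None,
) -> None:
    """Write velocity components and/or tracer fields to a NetCDF file.

    ``phi`` may be (ny, nx) or (n_tracers, ny, nx); in the latter case a
    ``tracer`` dimension with label coordinates is written.
    """
    coords = {"x": grid.x_centers(), "y": grid.y_centers()}
    data = {}
    if u is not None:
        data["u"] = (("y", "x"), np.asarray(u))
    if v is not None:
        data["v"] = (("y", "x"), np.asarray(v))
    if phi is not None:
        phi = np.asarray(phi)
        if phi.ndim == 2:
            data["phi"] = (("y", "x"), phi)
        else:
            data["phi"] = (("tracer", "y", "x"), phi)
            coords["tracer"] = tracer_labels or [
                str(k) for k in range(phi.shape[0])
            ]
    ds = xr.Dataset(data, coords=coords)
    ds.attrs["dx"] = grid.dx
    ds.attrs["dy"] = grid.dy
    ds.to_netcdf(path, engine="scipy")


def read_gridded_field(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


# ---------------------------------------------------------------------------
# Descriptive statistics for the analyze path

def describe_samples(table: SampleTable, prevalence_cutoff: float = 0.30) -> dict:
    """Per-species presence fractions and maxima, plus sample counts.

    Mirrors the descriptive numbers a field study reports about its
    species table: in how many samples each taxon occurs, its maximum
    abundance, and how many taxa exceed a prevalence cutoff.
    """
    ab = table.abundances()
    present = (ab > 0).mean(axis=0)
    return {
        "n_samples": int(len(table)),
        "n_species": len(table.species),
        "presence_fraction": {sp: float(present[sp]) for sp in table.species},
        "max_abundance": {sp: float(ab[sp].max()) for sp in table.species},
        "mean_abundance": {sp: float(ab[sp].mean()) for sp in table.species},
        "n_species_above_prevalence": int((present > prevalence_cutoff).sum()),
        "prevalence_cutoff": prevalence_cutoff,
    }


# ---------------------------------------------------------------------------
# Pipeline

def _write_ordination(ord_: Ordination2D, stem: Path) -> None:
    df = pd.DataFrame(
        {
            "label": ord_.labels,
            "axis1": ord_.coordinates[:, 0],
            "axis2": ord_.coordinates[:, 1],
        }
    )
    df.to_csv(stem.with_suffix(".csv"), index=False)
    meta = {
        "stress": ord_.stress,
        "n_restarts": ord_.n_restarts,
        "seed": ord_.seed,
        "converged": ord_.converged,
    }
    stem.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def _sector_of(label: str) -> str:
    return label.rstrip("0123456789")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact directory.

    Stages, in order: tracer integration (final fields to NetCDF),
    exposure and connectivity matrices (labelled CSV + metadata),
    connectivity ordination, sample table (loaded or synthesised),
    depth filter, community Bray–Curtis + ordination, ANOSIM by sector,
    per-domain linkage regressions, and a manifest.  Outputs contain no
    timestamps, so a rerun with the same config is byte-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    scenario = build_scenario(
        config.scenario, overrides=config.overrides, seed=config.seed
    )
    logger.info("stage=scenario name=%s", scenario.name)

    # --- tracers + connectivity ------------------------------------------
    from .tracer_transport import run_exposure

    acc = run_exposure(
        scenario.grid,
        scenario.field,
        scenario.subdomains,
        scenario.K,
        scenario.horizon,
        boundary=scenario.boundary,
    )
    from .connectivity import connectivity_matrix, exposure_time

    expo = exposure_time(acc)
    areas = np.array([d.area for d in scenario.subdomains])
    conn = connectivity_matrix(expo, areas, scenario.tau)
    logger.info("stage=tracer t=%.2fs", time.perf_counter() - t0)

    write_matrix_csv(expo.T, expo.labels, out / "exposure_time_days.csv")
    write_matrix_csv(conn.P, conn.labels, out / "connectivity_per_m2.csv")
    (out / "connectivity.meta.json").write_text(
        json.dumps(
            {
                "tau_days": scenario.tau,
                "horizon_days": scenario.horizon,
                "diffusivity_m2_s": scenario.K,
                "boundary": scenario.boundary,
                "dissimilarity_transform": DISSIMILARITY_TRANSFORM,
                "grid": {
                    "nx": scenario.grid.nx,
                    "ny": scenario.grid.ny,
                    "dx": scenario.grid.dx,
                    "dy": scenario.grid.dy,
                },
            },
            indent=2,
        )
    )
    write_gridded_field(
        out / "velocity.nc", scenario.grid, u=scenario.field.u, v=scenario.field.v
    )

    conn_diss = connectivity_to_dissimilarity(conn)
    conn_ord = nmds2(conn_diss, n_restarts=config.nmds_restarts, seed=config.seed)
    _write_ordination(conn_ord, out / "ordination_connectivity")
    logger.info(
        "stage=connectivity_ordination stress=%.4f t=%.2fs",
        conn_ord.stress,
        time.perf_counter() - t0,
    )

    # --- samples ----------------------------------------------------------
    if config.sample_table:
        table = read_sample_table(config.sample_table)
        source = "file"
    else:
        model = default_community_model(
            scenario,
            sigma=config.sigma,
            samples_per_domain=config.samples_per_domain,
            mode=config.community_mode,
        )
        table = synth_communities(model, conn, seed=config.seed + 1)
        source = "synthetic"
    write_sample_table(table, out / "sample_table.csv")

    deep = filter_by_depth(table, config.depth_cutoff)
    logger.info(
        "stage=depth_filter cutoff=%.1f retained=%d/%d",
        config.depth_cutoff,
        len(deep),
        len(table),
    )

    bc = bray_curtis(deep)
    write_matrix_csv(bc.D, bc.labels, out / "bray_curtis.csv")
    eco_ord = nmds2(bc, n_restarts=config.nmds_restarts, seed=config.seed + 2)
    _write_ordination(eco_ord, out / "ordination_community")

    assign = assign_domains(deep, scenario.subdomains, scenario.grid, scenario.georef)
    groups = [_sector_of(assign.domain_of[s]) for s in deep.sample_ids]
    anosim_res = None
    sizes = pd.Series(groups).value_counts()
    if len(sizes) >= 2 and (sizes >= 2).all():
        anosim_res = anosim(
            bc, groups, n_perm=config.n_perm, seed=config.seed + 3
        )
        (out / "anosim.json").write_text(
            json.dumps(
                {
                    "grouping": "bathymetric_sector",
                    "R": anosim_res.R,
                    "p": anosim_res.p,
                    "n_perm": anosim_res.n_perm,
                    "method": anosim_res.method,
                    "seed": anosim_res.seed,
                },
                indent=2,
            )
        )
        logger.info("stage=anosim R=%.3f p=%.4g", anosim_res.R, anosim_res.p)

    link = explainers_table(eco_ord, conn_ord, deep, assign)
    link.with_significance().to_csv(out / "linkage_table.csv", index=False)

    stats_block = describe_samples(table)
    stats_block["n_below_cutoff"] = int(len(deep))
    stats_block["community_nmds_stress"] = eco_ord.stress
    stats_block["connectivity_nmds_stress"] = conn_ord.stress
    if anosim_res is not None:
        stats_block["anosim_R"] = anosim_res.R
        stats_block["anosim_p"] = anosim_res.p
    (out / "descriptive_stats.json").write_text(json.dumps(stats_block, indent=2))

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "sample_source": source,
        "seeds": {
            "scenario": config.seed,
            "communities": config.seed + 1 if source == "synthetic" else None,
            "nmds_community": config.seed + 2,
            "anosim": config.seed + 3,
        },
        "n_samples": len(table),
        "n_samples_below_cutoff": len(deep),
        "format_version": 1,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("stage=done t=%.2fs out=%s", time.perf_counter() - t0, out)
    return out
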