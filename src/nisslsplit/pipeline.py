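"""End-to-end pipeline: preprocess → channel split → fusion → morphometry,
with a validated config, per-stage logging and a checksummed artifact
manifest.  Re-running with identical input and config reproduces identical
checksums (no stage here uses randomness)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import channels as ch
from . import morphometry as mm
from . import preprocess as pp
from .errors import ValidationError
from .volume import LabelVolume, Volume, read_volume, write_volume

log = logging.getLogger(__name__)


class PreprocessParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    background: bool = True
    window_um: float = 250.0
    destripe: bool = True
    max_peaks: int = 4
    contrast: bool = True
    p_low: float = 0.05
    p_high: float = 99.95


class BandParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dark_quantile: float = 0.09
    bright_quantile: float = 0.9975


class VesselParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    seed_quantile: float = 0.9985
    grow_tolerance: float = 8.0
    min_component_um3: float = 250.0


class PlaqueParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    core_radius_um: float = 5.0
    rim_inner_um: float = 5.5
    rim_outer_um: float = 6.5
    # min contrast as a fraction of (t_bright − t_dark): invariant to the
    # (affine) contrast stretch applied during preprocessing
    min_score_frac: float = 0.75
    rim_elevation_frac: float = 0.12
    min_diameter_um: float = 10.0
    max_diameter_um: float = 55.0


class DarkBodyParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    soma_diameter_range_um: tuple[float, float] = (5.0, 18.0)
    tract_min_diameter_um: float = 30.0
    elongation_min: float = 2.0
    soma_small_max_um: float = 10.0


class ProcessParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    tubeness_min: float = 2.0
    sigma_um: float = 1.0


class MorphometryParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    heatmap_bin_edge_um: float = 100.0
    export_meshes: bool = False


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    input: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    output_dir: str = "nisslsplit_out"
    preprocess: PreprocessParams = Field(default_factory=PreprocessParams)
    bands: BandParams = Field(default_factory=BandParams)
    vessels: VesselParams = Field(default_factory=VesselParams)
    plaques: PlaqueParams = Field(default_factory=PlaqueParams)
    dark_bodies: DarkBodyParams = Field(default_factory=DarkBodyParams)
    processes: ProcessParams = Field(default_factory=ProcessParams)
    morphometry: MorphometryParams = Field(default_factory=MorphometryParams)
    seed: int | None = None  # used only by the phantom subcommand

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Artifacts:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.paths: list[Path] = []

    def add(self, path: Path) -> None:
        self.paths.append(path)

    def csv(self, df: pd.DataFrame, name: str) -> Path:
        p = self.outdir / name
        df.to_csv(p, index=False)
        self.add(p)
        return p

    def tif(self, vol: Volume | LabelVolume, name: str) -> Path:
        p = self.outdir / name
        write_volume(vol, p)
        self.add(p)
        if isinstance(vol, LabelVolume):
            self.add(Path(str(p) + ".legend.txt"))
        return p

    def json(self, obj, name: str) -> Path:
        p = self.outdir / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        self.add(p)
        return p


def _stage(name: str, **params):
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in params.items()))
    return time.time()


def run_preprocess(volume: Volume, params: PreprocessParams) -> tuple[Volume, list[dict]]:
    reports = []
    if params.background:
        volume, rep = pp.correct_background(volume, window_um=params.window_um)
        reports.append(rep.to_dict())
    if params.destripe:
        volume, rep = pp.remove_periodic_noise(volume, max_peaks=params.max_peaks)
        reports.append(rep.to_dict())
    if params.contrast:
        volume, rep = pp.enhance_contrast(volume, p_low=params.p_low, p_high=params.p_high)
        reports.append(rep.to_dict())
    return volume, reports


def run_pipeline(config: PipelineConfig, volume: Volume | None = None) -> dict:
    """Execute the full pipeline and return the artifact manifest.

    ``volume`` may be passed directly (e.g. a freshly generated phantom);
    otherwise ``config.input`` is read from disk.  All artifacts plus the
    resolved config land in ``config.output_dir``; the manifest maps artifact
    names to SHA-256 checksums.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    art = _Artifacts(outdir)
    if volume is None:
        _stage("read", input=config.input)
        volume = read_volume(config.input, config.spacing)

    # written beside the outputs but not checksummed: it embeds run paths
    (outdir / "config.resolved.yaml").write_text(
        yaml.safe_dump(config.model_dump(mode="json"))
    )

    t0 = _stage("preprocess", **config.preprocess.model_dump())
    pre, reports = run_preprocess(volume, config.preprocess)
    art.tif(pre, "preprocessed.tif")
    art.json(reports, "preprocess_report.json")
    log.info("stage=preprocess done in %.1fs", time.time() - t0)

    t0 = _stage("bands", **config.bands.model_dump())
    bands = ch.fit_band_thresholds(
        pre, config.bands.dark_quantile, config.bands.bright_quantile
    )
    log.info("bands t_dark=%.1f t_bright=%.1f", bands.t_dark, bands.t_bright)

    chans = ch.ChannelSet(spacing=pre.spacing)
    score = None
    plaque_table = pd.DataFrame()
    if config.vessels.enabled:
        t0 = _stage("vessels", **config.vessels.model_dump())
        chans.vessel = ch.extract_vessels(
            pre, bands,
            seed_quantile=config.vessels.seed_quantile,
            grow_tolerance=config.vessels.grow_tolerance,
            min_component_um3=config.vessels.min_component_um3,
        )
        log.info("stage=vessels done in %.1fs (%d voxels)", time.time() - t0,
                 int(chans.vessel.sum()))
    if config.plaques.enabled:
        t0 = _stage("plaques", **config.plaques.model_dump())
        pq = config.plaques
        params = ch.PlaqueSignatureParams(
            core_radius_um=pq.core_radius_um,
            rim_inner_um=pq.rim_inner_um,
            rim_outer_um=pq.rim_outer_um,
            min_score=pq.min_score_frac * (bands.t_bright - bands.t_dark),
            min_diameter_um=pq.min_diameter_um,
            max_diameter_um=pq.max_diameter_um,
        )
        score = ch.multiscale_plaque_score(pre, params)
        chans.plaque, _prov = ch.detect_plaques(
            pre, params, bands, score=score,
            rim_elevation_frac=pq.rim_elevation_frac,
        )
        log.info("stage=plaques done in %.1fs (%d detections)", time.time() - t0, len(_prov))
    if config.dark_bodies.enabled:
        t0 = _stage("dark_bodies", **config.dark_bodies.model_dump())
        exclude = [m for m in (chans.vessel, chans.plaque) if m is not None]
        db = config.dark_bodies
        chans.soma, chans.tract, soma_table = ch.detect_dark_bodies(
            pre, bands, exclude,
            soma_diameter_range_um=db.soma_diameter_range_um,
            tract_min_diameter_um=db.tract_min_diameter_um,
            elongation_min=db.elongation_min,
            soma_small_max_um=db.soma_small_max_um,
        )
        art.csv(soma_table, "somata.csv")
        log.info("stage=dark_bodies done in %.1fs (%d somata)", time.time() - t0,
                 len(soma_table))
    if config.processes.enabled:
        t0 = _stage("processes", **config.processes.model_dump())
        exclude = [m for m in (chans.vessel, chans.plaque, chans.soma, chans.tract)
                   if m is not None]
        chans.process = ch.extract_processes(
            pre, bands, exclude,
            tubeness_min=config.processes.tubeness_min,
            sigma_um=config.processes.sigma_um,
        )
        log.info("stage=processes done in %.1fs", time.time() - t0)

    t0 = _stage("fuse")
    fused = ch.fuse_channels(chans)
    art.tif(fused, "labels.tif")
    for name, _mask in chans.items():
        art.tif(Volume(fused.mask(name).astype(np.uint8) * 255, pre.spacing, bit_depth=8),
                f"mask_{name}.tif")
    log.info("stage=fuse done in %.1fs", time.time() - t0)

    t0 = _stage("morphometry")
    if chans.plaque is not None:
        plaque_table = mm.plaque_morphometry(
            fused.mask("plaque") if config.plaques.enabled else chans.plaque,
            pre, score=score,
        )
        plaque_table, bin_counts = mm.bin_by_diameter(plaque_table)
        art.csv(plaque_table, "plaques.csv")
        art.json(bin_counts, "diameter_bins.json")
        cents = plaque_table[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
        grid = mm.density_heatmap(
            cents, bin_edge_um=config.morphometry.heatmap_bin_edge_um,
            extent_um=pre.extent_um,
        )
        art.tif(Volume(np.clip(grid.counts, 0, 65535).astype(np.uint16),
                       (grid.bin_edge_um,) * 3, bit_depth=16), "plaque_density.tif")
        if config.morphometry.export_meshes and chans.plaque.any():
            art.add(mm.export_mesh(chans.plaque, pre.spacing, outdir / "plaques.obj"))
    if chans.vessel is not None:
        graph = mm.skeletonize_vessels(chans.vessel, pre.spacing)
        art.csv(graph.to_frame(), "vessel_graph.csv")
        if chans.plaque is not None and len(plaque_table):
            prox, summary = mm.plaque_vessel_proximity(plaque_table, graph)
            art.csv(prox, "plaque_vessel_proximity.csv")
            art.json(summary, "proximity_summary.json")
    log.info("stage=morphometry done in %.1fs", time.time() - t0)

    manifest = {
        "artifacts": {p.name: _sha256(p) for p in art.paths},
        "n_artifacts": len(art.paths),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
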