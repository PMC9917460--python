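"""Stage orchestration: simulate/load → segment → zones → quantify → stats.

A :class:`RunConfig` (one YAML file) drives the whole chain.  Every output
CSV carries the config hash and seed in a comment header, so a rerun with
an identical config is byte-identical and any table can be traced back to
its parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quantify
from .image import (BinaryMask, CalibratedImage, LabelMap, read_image,
                    write_image, write_labels)
from .segmentation import (SegmentationParams, detect_particles,
                           make_clone_labels, make_disc_mask)
from .synthetic import GroundTruth, SyntheticSpec, simulate
from .zonation import ZoneMap, ZoneParams, build_zone_map

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (exit code 2 in the CLI)."""


DEFAULT_CHANNEL_MAP = {"dapi": "DAPI", "gfp": "GFP", "reporter": "TRE",
                       "cdcp1": "cDcp1"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a TIFF) or ``simulate`` (a SyntheticSpec)
    must be given.
    """

    output_dir: str = "pipeline_out"
    input_path: str | None = None
    simulate: SyntheticSpec | None = None
    channel_names: list[str] | None = None  # order in the input TIFF
    channel_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    pixel_size_um: float | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    zones: ZoneParams = field(default_factory=ZoneParams)
    per_clone: bool = True
    seed: int = 0
    disc_id: str = "disc"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of input_path / simulate must be set"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        try:
            if "simulate" in raw and raw["simulate"] is not None:
                sim = dict(raw["simulate"])
                for key in ("shape_px", "disc_axes_um", "disc_center_um",
                            "growth_steps"):
                    if key in sim and isinstance(sim[key], list):
                        sim[key] = tuple(sim[key])
                raw["simulate"] = SyntheticSpec(**sim)
            if "segmentation" in raw:
                raw["segmentation"] = SegmentationParams(**raw["segmentation"])
            if "zones" in raw:
                raw["zones"] = ZoneParams(**raw["zones"])
            return cls(**raw)
        except (TypeError, ValueError) as err:
            raise ConfigError(str(err)) from err

    def to_canonical(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        Where outputs land (and how verbosely the run logs) does not change
        the results, so those keys are excluded: the same analysis written
        to two directories carries one hash.
        """
        canonical = self.to_canonical()
        for key in ("output_dir", "log_level"):
            canonical.pop(key, None)
        blob = json.dumps(canonical, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    image: CalibratedImage
    disc: BinaryMask
    clones: LabelMap
    particles: BinaryMask
    zones: ZoneMap
    zone_stats: pd.DataFrame
    apoptosis_stats: pd.DataFrame
    clone_table: pd.DataFrame
    truth: GroundTruth | None = None
    config_hash: str = ""


def _csv_header(config: RunConfig) -> str:
    return (f"# mosaicband config_hash={config.hash()} seed={config.seed}\n")


def _write_csv(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_csv_header(config))
        df.to_csv(fh, index=False)


def load_input(config: RunConfig) -> tuple[CalibratedImage, GroundTruth | None]:
    if config.simulate is not None:
        spec = dataclasses.replace(config.simulate, seed=config.seed)
        image, truth = simulate(spec)
        return image, truth
    image = read_image(config.input_path, config.channel_names,
                       config.pixel_size_um)
    return image, None


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full stage graph for one field of view.

    Stages: acquire (simulate or read) → disc mask → clone labels →
    particle mask → zone map → tidy measurement tables.  Outputs are
    written under ``config.output_dir`` unless ``write=False``.
    """
    image, truth = load_input(config)
    cmap = config.channel_map
    for role in ("dapi", "gfp", "cdcp1"):
        name = cmap.get(role)
        if name not in image.channels:
            raise ConfigError(
                f"configured {role} channel {name!r} not found in input; "
                f"available: {sorted(image.channels)}"
            )
    seg = config.segmentation
    disc = make_disc_mask(image.channel(cmap["dapi"]), seg,
                          image.pixel_size_um)
    clones = make_clone_labels(image.channel(cmap["gfp"]), disc, seg)
    particles = detect_particles(image.channel(cmap["cdcp1"]), disc, seg)
    zones = build_zone_map(disc, clones, config.zones)
    log.info(
        "segmented disc=%.0f um2, %d clones (%d border), particles=%.0f um2",
        disc.area_um2, clones.n_labels, len(clones.border_labels),
        particles.area_um2,
    )

    reporter = cmap.get("reporter")
    intensity_channels = {}
    if reporter and reporter in image.channels:
        intensity_channels[reporter] = image.channel(reporter)
    zone_stats = pd.concat(
        [quantify.zone_intensity(img, zones, per_clone=config.per_clone,
                                 channel=name, disc_id=config.disc_id)
         for name, img in intensity_channels.items()],
        ignore_index=True,
    ) if intensity_channels else pd.DataFrame(columns=quantify.TIDY_COLUMNS)
    apoptosis = quantify.percent_apoptotic(particles, zones,
                                           per_clone=config.per_clone,
                                           disc_id=config.disc_id)
    clone_table = quantify.clone_zone_table(
        intensity_channels, particles, zones, clones, disc_id=config.disc_id)

    result = PipelineResult(image, disc, clones, particles, zones,
                            zone_stats, apoptosis, clone_table, truth,
                            config.hash())
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_image(out / "channels.ome.tif", image)
        write_labels(out / "disc_mask.tif", disc)
        write_labels(out / "clone_labels.tif", clones)
        write_labels(out / "particle_mask.tif", particles)
        zone_lm = LabelMap(zones.zone.astype(np.int32), zones.pixel_size_um)
        write_labels(out / "zone_class.tif", zone_lm)
        owner_lm = LabelMap(zones.owner, zones.pixel_size_um)
        write_labels(out / "zone_owner.tif", owner_lm)
        _write_csv(out / "zone_stats.csv", zone_stats, config)
        _write_csv(out / "apoptosis_stats.csv", apoptosis, config)
        _write_csv(out / "clone_table.csv", clone_table, config)
        (out / "config.json").write_text(
            json.dumps({"config": config.to_canonical(),
                        "config_hash": config.hash()}, sort_keys=True,
                       indent=2)
        )
    return result
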