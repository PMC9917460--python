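"""Calibrated image containers and TIFF IO.

All pipeline stages operate on 2D channels with an isotropic physical
calibration (``pixel_size_um``).  The containers here are thin, validated
wrappers around numpy arrays; conversions between pixel counts and physical
areas happen in one place so they cannot drift between modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile


class CalibrationError(ValueError):
    """Raised when pixel sizes or shapes of combined objects disagree."""


@dataclass
class CalibratedImage:
    """Named 2D intensity channels sharing one shape and pixel size.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"DAPI"``, ``"GFP"``, ``"TRE"``,
        ``"cDcp1"``) to a 2D float array of non-negative intensities in
        arbitrary units.
    pixel_size_um
        Isotropic physical size of one pixel, in micrometres.
    projection_note
        Free text describing how z-information was reduced (e.g.
        "max projection of slices 2-4 of the basal stack").
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    projection_note: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("CalibratedImage needs at least one channel")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first or len(s) != 2 for s in shapes.values()):
            raise ValueError(f"channels must share one 2D shape, got {shapes}")
        clean = {}
        for name, ch in self.channels.items():
            arr = np.asarray(ch, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            clean[name] = arr
        self.channels = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None


@dataclass
class BinaryMask:
    """A boolean pixel mask with physical calibration."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2


@dataclass
class LabelMap:
    """Non-negative integer labels; 0 is background.

    Positive labels are consecutive from 1, each one 8-connected component
    (enforced by the producing operations, asserted cheaply here).
    ``border_labels`` records components that touch the disc border and are
    excluded from per-clone statistics by default.
    """

    labels: np.ndarray
    pixel_size_um: float
    border_labels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        self.border_labels = frozenset(int(b) for b in self.border_labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def areas_um2(self) -> dict[int, float]:
        """Area of each positive label, in µm²."""
        counts = np.bincount(self.labels.ravel())
        return {
            lab: float(counts[lab]) * self.pixel_size_um**2
            for lab in range(1, len(counts))
            if counts[lab] > 0
        }

    def foreground(self) -> np.ndarray:
        return self.labels > 0


def check_same_grid(*objs) -> None:
    """Raise CalibrationError unless all objects share shape and pixel size."""
    shapes = {o.shape for o in objs}
    sizes = {round(float(o.pixel_size_um), 9) for o in objs}
    if len(shapes) > 1:
        raise CalibrationError(f"shape mismatch: {shapes}")
    if len(sizes) > 1:
        raise CalibrationError(f"pixel size mismatch: {sizes}")


# ---------------------------------------------------------------------------
# TIFF IO


def read_image(
    path: str | Path,
    channel_names: list[str] | None = None,
    pixel_size_um: float | None = None,
    projection_note: str = "",
) -> CalibratedImage:
    """Read a single- or multi-channel (OME-)TIFF into a CalibratedImage.

    Pixel size is taken from OME metadata or TIFF resolution tags unless
    overridden.  A 3D array is interpreted as channels-first.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tiff(tf)
    if pixel_size_um is None:
        raise CalibrationError(
            f"{path}: no pixel size in metadata; pass pixel_size_um explicitly"
        )
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2D or 3D (C,Y,X) data, got {arr.shape}")
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(arr.shape[0])]
    if len(channel_names) != arr.shape[0]:
        raise ValueError(
            f"{path}: {arr.shape[0]} channels but {len(channel_names)} names"
        )
    channels = {name: arr[i].astype(float) for i, name in enumerate(channel_names)}
    return CalibratedImage(channels, pixel_size_um, projection_note)


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    if tf.ome_metadata:
        # tifffile exposes OME physical sizes via xml; parse the attribute.
        import re

        m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tf.ome_metadata)
        if m:
            return float(m.group(1))
    page = tf.pages[0]
    res = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if res is not None and unit is not None:
        num, den = res.value
        if num and unit.value == 3:  # pixels per centimetre
            return 1e4 * den / num
        if num and unit.value == 2:  # pixels per inch
            return 25400.0 * den / num
    return None


def write_image(path: str | Path, image: CalibratedImage) -> None:
    """Write channels as an OME-TIFF with pixel size in metadata."""
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
        },
        ome=True,
    )


def write_labels(path: str | Path, labels: LabelMap | BinaryMask) -> None:
    """Write a mask or label map as 16-bit TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    if isinstance(labels, BinaryMask):
        data = labels.pixels.astype(np.uint16)
        meta = {"kind": "binary_mask"}
    else:
        if labels.n_labels > np.iinfo(np.uint16).max:
            raise ValueError("too many labels for 16-bit TIFF")
        data = labels.labels.astype(np.uint16)
        meta = {"kind": "label_map", "border_labels": sorted(labels.border_labels)}
    tifffile.imwrite(path, data)
    meta["pixel_size_um"] = labels.pixel_size_um
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True))


def read_labels(path: str | Path) -> LabelMap | BinaryMask:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    if meta["kind"] == "binary_mask":
        return BinaryMask(data.astype(bool), meta["pixel_size_um"])
    return LabelMap(
        data.astype(np.int32),
        meta["pixel_size_um"],
        frozenset(meta.get("border_labels", [])),
    )
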