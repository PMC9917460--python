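"""Per-zone measurement tables.

Everything downstream of masks is expressed as tidy pandas tables with a
stable schema, one row per (disc, clone-or-ALL, zone, channel, metric):

==========  =====================================================
column      meaning
==========  =====================================================
disc_id     caller-supplied identifier of the field of view
clone       clone label, or 0 for pooled ("ALL") rows
zone        ZoneClass name
channel     intensity channel name, or "cDcp1_mask" for area rows
metric      mean / median / sd / area_um2 / percent_apoptotic / ...
value       the number
n_pixels    pixels contributing
==========  =====================================================

Percent apoptotic is an **area** fraction (particle-mask pixels over zone
pixels), not a particle count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image import BinaryMask, LabelMap, check_same_grid
from .zonation import CLONE_ZONES, ZoneClass, ZoneMap

log = logging.getLogger(__name__)

#: Half-open clone-size bins in µm² (upper bin unbounded).
SIZE_BINS = {"small": (10.0, 140.0), "medium": (140.0, 650.0),
             "large": (650.0, np.inf)}

TIDY_COLUMNS = ["disc_id", "clone", "zone", "channel", "metric", "value",
                "n_pixels"]


def bin_clone_areas(area_um2):
    """Size bin for a clone area: small [10,140), medium [140,650), large [650,∞).

    Areas below the 10 µm² inclusion threshold should never reach this point
    and raise.
    """
    arr = np.atleast_1d(np.asarray(area_um2, dtype=float))
    if np.any(arr < SIZE_BINS["small"][0]):
        raise ValueError(
            "clone area below the 10 µm² inclusion filter reached binning"
        )
    out = np.where(arr < SIZE_BINS["small"][1], "small",
                   np.where(arr < SIZE_BINS["medium"][1], "medium", "large"))
    if np.isscalar(area_um2) or np.asarray(area_um2).ndim == 0:
        return str(out[0])
    return out


def _zone_iter(zones: ZoneMap, per_clone: bool):
    """Yield (zone, clone_label, pixel mask) for every non-empty zone."""
    for z in ZoneClass:
        if z in (ZoneClass.OUTSIDE_DISC, ZoneClass.NONE):
            continue
        zmask = zones.mask(z)
        if not zmask.any():
            continue
        yield z, 0, zmask
        if per_clone:
            for lab in np.unique(zones.owner[zmask]):
                if lab == 0:
                    continue
                yield z, int(lab), zmask & (zones.owner == lab)


def zone_intensity(
    img: np.ndarray,
    zones: ZoneMap,
    per_clone: bool = False,
    channel: str = "intensity",
    disc_id: str = "disc",
) -> pd.DataFrame:
    """Mean / median / sd of pixel intensity per zone (and per clone).

    Empty zones are omitted (with a logged notice); pooled rows carry
    ``clone == 0``.
    """
    img = np.asarray(img, dtype=float)
    if img.shape != zones.shape:
        raise ValueError("image and zone map shapes differ")
    rows = []
    seen = set()
    for z, lab, mask in _zone_iter(zones, per_clone):
        seen.add(z)
        vals = img[mask]
        n = int(vals.size)
        for metric, value in (("mean", vals.mean()), ("median",
                              float(np.median(vals))),
                              ("sd", vals.std(ddof=1) if n > 1 else 0.0)):
            rows.append((disc_id, lab, z.name, channel, metric,
                         float(value), n))
    for z in ZoneClass:
        if z not in seen and z not in (ZoneClass.OUTSIDE_DISC, ZoneClass.NONE):
            log.info("zone %s empty: no intensity rows emitted", z.name)
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def percent_apoptotic(
    particles: BinaryMask,
    zones: ZoneMap,
    per_clone: bool = False,
    disc_id: str = "disc",
) -> pd.DataFrame:
    """Percent of each zone's area covered by the particle mask.

    Emits ``percent_apoptotic`` (0–100), ``apoptotic_area_um2`` and
    ``area_um2`` per zone; zero-area zones are omitted.
    """
    if particles.shape != zones.shape:
        raise ValueError("particle mask and zone map shapes differ")
    psz2 = zones.pixel_size_um**2
    rows = []
    for z, lab, mask in _zone_iter(zones, per_clone):
        n = int(mask.sum())
        hit = int((particles.pixels & mask).sum())
        rows.extend([
            (disc_id, lab, z.name, "cDcp1_mask", "area_um2", n * psz2, n),
            (disc_id, lab, z.name, "cDcp1_mask", "apoptotic_area_um2",
             hit * psz2, n),
            (disc_id, lab, z.name, "cDcp1_mask", "percent_apoptotic",
             100.0 * hit / n, n),
        ])
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def split_particles_by_genotype(
    particles: BinaryMask, clones: LabelMap
) -> tuple[BinaryMask, BinaryMask]:
    """Partition the particle mask into clone-marker-positive and -negative.

    ``inside`` is the pixel-wise AND with the clone foreground; ``outside``
    is the remainder.  Together they reproduce the particle mask exactly.
    """
    check_same_grid(particles, clones)
    inside = particles.pixels & clones.foreground()
    outside = particles.pixels & ~inside
    return (BinaryMask(inside, particles.pixel_size_um),
            BinaryMask(outside, particles.pixel_size_um))


def count_apical_basal(
    apical: LabelMap, basal: LabelMap, pouch: BinaryMask
) -> tuple[int, int]:
    """Clone counts in apical vs basal projections, restricted to the pouch.

    A clone is counted if its centroid falls inside the pouch mask.  Clone
    identity is not tracked between the two sections.
    """
    check_same_grid(apical, basal, pouch)
    if not pouch.pixels.any():
        raise ValueError("pouch mask is empty")

    def _count(lm: LabelMap) -> int:
        n = 0
        for lab in range(1, lm.n_labels + 1):
            mask = lm.labels == lab
            if not mask.any():
                continue
            cy, cx = ndi.center_of_mass(mask)
            if pouch.pixels[int(round(cy)), int(round(cx))]:
                n += 1
        return n

    return _count(apical), _count(basal)


@dataclass
class EllipseRegion:
    """An elliptical region in physical coordinates (as drawn by hand with
    an oval tool): centre (µm), semi-axes (µm), rotation angle (degrees)."""

    center_um: tuple[float, float]  # (y, x)
    axes_um: tuple[float, float]  # (semi_y, semi_x) before rotation
    angle_deg: float = 0.0

    def mask(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
        yy = yy * pixel_size_um - self.center_um[0]
        xx = xx * pixel_size_um - self.center_um[1]
        t = np.deg2rad(self.angle_deg)
        u = np.cos(t) * xx + np.sin(t) * yy
        v = -np.sin(t) * xx + np.cos(t) * yy
        a, b = self.axes_um[1], self.axes_um[0]
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def paired_region_apoptosis(
    particles: BinaryMask,
    clones: LabelMap,
    region_pairs: list[tuple[int, EllipseRegion | np.ndarray,
                             EllipseRegion | np.ndarray]],
    boundary_band_um: float = 4.0,
) -> pd.DataFrame:
    """Clone-restricted particle area in paired buckling vs planar regions.

    Each pair names a clone and two regions inside it (apically buckled and
    planar control, drawn by the analyst).  The planar region must stay
    clear of the clone's boundary band so interface-driven apoptosis cannot
    confound the comparison.  Returns one row per pair with areas and
    densities of both regions, ready for a paired test.
    """
    check_same_grid(particles, clones)
    psz = clones.pixel_size_um
    psz2 = psz**2
    rows = []
    from .zonation import inward_zones

    interface, _, small = inward_zones(clones, boundary_band_um, 0.0)
    for i, (lab, buck, planar) in enumerate(region_pairs):
        clone_mask = clones.labels == lab
        if not clone_mask.any():
            raise ValueError(f"pair {i}: clone {lab} not in label map")
        masks = {}
        for name, reg in (("buckling", buck), ("planar", planar)):
            m = (reg.mask(clones.shape, psz) if isinstance(reg, EllipseRegion)
                 else np.asarray(reg, dtype=bool))
            if np.any(m & ~clone_mask):
                raise ValueError(
                    f"pair {i}: {name} region leaves clone {lab}"
                )
            masks[name] = m
        if np.any(masks["planar"] & (interface.labels == lab)):
            raise ValueError(
                f"pair {i}: planar region touches the clone boundary band"
            )
        row = {"pair": i, "clone": lab}
        for name, m in masks.items():
            area = float(m.sum()) * psz2
            apo = float((particles.pixels & m).sum()) * psz2
            row[f"{name}_area_um2"] = area
            row[f"{name}_apoptotic_um2"] = apo
            row[f"{name}_density"] = apo / area if area else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def select_clones_by_reference(
    clone_table: pd.DataFrame,
    tol_au: float = 20.0,
    clone_col: str = "clone_ref_mean",
    band_col: str = "band_ref_mean",
) -> pd.DataFrame:
    """Classify clones by agreement of a reference channel with their band.

    A clone is ``matched`` when the reference-channel mean inside the clone
    and in its surrounding band differ by at most ``tol_au`` (arbitrary
    units) — i.e. the clone sits inside the same endogenous signalling
    domain as its neighbours; otherwise ``mismatched``.  Clones missing a
    band mean are dropped with a notice.
    """
    df = clone_table.copy()
    missing = df[band_col].isna() | df[clone_col].isna()
    if missing.any():
        log.info("excluding %d clones with no reference band mean",
                 int(missing.sum()))
        df = df[~missing]
    diff = (df[clone_col] - df[band_col]).abs()
    df = df.assign(
        ref_abs_diff=diff,
        ref_class=np.where(diff <= tol_au, "matched", "mismatched"),
    )
    return df


def clone_zone_table(
    images: dict[str, np.ndarray],
    particles: BinaryMask | None,
    zones: ZoneMap,
    clones: LabelMap,
    disc_id: str = "disc",
    include_border: bool = False,
) -> pd.DataFrame:
    """Wide per-clone summary: area, size bin, per-zone means and apoptosis.

    One row per clone; columns ``{zone}_{channel}_mean``,
    ``{zone}_percent_apoptotic``, ``whole_{channel}_mean`` etc.  Clones
    flagged border-touching are excluded unless ``include_border``.
    """
    psz2 = zones.pixel_size_um**2
    areas = clones.areas_um2()
    rows = []
    for lab, area in sorted(areas.items()):
        if not include_border and lab in clones.border_labels:
            continue
        clone_mask = clones.labels == lab
        cy, cx = ndi.center_of_mass(clone_mask)
        row = {
            "disc_id": disc_id,
            "clone": lab,
            "area_um2": area,
            "size_bin": bin_clone_areas(area),
            "border": lab in clones.border_labels,
            "centroid_y_um": cy * zones.pixel_size_um,
            "centroid_x_um": cx * zones.pixel_size_um,
        }
        for ch, img in images.items():
            row[f"whole_{ch}_mean"] = float(img[clone_mask].mean())
        if particles is not None:
            hit = float((particles.pixels & clone_mask).sum())
            row["whole_apoptotic_area_um2"] = hit * psz2
            row["whole_percent_apoptotic"] = 100.0 * hit / clone_mask.sum()
        for z in (*CLONE_ZONES, ZoneClass.WT_INTERFACE, ZoneClass.WT_ROW2):
            zmask = zones.mask(z, owner=lab)
            n = int(zmask.sum())
            prefix = z.name.lower()
            row[f"{prefix}_area_um2"] = n * psz2
            if n == 0:
                continue
            for ch, img in images.items():
                row[f"{prefix}_{ch}_mean"] = float(img[zmask].mean())
            if particles is not None:
                hit = float((particles.pixels & zmask).sum())
                row[f"{prefix}_percent_apoptotic"] = 100.0 * hit / n
        rows.append(row)
    return pd.DataFrame(rows)


def size_scaling_table(clone_table: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Per-clone whole-clone and interface means, arranged for size-bin
    analyses.

    Clones below the interior cutoff have no distinct interface zone; for
    them the whole-clone mean serves as the interface value (they are all
    interface, being at most a couple of cell rows across).
    """
    df = clone_table.copy()
    whole = df[f"whole_{channel}_mean"]
    iface_col = f"clone_interface_{channel}_mean"
    iface = df[iface_col] if iface_col in df else pd.Series(np.nan,
                                                            index=df.index)
    df["whole_mean"] = whole
    df["interface_mean"] = iface.fillna(whole)
    wt_col = f"wt_interface_{channel}_mean"
    if wt_col in df:
        df["wt_interface_mean"] = df[wt_col]
    return df[[c for c in ("disc_id", "clone", "area_um2", "size_bin",
                           "whole_mean", "interface_mean",
                           "wt_interface_mean") if c in df]]
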