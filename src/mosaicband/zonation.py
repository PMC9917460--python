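"""Zone construction around and inside mosaic clones.

Cell rows at the clone/wild-type interface are approximated as bands of
fixed physical width (default 4 µm ≈ one cell row, from a measured mean
nuclear size of 3.75 µm plus cytoplasm).  A :class:`ZoneMap` partitions the
image into disjoint classes:

* ``OUTSIDE_DISC`` — beyond the tissue mask;
* ``WT_INTERFACE`` — wild-type pixels within one band width of a clone;
* ``WT_ROW2`` — the next band outward (one further cell row);
* ``WT_BACKGROUND`` — remaining wild-type tissue;
* ``CLONE_INTERFACE`` / ``CLONE_INTERIOR`` — the inner band and the deep
  interior of clones large enough (≥ 180 µm²) to have a distinct interior;
* ``CLONE_SMALL`` — whole clones below the interior-area cutoff.

Distances are exact Euclidean distances between pixel centres, in µm.
Band membership is half-open, ``0 < d <= width``: the clone's own boundary
pixels belong to the clone.  Outward-band pixels are owned by the nearest
clone; equidistant pixels go to the smaller label.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage as ndi

from .image import BinaryMask, CalibrationError, LabelMap, check_same_grid


class ZoneClass(IntEnum):
    OUTSIDE_DISC = 0
    WT_BACKGROUND = 1
    WT_ROW2 = 2
    WT_INTERFACE = 3
    CLONE_INTERFACE = 4
    CLONE_INTERIOR = 5
    CLONE_SMALL = 6
    NONE = 7  # excluded from statistics (e.g. non-nuclear pixels)


#: Zones measured inside clone tissue.
CLONE_ZONES = (ZoneClass.CLONE_INTERFACE, ZoneClass.CLONE_INTERIOR,
               ZoneClass.CLONE_SMALL)
#: Zones measured in wild-type tissue.
WT_ZONES = (ZoneClass.WT_INTERFACE, ZoneClass.WT_ROW2, ZoneClass.WT_BACKGROUND)


@dataclass
class ZoneParams:
    """Band geometry parameters.

    band_width_um
        Width of one approximated cell row (µm).
    interior_min_area_um2
        Minimum clone area for an interface/interior split; smaller clones
        are kept whole as ``CLONE_SMALL``.
    row2
        Whether to build the second outward band.
    nucleus_diameter_um
        Mean nuclear diameter the band width was derived from (provenance
        only; not used in computation).
    """

    band_width_um: float = 4.0
    interior_min_area_um2: float = 180.0
    row2: bool = True
    nucleus_diameter_um: float = 3.75

    def __post_init__(self) -> None:
        if not self.band_width_um > 0:
            raise ValueError("band_width_um must be > 0")
        if self.interior_min_area_um2 < 0:
            raise ValueError("interior_min_area_um2 must be >= 0")


@dataclass
class ZoneMap:
    """Per-pixel zone class and owning clone label.

    ``owner`` is the clone a band pixel is attributed to (nearest clone for
    wild-type bands, the containing clone for clone zones, 0 elsewhere).
    ``compartment`` optionally tags pixels inside a compartment mask so
    per-compartment tables can be split.
    """

    zone: np.ndarray
    owner: np.ndarray
    pixel_size_um: float
    border_labels: frozenset[int] = frozenset()
    compartment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.zone = np.asarray(self.zone, dtype=np.uint8)
        self.owner = np.asarray(self.owner, dtype=np.int32)
        if self.zone.shape != self.owner.shape:
            raise ValueError("zone and owner shapes differ")
        if self.compartment is not None:
            self.compartment = np.asarray(self.compartment, dtype=bool)
            if self.compartment.shape != self.zone.shape:
                raise ValueError("compartment shape differs")

    @property
    def shape(self) -> tuple[int, int]:
        return self.zone.shape

    def mask(self, zone: ZoneClass, owner: int | None = None) -> np.ndarray:
        m = self.zone == int(zone)
        if owner is not None:
            m &= self.owner == owner
        return m

    def area_um2(self, zone: ZoneClass, owner: int | None = None) -> float:
        return float(self.mask(zone, owner).sum()) * self.pixel_size_um**2

    def owners(self) -> np.ndarray:
        labs = np.unique(self.owner)
        return labs[labs > 0]


# ---------------------------------------------------------------------------
# Distance machinery

def _squared_px_distance_to_label(mask: np.ndarray) -> np.ndarray:
    """Exact integer squared pixel distance to the True pixels of ``mask``.

    The Euclidean distance transform returns sqrt of an integer number of
    px²; squaring and rounding recovers that integer exactly, which makes
    band-boundary comparisons bit-reproducible against integer oracles.
    """
    d = ndi.distance_transform_edt(~mask)
    return np.rint(d * d).astype(np.int64)


def nearest_clone_distance(clones: LabelMap) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (squared px distance, owning label) to the nearest clone.

    Ties are broken toward the smaller label by scanning labels in
    increasing order with a strict-< replacement rule.
    """
    shape = clones.shape
    best = np.full(shape, np.iinfo(np.int64).max, dtype=np.int64)
    owner = np.zeros(shape, dtype=np.int32)
    for lab in range(1, clones.n_labels + 1):
        mask = clones.labels == lab
        if not mask.any():
            continue
        d2 = _squared_px_distance_to_label(mask)
        closer = d2 < best
        best[closer] = d2[closer]
        owner[closer] = lab
    return best, owner


def outward_band(
    clones: LabelMap,
    disc: BinaryMask,
    width_um: float,
    order: int = 1,
) -> LabelMap:
    """Band of wild-type pixels around clones, owned by the nearest clone.

    Order 1 is the interface band (``0 < d <= width``); order 2 is the
    row-2 band (``width < d <= 2*width``).  Pixels inside any clone or
    outside the disc are never band members.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    check_same_grid(clones, disc)
    psz = clones.pixel_size_um
    if clones.n_labels == 0 or not clones.foreground().any():
        return LabelMap(np.zeros(clones.shape, dtype=np.int32), psz)
    d2, owner = nearest_clone_distance(clones)
    w2 = (width_um / psz) ** 2
    lo2 = 0.0 if order == 1 else w2
    hi2 = w2 if order == 1 else (2.0 * width_um / psz) ** 2
    member = (d2 > lo2) & (d2 <= hi2) & disc.pixels & ~clones.foreground()
    out = np.where(member, owner, 0).astype(np.int32)
    return LabelMap(out, psz, border_labels=clones.border_labels)


def inward_zones(
    clones: LabelMap,
    width_um: float,
    interior_min_area_um2: float,
) -> tuple[LabelMap, LabelMap, LabelMap]:
    """Split each clone into interface band and interior.

    For clones with area >= ``interior_min_area_um2``: interior pixels lie
    strictly more than ``width_um`` from the clone's complement; the
    interface is the rest of the clone.  Smaller clones are returned whole
    in the third map.
    """
    psz = clones.pixel_size_um
    shape = clones.shape
    interface = np.zeros(shape, dtype=np.int32)
    interior = np.zeros(shape, dtype=np.int32)
    small = np.zeros(shape, dtype=np.int32)
    w2 = (width_um / psz) ** 2
    areas = clones.areas_um2()
    for lab, area in areas.items():
        mask = clones.labels == lab
        if area < interior_min_area_um2:
            small[mask] = lab
            continue
        d = ndi.distance_transform_edt(mask)
        d2 = np.rint(d * d).astype(np.int64)
        inner = mask & (d2 > w2)
        interface[mask & ~inner] = lab
        interior[inner] = lab
    kw = dict(pixel_size_um=psz, border_labels=clones.border_labels)
    return (LabelMap(interface, **kw), LabelMap(interior, **kw),
            LabelMap(small, **kw))


def build_zone_map(
    disc: BinaryMask,
    clones: LabelMap,
    params: ZoneParams | None = None,
    compartment: BinaryMask | None = None,
) -> ZoneMap:
    """Assemble the full disjoint zone partition.

    The partition is built by priority: clone zones first (clone pixels are
    never band pixels), then the order-1 wild-type band, then row 2, then
    background.  Because both bands derive from one nearest-clone distance
    field, a pixel in another clone's order-1 range can never be row 2.
    """
    params = params or ZoneParams()
    check_same_grid(disc, clones)
    if compartment is not None:
        check_same_grid(disc, compartment)
    psz = disc.pixel_size_um
    zone = np.full(disc.shape, int(ZoneClass.OUTSIDE_DISC), dtype=np.uint8)
    owner = np.zeros(disc.shape, dtype=np.int32)
    zone[disc.pixels] = int(ZoneClass.WT_BACKGROUND)

    interface, interior, small = inward_zones(
        clones, params.band_width_um, params.interior_min_area_um2
    )
    for lm, cls in ((small, ZoneClass.CLONE_SMALL),
                    (interface, ZoneClass.CLONE_INTERFACE),
                    (interior, ZoneClass.CLONE_INTERIOR)):
        m = lm.labels > 0
        zone[m] = int(cls)
        owner[m] = lm.labels[m]

    band1 = outward_band(clones, disc, params.band_width_um, order=1)
    m1 = band1.labels > 0
    zone[m1] = int(ZoneClass.WT_INTERFACE)
    owner[m1] = band1.labels[m1]
    if params.row2:
        band2 = outward_band(clones, disc, params.band_width_um, order=2)
        m2 = (band2.labels > 0) & ~m1
        zone[m2] = int(ZoneClass.WT_ROW2)
        owner[m2] = band2.labels[m2]

    zm = ZoneMap(zone, owner, psz, border_labels=clones.border_labels,
                 compartment=None if compartment is None else compartment.pixels)
    _audit_partition(zm, disc, clones)
    return zm


def _audit_partition(zm: ZoneMap, disc: BinaryMask, clones: LabelMap) -> None:
    # Internal invariant: clone pixels carry clone classes, wild-type band /
    # background pixels lie inside the disc and outside all clones.
    clone_classes = np.isin(zm.zone, [int(z) for z in CLONE_ZONES])
    if not np.array_equal(clone_classes, clones.foreground()):
        raise AssertionError("clone zones do not coincide with the clone mask")
    wt = np.isin(zm.zone, [int(z) for z in WT_ZONES])
    if np.any(wt & ~disc.pixels) or np.any(wt & clones.foreground()):
        raise AssertionError("wild-type zones leak outside disc or into clones")


def restrict_to_nuclei(zones: ZoneMap, nuclei: BinaryMask) -> ZoneMap:
    """Intersect every zone with a nuclear mask.

    Non-nuclear pixels get the ``NONE`` class (owner 0) and are excluded
    from statistics; used for nuclear reporters where cytoplasmic pixels
    would dilute zone means.
    """
    if nuclei.shape != zones.shape:
        raise CalibrationError("nuclei mask shape differs from zone map")
    if not nuclei.pixels.any():
        import warnings

        warnings.warn("empty nuclear mask: all zones become empty", stacklevel=2)
    zone = zones.zone.copy()
    owner = zones.owner.copy()
    off = ~nuclei.pixels
    zone[off] = int(ZoneClass.NONE)
    owner[off] = 0
    return ZoneMap(zone, owner, zones.pixel_size_um,
                   border_labels=zones.border_labels,
                   compartment=zones.compartment)
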