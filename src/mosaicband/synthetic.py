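"""Synthetic mosaic-disc images with full ground truth.

No real micrographs ship with the measurement procedure this package
implements, so every stage is validated against generated data whose truth
is known by construction: an elliptical disc of Voronoi cells on a jittered
hexagonal point set (mean cell diameter 3.75 µm, the measured nuclear
scale), connected clones of a second genotype grown by random neighbour
accretion, a reporter channel elevated at clone/wild-type contacts (either
per-cell contact-proportional or as a uniform band of enrichment ``E``
within ``λ`` of the interface), and punctate apoptosis whose expected
area fraction per zone is specified directly.

The generator is fully deterministic under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .image import BinaryMask, CalibratedImage, LabelMap
from .zonation import ZoneClass, ZoneMap, ZoneParams, build_zone_map

log = logging.getLogger(__name__)

#: Fraction of each zone's area expected to be covered by apoptotic spots.
DEFAULT_APOPTOSIS_RATES = {
    "CLONE_INTERFACE": 0.10,
    "CLONE_INTERIOR": 0.02,
    "CLONE_SMALL": 0.10,
    "WT_INTERFACE": 0.04,
    "WT_ROW2": 0.01,
    "WT_BACKGROUND": 0.005,
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic mosaic disc.

    Intensities are arbitrary units; the default signal amplitude of 100
    with Gaussian noise sd 10 gives SNR 10.  ``growth_steps`` may be a
    single int or an inclusive ``(lo, hi)`` range sampled per clone, which
    spreads clone areas across the small/medium/large bins.
    """

    shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    disc_center_um: tuple[float, float] | None = None  # default: image centre
    disc_axes_um: tuple[float, float] = (220.0, 170.0)  # semi-axes (y, x)
    cell_diameter_um: float = 3.75
    jitter: float = 0.3  # fraction of lattice spacing
    n_clone_seeds: int = 10
    growth_steps: int | tuple[int, int] = (5, 40)
    clone_compactness: float = 2.0  # accretion weight exponent; 0 = ragged
    reporter_model: str = "band"  # "band" or "contact"
    reporter_base: float = 20.0
    reporter_enrichment: float = 2.0  # E, band model
    reporter_lambda_um: float = 4.0  # λ, band model
    reporter_per_contact: float = 10.0  # g, contact model
    apoptosis_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_APOPTOSIS_RATES))
    spot_diameter_um: float = 2.0
    gfp_level: float = 100.0
    dapi_amplitude: float = 100.0
    nuclear_diameter_um: float = 3.75
    cdcp1_level: float = 150.0
    cdcp1_background: float = 5.0
    noise_sd: float = 10.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 <= r <= 1.0 for r in self.apoptosis_rates.values()):
            raise ValueError("apoptosis rates must lie in [0, 1]")
        for name in ("pixel_size_um", "cell_diameter_um", "spot_diameter_um",
                     "nuclear_diameter_um", "reporter_lambda_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.reporter_model not in ("band", "contact"):
            raise ValueError("reporter_model must be 'band' or 'contact'")

    @property
    def center_um(self) -> tuple[float, float]:
        if self.disc_center_um is not None:
            return self.disc_center_um
        return (self.shape_px[0] * self.pixel_size_um / 2.0,
                self.shape_px[1] * self.pixel_size_um / 2.0)


@dataclass
class GroundTruth:
    """Everything the generator knows about one realization."""

    cells: LabelMap  # Voronoi cell label per pixel, 0 outside disc
    genotype: LabelMap  # clone label per pixel, 0 = wild type / outside
    disc: BinaryMask
    cell_centers_um: np.ndarray  # (n_cells, 2), row i -> cell label i+1
    cell_clone: np.ndarray  # clone label per cell (0 = wild type)
    heterotypic_contacts: np.ndarray  # per cell, neighbours of other genotype
    zones: ZoneMap  # built from the true clone geometry
    spots: pd.DataFrame  # columns y_um, x_um, diameter_um, zone
    spec: SyntheticSpec


# ---------------------------------------------------------------------------


def _ellipse_mask(spec: SyntheticSpec) -> np.ndarray:
    h, w = spec.shape_px
    cy, cx = spec.center_um
    ay, ax = spec.disc_axes_um
    yy, xx = np.mgrid[:h, :w].astype(float) * spec.pixel_size_um
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_tessellation(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[LabelMap, np.ndarray]:
    """Voronoi cell map from a jittered hexagonal point set in the ellipse.

    Returns the cell label map (labels 1..n inside the disc, 0 outside) and
    the seed-point coordinates in µm (row i is the centre of label i+1).
    The lattice spacing is chosen so the mean cell area equals that of a
    disc of ``cell_diameter_um``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    d = spec.cell_diameter_um
    ay, ax = spec.disc_axes_um
    if d >= 2 * min(ay, ax):
        raise ValueError("cell diameter exceeds the disc")
    target_area = np.pi * (d / 2.0) ** 2
    spacing = np.sqrt(target_area / (np.sqrt(3.0) / 2.0))
    cy, cx = spec.center_um
    row_h = spacing * np.sqrt(3.0) / 2.0
    ny = int(np.ceil(2 * ay / row_h)) + 2
    nx = int(np.ceil(2 * ax / spacing)) + 2
    pts = []
    for iy in range(-ny // 2, ny // 2 + 1):
        y = cy + iy * row_h
        offset = (iy % 2) * spacing / 2.0
        for ix in range(-nx // 2, nx // 2 + 1):
            x = cx + ix * spacing + offset
            pts.append((y, x))
    pts = np.asarray(pts, dtype=float)
    if spec.jitter > 0:
        pts = pts + rng.uniform(-spec.jitter * spacing / 2.0,
                                spec.jitter * spacing / 2.0, size=pts.shape)
    inside = (((pts[:, 0] - cy) / ay) ** 2 + ((pts[:, 1] - cx) / ax) ** 2) <= 1.0
    pts = pts[inside]
    if len(pts) == 0:
        raise ValueError("no cell seeds fall inside the disc")
    disc = _ellipse_mask(spec)
    yy, xx = np.nonzero(disc)
    coords = np.column_stack([yy, xx]).astype(float) * spec.pixel_size_um
    _, idx = cKDTree(pts).query(coords, k=1)
    labels = np.zeros(spec.shape_px, dtype=np.int32)
    labels[yy, xx] = idx + 1
    return LabelMap(labels, spec.pixel_size_um), pts


def cell_adjacency(cells: LabelMap) -> dict[int, set[int]]:
    """4-connectivity adjacency between Voronoi cell labels."""
    lab = cells.labels
    pairs = set()
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        diff = (a != b) & (a > 0) & (b > 0)
        pairs.update(zip(a[diff].tolist(), b[diff].tolist()))
    adj: dict[int, set[int]] = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def induce_clones(
    cells: LabelMap,
    n_seeds: int,
    growth_steps: int | tuple[int, int],
    rng: np.random.Generator | int | None = None,
    compactness: float = 2.0,
) -> LabelMap:
    """Mark connected groups of cells as clones by random accretion.

    Seeds are drawn uniformly from the cells; each clone then adds one
    random unassigned neighbouring cell per growth step (the discrete
    analogue of scaling clone sizes by induction time).  Accretion is
    weighted by the squared number of clone neighbours a candidate already
    has (``compactness`` exponent), mimicking the interface smoothening
    that contractile clone borders impose in tissue; 0 gives fully random
    ragged growth.  Clones whose growth makes them touch merge into one
    label; the final map is relabelled by pixel connectivity.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n_cells = cells.n_labels
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if n_seeds > n_cells:
        raise ValueError(f"n_seeds={n_seeds} exceeds cell count {n_cells}")
    adj = cell_adjacency(cells)
    seeds = rng.choice(np.arange(1, n_cells + 1), size=n_seeds, replace=False)
    assignment = {int(s): i + 1 for i, s in enumerate(seeds)}
    members: dict[int, list[int]] = {i + 1: [int(s)]
                                     for i, s in enumerate(seeds)}
    for clone_id in sorted(members):
        if isinstance(growth_steps, tuple):
            lo, hi = growth_steps
            steps = int(rng.integers(lo, hi + 1))
        else:
            steps = int(growth_steps)
        mine = set(members[clone_id])
        for _ in range(steps):
            frontier = sorted({
                nb for c in mine for nb in adj.get(c, ())
                if nb not in assignment
            })
            if not frontier:
                break
            if compactness > 0:
                w = np.array([
                    len(adj.get(f, set()) & mine) ** compactness
                    for f in frontier
                ], dtype=float)
                pick = int(frontier[rng.choice(len(frontier), p=w / w.sum())])
            else:
                pick = int(frontier[rng.integers(len(frontier))])
            assignment[pick] = clone_id
            mine.add(pick)
            members[clone_id].append(pick)
    clone_of_cell = np.zeros(n_cells + 1, dtype=np.int32)
    for cell, clone in assignment.items():
        clone_of_cell[cell] = clone
    genotype_px = clone_of_cell[cells.labels]
    relabeled, n_final = ndi.label(genotype_px > 0, structure=np.ones((3, 3)))
    if n_final < n_seeds:
        log.info("clone growth merged %d seeds into %d clones",
                 n_seeds, n_final)
    return LabelMap(relabeled.astype(np.int32), cells.pixel_size_um)


def heterotypic_contact_counts(
    cells: LabelMap, genotype: LabelMap
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell clone membership and count of other-genotype neighbours."""
    n_cells = cells.n_labels
    # genotype is painted per whole cell, so any pixel of the cell carries
    # its clone label; take the per-cell maximum, vectorized
    cell_clone = np.zeros(n_cells + 1, dtype=np.int32)
    if n_cells:
        cell_clone[1:] = ndi.maximum(
            genotype.labels, labels=cells.labels,
            index=np.arange(1, n_cells + 1)
        ).astype(np.int32)
    adj = cell_adjacency(cells)
    contacts = np.zeros(n_cells + 1, dtype=np.int32)
    for lab in range(1, n_cells + 1):
        mine = cell_clone[lab] > 0
        contacts[lab] = sum(
            1 for nb in adj.get(lab, ()) if (cell_clone[nb] > 0) != mine
        )
    return cell_clone[1:], contacts[1:]


# ---------------------------------------------------------------------------
# Rendering


def _paint_nuclei(spec: SyntheticSpec, centers_um: np.ndarray) -> np.ndarray:
    sigma_px = spec.nuclear_diameter_um / 4.0 / spec.pixel_size_um
    img = np.zeros(spec.shape_px, dtype=float)
    px = np.round(centers_um / spec.pixel_size_um).astype(int)
    px[:, 0] = np.clip(px[:, 0], 0, spec.shape_px[0] - 1)
    px[:, 1] = np.clip(px[:, 1], 0, spec.shape_px[1] - 1)
    np.add.at(img, (px[:, 0], px[:, 1]), 1.0)
    img = ndi.gaussian_filter(img, sigma=sigma_px)
    peak = 1.0 / (2.0 * np.pi * sigma_px**2)
    return spec.dapi_amplitude * img / peak


def _interface_band(genotype: LabelMap, disc: np.ndarray,
                    lambda_um: float) -> np.ndarray:
    """Pixels within λ of the clone/wild-type interface, on both sides."""
    psz = genotype.pixel_size_um
    fg = genotype.foreground()
    lam_px2 = (lambda_um / psz) ** 2
    d_out = ndi.distance_transform_edt(~fg)
    d_in = ndi.distance_transform_edt(fg)
    d2_out = np.rint(d_out * d_out).astype(np.int64)
    d2_in = np.rint(d_in * d_in).astype(np.int64)
    outside = (~fg) & (d2_out > 0) & (d2_out <= lam_px2)
    inside = fg & (d2_in <= lam_px2)
    return (outside | inside) & disc


def _spot_disk_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = max(int(np.floor(radius_px)), 0)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    keep = (y * y + x * x) <= radius_px * radius_px
    return y[keep], x[keep]


def _place_spots(
    spec: SyntheticSpec,
    zones: ZoneMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Spot mask with expected per-zone area fractions matching the spec.

    Spots are placed wholly inside their zone when the zone is thick enough
    (centres drawn from the zone eroded by the spot radius); otherwise the
    centre lies in the zone and straddling pixels are attributed by centre.
    """
    psz = zones.pixel_size_um
    r_px = spec.spot_diameter_um / 2.0 / psz
    dy, dx = _spot_disk_offsets(r_px)
    spot_area_px = len(dy)
    mask = np.zeros(zones.shape, dtype=bool)
    rows = []
    fp_size = int(np.ceil(2 * r_px)) + 1
    for zname, rate in spec.apoptosis_rates.items():
        if rate <= 0:
            continue
        z = ZoneClass[zname]
        zmask = zones.mask(z)
        n_zone = int(zmask.sum())
        if n_zone == 0:
            continue
        n_spots = int(round(rate * n_zone / spot_area_px))
        if n_spots == 0:
            continue
        eroded = ndi.binary_erosion(
            zmask, structure=np.ones((fp_size, fp_size)), border_value=0
        )
        candidates = np.flatnonzero((eroded if eroded.any() else zmask).ravel())
        picks = rng.choice(candidates, size=n_spots,
                           replace=len(candidates) < n_spots)
        ys, xs = np.unravel_index(picks, zones.shape)
        for y, x in zip(ys, xs):
            yy = np.clip(y + dy, 0, zones.shape[0] - 1)
            xx = np.clip(x + dx, 0, zones.shape[1] - 1)
            mask[yy, xx] = True
            rows.append({"y_um": y * psz, "x_um": x * psz,
                         "diameter_um": spec.spot_diameter_um, "zone": zname})
    return mask, pd.DataFrame(rows, columns=["y_um", "x_um", "diameter_um",
                                             "zone"])


def render(
    spec: SyntheticSpec,
    cells: LabelMap,
    genotype: LabelMap,
    centers_um: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[CalibratedImage, GroundTruth]:
    """Render the four channels and assemble the ground truth.

    Channels: ``DAPI`` Gaussian nuclei at cell centres; ``GFP`` uniform
    over clone pixels; ``TRE`` reporter per the band or contact model;
    ``cDcp1`` punctate spots at per-zone rates.  Gaussian noise is added
    last and intensities clipped at zero.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    disc_px = cells.foreground()
    disc = BinaryMask(disc_px, spec.pixel_size_um)
    zones = build_zone_map(disc, genotype, ZoneParams())

    dapi = _paint_nuclei(spec, centers_um)
    gfp = np.where(genotype.foreground(), spec.gfp_level, 0.0)

    cell_clone, contacts = heterotypic_contact_counts(cells, genotype)
    tre = np.zeros(spec.shape_px, dtype=float)
    if spec.reporter_model == "band":
        tre[disc_px] = spec.reporter_base
        band = _interface_band(genotype, disc_px, spec.reporter_lambda_um)
        tre[band] = spec.reporter_base * spec.reporter_enrichment
    else:
        per_cell = spec.reporter_base + spec.reporter_per_contact * contacts
        lut = np.concatenate([[0.0], per_cell])
        tre = lut[cells.labels]

    spot_mask, spots = _place_spots(spec, zones, rng)
    cdcp1 = np.where(disc_px, spec.cdcp1_background, 0.0)
    cdcp1[spot_mask] = spec.cdcp1_level

    channels = {"DAPI": dapi, "GFP": gfp, "TRE": tre, "cDcp1": cdcp1}
    for name, img in channels.items():
        noisy = img
        if spec.poisson_noise:
            noisy = rng.poisson(np.maximum(noisy, 0.0)).astype(float)
        if spec.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[name] = np.clip(noisy, 0.0, None)

    image = CalibratedImage(channels, spec.pixel_size_um,
                            projection_note=f"synthetic seed={spec.seed}")
    truth = GroundTruth(
        cells=cells, genotype=genotype, disc=disc,
        cell_centers_um=centers_um, cell_clone=cell_clone,
        heterotypic_contacts=contacts, zones=zones, spots=spots, spec=spec,
    )
    return image, truth


def simulate(spec: SyntheticSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Full generation: tessellate, induce clones, render.

    One seed fixes the entire realization.
    """
    rng = np.random.default_rng(spec.seed)
    cells, centers = make_tessellation(spec, rng)
    genotype = induce_clones(cells, spec.n_clone_seeds, spec.growth_steps,
                             rng, compactness=spec.clone_compactness)
    return render(spec, cells, genotype, centers, rng)
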