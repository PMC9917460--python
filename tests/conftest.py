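"""Shared fixtures and independent brute-force oracles.

The oracles here recompute band membership, ownership and erosion from the
raw Euclidean definition (all-pairs integer squared pixel distances), with
no morphology or distance-transform shortcuts, so they stay independent of
the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from mosaicband.image import BinaryMask, LabelMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_label_map(rng: np.random.Generator, shape=(64, 64),
                     pixel_size_um: float = 1.0) -> LabelMap:
    """Random blobby label map: smoothed noise, thresholded, labelled."""
    noise = ndi.gaussian_filter(rng.normal(size=shape), sigma=3)
    fg = noise > np.quantile(noise, 0.85)
    labels, _ = ndi.label(fg, structure=np.ones((3, 3)))
    # consecutive labels from 1
    uniq = np.unique(labels)
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[uniq[uniq > 0]] = np.arange(1, (uniq > 0).sum() + 1)
    return LabelMap(lut[labels], pixel_size_um)


def brute_force_nearest(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs integer squared distance to the nearest labelled pixel and
    the owning label (ties -> smaller label)."""
    h, w = labels.shape
    ys, xs = np.nonzero(labels > 0)
    labs = labels[ys, xs]
    yy, xx = np.mgrid[:h, :w]
    pts_y = yy.ravel()[:, None]
    pts_x = xx.ravel()[:, None]
    d2_all = (pts_y - ys[None, :]) ** 2 + (pts_x - xs[None, :]) ** 2
    best = np.full(h * w, np.iinfo(np.int64).max, dtype=np.int64)
    owner = np.zeros(h * w, dtype=np.int32)
    for lab in np.unique(labs):
        dl = d2_all[:, labs == lab].min(axis=1)
        closer = dl < best
        best[closer] = dl[closer]
        owner[closer] = lab
    return best.reshape(h, w), owner.reshape(h, w)


def brute_force_band(clones: LabelMap, disc: BinaryMask, width_um: float,
                     order: int) -> np.ndarray:
    """Band membership/ownership from the raw distance definition."""
    if not (clones.labels > 0).any():
        return np.zeros(clones.shape, dtype=np.int32)
    psz = clones.pixel_size_um
    d2, owner = brute_force_nearest(clones.labels)
    w2 = (width_um / psz) ** 2
    lo2 = 0.0 if order == 1 else w2
    hi2 = w2 if order == 1 else (2.0 * width_um / psz) ** 2
    member = ((d2 > lo2) & (d2 <= hi2) & disc.pixels
              & (clones.labels == 0))
    return np.where(member, owner, 0).astype(np.int32)


def brute_force_interior(clones: LabelMap, lab: int,
                         width_um: float) -> np.ndarray:
    """Pixels of clone ``lab`` farther than width from its complement."""
    psz = clones.pixel_size_um
    mask = clones.labels == lab
    h, w = mask.shape
    ys, xs = np.nonzero(~mask)
    iy, ix = np.nonzero(mask)
    d2 = ((iy[:, None] - ys[None, :]) ** 2
          + (ix[:, None] - xs[None, :]) ** 2).min(axis=1)
    keep = d2 > (width_um / psz) ** 2
    out = np.zeros_like(mask)
    out[iy[keep], ix[keep]] = True
    return out
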