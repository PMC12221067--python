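"""Handcrafted region descriptors: LBP texture, intensity moments, shape.

All three families follow the printed definitions exactly:

* LBP with P=8, R=1: each interior pixel is encoded as
  ``sum_N s(i_N - i_c) * 2^N`` with ``s(x) = 1 iff x >= 0`` and the
  neighbours ordered clockwise starting at the top-left corner; the
  256-bin code histogram is normalized to sum 1.
* Intensity ("colour") moments: mean, population variance (1/n), and the
  raw third central moment (not standardized skewness).
* Shape: area = pixel count; perimeter = number of foreground pixels
  with at least one background 4-neighbour (the image border counts as
  background); eccentricity from the equivalent ellipse of the
  coordinate covariance; compactness = perimeter^2 / area.

Eccentricity treats each pixel as a unit square (1/12 is added to both
covariance eigenvalues), so a one-pixel-wide line has eccentricity
strictly below 1 and a single pixel exactly 0.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi

from .config import FeaturesConfig
from .types import FeatureTable, VolumeImage

logger = logging.getLogger("fasf_tle")

__all__ = [
    "lbp_histogram",
    "color_moments",
    "shape_features",
    "extract_features",
    "MISSING",
]

#: sentinel recorded when a region is absent on the selected slices
MISSING = np.nan

# neighbour offsets clockwise from top-left, paired with weights 2^0 .. 2^7
_LBP_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
]


def lbp_histogram(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """256-bin normalized local-binary-pattern histogram of a 2-D slice."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("lbp_histogram expects a 2-D slice")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    interior = mask.copy()
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    if not interior.any():
        logger.warning("lbp_histogram: empty interior, returning zero histogram")
        return np.zeros(256)

    codes = np.zeros(image.shape, dtype=np.int32)
    center = image
    for weight_bit, (dy, dx) in enumerate(_LBP_OFFSETS):
        neigh = np.roll(np.roll(image, -dy, axis=0), -dx, axis=1)
        codes += ((neigh - center) >= 0).astype(np.int32) << weight_bit

    hist = np.bincount(codes[interior].ravel(), minlength=256).astype(float)
    return hist / hist.sum()


def color_moments(values: np.ndarray) -> tuple[float, float, float]:
    """Mean, population variance and raw third central moment."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty region has no moments")
    m1 = float(values.mean())
    dev = values - m1
    m2 = float(np.mean(dev**2))
    m3 = float(np.mean(dev**3))
    return m1, m2, m3


def _largest_component(mask: np.ndarray) -> np.ndarray:
    comp, n = ndi.label(mask)
    if n <= 1:
        return mask
    sizes = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    return comp == (1 + int(np.argmax(sizes)))


def shape_features(mask: np.ndarray) -> tuple[int, int, float, float]:
    """(area, perimeter, eccentricity, compactness) of a 2-D binary region."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("shape_features expects a 2-D mask")
    if not mask.any():
        raise ValueError("empty mask has no shape")
    mask = _largest_component(mask)

    area = int(mask.sum())

    padded = np.pad(mask, 1, constant_values=False)
    bg_neighbour = (
        ~padded[:-2, 1:-1] | ~padded[2:, 1:-1] | ~padded[1:-1, :-2] | ~padded[1:-1, 2:]
    )
    perimeter = int(np.sum(mask & bg_neighbour))

    coords = np.argwhere(mask).astype(float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / area + np.eye(2) / 12.0  # pixel = unit square
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    a_axis, b_axis = 2.0 * np.sqrt(lam[0]), 2.0 * np.sqrt(lam[1])
    ecc = float(np.sqrt(max(a_axis**2 - b_axis**2, 0.0)) / a_axis) if a_axis > 0 else 0.0

    compactness = perimeter**2 / area
    return area, perimeter, ecc, float(compactness)


def _mid_slice(mask3d: np.ndarray, axis: int) -> int | None:
    """Index of the mask's central occupied slice along *axis*, or None."""
    occupancy = mask3d.sum(axis=tuple(i for i in range(mask3d.ndim) if i != axis))
    occupied = np.where(occupancy > 0)[0]
    if occupied.size == 0:
        return None
    return int(occupied[len(occupied) // 2])


def _region_feature_names(region_id: int) -> list[str]:
    return (
        [f"r{region_id}_lbp{k}" for k in range(256)]
        + [f"r{region_id}_m1", f"r{region_id}_m2", f"r{region_id}_m3"]
        + [
            f"r{region_id}_area",
            f"r{region_id}_perimeter",
            f"r{region_id}_eccentricity",
            f"r{region_id}_compactness",
        ]
    )


def extract_features(
    vol: VolumeImage,
    masks: dict[int, np.ndarray],
    slice_axis: int = 2,
    config: FeaturesConfig | None = None,
    sample_id: str = "sample",
) -> FeatureTable:
    """Per-region descriptors on the central occupied slice of each mask.

    Each region contributes 256 LBP bins + 3 moments + 4 shape values,
    flattened with deterministic names ``r<id>_lbp<k>``, ``r<id>_m1`` ...
    ``r<id>_compactness``.  Regions absent on the selected slices are
    recorded as NaN sentinels and logged.
    """
    config = config or FeaturesConfig()
    data = vol.data
    names: list[str] = []
    row: list[float] = []
    for rid in sorted(masks):
        mask = np.asarray(masks[rid], dtype=bool)
        names.extend(_region_feature_names(rid))
        if data.ndim == 3:
            k = _mid_slice(mask, slice_axis)
            if k is None:
                logger.warning("region %d absent on all slices; recording NaN", rid)
                row.extend([MISSING] * (256 + 3 + 4))
                continue
            sl = [slice(None)] * 3
            sl[slice_axis] = k
            img2d, mask2d = data[tuple(sl)], mask[tuple(sl)]
        else:
            img2d, mask2d = data, mask
        if not mask2d.any():
            logger.warning("region %d empty on selected slice; recording NaN", rid)
            row.extend([MISSING] * (256 + 3 + 4))
            continue
        hist = lbp_histogram(img2d, mask2d)
        m1, m2, m3 = color_moments(img2d[mask2d])
        area, perim, ecc, comp = shape_features(mask2d)
        row.extend(hist.tolist() + [m1, m2, m3, area, perim, ecc, comp])

    values = np.array([row], dtype=float)
    if np.all(np.isfinite(values)):
        return FeatureTable([sample_id], names, values)
    # NaN here is the documented missing-region sentinel, so bypass the
    # finite-values invariant rather than silently imputing
    logger.warning("feature table contains missing-region sentinels")
    table = FeatureTable.__new__(FeatureTable)
    table.sample_ids = [sample_id]
    table.feature_names = names
    table.values = values
    table.labels = None
    return table
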