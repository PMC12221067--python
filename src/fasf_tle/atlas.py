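"""Atlas label transfer: map segmented voxels onto named anatomical regions.

Each in-brain subject voxel (X, Y, Z) is pushed through the 4x4 affine
``h`` into atlas voxel coordinates, the atlas label is sampled by
nearest neighbour (labels are categorical), and the voxel receives that
region id; coordinates falling outside the atlas grid map to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import AtlasRef, LabelVolume

__all__ = ["aal_label", "region_masks"]


def aal_label(seg: LabelVolume, atlas: AtlasRef) -> tuple[LabelVolume, pd.DataFrame]:
    """Transfer atlas region ids onto a segmented volume.

    Returns the region label volume and a stats table with one row per
    (region x tissue class) giving the voxel count.
    """
    seg_arr = seg.labels
    atlas_arr = atlas.labels.labels
    h = atlas.affine_h

    in_brain = seg_arr > 0
    coords = np.argwhere(in_brain)  # (n, ndim) voxel indices
    if coords.size == 0:
        regions = np.zeros_like(seg_arr)
        stats = pd.DataFrame(columns=["region_id", "region_name", "tissue", "voxels"])
        return LabelVolume(regions, dict(atlas.legend), seg.spacing, seg.affine), stats

    ndim = seg_arr.ndim
    homog = np.concatenate(
        [coords.astype(float), np.ones((len(coords), 4 - ndim))], axis=1
    )
    mapped = homog @ h.T  # atlas voxel coordinates
    idx = np.rint(mapped[:, :ndim]).astype(int)

    inside = np.all((idx >= 0) & (idx < np.array(atlas_arr.shape)), axis=1)
    if not inside.any():
        raise ValueError("affine maps every in-brain voxel outside the atlas grid")

    region_of = np.zeros(len(coords), dtype=atlas_arr.dtype)
    region_of[inside] = atlas_arr[tuple(idx[inside].T)]

    regions = np.zeros_like(seg_arr)
    regions[tuple(coords.T)] = region_of

    tissue_of = seg_arr[tuple(coords.T)]
    rows = []
    for rid in sorted(atlas.legend):
        for tis in sorted(np.unique(tissue_of)):
            count = int(np.sum((region_of == rid) & (tissue_of == tis)))
            rows.append(
                {
                    "region_id": int(rid),
                    "region_name": atlas.legend[rid],
                    "tissue": seg.legend.get(int(tis), str(tis)),
                    "voxels": count,
                }
            )
    stats = pd.DataFrame(rows, columns=["region_id", "region_name", "tissue", "voxels"])
    return LabelVolume(regions, dict(atlas.legend), seg.spacing, seg.affine), stats


def region_masks(labeled: LabelVolume, roi_ids: list[int]) -> list[np.ndarray]:
    """One binary mask per requested region id; masks are pairwise disjoint."""
    known = set(labeled.legend)
    unknown = [r for r in roi_ids if r not in known]
    if unknown:
        raise ValueError(f"unknown region id(s) {unknown}; known ids: {sorted(known)}")
    return [labeled.labels == rid for rid in roi_ids]
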