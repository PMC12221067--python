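"""Seeded phantom and dataset generators with full ground truth.

These generators produce every input the pipeline needs at desk scale:

* :func:`make_phantom` — an ellipsoidal three-tissue brain (nested
  CSF/GM/WM-like intensity classes), a dark gap, a bright skull shell,
  a smooth multiplicative bias field and impulse+Gaussian noise, with
  the true tissue labels, bias field and brain mask returned alongside.
* :func:`make_toy_atlas` — a contiguous-block partition of the brain
  ellipsoid standing in for a named-region atlas (one block is flagged
  temporal-lobe-like).
* :func:`make_feature_dataset` — a two-class feature table with a known
  informative subset at a controlled standardized mean difference.
* :func:`make_slice_dataset` — tiny slice-sequence image datasets where
  class 1 carries a bright blob in a fixed quadrant of the mid slices.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .types import AtlasRef, FeatureTable, LabelVolume, VolumeImage

__all__ = [
    "PhantomSpec",
    "FeatureSpec",
    "make_phantom",
    "make_toy_atlas",
    "make_feature_dataset",
    "make_slice_dataset",
]


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 32)
    tissue_means: tuple[float, ...] = (0.2, 0.5, 0.8)
    tissue_sds: tuple[float, ...] = (0.03, 0.03, 0.03)
    shell_thickness: float = 2.0
    shell_intensity: float = 0.9
    gap_thickness: float = 3.0
    bias_amplitude: float = 0.2
    bias_smoothness: float = 12.0
    impulse_fraction: float = 0.02
    gaussian_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError("phantom shape must be 3-D with every axis >= 8")
        if not 0.0 <= self.impulse_fraction <= 0.2:
            raise ValueError("impulse fraction must lie in [0, 0.2]")
        means = np.asarray(self.tissue_means)
        if np.any(np.diff(means) <= 0):
            raise ValueError("tissue means must be strictly increasing")


@dataclass
class FeatureSpec:
    n_per_class: int = 30
    n_informative: int = 2
    n_noise: int = 8
    effect_size: float = 4.0
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_informative < 1 or self.n_noise < 0:
            raise ValueError("counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect size must be nonnegative")


def _ellipsoid_radius(shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Normalized radius grid: 1.0 at the bounding ellipsoid surface."""
    grids = np.meshgrid(*[np.arange(s) - (s - 1) / 2 for s in shape], indexing="ij")
    semi = np.array([(s - 1) / 2 for s in shape])
    r = np.sqrt(sum((g / a) ** 2 for g, a in zip(grids, semi)))
    return r, semi


def make_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[VolumeImage, LabelVolume, np.ndarray, np.ndarray]:
    """Build the phantom; returns (volume, truth labels, bias field, brain mask)."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    r, semi = _ellipsoid_radius(shape)
    min_semi = semi.min()

    shell_outer = 0.98
    shell_inner = shell_outer - spec.shell_thickness / min_semi
    brain_outer = shell_inner - spec.gap_thickness / min_semi
    if brain_outer <= 0.15:
        raise ValueError(
            f"shape {shape} too small for shell thickness {spec.shell_thickness}"
            f" and gap {spec.gap_thickness}: no room left for the brain"
        )

    n_classes = len(spec.tissue_means)
    # nested radial bands, anatomically ordered: a small dark CSF-like
    # ventricle core, a thick bright WM-like middle, a GM-like outer band
    labels = np.zeros(shape, dtype=np.int32)
    if n_classes == 3:
        fracs = np.array([0.3, 0.75, 1.0])
    else:
        fracs = np.linspace(0, 1, n_classes + 1)[1:] ** (1.0 / 3.0)
    thresholds = np.concatenate([[0.0], brain_outer * fracs])
    order = [1] + list(range(n_classes, 1, -1))  # CSF core, then WM..GM outward
    for k in range(n_classes):
        band = (r >= thresholds[k]) & (r < thresholds[k + 1])
        labels[band] = order[k]

    brain_mask = labels > 0
    data = np.zeros(shape)
    for k in range(n_classes):
        cls = labels == (k + 1)
        data[cls] = spec.tissue_means[k] + (
            rng.normal(0.0, spec.tissue_sds[k], size=int(cls.sum()))
            if spec.tissue_sds[k] > 0
            else 0.0
        )
    shell = (r >= shell_inner) & (r < shell_outer)
    data[shell] = spec.shell_intensity
    data = np.clip(data, 0.0, None)

    if spec.bias_amplitude > 0:
        g = ndi.gaussian_filter(rng.normal(size=shape), spec.bias_smoothness)
        g *= spec.bias_amplitude / max(np.abs(g).max(), 1e-12)
        bias = np.exp(g)
    else:
        bias = np.ones(shape)
    data = data * bias

    if spec.gaussian_sd > 0:
        data = data + rng.normal(0.0, spec.gaussian_sd, size=shape)
    if spec.impulse_fraction > 0:
        n_imp = int(round(spec.impulse_fraction * data.size))
        flat = rng.choice(data.size, size=n_imp, replace=False)
        vals = np.where(rng.random(n_imp) < 0.5, 0.0, 1.0)  # pepper / salt
        data.ravel()[flat] = vals
    data = np.clip(data, 0.0, None)

    legend = {1: "CSF", 2: "GM", 3: "WM"} if n_classes == 3 else {
        k + 1: f"tissue_{k + 1}" for k in range(n_classes)
    }
    vol = VolumeImage(data, meta={"generator": "make_phantom", "seed": spec.seed})
    truth = LabelVolume(labels, legend)
    return vol, truth, bias, brain_mask


def make_toy_atlas(
    shape: tuple[int, int, int] = (64, 64, 32),
    n_regions: int = 4,
    seed: int = 0,
) -> AtlasRef:
    """Partition the brain ellipsoid into contiguous, equal-count slabs.

    Region 1 is flagged temporal-lobe-like; the affine defaults to
    identity (atlas grid == subject grid).
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    spec = PhantomSpec(shape=shape, bias_amplitude=0.0, impulse_fraction=0.0, seed=seed)
    _, truth, _, brain_mask = make_phantom(spec)
    n_brain = int(brain_mask.sum())
    if n_regions > n_brain:
        raise ValueError(f"{n_regions} regions exceed {n_brain} brain voxels")

    # slab split by lexicographic (x, y, z) rank: exactly equal counts,
    # each region a contiguous block of x-planes (boundary planes split
    # along y)
    coords = np.argwhere(brain_mask)  # argwhere is already lexicographic
    region = 1 + (np.arange(n_brain) * n_regions) // n_brain
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(coords.T)] = region
    legend = {1: "temporal_lobe_like"}
    legend.update({k: f"region_{k}" for k in range(2, n_regions + 1)})
    return AtlasRef(LabelVolume(labels, legend), np.eye(4))


@dataclass
class FeatureDataset:
    table: FeatureTable
    informative_columns: list[int]
    permutation: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def make_feature_dataset(spec: FeatureSpec | None = None) -> FeatureDataset:
    """Two-class table: informative class-conditional normals plus noise.

    Informative features have unit variance and class means separated by
    ``effect_size`` standard deviations; noise features are standard
    normal, independent of class.  Columns are shuffled with a recorded
    permutation so the informative subset stays known.
    """
    spec = spec or FeatureSpec()
    rng = np.random.default_rng(spec.seed)
    n, p_inf, p_noise = spec.n_per_class, spec.n_informative, spec.n_noise
    d = p_inf + p_noise

    cov = np.full((p_inf, p_inf), spec.correlation)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    inf0 = rng.normal(size=(n, p_inf)) @ chol.T
    inf1 = rng.normal(size=(n, p_inf)) @ chol.T + spec.effect_size
    noise = rng.normal(size=(2 * n, p_noise))
    X = np.concatenate([np.concatenate([inf0, inf1], axis=0), noise], axis=1)
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])

    perm = rng.permutation(d)
    X = X[:, perm]
    informative = [int(np.where(perm == j)[0][0]) for j in range(p_inf)]

    table = FeatureTable(
        [f"s{i}" for i in range(2 * n)],
        [f"f{j}" for j in range(d)],
        X,
        y,
    )
    return FeatureDataset(table, sorted(informative), perm)


def make_slice_dataset(
    n_per_class: int = 20,
    blob_contrast: float = 0.8,
    quadrant: tuple[int, int] = (0, 0),
    shape: tuple[int, int] = (16, 16),
    n_slices: int = 6,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Labelled slice sequences: class 1 carries a bright mid-slice blob.

    Returns (X of shape (2n, T, H, W), y, quadrant) where *quadrant*
    (row, col) in {0,1}^2 names the image quarter containing the blob.
    """
    if n_per_class < 4:
        raise ValueError("need at least 4 sequences per class")
    rng = np.random.default_rng(seed)
    H, W = shape
    T = n_slices
    cy = H // 4 + quadrant[0] * H // 2
    cx = W // 4 + quadrant[1] * W // 2
    yy, xx = np.mgrid[0:H, 0:W]
    blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * (min(H, W) / 8) ** 2)))

    X = rng.normal(0.2, noise_sd, size=(2 * n_per_class, T, H, W))
    y = np.concatenate([np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)])
    mid = [T // 2 - 1, T // 2] if T >= 2 else [0]
    for i in range(n_per_class, 2 * n_per_class):
        jitter = rng.normal(0.0, 0.05)
        for t in mid:
            X[i, t] += (blob_contrast + jitter) * blob
    return np.clip(X, 0.0, None), y, quadrant
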