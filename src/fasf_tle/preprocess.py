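"""MRI preprocessing: skull stripping, bias field correction, min-max
normalization and median filtering, applied in that order.

Bias field correction models the image as a multiplicative pair
``I = B * C`` (smooth scanner field times true tissue contrast) and works
in the log domain: each iteration removes a piecewise-constant tissue
structure estimate from the log image, low-pass filters the residual with
a wide Gaussian, and accumulates it into the field.  The energy is the
masked sum of squared residuals after structure removal; the loop stops
when its relative change drops below ``tol`` (or reverts and stops if an
iteration would increase it, so the recorded trace is non-increasing by
construction).  The mean of ``log B`` over the mask is pinned to zero so
the decomposition is identified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import ball, disk

from .config import PipelineConfig, PreprocessConfig
from .types import VolumeImage

logger = logging.getLogger("fasf_tle")

__all__ = [
    "BrainMask",
    "BiasModel",
    "skull_strip",
    "bias_field_correct",
    "min_max_normalize",
    "median_filter",
    "preprocess_pipeline",
]


@dataclass
class BrainMask:
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class BiasModel:
    """Estimated multiplicative field with its optimisation trace."""

    field: np.ndarray
    iterations_run: int
    energy_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.field <= 0):
            raise ValueError("bias field must be strictly positive")


def skull_strip(
    vol: VolumeImage,
    threshold_quantile: float = 0.5,
    morph_radius: int = 2,
    method: str = "otsu",
) -> tuple[VolumeImage, BrainMask]:
    """Remove non-brain voxels: threshold, open, keep largest, close, fill.

    The skull shell survives thresholding but is thin: erosion by
    ``morph_radius`` destroys it while the solid brain survives, so the
    largest component after the morphological opening is the brain.  The
    opening's dilation restores the brain outline; closing and hole
    filling then recover dark interior structures (e.g. CSF).
    """
    data = vol.data
    if not np.all(np.isfinite(data)):
        raise ValueError("volume intensities must be finite")
    if not np.any(data > 0):
        raise ValueError("no foreground: volume is entirely zero")

    positive = data[data > 0]
    if method == "otsu":
        # half the Otsu cut: keeps tissue darkened by bias fields while
        # still rejecting the near-zero gap between brain and skull
        thr = 0.5 * threshold_otsu(positive) if np.unique(positive).size > 1 else 0.0
    elif method == "quantile":
        thr = np.quantile(positive, threshold_quantile)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    fg = data > thr
    if not fg.any():
        # threshold swallowed everything (e.g. binary image) — fall back
        fg = data > 0

    selem = None
    if morph_radius > 0:
        selem = ball(morph_radius) if data.ndim == 3 else disk(morph_radius)
        core = ndi.binary_erosion(fg, structure=selem, border_value=1)
    else:
        core = fg
    comp, n = ndi.label(core)
    if n == 0:
        raise ValueError("no foreground after thresholding and erosion")
    sizes = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    mask = comp == (1 + int(np.argmax(sizes)))
    if selem is not None:
        mask = ndi.binary_dilation(mask, structure=selem) & fg
        # union with the closing so border voxels are never trimmed
        mask = mask | ndi.binary_closing(mask, structure=selem)
    mask = ndi.binary_fill_holes(mask)

    stripped = np.where(mask, data, 0.0)
    out = vol.with_data(stripped, step="skull_strip", method=method,
                        morph_radius=morph_radius)
    return out, BrainMask(mask)


def _structure_estimate(values: np.ndarray, n_classes: int, max_iter: int = 20) -> np.ndarray:
    """Piecewise-constant fit: tiny Lloyd k-means with quantile init."""
    n_classes = min(n_classes, np.unique(values).size)
    centers = np.quantile(values, (np.arange(n_classes) + 0.5) / n_classes)
    centers = np.unique(centers)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array([
            values[assign == k].mean() if np.any(assign == k) else centers[k]
            for k in range(centers.size)
        ])
        if np.allclose(new, centers, atol=1e-10):
            centers = new
            break
        centers = new
    assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    return centers[assign]


def _masked_gaussian(img: np.ndarray, mask: np.ndarray, sigma_vox: tuple[float, ...]) -> np.ndarray:
    """Normalized-convolution Gaussian: smooth inside the mask only."""
    m = mask.astype(float)
    num = ndi.gaussian_filter(img * m, sigma_vox)
    den = ndi.gaussian_filter(m, sigma_vox)
    out = np.zeros_like(img)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


def bias_field_correct(
    vol: VolumeImage,
    smoothing_sigma_mm: float = 8.0,
    max_iter: int = 20,
    tol: float = 1e-3,
    n_classes: int = 3,
) -> tuple[VolumeImage, BiasModel]:
    """Estimate and divide out a smooth multiplicative intensity field."""
    data = vol.data
    if np.any(data < 0):
        raise ValueError("negative intensities: normalize to nonnegative first")
    mask = data > 0
    if not mask.any():
        raise ValueError("no positive voxels to correct")

    sigma_vox = tuple(smoothing_sigma_mm / s for s in vol.spacing)
    log_img = np.zeros_like(data)
    log_img[mask] = np.log(data[mask])

    b = np.zeros_like(data)  # accumulated log-field
    energy_trace: list[float] = []
    iters = 0
    for iters in range(1, max_iter + 1):
        corrected = log_img - b
        structure = np.zeros_like(data)
        structure[mask] = _structure_estimate(corrected[mask], n_classes)
        residual = np.where(mask, corrected - structure, 0.0)
        energy = float(np.sum(residual[mask] ** 2))
        if energy_trace and energy > energy_trace[-1]:
            iters -= 1
            break  # revert: trace stays non-increasing
        energy_trace.append(energy)
        b_new = b + _masked_gaussian(residual, mask, sigma_vox)
        b_new -= b_new[mask].mean()  # gauge: mean log-field zero over mask
        rel = (
            abs(energy_trace[-2] - energy) / max(energy_trace[-2], 1e-30)
            if len(energy_trace) > 1
            else np.inf
        )
        b = b_new
        if rel < tol:
            break

    field_arr = np.ones_like(data)
    field_arr[mask] = np.exp(b[mask])
    corrected = np.where(mask, data / field_arr, data)
    out = vol.with_data(corrected, step="bias_field_correct",
                        smoothing_sigma_mm=smoothing_sigma_mm)
    return out, BiasModel(field_arr, iters, energy_trace)


def min_max_normalize(vol: VolumeImage) -> VolumeImage:
    """Rescale intensities to [0, 1]: (x - Min) / (Max - Min)."""
    data = vol.data
    if not np.all(np.isfinite(data)):
        raise ValueError("volume intensities must be finite")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        logger.warning("min_max_normalize: constant image, returning all zeros")
        return vol.with_data(np.zeros_like(data), step="min_max_normalize")
    return vol.with_data((data - lo) / (hi - lo), step="min_max_normalize")


def median_filter(vol: VolumeImage, window: int = 3) -> VolumeImage:
    """Median filter with reflect padding at the borders."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    out = ndi.median_filter(vol.data, size=window, mode="reflect")
    return vol.with_data(out, step="median_filter", window=window)


def preprocess_pipeline(
    vol: VolumeImage, config: PipelineConfig | PreprocessConfig | None = None
) -> VolumeImage:
    """Skull strip -> bias correct -> min-max normalize -> median filter."""
    if config is None:
        cfg = PreprocessConfig()
    elif isinstance(config, PipelineConfig):
        cfg = config.preprocess
    else:
        cfg = config
    out = vol
    if not cfg.enabled:
        return out
    if cfg.skull_strip:
        out, _ = skull_strip(out, cfg.threshold_quantile, cfg.morph_radius,
                             cfg.threshold_method)
    if cfg.bias_correct:
        out, _ = bias_field_correct(out, cfg.smoothing_sigma_mm, cfg.bias_max_iter,
                                    cfg.bias_tol, cfg.bias_n_classes)
    if cfg.normalize:
        out = min_max_normalize(out)
    if cfg.median:
        out = median_filter(out, cfg.median_window)
    return out
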