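"""Core containers shared by every pipeline stage.

A :class:`VolumeImage` is the object every image stage consumes and
produces: a 2-D or 3-D floating-point intensity grid together with the
voxel size in mm, a 4x4 voxel-to-world affine (NIfTI convention, 0-based
voxel indices) and a free-form provenance record.  Label maps travel as
:class:`LabelVolume` (non-negative integer grid plus a legend), tabular
features as :class:`FeatureTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VolumeImage",
    "LabelVolume",
    "FeatureTable",
    "AtlasRef",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine must be invertible")
    return affine


@dataclass
class VolumeImage:
    """2-D or 3-D intensity grid with spacing, affine and provenance."""

    data: np.ndarray
    spacing: tuple[float, ...] | None = None
    affine: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"data must have 2 or 3 axes, got {self.data.ndim}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match data dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0] * (4 - self.data.ndim))
            self.affine[3, 3] = 1.0
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray, step: str | None = None, **params) -> "VolumeImage":
        """Copy of this volume with new voxel data; records *step* in meta."""
        meta = dict(self.meta)
        if step is not None:
            meta.setdefault("steps", []).__class__  # keep type checkers calm
            meta["steps"] = list(meta.get("steps", [])) + [{"name": step, **params}]
        return VolumeImage(np.asarray(data), self.spacing, self.affine.copy(), meta)


@dataclass
class LabelVolume:
    """Integer label grid; 0 is background, every nonzero id is in the legend."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    spacing: tuple[float, ...] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int32)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("labels must be integers")
            self.labels = as_int
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            # auto-fill with generic names; invariant demands coverage
            for lab in sorted(missing):
                self.legend[lab] = f"region_{lab}"
        if self.spacing is None:
            self.spacing = (1.0,) * self.labels.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass
class FeatureTable:
    """Samples x named features, with optional binary class labels."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = sorted({f for f in self.feature_names if self.feature_names.count(f) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValueError("labels length must match number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def select(self, mask: Sequence[bool] | np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_features,):
            raise ValueError("mask length must equal feature count")
        names = [f for f, m in zip(self.feature_names, mask) if m]
        return FeatureTable(self.sample_ids, names, self.values[:, mask], self.labels)


@dataclass
class AtlasRef:
    """Atlas label volume plus the subject-voxel -> atlas-voxel affine."""

    labels: LabelVolume
    affine_h: np.ndarray
    legend: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.affine_h = _check_affine(self.affine_h)
        if self.legend is None:
            self.legend = dict(self.labels.legend)
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.labels.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend missing atlas labels: {sorted(missing)}")
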