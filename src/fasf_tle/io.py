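"""Readers and writers for the formats the pipeline touches.

Volumes travel as NIfTI-1 (via nibabel) or as lexicographically ordered
stacks of single-channel PNG/TIFF slices (identity affine, unit spacing).
Label legends ride in a JSON sidecar next to the NIfTI file.  Feature
tables are CSV with a header row, first column the sample id and an
optional trailing ``label`` column.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .types import FeatureTable, LabelVolume, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_feature_table",
    "write_feature_table",
]

_SLICE_EXTS = {".png", ".tif", ".tiff"}


def _legend_sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".legend.json")
    return path.with_suffix(".legend.json")


def _read_slice(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[-1] == 1:
            arr = arr[..., 0]
        else:
            raise ValueError(
                f"expected grayscale image, got {arr.shape[-1]} channels: {path}"
            )
    return np.asarray(arr, dtype=np.float64)


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 volume, a single 2-D slice, or a directory slice stack.

    PNG/TIFF stacks are ordered lexicographically by filename and stacked
    along the last axis; they get unit spacing and an identity affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")

    if path.is_dir():
        slices = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTS
        )
        if not slices:
            raise ValueError(f"no PNG/TIFF slices found in directory: {path}")
        arrs = [_read_slice(p) for p in slices]
        shapes = {a.shape for a in arrs}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice shapes {shapes} in {path}")
        data = np.stack(arrs, axis=-1)
        return VolumeImage(data, meta={"source": str(path), "n_slices": len(arrs)})

    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D NIfTI, got {data.ndim}-D: {path}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return VolumeImage(data, spacing, np.asarray(img.affine), meta={"source": str(path)})

    if path.suffix.lower() in _SLICE_EXTS:
        return VolumeImage(_read_slice(path), meta={"source": str(path)})

    raise ValueError(f"unsupported volume format ({path.suffix!r}): {path}")


def write_volume(vol: VolumeImage | LabelVolume, path: str | Path) -> None:
    """Write a volume (or label map) as NIfTI-1.

    Labels are written with an integer datatype and their legend as a JSON
    sidecar ``<stem>.legend.json``.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")

    if isinstance(vol, LabelVolume):
        if vol.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        img = nib.Nifti1Image(vol.labels.astype(np.int32), vol.affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
        sidecar = _legend_sidecar(path)
        sidecar.write_text(
            json.dumps({str(k): v for k, v in sorted(vol.legend.items())}, indent=0)
            + "\n"
        )
        return

    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read an integer label volume and its legend sidecar (if present)."""
    path = Path(path)
    vol = read_volume(path)
    labels = vol.data
    as_int = np.rint(labels).astype(np.int32)
    if not np.allclose(labels, as_int):
        raise ValueError(f"volume is not integer-valued, cannot be labels: {path}")
    legend: dict[int, str] = {}
    sidecar = _legend_sidecar(path)
    if sidecar.exists():
        legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabelVolume(as_int, legend, vol.spacing, vol.affine)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, "sample_id", table.sample_ids)
    if table.labels is not None:
        df["label"] = table.labels
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such feature table: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"feature table needs a sample-id column plus features: {path}")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    cols = list(df.columns[1:])
    labels = None
    if cols and cols[-1] == "label":
        labels = df["label"].to_numpy(dtype=int)
        cols = cols[:-1]
    values = df[cols].to_numpy(dtype=float)
    return FeatureTable(sample_ids, cols, values, labels)


def feature_table_io(
    table: FeatureTable | None, path: str | Path, mode: str
) -> FeatureTable | None:
    """Single entry point for CSV feature-table round trips."""
    if mode == "write":
        if table is None:
            raise ValueError("mode='write' requires a table")
        write_feature_table(table, path)
        return None
    if mode == "read":
        return read_feature_table(path)
    raise ValueError(f"mode must be 'read' or 'write', got {mode!r}")
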