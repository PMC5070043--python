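"""File formats: NIfTI-1 volumes and dot-decimal TSV tables."""

from __future__ import annotations

import pathlib
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import GeometryError, MalformedInputError
from .glm import VolumetricImage


def write_volume(
    path: str | pathlib.Path, values: np.ndarray, voxel_size: float
) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    if np.issubdtype(np.asarray(values).dtype, np.integer):
        data = np.asarray(values, dtype=np.int32)
    else:
        data = np.asarray(values, dtype=np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path: str | pathlib.Path) -> VolumetricImage:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-4:
        raise GeometryError(f"{path}: anisotropic voxels are not supported")
    return VolumetricImage(
        values=np.asarray(img.dataobj, dtype=float), voxel_size=float(zooms[0])
    )


def read_label_volume(path: str | pathlib.Path) -> tuple[np.ndarray, float]:
    vol = read_volume(path)
    labels = np.rint(vol.values).astype(np.int32)
    if np.abs(vol.values - labels).max() > 1e-3:
        raise MalformedInputError(f"{path}: label volume has non-integer values")
    return labels, vol.voxel_size


def read_volume_stack(
    paths: Sequence[str | pathlib.Path],
) -> tuple[np.ndarray, float]:
    """Load subject volumes, enforcing a common grid and voxel size."""
    if not paths:
        raise MalformedInputError("no volumes given")
    images = [read_volume(p) for p in paths]
    shape, vs = images[0].grid_shape, images[0].voxel_size
    for p, im in zip(paths, images):
        if im.grid_shape != shape or abs(im.voxel_size - vs) > 1e-4:
            raise GeometryError(
                f"{p}: grid {im.grid_shape}@{im.voxel_size}mm does not match "
                f"{shape}@{vs}mm"
            )
    return np.stack([im.values for im in images]), vs


def read_table(path: str | pathlib.Path, numeric: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV with dot decimals; comma decimals raise instead of corrupting."""
    df = pd.read_csv(path, sep="\t")
    for col in numeric:
        if col not in df.columns:
            raise MalformedInputError(f"{path}: missing column {col!r}")
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise MalformedInputError(
                f"{path}: column {col!r} is not numeric (comma decimal "
                f"separators are not supported): {exc}"
            ) from None
    return df


def write_table(df: pd.DataFrame, path: str | pathlib.Path) -> None:
    df.to_csv(path, sep="\t", index=False)
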