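"""Neuroimaging I/O and representation changes.

All volumetric data move through NIfTI-1 files (via :mod:`nibabel`) and three
in-memory representations:

* voxel space — 3D/4D arrays inside :class:`VolumeGrid` / :class:`TimeSeriesVolume`;
* masked-matrix space — frames flattened to ``(t, n_mask_voxels)``, the space
  in which clustering operates;
* region-vector space — one value per atlas region, the space in which
  cross-species spatial correlations are computed.

No registration or resampling is performed: every object in a given analysis
is assumed to live on the same, already co-registered grid, and a
:class:`~trinet.errors.GeometryError` is raised when shapes disagree.

Motion traces are whitespace/tab-delimited ``t x 6`` text files, columns
``tx ty tz`` in millimetres followed by ``rx ry rz`` in radians.

Regions with zero voxels yield NaN (an explicit undefined marker) rather than
zero, so that downstream spatial correlations can drop them instead of being
silently biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError, UnsupportedRankError, ValidationError

__all__ = [
    "VolumeGrid",
    "TimeSeriesVolume",
    "MotionTrace",
    "Parcellation",
    "RegionVector",
    "read_volume",
    "write_volume",
    "read_motion_trace",
    "write_motion_trace",
    "read_parcellation",
    "write_parcellation",
    "extract_region_means",
    "map_to_region_vector",
    "mask_frames",
    "unmask",
]


@dataclass
class VolumeGrid:
    """A single 3D scalar map on a regular voxel grid.

    Parameters
    ----------
    values : ndarray, shape (x, y, z)
    voxel_size : mm extent of a voxel along each axis (strictly positive).
    origin_offset : mm world coordinate of the first voxel.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError(f"VolumeGrid needs a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValidationError("all three dimensions must be >= 1")
        if min(self.voxel_size) <= 0:
            raise ValidationError("voxel_size must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin_offset
        return aff


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame.

    ``translations_mm`` and ``rotations_rad`` are both ``(t, 3)``.
    """

    translations_mm: np.ndarray
    rotations_rad: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        self.rotations_rad = np.atleast_2d(np.asarray(self.rotations_rad, dtype=float))
        if self.translations_mm.shape != self.rotations_rad.shape:
            raise ValidationError("translations and rotations must have equal shapes")
        if self.translations_mm.shape[1] != 3:
            raise ValidationError("motion trace needs 3 translation and 3 rotation columns")

    @property
    def n_frames(self) -> int:
        return self.translations_mm.shape[0]


@dataclass
class TimeSeriesVolume:
    """A 4D functional run.

    ``frames`` is ``(x, y, z, t)``; ``mask`` marks in-brain voxels; ``motion``
    optionally carries the run's realignment parameters.
    """

    frames: np.ndarray
    tr_seconds: float
    mask: Optional[np.ndarray] = None
    motion: Optional[MotionTrace] = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValidationError(f"TimeSeriesVolume needs a 4D array, got ndim={self.frames.ndim}")
        if self.frames.shape[3] < 2:
            raise ValidationError("a run needs at least 2 frames")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[:3]:
                raise GeometryError("mask shape must equal the spatial shape of the frames")
        if self.motion is not None and self.motion.n_frames != self.n_frames:
            raise ValidationError("motion trace length must equal the number of frames")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[3]


@dataclass
class Parcellation:
    """Integer label volume plus a region table.

    ``labels`` uses 0 for background; every nonzero label must appear in
    ``region_table`` (index = region id, columns ``name`` and ``hemisphere``).
    """

    labels: np.ndarray
    region_table: pd.DataFrame
    atlas_id: str = "atlas"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("parcellation labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("parcellation labels must be integers")
        if self.labels.min() < 0:
            raise ValidationError("parcellation labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.region_table.index)
        if missing:
            raise ValidationError(f"labels missing from region table: {sorted(missing)}")

    @property
    def region_ids(self) -> np.ndarray:
        """Region ids in table order."""
        return np.asarray(self.region_table.index)

    @property
    def n_regions(self) -> int:
        return len(self.region_table)


@dataclass
class RegionVector:
    """One scalar per atlas region; NaN marks undefined (empty) regions."""

    values: pd.Series
    atlas_id: str = "atlas"

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy()


# ---------------------------------------------------------------------------
# NIfTI round trips


def read_volume(path: Union[str, Path]) -> Union[VolumeGrid, TimeSeriesVolume]:
    """Read a NIfTI-1 file as a :class:`VolumeGrid` (3D) or :class:`TimeSeriesVolume` (4D).

    The repetition time of a 4D file is taken from the header time step.
    Raises :class:`FormatError` for unreadable files and
    :class:`UnsupportedRankError` for 5D+ data.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except UnsupportedRankError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read {path} as NIfTI-1: {exc}") from exc
    data = np.squeeze(data) if data.ndim > 4 and all(s == 1 for s in data.shape[4:]) else data
    if data.ndim not in (3, 4):
        raise UnsupportedRankError(f"{path}: rank-{data.ndim} volumes are not supported")
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if data.ndim == 3:
        return VolumeGrid(data, voxel_size=voxel_size, origin_offset=origin)
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return TimeSeriesVolume(data, tr_seconds=tr, voxel_size=voxel_size, origin_offset=origin)


def write_volume(obj: Union[VolumeGrid, TimeSeriesVolume, Parcellation], path: Union[str, Path]) -> Path:
    """Write a volume to NIfTI-1. Scalar data are stored as float32, labels as int32."""
    path = Path(path)
    if isinstance(obj, Parcellation):
        aff = np.eye(4)
        img = nib.Nifti1Image(obj.labels.astype(np.int32), aff)
    elif isinstance(obj, TimeSeriesVolume):
        aff = np.diag(list(obj.voxel_size) + [1.0])
        aff[:3, 3] = obj.origin_offset
        img = nib.Nifti1Image(obj.frames.astype(np.float32), aff)
        img.header.set_zooms(tuple(obj.voxel_size) + (obj.tr_seconds,))
        img.header.set_xyzt_units("mm", "sec")
    else:
        img = nib.Nifti1Image(obj.values.astype(np.float32), obj.affine())
        img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Motion & parcellation tables


def read_motion_trace(path: Union[str, Path]) -> MotionTrace:
    """Read a whitespace-delimited t x 6 motion file (translations mm, rotations rad)."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise FormatError(f"motion file must have 6 columns, got {arr.shape[1]}")
    return MotionTrace(arr[:, :3], arr[:, 3:])


def write_motion_trace(trace: MotionTrace, path: Union[str, Path]) -> Path:
    path = Path(path)
    arr = np.hstack([trace.translations_mm, trace.rotations_rad])
    np.savetxt(path, arr, fmt="%.8g", delimiter="\t")
    return path


def read_parcellation(labels_path: Union[str, Path], table_path: Union[str, Path],
                      atlas_id: str = "atlas") -> Parcellation:
    """Read a label NIfTI plus a TSV region table (columns: region_id, name, hemisphere)."""
    vol = read_volume(labels_path)
    if not isinstance(vol, VolumeGrid):
        raise FormatError("parcellation label file must be 3D")
    table = pd.read_csv(table_path, sep="\t").set_index("region_id")
    return Parcellation(np.rint(vol.values).astype(int), table, atlas_id=atlas_id)


def write_parcellation(atlas: Parcellation, labels_path: Union[str, Path],
                       table_path: Union[str, Path]) -> None:
    write_volume(atlas, labels_path)
    atlas.region_table.rename_axis("region_id").to_csv(table_path, sep="\t")


# ---------------------------------------------------------------------------
# Representation changes


def _check_spatial(shape_a: Sequence[int], shape_b: Sequence[int]) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise GeometryError(f"spatial shapes differ: {tuple(shape_a)} vs {tuple(shape_b)}")


def extract_region_means(ts: TimeSeriesVolume, atlas: Parcellation) -> pd.DataFrame:
    """Mean time course per atlas region.

    Returns a ``(t, n_regions)`` DataFrame, columns in region-table order.
    Background voxels (label 0) are excluded; a region with zero voxels gets a
    NaN column rather than a silent zero.
    """
    _check_spatial(ts.spatial_shape, atlas.labels.shape)
    flat_labels = atlas.labels.ravel()
    flat = ts.frames.reshape(-1, ts.n_frames)  # (voxels, t)
    n_labels = int(flat_labels.max()) + 1
    counts = np.bincount(flat_labels, minlength=n_labels).astype(float)
    sums = np.zeros((n_labels, ts.n_frames))
    for t in range(ts.n_frames):
        sums[:, t] = np.bincount(flat_labels, weights=flat[:, t], minlength=n_labels)
    out = np.full((ts.n_frames, atlas.n_regions), np.nan)
    for j, rid in enumerate(atlas.region_ids):
        if rid < n_labels and counts[rid] > 0:
            out[:, j] = sums[rid] / counts[rid]
    return pd.DataFrame(out, columns=atlas.region_ids)


def map_to_region_vector(vol: VolumeGrid, atlas: Parcellation) -> RegionVector:
    """Per-region mean of a 3D map; empty regions map to NaN."""
    _check_spatial(vol.shape, atlas.labels.shape)
    flat_labels = atlas.labels.ravel()
    flat = vol.values.ravel()
    n_labels = int(flat_labels.max()) + 1
    counts = np.bincount(flat_labels, minlength=n_labels).astype(float)
    sums = np.bincount(flat_labels, weights=flat, minlength=n_labels)
    vals = {}
    for rid in atlas.region_ids:
        vals[rid] = sums[rid] / counts[rid] if (rid < n_labels and counts[rid] > 0) else np.nan
    return RegionVector(pd.Series(vals), atlas_id=atlas.atlas_id)


def mask_frames(ts: TimeSeriesVolume) -> np.ndarray:
    """Flatten a run to ``(t, n_mask_voxels)`` masked-matrix form."""
    return ts.frames[ts.mask].T.copy()


def unmask(vector: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Scatter a masked-voxel vector back to a 3D array."""
    out = np.full(mask.shape, fill, dtype=float)
    out[mask] = vector
    return out
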