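"""Volume / label-map I/O and grid handling.

Volumes are 3D intensity grids with physical voxel spacing; label maps are
integer region-id grids aligned voxel-for-voxel with their volume.  All
images are reoriented to a canonical (RAS) axis order on read so that
downstream geometry never has to reason about orientation codes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


class FormatError(ValueError):
    """Raised when an on-disk image violates the expected format."""


class ValidationError(ValueError):
    """Raised when image content is inconsistent with its metadata/table."""


@dataclass
class Volume:
    """A 3D intensity grid with physical spacing (mm) and origin (mm)."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError(f"volume grid must be 3D, got {self.grid.ndim}D")
        if min(self.grid.shape) < 1:
            raise FormatError("volume grid must have size >= 1 along each axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be finite and positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelMap:
    """Integer region-id grid aligned with a :class:`Volume`; 0 = background."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise FormatError(f"label grid must be 3D, got {grid.ndim}D")
        if not np.issubdtype(grid.dtype, np.integer):
            if not np.allclose(grid, np.round(grid)):
                raise FormatError("label map contains non-integer values")
            grid = np.round(grid).astype(np.int32)
        if grid.min() < 0:
            raise ValidationError("label ids must be non-negative")
        self.grid = grid.astype(np.int32, copy=False)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def ids(self) -> np.ndarray:
        """Sorted nonzero region ids present in the map."""
        u = np.unique(self.grid)
        return u[u != 0]

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


class RegionTable:
    """Region-id dictionary: id, name, hemisphere (left|right|none), set (WM45|CTX70).

    The shipped default table follows the 115-region convention used for
    whole-brain parcellations: 45 white-matter regions plus 70 cortical
    regions.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"id", "name", "hemisphere", "set"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"region table missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["id"] = frame["id"].astype(int)
        if frame["id"].duplicated().any():
            dup = frame.loc[frame["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate region ids: {dup}")
        if (frame["id"] <= 0).any():
            raise ValidationError("region ids must be positive")
        bad = set(frame["set"]) - {"WM45", "CTX70"}
        if bad:
            raise ValidationError(f"unknown region set labels: {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    def name_of(self, region_id: int) -> str:
        row = self.frame.loc[self.frame["id"] == region_id]
        if row.empty:
            raise KeyError(f"region id {region_id} not in table")
        return str(row["name"].iloc[0])

    def subset(self, region_set: str) -> "RegionTable":
        """Restrict to ``WM45`` or return the full table for ``ALL115``."""
        if region_set == "ALL115":
            return self
        if region_set in ("WM45", "CTX70"):
            return RegionTable(self.frame[self.frame["set"] == region_set])
        raise ValueError(f"unknown region set {region_set!r}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RegionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def default(cls) -> "RegionTable":
        """The shipped 115-region table (45 WM + 70 cortical)."""
        ref = importlib.resources.files("apvpipe.data") / "regions_115.tsv"
        with importlib.resources.as_file(ref) as p:
            table = cls.read_tsv(p)
        n_wm = (table.frame["set"] == "WM45").sum()
        n_ctx = (table.frame["set"] == "CTX70").sum()
        assert n_wm == 45 and n_ctx == 70
        return table


def _load_canonical(path: str | Path) -> tuple[np.ndarray, tuple, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad headers
        raise FormatError(f"could not read NIfTI header of {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D image, got {data.ndim}D with shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    axcodes = tuple(nib.aff2axcodes(img.affine))
    return data, spacing, origin, axcodes


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 intensity image (optionally .nii.gz)."""
    data, spacing, origin, axcodes = _load_canonical(path)
    return Volume(grid=data.astype(np.float64), spacing=spacing, origin=origin, axcodes=axcodes)


def write_volume(vol: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.grid, dtype=np.float64), vol.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_labelmap(path: str | Path, regions: RegionTable) -> LabelMap:
    """Read an integer label map and validate every nonzero id against ``regions``."""
    data, spacing, origin, axcodes = _load_canonical(path)
    lmap = LabelMap(grid=data, spacing=spacing, origin=origin, axcodes=axcodes)
    unknown = sorted(set(lmap.ids().tolist()) - set(regions.ids.tolist()))
    if unknown:
        raise ValidationError(f"label map contains ids absent from the region table: {unknown}")
    return lmap


def write_labelmap(lmap: LabelMap, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(lmap.grid, dtype=np.int32), lmap.affine())
    img.header.set_zooms(lmap.spacing)
    nib.save(img, str(path))


def resample_isotropic(
    vol: Volume, lmap: LabelMap | None = None, target: float = 1.0
) -> tuple[Volume, LabelMap | None]:
    """Resample to an isotropic grid (default 1 mm).

    Intensities are interpolated trilinearly; labels with nearest neighbour so
    no new region id can appear.  Resampling to the native spacing is the
    identity on the grid.
    """
    if target <= 0 or not np.isfinite(target):
        raise ValueError("target spacing must be finite and positive")
    if lmap is not None and lmap.shape != vol.shape:
        raise ValidationError(f"volume {vol.shape} and label map {lmap.shape} are misaligned")
    if all(abs(s - target) < 1e-12 for s in vol.spacing):
        out_map = None if lmap is None else replace(lmap, grid=lmap.grid.copy())
        return replace(vol, grid=vol.grid.copy()), out_map

    old_shape = vol.shape
    new_shape = tuple(
        max(1, int(round(n * s / target))) for n, s in zip(old_shape, vol.spacing)
    )
    # output index j samples input coordinate j * target / spacing
    coords = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(new_shape, vol.spacing)],
        indexing="ij",
    )
    coords = np.stack(coords)
    new_grid = ndimage.map_coordinates(
        vol.grid.astype(np.float64), coords, order=1, mode="nearest"
    )
    out_vol = Volume(
        grid=new_grid,
        spacing=(target,) * 3,
        origin=vol.origin,
        axcodes=vol.axcodes,
    )
    out_map = None
    if lmap is not None:
        new_labels = ndimage.map_coordinates(lmap.grid, coords, order=0, mode="nearest")
        out_map = LabelMap(
            grid=new_labels,
            spacing=(target,) * 3,
            origin=lmap.origin,
            axcodes=lmap.axcodes,
        )
    return out_vol, out_map


@dataclass
class RegionVoxels:
    """All voxels of one region: intensities, integer coordinates, bounding box."""

    region_id: int
    intensities: np.ndarray          # (n,)
    coords: np.ndarray               # (n, 3) integer voxel indices
    bbox: tuple[slice, slice, slice] | None

    def __len__(self) -> int:
        return len(self.intensities)


def region_voxels(vol: Volume, lmap: LabelMap, region_id: int) -> RegionVoxels:
    """Extract exactly the voxels where the label map equals ``region_id``."""
    if region_id == 0:
        raise ValueError("region id 0 is background")
    if lmap.shape != vol.shape:
        raise ValidationError(f"volume {vol.shape} and label map {lmap.shape} are misaligned")
    mask = lmap.grid == region_id
    coords = np.argwhere(mask)
    if coords.size == 0:
        return RegionVoxels(region_id, np.empty(0), coords.reshape(0, 3), None)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    bbox = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return RegionVoxels(region_id, vol.grid[mask], coords, bbox)
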