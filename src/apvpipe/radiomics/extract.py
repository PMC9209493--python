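"""Per-subject feature extraction over a multi-region label map."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..image_io import LabelMap, RegionTable, ValidationError, Volume
from .catalogue import FeatureCatalogue, default_catalogue
from .firstorder import discretize, firstorder_features
from .shape import fractal_dimension, shape_features
from .texture import texture_features, texture_matrices
from .wavelet import wavelet_bank

#: regions smaller than this many voxels are fully masked: texture statistics
#: are meaningless on tiny supports
MIN_REGION_VOXELS = 27


def feature_column_name(region: str, channel: str, family: str, name: str) -> str:
    return f"{region}__{channel}__{family}__{name}"


def extract_region_features(
    channel_grids: dict[str, np.ndarray],
    mask: np.ndarray,
    coords: np.ndarray,
    spacing: tuple[float, float, float],
    catalogue: FeatureCatalogue,
) -> dict[str, float]:
    """Feature values of one region, keyed ``channel__family__name``."""
    out: dict[str, float] = {}
    shape_vals: dict[str, float] | None = None
    per_channel: dict[str, dict[str, dict[str, float]]] = {}
    for ch in catalogue.channels:
        families = [f for f in catalogue.families_for(ch) if f != "shape"]
        if not families:
            continue
        grid = channel_grids[ch]
        values = grid[mask]
        levels = np.where(mask, discretize_grid(grid, mask, catalogue), 0)
        fam_vals: dict[str, dict[str, float]] = {}
        if "firstorder" in families:
            fam_vals["firstorder"] = firstorder_features(values, catalogue.discretization)
        if any(f in families for f in ("glcm", "glrlm", "glszm", "ngtdm", "ngldm")):
            mats = texture_matrices(levels, mask, catalogue.geometry)
            fam_vals.update(texture_features(mats))
        per_channel[ch] = fam_vals
    for fid in catalogue.feature_ids:
        if fid.family == "shape":
            if shape_vals is None:
                shape_vals = shape_features(coords, spacing)
                shape_vals["fractal_dimension"] = fractal_dimension(coords)
            out[str(fid)] = shape_vals[fid.name]
        else:
            out[str(fid)] = per_channel[fid.channel][fid.family][fid.name]
    return out


def discretize_grid(
    grid: np.ndarray, mask: np.ndarray, catalogue: FeatureCatalogue
) -> np.ndarray:
    """Discretize the in-mask voxels of a bounding-box grid to levels 1..L."""
    levels = np.zeros(grid.shape, dtype=np.int64)
    levels[mask] = discretize(grid[mask], catalogue.discretization)
    return levels


def extract_subject_features(
    vol: Volume,
    lmap: LabelMap,
    regions: RegionTable,
    catalogue: FeatureCatalogue | None = None,
    region_set: str = "WM45",
    min_voxels: int = MIN_REGION_VOXELS,
) -> pd.Series:
    """One subject's flattened feature row over a region set.

    Column order is deterministic: regions in table order, features in
    catalogue order, named ``region__channel__family__name``.  Regions with
    fewer than ``min_voxels`` voxels (including absent regions) contribute a
    fully masked (NaN) block of one catalogue length.
    """
    if lmap.shape != vol.shape:
        raise ValidationError(f"volume {vol.shape} and label map {lmap.shape} are misaligned")
    catalogue = catalogue or default_catalogue()
    table = regions.subset(region_set)

    wanted_wavelets = tuple(ch for ch in catalogue.channels if ch != "original")
    full_channels: dict[str, np.ndarray] = {"original": np.asarray(vol.grid, dtype=np.float64)}
    if wanted_wavelets:
        full_channels.update(wavelet_bank(vol.grid, catalogue.wavelet, wanted_wavelets))

    values: dict[str, float] = {}
    for _, row in table.frame.iterrows():
        rid = int(row["id"])
        rname = str(row["name"])
        mask_full = lmap.grid == rid
        coords = np.argwhere(mask_full)
        if len(coords) < min_voxels:
            for fid in catalogue.feature_ids:
                values[feature_column_name(rname, *fid)] = np.nan
            continue
        lo = coords.min(axis=0)
        hi = coords.max(axis=0) + 1
        bbox = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        mask = mask_full[bbox]
        channel_grids = {ch: g[bbox] for ch, g in full_channels.items()}
        region_vals = extract_region_features(
            channel_grids, mask, coords, vol.spacing, catalogue
        )
        for key, val in region_vals.items():
            values[f"{rname}__{key}"] = val
    return pd.Series(values, dtype=np.float64)
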