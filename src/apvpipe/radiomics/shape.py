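"""Mask-based shape descriptors and box-counting fractal dimension."""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .firstorder import EmptyRegionError


def _exposed_face_area(coords: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Surface area as the summed area of voxel faces not shared with the region."""
    lo = coords.min(axis=0)
    shape = coords.max(axis=0) - lo + 1
    mask = np.zeros(tuple(shape), dtype=bool)
    mask[tuple((coords - lo).T)] = True
    pad = np.pad(mask, 1)
    area = 0.0
    face = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    for axis in range(3):
        for shift in (1, -1):
            neighbour = np.roll(pad, shift, axis=axis)
            area += float(np.count_nonzero(pad & ~neighbour)) * face[axis]
    return area


def _max_diameter(phys: np.ndarray) -> float:
    """Largest pairwise distance between voxel centres (mm)."""
    pts = phys
    if len(pts) > 400:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (flat) point sets: fall back to pairwise
    if len(pts) > 3000:  # pathological flat regions; subsample deterministically
        pts = pts[:: len(pts) // 3000 + 1]
    if len(pts) < 2:
        return 0.0
    return float(pdist(pts).max())


def shape_features(
    coords: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> dict[str, float]:
    """The 8 default shape descriptors of a voxel mask.

    Volume is voxel count times voxel volume; surface area counts exposed
    voxel faces; sphericity = pi^(1/3) (6V)^(2/3) / A equals ~0.806 for a
    cube and 1 for an ideal sphere.
    """
    coords = np.asarray(coords, dtype=np.int64)
    if coords.size == 0:
        raise EmptyRegionError("cannot compute shape features of an empty region")
    n = len(coords)
    voxel_volume = float(np.prod(spacing))
    volume = n * voxel_volume
    area = _exposed_face_area(coords, spacing)
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    compactness = float(volume / (np.sqrt(np.pi) * area ** 1.5))
    phys = coords * np.asarray(spacing)
    diameter = _max_diameter(phys)
    if n > 1:
        cov = np.cov(phys.T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    if eig[0] > 0:
        elongation = float(np.sqrt(eig[1] / eig[0]))
        flatness = float(np.sqrt(eig[2] / eig[0]))
    else:
        elongation = 1.0
        flatness = 1.0
    return {
        "volume_mm3": volume,
        "voxel_count": float(n),
        "surface_area_mm2": area,
        "sphericity": sphericity,
        "compactness": compactness,
        "max_3d_diameter": diameter,
        "elongation": elongation,
        "flatness": flatness,
    }


def fractal_dimension(coords: np.ndarray) -> float:
    """Box-counting dimension of a voxel mask.

    Least-squares slope of log N(s) against log(1/s) over dyadic box sizes
    s = 1, 2, 4, ...; returns NaN (undefined, to be masked) when fewer than
    two voxels or two usable box sizes exist.
    """
    coords = np.asarray(coords, dtype=np.int64)
    if len(coords) < 2:
        return float("nan")
    coords = coords - coords.min(axis=0)
    extent = int(coords.max()) + 1
    sizes = []
    s = 1
    while s <= max(2, extent // 2):
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return float("nan")
    counts = []
    for s in sizes:
        boxes = coords // s
        dims = boxes.max(axis=0) + 1
        keys = (boxes[:, 0] * dims[1] + boxes[:, 1]) * dims[2] + boxes[:, 2]
        counts.append(len(np.unique(keys)))
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes)), np.log(counts), 1)[0]
    return float(slope)
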