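"""Grey-level discretization and first-order (intensity histogram) features."""

from __future__ import annotations

import numpy as np

from .catalogue import DiscretizationSpec


class EmptyRegionError(ValueError):
    """Operation requested on a region with no voxels."""


def discretize(values: np.ndarray, spec: DiscretizationSpec | None = None) -> np.ndarray:
    """Map intensities to integer grey levels 1..L.

    Fixed-bin-count mode uses equal-width bins over the region [min, max];
    bins are half-open with the last bin closed, so the maximum falls in bin
    L.  A constant region maps to a single level (all ones).
    """
    spec = spec or DiscretizationSpec()
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise EmptyRegionError("cannot discretize an empty region")
    vmin = values.min()
    vmax = values.max()
    if spec.mode == "fixed-bin-count":
        if vmax == vmin:
            return np.ones(values.shape, dtype=np.int64)
        width = (vmax - vmin) / spec.bins
        levels = np.floor((values - vmin) / width).astype(np.int64) + 1
        return np.clip(levels, 1, spec.bins)
    # fixed-bin-width: bins anchored at the region minimum
    levels = np.floor((values - vmin) / spec.width).astype(np.int64) + 1
    return levels


def firstorder_features(
    values: np.ndarray, spec: DiscretizationSpec | None = None
) -> dict[str, float]:
    """The 18 default first-order statistics of a voxel intensity list.

    Moment-based statistics use the population (1/n) convention; kurtosis is
    the non-excess (Pearson) form, so a normal sample approaches 3.  Entropy
    (bits) and uniformity are computed on the discretized grey levels.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise EmptyRegionError("cannot compute first-order features of an empty region")
    n = x.size
    mean = x.mean()
    var = x.var()                      # population variance
    sd = np.sqrt(var)
    centred = x - mean
    if sd > 0:
        skewness = np.mean(centred**3) / sd**3
        kurtosis = np.mean(centred**4) / var**2
    else:
        skewness = 0.0
        kurtosis = 0.0
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    levels = discretize(x, spec)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    return {
        "mean": float(mean),
        "median": float(np.median(x)),
        "sd": float(sd),
        "variance": float(var),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "p10": float(p10),
        "p90": float(p90),
        "iqr": float(p75 - p25),
        "skewness": float(skewness),
        "kurtosis": float(kurtosis),
        "energy": float((x**2).sum()),
        "rms": float(np.sqrt((x**2).mean())),
        "mad": float(np.abs(centred).mean()),
        "entropy": entropy,
        "uniformity": uniformity,
        "robust_mean": float(robust.mean()) if robust.size else float(mean),
    }
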