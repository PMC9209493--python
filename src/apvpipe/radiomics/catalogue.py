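"""Feature catalogue: the per-region feature dictionary.

The default catalogue totals exactly 656 features per region:

    8 shape (original channel only)
  + 9 channels x (18 first-order + 22 GLCM + 11 GLRLM + 11 GLSZM
                  + 5 NGTDM + 5 NGLDM)
  = 8 + 9 x 72 = 656

where the 9 channels are the unfiltered image plus the 8 sub-bands of a
one-level separable 3D stationary wavelet transform (LLL ... HHH).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple


WAVELET_CHANNELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
CHANNELS = ("original",) + WAVELET_CHANNELS

SHAPE_FEATURES = (
    "volume_mm3", "voxel_count", "surface_area_mm2", "sphericity",
    "compactness", "max_3d_diameter", "elongation", "flatness",
)

FIRSTORDER_FEATURES = (
    "mean", "median", "sd", "variance", "minimum", "maximum", "range",
    "p10", "p90", "iqr", "skewness", "kurtosis", "energy", "rms", "mad",
    "entropy", "uniformity", "robust_mean",
)

GLCM_FEATURES = (
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "joint_energy", "contrast", "dissimilarity", "inverse_difference",
    "inverse_difference_moment", "inverse_variance", "correlation",
    "autocorrelation", "cluster_tendency", "cluster_shade",
    "cluster_prominence", "sum_average", "sum_entropy", "difference_average",
    "difference_variance", "difference_entropy", "imc1", "imc2",
)

GLRLM_FEATURES = (
    "short_run_emphasis", "long_run_emphasis", "grey_level_nonuniformity",
    "run_length_nonuniformity", "run_percentage",
    "low_grey_level_run_emphasis", "high_grey_level_run_emphasis",
    "short_run_low_grey_level_emphasis", "short_run_high_grey_level_emphasis",
    "long_run_low_grey_level_emphasis", "long_run_high_grey_level_emphasis",
)

GLSZM_FEATURES = (
    "small_zone_emphasis", "large_zone_emphasis", "grey_level_nonuniformity",
    "zone_size_nonuniformity", "zone_percentage",
    "low_grey_level_zone_emphasis", "high_grey_level_zone_emphasis",
    "small_zone_low_grey_level_emphasis", "small_zone_high_grey_level_emphasis",
    "large_zone_low_grey_level_emphasis", "large_zone_high_grey_level_emphasis",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

NGLDM_FEATURES = (
    "low_dependence_emphasis", "high_dependence_emphasis",
    "dependence_nonuniformity", "dependence_variance", "dependence_entropy",
)

FAMILY_FEATURES = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "ngldm": NGLDM_FEATURES,
}


class FeatureID(NamedTuple):
    channel: str   # original | LLL..HHH
    family: str    # shape | firstorder | glcm | glrlm | glszm | ngtdm | ngldm
    name: str

    def __str__(self) -> str:
        return f"{self.channel}__{self.family}__{self.name}"


@dataclass(frozen=True)
class DiscretizationSpec:
    """Grey-level discretization rule used by all texture matrices."""

    mode: str = "fixed-bin-count"
    bins: int = 32
    width: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed-bin-count", "fixed-bin-width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed-bin-count" and self.bins < 2:
            raise ValueError("bin count must be >= 2")
        if self.mode == "fixed-bin-width" and (self.width is None or self.width <= 0):
            raise ValueError("bin width must be positive")


@dataclass(frozen=True)
class TextureGeometrySpec:
    """Geometry conventions for the texture matrices.

    GLCM/GLRLM use distance-1 neighbours along the 13 unique 3D directions;
    GLSZM zones and NGTDM/NGLDM neighbourhoods are 26-connected.
    """

    glcm_distance: int = 1
    connectivity: int = 26
    ngldm_alpha: int = 0


@dataclass
class FeatureCatalogue:
    """Ordered list of feature ids plus the discretization/geometry specs."""

    feature_ids: tuple[FeatureID, ...]
    discretization: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    geometry: TextureGeometrySpec = field(default_factory=TextureGeometrySpec)
    wavelet: str = "coif1"

    def __post_init__(self) -> None:
        self.feature_ids = tuple(
            fid if isinstance(fid, FeatureID) else FeatureID(*fid) for fid in self.feature_ids
        )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature ids must be unique")
        for fid in self.feature_ids:
            if fid.family == "shape" and fid.channel != "original":
                raise ValueError("shape features are defined on the original channel only")
            if fid.channel not in CHANNELS:
                raise ValueError(f"unknown channel {fid.channel!r}")
            if fid.family not in FAMILY_FEATURES:
                raise ValueError(f"unknown family {fid.family!r}")

    def __len__(self) -> int:
        return len(self.feature_ids)

    @property
    def channels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for fid in self.feature_ids:
            if fid.channel not in seen:
                seen.append(fid.channel)
        return tuple(seen)

    def families_for(self, channel: str) -> tuple[str, ...]:
        seen: list[str] = []
        for fid in self.feature_ids:
            if fid.channel == channel and fid.family not in seen:
                seen.append(fid.family)
        return tuple(seen)

    def content_hash(self) -> str:
        payload = json.dumps(self._as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def _as_dict(self) -> dict:
        return {
            "feature_ids": [list(fid) for fid in self.feature_ids],
            "discretization": {
                "mode": self.discretization.mode,
                "bins": self.discretization.bins,
                "width": self.discretization.width,
            },
            "geometry": {
                "glcm_distance": self.geometry.glcm_distance,
                "connectivity": self.geometry.connectivity,
                "ngldm_alpha": self.geometry.ngldm_alpha,
            },
            "wavelet": self.wavelet,
        }

    def to_json(self, path: str | Path) -> None:
        d = self._as_dict()
        d["content_hash"] = self.content_hash()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureCatalogue":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_ids=tuple(FeatureID(*fid) for fid in d["feature_ids"]),
            discretization=DiscretizationSpec(**d["discretization"]),
            geometry=TextureGeometrySpec(**d["geometry"]),
            wavelet=d["wavelet"],
        )


def default_catalogue(
    channels: Iterable[str] = CHANNELS,
    discretization: DiscretizationSpec | None = None,
    wavelet: str = "coif1",
) -> FeatureCatalogue:
    """Build the catalogue: shape on the original channel, then the intensity
    and texture families on every requested channel.

    With all 9 channels this totals 8 + 9*72 = 656 features per region.
    """
    channels = tuple(channels)
    ids: list[FeatureID] = []
    if "original" in channels:
        ids.extend(FeatureID("original", "shape", n) for n in SHAPE_FEATURES)
    for ch in channels:
        for family in ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "ngldm"):
            ids.extend(FeatureID(ch, family, n) for n in FAMILY_FEATURES[family])
    return FeatureCatalogue(
        feature_ids=tuple(ids),
        discretization=discretization or DiscretizationSpec(),
        wavelet=wavelet,
    )
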