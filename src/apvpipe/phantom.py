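"""Seeded synthetic multi-region brain phantoms.

Cohorts of labelled 3D volumes whose groups differ in planted, controllable
ways: region volume (atrophy, implemented as inward boundary erosion),
region mean intensity (shift in units of the noise standard deviation), and
texture correlation length (stationary Gaussian random fields obtained by
smoothing white noise; kernel sd = correlation length).  Everything is
bit-reproducible from (spec, seed).

These phantoms are the stand-in for restricted clinical imaging cohorts in
all end-to-end tests; they emulate group differences detectable by shape,
first-order and texture features, not anatomy or MR physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import LabelMap, RegionTable, Volume


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class RegionEffect:
    """Planted group-level signal for one region."""

    volume_scale: float = 1.0        # target fraction of the unscaled volume, (0, 1.5]
    intensity_shift: float = 0.0     # region mean shift in noise-sd units
    texture_corr: float = 0.0        # Gaussian texture correlation length (voxels)

    def __post_init__(self) -> None:
        if not 0.0 < self.volume_scale <= 1.5:
            raise ValueError("volume scale must lie in (0, 1.5]")
        if self.texture_corr < 0:
            raise ValueError("correlation length must be >= 0")


@dataclass
class PhantomSpec:
    """Generator configuration: geometry, groups, and per-group effect maps."""

    shape: tuple[int, int, int] = (64, 64, 64)
    n_regions: int = 8
    groups: tuple[str, ...] = ("CN", "MCI_AD", "AD")
    effects: dict[str, dict[int, RegionEffect]] = dataclass_field(default_factory=dict)
    noise_sd: float = 1.0
    base_intensity: float = 10.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    geometry_seed: int = 0
    subject_jitter: float = 0.5      # sd (voxels) of per-subject seed-point jitter

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if min(self.shape) < 8:
            raise GeometryError("grid too small to pack regions")
        textured = any(
            e.texture_corr > 0 for g in self.effects.values() for e in g.values()
        )
        if textured and min(self.shape) < 32:
            raise GeometryError("texture-bearing phantoms need a grid of at least 32^3")
        for g in self.effects:
            if g not in self.groups:
                raise ValueError(f"effect map references unknown group {g!r}")

    def effect_for(self, group: str, region_id: int) -> RegionEffect:
        return self.effects.get(group, {}).get(region_id, RegionEffect())

    def truth_table(self) -> pd.DataFrame:
        """Signal-bearing (group, region, property) triples."""
        rows = []
        for group, regions in self.effects.items():
            for rid, eff in regions.items():
                if eff.volume_scale != 1.0:
                    rows.append((group, rid, "volume_scale", eff.volume_scale))
                if eff.intensity_shift != 0.0:
                    rows.append((group, rid, "intensity_shift", eff.intensity_shift))
                if eff.texture_corr != 0.0:
                    rows.append((group, rid, "texture_corr", eff.texture_corr))
        return pd.DataFrame(rows, columns=["group", "region_id", "property", "value"])

    def signal_regions(self) -> set[int]:
        tt = self.truth_table()
        return set() if tt.empty else set(tt["region_id"].astype(int))


def _brain_ellipsoid(shape: tuple[int, int, int]) -> np.ndarray:
    centre = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.42
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, centre, semi))
    return r2 <= 1.0


def _seed_points(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Region seed points inside the ellipsoid, from the geometry seed so the
    region vocabulary is shared across the whole cohort."""
    geo = np.random.default_rng(spec.geometry_seed)
    centre = (np.asarray(spec.shape) - 1) / 2.0
    semi = np.asarray(spec.shape) * 0.42
    pts = []
    tries = 0
    while len(pts) < spec.n_regions:
        cand = geo.uniform(0, 1, 3) * (np.asarray(spec.shape) - 1)
        if (((cand - centre) / semi) ** 2).sum() <= 0.7:  # keep seeds interior
            pts.append(cand)
        tries += 1
        if tries > 10000:
            raise GeometryError("could not place region seed points")
    pts = np.asarray(pts)
    if spec.subject_jitter > 0:
        pts = pts + rng.normal(0.0, spec.subject_jitter, pts.shape)
    return pts


def _scale_region(mask: np.ndarray, region: np.ndarray, scale: float) -> np.ndarray:
    """Shrink (erode inward) or grow a region to ~scale x its voxel count."""
    count = int(region.sum())
    target = max(1, int(round(count * scale)))
    if target == count:
        return region
    if target < count:
        coords = np.argwhere(region)
        lo = coords.min(axis=0)
        hi = coords.max(axis=0) + 1
        bbox = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        dist = ndimage.distance_transform_edt(np.pad(region[bbox], 1))[1:-1, 1:-1, 1:-1]
        vals = dist[region[bbox]]
        order = np.argsort(vals, kind="stable")[::-1]  # keep the deepest voxels
        keep = np.zeros(count, dtype=bool)
        keep[order[:target]] = True
        out = np.zeros_like(region)
        out[tuple(coords[keep].T)] = True
        return out
    # growth: annex the nearest background voxels
    background = mask & ~region
    dist = ndimage.distance_transform_edt(~region)
    cand = np.argwhere(background)
    cand_d = dist[background]
    order = np.argsort(cand_d, kind="stable")
    extra = cand[order[: target - count]]
    out = region.copy()
    out[tuple(extra.T)] = True
    return out


def make_labelmap(spec: PhantomSpec, subject_seed: int, group: str | None = None) -> LabelMap:
    """Voronoi parcellation of a central brain ellipsoid into connected
    regions, with per-group atrophy applied as inward boundary erosion
    (removed voxels become background)."""
    rng = np.random.default_rng(subject_seed)
    brain = _brain_ellipsoid(spec.shape)
    pts = _seed_points(spec, rng)
    coords = np.argwhere(brain)
    d2 = ((coords[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1) + 1
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[tuple(coords.T)] = assign
    if group is not None:
        for rid in range(1, spec.n_regions + 1):
            eff = spec.effect_for(group, rid)
            if eff.volume_scale != 1.0:
                region = labels == rid
                scaled = _scale_region(brain, region, eff.volume_scale)
                labels[region & ~scaled] = 0
                labels[scaled & (labels == 0)] = rid
    present = np.unique(labels)
    if len(present[present > 0]) < spec.n_regions:
        raise GeometryError("a region vanished during packing/atrophy")
    return LabelMap(grid=labels, spacing=spec.spacing)


def make_subject(
    spec: PhantomSpec, group: str, subject_seed: int
) -> tuple[Volume, LabelMap]:
    """One synthetic subject: intensities = base level + group shift +
    correlated Gaussian texture + white noise, all in noise-sd units."""
    if group not in spec.groups:
        raise ValueError(f"group {group!r} not in spec groups {spec.groups}")
    lmap = make_labelmap(spec, subject_seed, group)
    rng = np.random.default_rng(np.random.SeedSequence([subject_seed, 1]))
    grid = np.zeros(spec.shape, dtype=np.float64)
    inside = lmap.grid > 0
    grid[inside] = spec.base_intensity

    corr_lengths = sorted(
        {
            spec.effect_for(group, rid).texture_corr
            for rid in range(1, spec.n_regions + 1)
        }
        - {0.0}
    )
    fields = {}
    for cl in corr_lengths:
        f = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=cl)
        fields[cl] = f / f.std()
    for rid in range(1, spec.n_regions + 1):
        eff = spec.effect_for(group, rid)
        region = lmap.grid == rid
        if eff.intensity_shift != 0.0:
            grid[region] += eff.intensity_shift * spec.noise_sd
        if eff.texture_corr > 0.0:
            grid[region] += fields[eff.texture_corr][region] * spec.noise_sd
    grid += rng.normal(0.0, spec.noise_sd, spec.shape)
    return Volume(grid=grid, spacing=spec.spacing), lmap


@dataclass
class CohortSubject:
    subject_id: str
    volume: Volume
    labelmap: LabelMap
    group: str


@dataclass
class SyntheticCohort:
    subjects: list[CohortSubject]
    truth: pd.DataFrame
    spec: PhantomSpec
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)

    def groups(self) -> pd.Series:
        return pd.Series(
            {s.subject_id: s.group for s in self.subjects}, name="group"
        ).rename_axis("subject_id")


def make_cohort(spec: PhantomSpec, n_per_group: int, seed: int) -> SyntheticCohort:
    """Generate n subjects per group with deterministic per-subject seeds."""
    if n_per_group < 1:
        raise ValueError("need at least one subject per group")
    root = np.random.SeedSequence(seed)
    subjects = []
    idx = 0
    for group in spec.groups:
        for i in range(n_per_group):
            child = np.random.SeedSequence([seed, idx])
            subject_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            vol, lmap = make_subject(spec, group, subject_seed)
            subjects.append(
                CohortSubject(
                    subject_id=f"sub-{idx:04d}", volume=vol, labelmap=lmap, group=group
                )
            )
            idx += 1
    return SyntheticCohort(subjects=subjects, truth=spec.truth_table(), spec=spec, seed=seed)


def study_spec(
    shape: tuple[int, int, int] = (64, 64, 64),
    n_regions: int = 8,
    n_signal: int = 3,
    intensity_shift: float = 1.0,
    volume_scale: float = 0.7,
    texture_corr: float = 1.5,
) -> PhantomSpec:
    """The canonical strong-signal study phantom.

    Three groups (CN, MCI_AD, AD); the first ``n_signal`` regions carry the
    disease signal, with AD at full strength (intensity shift 1.0 noise-sd,
    volume scale 0.7, texture correlation length 1.5 voxels by default) and
    MCI_AD at half strength, mimicking a prodromal-to-late severity
    gradient.
    """
    effects = {}
    for group, strength in (("MCI_AD", 0.5), ("AD", 1.0)):
        effects[group] = {
            rid: RegionEffect(
                volume_scale=1.0 - (1.0 - volume_scale) * strength,
                intensity_shift=intensity_shift * strength,
                texture_corr=texture_corr * strength,
            )
            for rid in range(1, n_signal + 1)
        }
    return PhantomSpec(shape=shape, n_regions=n_regions, effects=effects)


def null_spec(
    shape: tuple[int, int, int] = (48, 48, 48), n_regions: int = 8
) -> PhantomSpec:
    """A signal-free phantom: identical group distributions (empty effect
    map), used for chance-level calibration."""
    return PhantomSpec(shape=shape, n_regions=n_regions, effects={})


def phantom_region_table(n_regions: int) -> RegionTable:
    """Region table for phantom label maps: ids 1..n, first 45 ids in the
    WM45 set, the remainder in CTX70."""
    rows = []
    for rid in range(1, n_regions + 1):
        hemisphere = "left" if rid % 2 else "right"
        region_set = "WM45" if rid <= 45 else "CTX70"
        rows.append((rid, f"region-{rid:03d}", hemisphere, region_set))
    return RegionTable(
        pd.DataFrame(rows, columns=["id", "name", "hemisphere", "set"])
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> pd.DataFrame:
    """Write NIfTI pairs plus cohort and truth CSVs; returns the manifest."""
    from pathlib import Path

    from .image_io import write_labelmap, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        vpath = out / f"{s.subject_id}_T1w.nii.gz"
        lpath = out / f"{s.subject_id}_labels.nii.gz"
        write_volume(s.volume, vpath)
        write_labelmap(s.labelmap, lpath)
        rows.append((s.subject_id, str(vpath), str(lpath), s.group))
    manifest = pd.DataFrame(rows, columns=["subject_id", "volume", "labelmap", "group"])
    manifest[["subject_id", "group"]].to_csv(out / "cohort.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    manifest[["subject_id", "volume", "labelmap"]].to_csv(out / "manifest.csv", index=False)
    return manifest
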