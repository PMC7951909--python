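"""Synthetic phantom cohorts with the statistical structure of a
multi-database MRI quality study.

Each phantom volume is a uniform background with three disjoint
axis-aligned cuboid structures: a white-matter-like corpus callosum
(CC) block flanked by two symmetric grey-matter-like caudate blocks
(LCN, RCN).  Structure means carry a per-database random intercept and
a linear age trend; i.i.d. Gaussian noise (whose SD may itself drift
linearly with age) is added everywhere.  Cuboids rather than
anatomical shapes are deliberate: the measurement protocol only ever
touches a small cube well inside each structure, so shape realism adds
nothing testable.

Databases differ in voxel size (0.25-1.2 mm span), scan time, field
strength and random intercept — enough structure to exercise voxel
normalization, scan-time regressions and random-intercept mixed models
downstream.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from mriq.io import (
    REGIONS,
    AgeInterval,
    AgePoint,
    RoiCenter,
    ScanRecord,
    VoxelGrid,
    write_manifest,
    write_roi_centers,
    write_volume,
)

__all__ = [
    "Cohort",
    "DegenerateConfigError",
    "GroundTruth",
    "PhantomConfig",
    "database_intercepts",
    "generate_cohort",
    "generate_volume",
    "iter_cohort",
    "simulate_lmm_table",
    "structure_centers",
]


class DegenerateConfigError(ValueError):
    """A phantom configuration cannot produce valid volumes."""


def _as_structure_map(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [r for r in REGIONS if r not in value]
        if missing:
            raise DegenerateConfigError(f"{name} missing structures {missing}")
        return {r: float(value[r]) for r in REGIONS}
    return {r: float(value) for r in REGIONS}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a phantom cohort.

    Defaults emulate the sampled-cohort design of large database
    comparisons: 20 databases of 5 subjects each, isotropic voxel
    sizes spanning 0.25-1.2 mm, adult ages 18-86, white matter around
    intensity 100 against grey matter at 80 over a background of 20,
    noise SD 5 at the reference age (the midpoint of the age range),
    a mild age-related signal decline, and between-database intercept
    spread of SD 5.
    """

    n_databases: int = 20
    subjects_per_database: int = 5
    grid_shape: tuple[int, int, int] = (36, 16, 16)
    structure_size: int = 9
    voxel_sizes_mm: tuple[tuple[float, float, float], ...] | None = None
    background_mean: float = 20.0
    structure_means: Mapping[str, float] = field(
        default_factory=lambda: {"CC": 100.0, "LCN": 80.0, "RCN": 80.0}
    )
    noise_sd: float = 5.0
    age_range_years: tuple[float, float] = (18.0, 86.0)
    age_slope_mean: Mapping[str, float] | float = field(
        default_factory=lambda: {"CC": -0.1, "LCN": -0.3, "RCN": -0.3}
    )
    age_slope_noise: float = 0.02
    database_intercept_sd: float = 5.0
    contrasts: tuple[str, ...] = ("T1w",)
    scan_times_s: tuple[float, ...] | None = None
    field_strengths_t: tuple[float, ...] | None = None
    database_sizes: tuple[int, ...] | None = None
    interval_databases: tuple[int, ...] = ()
    age_interval_width_years: float = 5.0
    slab_databases: tuple[int, ...] = ()
    slab_voxel_scale: float = 0.5
    allow_zero_contrast: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_databases < 1 or self.subjects_per_database < 1:
            raise DegenerateConfigError("need at least one database and one subject")
        if any(g < 9 for g in self.grid_shape):
            raise DegenerateConfigError(
                f"grid_shape {self.grid_shape} too small; every axis must be >= 9 "
                "to leave room for a 3x3x3 cube away from the boundaries"
            )
        if self.structure_size < 5 or self.structure_size % 2 == 0:
            raise DegenerateConfigError("structure_size must be an odd integer >= 5")
        object.__setattr__(self, "structure_means", _as_structure_map(self.structure_means, "structure_means"))
        object.__setattr__(self, "age_slope_mean", _as_structure_map(self.age_slope_mean, "age_slope_mean"))
        if self.noise_sd < 0:
            raise DegenerateConfigError("noise_sd must be >= 0")
        lo, hi = self.age_range_years
        if lo > hi:
            raise DegenerateConfigError(f"age range [{lo}, {hi}] is empty")
        # noise SD must stay positive over every attainable age; an exactly
        # zero SD is only legal for the explicitly noiseless phantom
        half_span = 0.5 * (hi - lo)
        min_sd = self.noise_sd - abs(self.age_slope_noise) * half_span
        if self.age_slope_noise != 0 and min_sd <= 0:
            raise DegenerateConfigError(
                f"age_slope_noise {self.age_slope_noise}/yr drives the noise SD to "
                f"{min_sd:.3g} <= 0 at an attainable age; reduce the slope or raise noise_sd"
            )
        if (
            self.structure_means["CC"] == self.structure_means["LCN"]
            and not self.allow_zero_contrast
        ):
            raise DegenerateConfigError(
                "zero white/grey contrast (structure_means CC == LCN); pass "
                "allow_zero_contrast=True if a zero-contrast phantom is intended"
            )
        for name in ("voxel_sizes_mm", "scan_times_s", "field_strengths_t", "database_sizes"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_databases:
                raise DegenerateConfigError(f"{name} must have one entry per database")
        if self.voxel_sizes_mm is not None and any(
            d <= 0 for triple in self.voxel_sizes_mm for d in triple
        ):
            raise DegenerateConfigError("all voxel dimensions must be > 0")
        structure_centers(self)  # raises if the three blocks do not fit

    @property
    def reference_age(self) -> float:
        lo, hi = self.age_range_years
        return 0.5 * (lo + hi)

    def voxel_size(self, database_index: int) -> tuple[float, float, float]:
        if self.voxel_sizes_mm is not None:
            return tuple(float(v) for v in self.voxel_sizes_mm[database_index])
        if self.n_databases == 1:
            iso = 1.0
        else:
            iso = 0.25 + (1.2 - 0.25) * database_index / (self.n_databases - 1)
        return (iso, iso, iso)

    def scan_time(self, database_index: int) -> float:
        if self.scan_times_s is not None:
            return float(self.scan_times_s[database_index])
        # finer voxels cost scan time: ~7 min at 1.2 mm up to ~38 min at 0.25 mm
        iso = self.voxel_size(database_index)[0]
        return 300.0 + 2000.0 * (1.35 - iso)

    def field_strength(self, database_index: int) -> float:
        if self.field_strengths_t is not None:
            return float(self.field_strengths_t[database_index])
        return 7.0 if self.voxel_size(database_index)[0] < 0.7 else 3.0

    def database_size(self, database_index: int) -> int:
        if self.database_sizes is not None:
            return int(self.database_sizes[database_index])
        return 100

    def database_label(self, database_index: int) -> str:
        return f"db{database_index:02d}"

    def noise_sd_at(self, age: float) -> float:
        return self.noise_sd + self.age_slope_noise * (age - self.reference_age)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("grid_shape", "age_range_years", "contrasts", "interval_databases",
                    "slab_databases", "scan_times_s", "field_strengths_t", "database_sizes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("voxel_sizes_mm") is not None:
            raw["voxel_sizes_mm"] = tuple(tuple(v) for v in raw["voxel_sizes_mm"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        raw = {
            k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
            for k, v in vars(self).items()
        }
        if raw.get("voxel_sizes_mm") is not None:
            raw["voxel_sizes_mm"] = [list(t) for t in self.voxel_sizes_mm]  # type: ignore[union-attr]
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(raw, sort_keys=True), encoding="utf-8")
        return path


@dataclass(frozen=True)
class GroundTruth:
    """The sampled generating values behind one phantom volume."""

    database: str
    subject: str
    contrast: str
    acquisition: str
    age: float
    true_means: Mapping[str, float]
    true_noise_sd: float
    centers: Mapping[str, RoiCenter]
    database_intercept: float


def structure_centers(config: PhantomConfig) -> dict[str, RoiCenter]:
    """Deterministic placement of the three blocks along the first axis.

    Order is LCN | CC | RCN with the nuclei flanking the white-matter
    block; every block keeps at least a one-voxel margin from the grid
    boundary and from its neighbours.
    """
    nx, ny, nz = config.grid_shape
    s = config.structure_size
    half = s // 2
    cy, cz = ny // 2, nz // 2
    centers_x = (nx // 6, nx // 2, nx - 1 - nx // 6)
    order = ("LCN", "CC", "RCN")
    spans = [(cx - half, cx + half) for cx in centers_x]
    if spans[0][0] < 1 or spans[-1][1] > nx - 2 or cy - half < 1 or cy + half > ny - 2 or cz - half < 1 or cz + half > nz - 2:
        raise DegenerateConfigError(
            f"structures of size {s} do not fit grid {config.grid_shape} with a one-voxel margin"
        )
    for (_, hi), (lo, _) in zip(spans, spans[1:]):
        if hi >= lo:
            raise DegenerateConfigError(
                f"structures of size {s} overlap along axis 0 of grid {config.grid_shape}"
            )
    return {
        region: RoiCenter(region=region, index=(cx, cy, cz))
        for region, cx in zip(order, centers_x)
    }


def database_intercepts(config: PhantomConfig) -> np.ndarray:
    """Per-database random intercepts, fixed by the config seed."""
    rng = np.random.default_rng([config.seed, 7919])
    return rng.normal(0.0, config.database_intercept_sd, config.n_databases)


def generate_volume(
    config: PhantomConfig,
    database_index: int,
    age: float,
    rng: np.random.Generator,
    voxel_mm: tuple[float, float, float] | None = None,
    noise_scale: float = 1.0,
) -> tuple[VoxelGrid, GroundTruth]:
    """Generate one phantom volume and the ground truth behind it.

    The grid equals ``background_mean`` everywhere except the three
    structure blocks, whose means carry the database intercept and the
    linear age trend; i.i.d. Gaussian noise with the age-dependent SD
    is then added to every voxel.
    """
    if not 0 <= database_index < config.n_databases:
        raise ValueError(f"database_index {database_index} out of range [0, {config.n_databases})")
    lo, hi = config.age_range_years
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside the configured range [{lo}, {hi}]")
    sd = config.noise_sd_at(age) * noise_scale
    if sd < 0 or (sd == 0 and (config.noise_sd > 0 or config.age_slope_noise != 0)):
        raise DegenerateConfigError(f"noise SD {sd:.3g} <= 0 at age {age}")

    intercept = float(database_intercepts(config)[database_index])
    centers = structure_centers(config)
    half = config.structure_size // 2
    delta = age - config.reference_age

    data = np.full(config.grid_shape, config.background_mean, dtype=np.float64)
    true_means: dict[str, float] = {}
    for region, center in centers.items():
        mean = (
            config.structure_means[region]
            + intercept
            + config.age_slope_mean[region] * delta
        )
        true_means[region] = mean
        i, j, k = center.index
        data[i - half : i + half + 1, j - half : j + half + 1, k - half : k + half + 1] = mean
    if sd > 0:
        data += rng.normal(0.0, sd, size=config.grid_shape)

    grid = VoxelGrid(data=data, voxel_mm=voxel_mm or config.voxel_size(database_index))
    truth = GroundTruth(
        database=config.database_label(database_index),
        subject="", contrast="", acquisition="wholebrain",
        age=float(age), true_means=true_means, true_noise_sd=float(sd),
        centers=centers, database_intercept=intercept,
    )
    return grid, truth


def _subject_age(config: PhantomConfig, database_index: int, subject_index: int) -> float:
    rng = np.random.default_rng([config.seed, 101, database_index, subject_index])
    lo, hi = config.age_range_years
    return float(rng.uniform(lo, hi))


def _recorded_age(config: PhantomConfig, database_index: int, age: float):
    if database_index not in config.interval_databases:
        return AgePoint(age)
    w = config.age_interval_width_years
    lo, hi = config.age_range_years
    return AgeInterval(max(lo, age - 0.5 * w), min(hi, age + 0.5 * w))


def iter_cohort(
    config: PhantomConfig,
    subject_offset: int = 0,
    subjects_per_database: int | None = None,
    databases: Sequence[int] | None = None,
) -> Iterator[tuple[ScanRecord, VoxelGrid, GroundTruth]]:
    """Yield (record, volume, truth) for every scan of a cohort.

    ``subject_offset`` selects a disjoint block of the per-database
    subject pool, which is how reliability re-samples draw subjects
    never seen by the first sample; ``databases`` restricts generation
    to a subset of database indices.  Ages are uniform over the
    configured range; a subject keeps one age across contrasts.
    """
    n_subj = subjects_per_database if subjects_per_database is not None else config.subjects_per_database
    for d in (range(config.n_databases) if databases is None else databases):
        slab = d in config.slab_databases
        for s_local in range(n_subj):
            s = s_local + subject_offset
            if s >= config.database_size(d):
                raise DegenerateConfigError(
                    f"database {config.database_label(d)}: subject index {s} exceeds "
                    f"its pool of {config.database_size(d)}"
                )
            age = _subject_age(config, d, s)
            for ci, contrast in enumerate(config.contrasts):
                acquisitions = ("wholebrain", "slab") if slab else ("wholebrain",)
                for ai, acq in enumerate(acquisitions):
                    rng = np.random.default_rng([config.seed, 202, d, s, ci, ai])
                    voxel = config.voxel_size(d)
                    if acq == "slab":
                        voxel = tuple(v * config.slab_voxel_scale for v in voxel)
                    grid, truth = generate_volume(config, d, age, rng, voxel_mm=voxel)
                    record = ScanRecord(
                        database=config.database_label(d),
                        subject=f"sub{s:03d}",
                        contrast=contrast,
                        voxel_mm=voxel,
                        scan_time_s=config.scan_time(d),
                        field_strength_t=config.field_strength(d),
                        age=_recorded_age(config, d, age),
                        acquisition=acq,
                    )
                    truth = replace(truth, subject=record.subject, contrast=contrast, acquisition=acq)
                    yield record, grid, truth


@dataclass
class Cohort:
    """A generated cohort: metadata, volumes and ground truth."""

    config: PhantomConfig
    records: list[ScanRecord]
    grids: dict[tuple[str, str, str, str], VoxelGrid]
    centers: dict[tuple[str, str, str], dict[str, RoiCenter]]
    truths: list[GroundTruth]

    def scans(self) -> Iterator[tuple[ScanRecord, VoxelGrid, Mapping[str, RoiCenter]]]:
        for r in self.records:
            yield r, self.grids[(r.database, r.subject, r.contrast, r.acquisition)], self.centers[r.key]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            row = {
                "database": t.database, "subject": t.subject, "contrast": t.contrast,
                "acquisition": t.acquisition, "age": t.age,
                "true_noise_sd": t.true_noise_sd, "database_intercept": t.database_intercept,
            }
            for region in REGIONS:
                row[f"true_mean_{region}"] = t.true_means[region]
            rows.append(row)
        return pd.DataFrame(rows)


def generate_cohort(
    config: PhantomConfig,
    out_dir: str | Path | None = None,
    subject_offset: int = 0,
    subjects_per_database: int | None = None,
) -> Cohort:
    """Generate a full cohort; optionally write volumes + CSVs to disk.

    On disk the cohort is NIfTI-1 (.nii.gz) volumes plus ``manifest.csv``,
    ``roi_centers.csv`` and ``ground_truth.csv``.
    """
    records: list[ScanRecord] = []
    grids: dict[tuple[str, str, str, str], VoxelGrid] = {}
    centers: dict[tuple[str, str, str], dict[str, RoiCenter]] = {}
    truths: list[GroundTruth] = []
    seen: set[tuple[str, str, str, str]] = set()
    out_path = Path(out_dir) if out_dir is not None else None
    for record, grid, truth in iter_cohort(config, subject_offset, subjects_per_database):
        full_key = (record.database, record.subject, record.contrast, record.acquisition)
        if full_key in seen:
            raise DegenerateConfigError(f"duplicate scan key {full_key}")
        seen.add(full_key)
        if out_path is not None:
            fname = f"{record.database}_{record.subject}_{record.contrast}_{record.acquisition}.nii.gz"
            vol_path = out_path / "volumes" / fname
            write_volume(grid, vol_path)
            record = replace(record, path=str(vol_path))
        records.append(record)
        grids[full_key] = grid
        centers[record.key] = dict(truth.centers)
        truths.append(truth)
    cohort = Cohort(config=config, records=records, grids=grids, centers=centers, truths=truths)
    if out_path is not None:
        write_manifest(records, out_path / "manifest.csv")
        write_roi_centers(centers, out_path / "roi_centers.csv")
        cohort.truth_frame().to_csv(out_path / "ground_truth.csv", index=False)
    return cohort


def simulate_lmm_table(
    n_databases: int,
    subjects_per_database: int,
    intercept_sd: float,
    resid_sd: float,
    age_slope: float,
    age_range: tuple[float, float] = (18.0, 86.0),
    baseline: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a response table directly from the random-intercept model.

    y = baseline + b_database + age_slope * (age - midpoint) + eps,
    b ~ N(0, intercept_sd^2), eps ~ N(0, resid_sd^2), ages uniform.
    Used for statistical calibration experiments where synthesising
    voxel data would only add runtime around the same generating model.
    """
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    mid = 0.5 * (lo + hi)
    db = np.repeat(np.arange(n_databases), subjects_per_database)
    ages = rng.uniform(lo, hi, db.size)
    intercepts = rng.normal(0.0, intercept_sd, n_databases)
    y = baseline + intercepts[db] + age_slope * (ages - mid) + rng.normal(0.0, resid_sd, db.size)
    return pd.DataFrame(
        {"database": [f"db{d:02d}" for d in db], "age": ages, "response": y}
    )
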