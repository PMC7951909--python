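"""Reading and writing the pipeline's standard formats.

Volumes are NIfTI-1 files read through nibabel; scan metadata and ROI
centres travel as UTF-8 CSV with a required header row.  Voxel indices
are 0-based everywhere.  The NIfTI header is authoritative for voxel
geometry: when a manifest disagrees with the header by more than
``VOXEL_TOL_MM`` a warning is emitted and the header wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AgeInterval",
    "AgePoint",
    "ManifestError",
    "RoiCenter",
    "ScanRecord",
    "VolumeError",
    "VoxelGrid",
    "MANIFEST_COLUMNS",
    "ROI_COLUMNS",
    "REGIONS",
    "manifest_to_frame",
    "read_manifest",
    "read_roi_centers",
    "read_volume",
    "write_manifest",
    "write_roi_centers",
    "write_volume",
]

REGIONS = ("CC", "LCN", "RCN")

MANIFEST_COLUMNS = [
    "database",
    "subject",
    "contrast",
    "age",
    "age_min",
    "age_max",
    "voxel_x_mm",
    "voxel_y_mm",
    "voxel_z_mm",
    "scan_time_s",
    "field_strength_t",
]

ROI_COLUMNS = ["database", "subject", "contrast", "region", "i", "j", "k"]

#: header/manifest voxel-size agreement tolerance (mm)
VOXEL_TOL_MM = 1e-4


class VolumeError(ValueError):
    """A NIfTI volume violates the pipeline's contracts."""


class ManifestError(ValueError):
    """A metadata or ROI table violates the pipeline's contracts."""


class AgePoint(NamedTuple):
    """A single known age in years."""

    years: float


class AgeInterval(NamedTuple):
    """An age reported only as a closed interval [min, max] years.

    Some databases report interval ages for privacy; these must be
    resolved to point ages by uniform sampling before any age model.
    """

    min_years: float
    max_years: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min_years + self.max_years)


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D scalar intensity array with voxel dimensions in mm."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"volume must be 3-D, got {data.ndim}-D array")
        if data.size == 0:
            raise VolumeError("volume is empty")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise VolumeError(f"voxel dimensions must be three positive reals, got {self.voxel_mm!r}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_mm", tuple(float(v) for v in self.voxel_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_mm
        return dx * dy * dz


@dataclass(frozen=True)
class RoiCenter:
    """Centre voxel of one measurement structure, 0-based indices."""

    region: str
    index: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ManifestError(f"unknown region label {self.region!r}; expected one of {REGIONS}")
        object.__setattr__(self, "index", tuple(int(i) for i in self.index))


@dataclass(frozen=True)
class ScanRecord:
    """One volume's metadata row."""

    database: str
    subject: str
    contrast: str
    voxel_mm: tuple[float, float, float]
    scan_time_s: float | None = None
    field_strength_t: float | None = None
    age: AgePoint | AgeInterval | None = None
    acquisition: str = "wholebrain"
    path: str | None = None

    def __post_init__(self) -> None:
        if not self.contrast:
            raise ManifestError("contrast label must be nonempty")
        if any(v <= 0 for v in self.voxel_mm):
            raise ManifestError(f"voxel dimensions must be positive, got {self.voxel_mm!r}")
        if isinstance(self.age, AgeInterval) and self.age.min_years > self.age.max_years:
            raise ManifestError(
                f"age interval min {self.age.min_years} > max {self.age.max_years} "
                f"for ({self.database}, {self.subject}, {self.contrast})"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.database, self.subject, self.contrast)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_mm
        return dx * dy * dz


def read_volume(path: str | Path) -> VoxelGrid:
    """Load a NIfTI-1 volume as a :class:`VoxelGrid`.

    Intensities are returned in native units beyond the header's
    scl slope/intercept (applied by nibabel); voxel dimensions come
    from the header pixdims.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeError(f"{path}: expected a 3-D volume, file is {img.ndim}-D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise VolumeError(f"{path}: nonpositive pixdim in header: {zooms}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return VoxelGrid(data=data, voxel_mm=zooms)  # type: ignore[arg-type]


def write_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a :class:`VoxelGrid` as NIfTI-1 with an identity-orientation
    affine scaled by the voxel dimensions."""
    path = Path(path)
    affine = np.diag([*grid.voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float64), affine)
    img.header.set_zooms(grid.voxel_mm)
    path.parent.mkdir(parents=True, exist_ok=True)
    img.to_filename(str(path))
    return path


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _parse_age(age, age_min, age_max, key) -> AgePoint | AgeInterval | None:
    age, age_min, age_max = _opt_float(age), _opt_float(age_min), _opt_float(age_max)
    if age is not None:
        return AgePoint(age)
    if age_min is not None or age_max is not None:
        if age_min is None or age_max is None:
            raise ManifestError(f"{key}: age_min and age_max must both be given")
        if age_min > age_max:
            raise ManifestError(f"{key}: age_min {age_min} > age_max {age_max}")
        return AgeInterval(age_min, age_max)
    return None


def read_manifest(path: str | Path) -> list[ScanRecord]:
    """Parse a scan manifest CSV into :class:`ScanRecord` rows.

    Required columns are ``MANIFEST_COLUMNS``; ``acquisition`` and
    ``path`` are recognised as optional extensions.  Duplicate
    (database, subject, contrast[, acquisition]) keys are rejected.
    """
    df = pd.read_csv(path, dtype={"database": str, "subject": str, "contrast": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    records: list[ScanRecord] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        key = (row["database"], row["subject"], row["contrast"])
        acq = str(row["acquisition"]) if "acquisition" in df.columns and not pd.isna(row.get("acquisition")) else "wholebrain"
        full_key = key + ((acq,) if "acquisition" in df.columns else ())
        if full_key in seen:
            raise ManifestError(f"{path}: duplicate scan key {full_key}")
        seen.add(full_key)
        records.append(
            ScanRecord(
                database=str(row["database"]),
                subject=str(row["subject"]),
                contrast=str(row["contrast"]),
                voxel_mm=(float(row["voxel_x_mm"]), float(row["voxel_y_mm"]), float(row["voxel_z_mm"])),
                scan_time_s=_opt_float(row["scan_time_s"]),
                field_strength_t=_opt_float(row["field_strength_t"]),
                age=_parse_age(row["age"], row["age_min"], row["age_max"], key),
                acquisition=acq,
                path=str(row["path"]) if "path" in df.columns and not pd.isna(row.get("path")) else None,
            )
        )
    return records


def write_manifest(records: Sequence[ScanRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        age = r.age.years if isinstance(r.age, AgePoint) else ""
        amin = r.age.min_years if isinstance(r.age, AgeInterval) else ""
        amax = r.age.max_years if isinstance(r.age, AgeInterval) else ""
        rows.append(
            {
                "database": r.database,
                "subject": r.subject,
                "contrast": r.contrast,
                "age": age,
                "age_min": amin,
                "age_max": amax,
                "voxel_x_mm": r.voxel_mm[0],
                "voxel_y_mm": r.voxel_mm[1],
                "voxel_z_mm": r.voxel_mm[2],
                "scan_time_s": r.scan_time_s if r.scan_time_s is not None else "",
                "field_strength_t": r.field_strength_t if r.field_strength_t is not None else "",
                "acquisition": r.acquisition,
                "path": r.path if r.path is not None else "",
            }
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def manifest_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    """Flatten ScanRecords to a DataFrame for the statistics layer.

    Point ages go to ``age``; interval ages leave ``age`` NaN and fill
    ``age_min``/``age_max`` (resolved later by uniform sampling).
    """
    rows = []
    for r in records:
        rows.append(
            {
                "database": r.database,
                "subject": r.subject,
                "contrast": r.contrast,
                "acquisition": r.acquisition,
                "age": r.age.years if isinstance(r.age, AgePoint) else np.nan,
                "age_min": r.age.min_years if isinstance(r.age, AgeInterval) else np.nan,
                "age_max": r.age.max_years if isinstance(r.age, AgeInterval) else np.nan,
                "voxel_x_mm": r.voxel_mm[0],
                "voxel_y_mm": r.voxel_mm[1],
                "voxel_z_mm": r.voxel_mm[2],
                "voxel_volume_mm3": r.voxel_volume_mm3,
                "scan_time_s": np.nan if r.scan_time_s is None else r.scan_time_s,
                "field_strength_t": np.nan if r.field_strength_t is None else r.field_strength_t,
            }
        )
    return pd.DataFrame(rows)


def read_roi_centers(path: str | Path) -> dict[tuple[str, str, str], dict[str, RoiCenter]]:
    """Parse an ROI-centre CSV into a per-scan mapping region -> centre.

    Every referenced scan carries the regions CC, LCN, RCN or a subset;
    incomplete scans are reported through a warning, unknown region
    labels are errors.
    """
    df = pd.read_csv(path, dtype={"database": str, "subject": str, "contrast": str, "region": str})
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing ROI columns {missing}")
    out: dict[tuple[str, str, str], dict[str, RoiCenter]] = {}
    for _, row in df.iterrows():
        key = (str(row["database"]), str(row["subject"]), str(row["contrast"]))
        region = str(row["region"])
        if region not in REGIONS:
            raise ManifestError(f"{path}: unknown region label {region!r} for scan {key}")
        centers = out.setdefault(key, {})
        if region in centers:
            raise ManifestError(f"{path}: duplicate region {region} for scan {key}")
        centers[region] = RoiCenter(region=region, index=(int(row["i"]), int(row["j"]), int(row["k"])))
    incomplete = {k: sorted(set(REGIONS) - set(v)) for k, v in out.items() if len(v) < len(REGIONS)}
    if incomplete:
        warnings.warn(f"scans with missing ROI regions: {incomplete}", stacklevel=2)
    return out


def write_roi_centers(
    centers: Mapping[tuple[str, str, str], Mapping[str, RoiCenter]], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for (db, subj, contrast), regions in centers.items():
        for region in REGIONS:
            if region in regions:
                c = regions[region]
                rows.append(
                    {"database": db, "subject": subj, "contrast": contrast, "region": region,
                     "i": c.index[0], "j": c.index[1], "k": c.index[2]}
                )
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def check_voxel_agreement(record: ScanRecord, grid: VoxelGrid) -> VoxelGrid:
    """Reconcile manifest and header voxel sizes; the header wins."""
    diffs = [abs(a - b) for a, b in zip(record.voxel_mm, grid.voxel_mm)]
    if max(diffs) > VOXEL_TOL_MM:
        warnings.warn(
            f"voxel size mismatch for {record.key}: manifest {record.voxel_mm} vs "
            f"header {grid.voxel_mm}; using header",
            stacklevel=2,
        )
    return grid
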