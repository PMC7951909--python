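"""ROI-cube quality metrics: SNR, pooled bilateral-CN SNR, CNR.

The measurement protocol samples a 3x3x3 cube of voxels around a
manually located centre voxel in the corpus callosum (CC, white
matter) and each caudate nucleus (LCN/RCN, grey matter):

* regional SNR = cube mean / cube SD,
* bilateral CN SNR pools the two 27-voxel cubes into one 54-voxel
  sample (mean of the 54 values over their SD; a literal sum of the
  signal is available behind ``pooling="sum"``),
* CNR = (mu_CC - mu_CN) / sqrt(sigma_CC**2 + sigma_CN**2), sign
  preserved (white minus grey),
* normalized ratios divide the raw value by the voxel volume in mm^3;
  quantitative contrasts (qT1, qT2*) are reported raw.

A volume-matched variant scales the cube side by the ratio of a
reference (largest) voxel size to the image's own, so all images are
measured over approximately the same physical extent.

SDs use the n-1 (sample) denominator throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mriq.io import REGIONS, RoiCenter, ScanRecord, VoxelGrid

__all__ = [
    "CUBE_SIDE",
    "DegenerateRoiError",
    "MetricRecord",
    "QUANTITATIVE_CONTRASTS",
    "RoiSample",
    "cnr",
    "extract_cube",
    "extract_cube_volume_matched",
    "measure_cohort",
    "measure_scan",
    "normalize_ratio",
    "snr_cn_pooled",
    "snr_region",
]

#: side length, in voxels, of the contiguous sampling cube
CUBE_SIDE = 3

#: contrasts whose voxel values are physical quantities (relaxometry
#: maps); their ratios are reported raw, never voxel-normalized
QUANTITATIVE_CONTRASTS = frozenset({"qT1", "qT2*"})


class DegenerateRoiError(ValueError):
    """An ROI sample has zero variance (noiseless or clipped data)."""


@dataclass(frozen=True)
class RoiSample:
    """Extracted voxel intensities for one structure in one volume."""

    region: str
    values: np.ndarray
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64).ravel()
        if values.size < 2:
            raise ValueError(f"RoiSample needs at least 2 voxels, got {values.size}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mu", float(values.mean()))
        object.__setattr__(self, "sigma", float(values.std(ddof=1)))

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class MetricRecord:
    """One (scan, region, method) quality measurement row."""

    database: str
    subject: str
    contrast: str
    acquisition: str
    region: str
    method: str
    n_voxels: int
    mu: float
    sigma: float
    snr_raw: float
    snr_normalized: float
    cnr_raw: float = math.nan
    cnr_normalized: float = math.nan


def _cube_slices(
    center: tuple[int, int, int], sides: tuple[int, int, int], shape: tuple[int, ...]
) -> tuple[slice, slice, slice]:
    slices = []
    for axis, (c, side, dim) in enumerate(zip(center, sides, shape)):
        half = side // 2
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > dim:
            raise ValueError(
                f"cube of side {side} at index {center} exceeds grid bounds on axis "
                f"{axis} (grid shape {shape}); centres must keep a full cube inside the volume"
            )
        slices.append(slice(lo, hi))
    return tuple(slices)  # type: ignore[return-value]


def extract_cube(grid: VoxelGrid, center: RoiCenter) -> RoiSample:
    """Extract the 3x3x3 (27-voxel) neighbourhood around a centre voxel.

    The centre must sit at least one voxel from every boundary; partial
    cubes are never returned.
    """
    slices = _cube_slices(center.index, (CUBE_SIDE,) * 3, grid.shape)
    return RoiSample(region=center.region, values=grid.data[slices])


def _matched_side(reference_mm: float, grid_mm: float) -> int:
    # nearest integer (half away from zero), then force odd upward so a
    # centre voxel exists
    side = int(math.floor(CUBE_SIDE * reference_mm / grid_mm + 0.5))
    if side % 2 == 0:
        side += 1
    return max(side, 1)


def extract_cube_volume_matched(
    grid: VoxelGrid, center: RoiCenter, reference_voxel_mm: Sequence[float]
) -> RoiSample:
    """Extract a cube matched to the physical extent of a reference voxel size.

    The side length per axis is ``round(3 * reference_dim / grid_dim)``
    voxels, forced up to the next odd integer, so every image samples
    approximately the same volume of tissue as the coarsest image's
    3x3x3 cube.  When the grid's voxel size equals the reference this
    reduces exactly to :func:`extract_cube`.
    """
    if len(reference_voxel_mm) != 3:
        raise ValueError("reference_voxel_mm must be a triple")
    for ref, own in zip(reference_voxel_mm, grid.voxel_mm):
        if ref < own - 1e-9:
            raise ValueError(
                f"reference voxel size {tuple(reference_voxel_mm)} must be >= the "
                f"grid's voxel size {grid.voxel_mm} on every axis"
            )
    sides = tuple(_matched_side(ref, own) for ref, own in zip(reference_voxel_mm, grid.voxel_mm))
    slices = _cube_slices(center.index, sides, grid.shape)
    return RoiSample(region=center.region, values=grid.data[slices])


def snr_region(sample: RoiSample) -> float:
    """SNR of one structure: cube mean over cube SD."""
    if sample.sigma <= 0:
        raise DegenerateRoiError(
            f"{sample.region}: zero intensity SD over {sample.n} voxels "
            "(noiseless or clipped ROI); SNR is undefined"
        )
    return sample.mu / sample.sigma


def snr_cn_pooled(
    left: RoiSample, right: RoiSample, pooling: str = "mean"
) -> tuple[RoiSample, float]:
    """Pool the two caudate cubes into one bilateral sample and its SNR.

    The pooled sample concatenates the voxel values of both sides
    (27 + 27 = 54 for the contiguous method).  The SNR divides the mean
    of the pooled values by their SD; ``pooling="sum"`` divides the
    literal summed signal instead, which scales the ratio by the pooled
    count.  Either way the result differs from the mean of the two
    per-side SNRs, because between-side spread inflates the pooled SD.
    """
    if left.n != right.n:
        raise ValueError(f"left and right samples must match in size, got {left.n} vs {right.n}")
    if pooling not in ("mean", "sum"):
        raise ValueError(f"pooling must be 'mean' or 'sum', got {pooling!r}")
    pooled = RoiSample(region="CN_pooled", values=np.concatenate([left.values, right.values]))
    if pooled.sigma <= 0:
        raise DegenerateRoiError("pooled CN sample has zero SD; SNR is undefined")
    numerator = pooled.values.sum() if pooling == "sum" else pooled.mu
    return pooled, float(numerator / pooled.sigma)


def cnr(cc: RoiSample, cn_pooled: RoiSample) -> float:
    """Contrast-to-noise ratio between white matter and pooled grey matter.

    CNR = (mu_CC - mu_CN) / sqrt(sigma_CC**2 + sigma_CN**2); the sign is
    preserved (white minus grey), so swapping the roles negates it.
    """
    denom = math.hypot(cc.sigma, cn_pooled.sigma)
    if denom <= 0:
        raise DegenerateRoiError("both ROI SDs are zero; CNR is undefined")
    return (cc.mu - cn_pooled.mu) / denom


def normalize_ratio(value: float, voxel_mm: Sequence[float]) -> float:
    """Divide a ratio by the voxel volume (product of the three dims, mm^3)."""
    if len(voxel_mm) != 3 or any(v <= 0 for v in voxel_mm):
        raise ValueError(f"voxel dimensions must be three positive reals, got {tuple(voxel_mm)}")
    dx, dy, dz = voxel_mm
    return value / (dx * dy * dz)


def measure_scan(
    grid: VoxelGrid,
    centers: Mapping[str, RoiCenter],
    record: ScanRecord,
    method: str = "contiguous",
    reference_voxel_mm: Sequence[float] | None = None,
    pooling: str = "mean",
    normalize_quantitative: bool = False,
) -> list[MetricRecord]:
    """Measure one volume: per-region SNR, pooled-CN SNR, and CNR.

    Returns tidy rows for CC, LCN, RCN and CN_pooled; the CNR (CC vs
    pooled CN) is carried on the CN_pooled row.  Quantitative contrasts
    keep raw values in the normalized fields unless
    ``normalize_quantitative`` is set.
    """
    if method == "contiguous":
        extract = lambda c: extract_cube(grid, c)  # noqa: E731
    elif method == "volume_matched":
        if reference_voxel_mm is None:
            raise ValueError("volume_matched method requires reference_voxel_mm")
        extract = lambda c: extract_cube_volume_matched(grid, c, reference_voxel_mm)  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}; expected 'contiguous' or 'volume_matched'")

    missing = [r for r in REGIONS if r not in centers]
    if missing:
        raise ValueError(f"scan {record.key}: missing ROI centres for {missing}")

    samples = {r: extract(centers[r]) for r in REGIONS}
    pooled, pooled_snr = snr_cn_pooled(samples["LCN"], samples["RCN"], pooling=pooling)
    cnr_value = cnr(samples["CC"], pooled)

    do_normalize = normalize_quantitative or record.contrast not in QUANTITATIVE_CONTRASTS
    norm = (lambda v: normalize_ratio(v, grid.voxel_mm)) if do_normalize else (lambda v: v)

    rows: list[MetricRecord] = []
    for region in REGIONS:
        s = samples[region]
        snr = snr_region(s)
        rows.append(
            MetricRecord(
                database=record.database, subject=record.subject, contrast=record.contrast,
                acquisition=record.acquisition, region=region, method=method,
                n_voxels=s.n, mu=s.mu, sigma=s.sigma,
                snr_raw=snr, snr_normalized=norm(snr),
            )
        )
    rows.append(
        MetricRecord(
            database=record.database, subject=record.subject, contrast=record.contrast,
            acquisition=record.acquisition, region="CN_pooled", method=method,
            n_voxels=pooled.n, mu=pooled.mu, sigma=pooled.sigma,
            snr_raw=pooled_snr, snr_normalized=norm(pooled_snr),
            cnr_raw=cnr_value, cnr_normalized=norm(cnr_value),
        )
    )
    return rows


def measure_cohort(
    scans: Iterable[tuple[ScanRecord, VoxelGrid, Mapping[str, RoiCenter]]],
    method: str = "contiguous",
    reference_voxel_mm: Sequence[float] | None = None,
    pooling: str = "mean",
    normalize_quantitative: bool = False,
) -> pd.DataFrame:
    """Measure a cohort of (record, grid, centres) into one tidy table."""
    rows: list[MetricRecord] = []
    for record, grid, centers in scans:
        rows.extend(
            measure_scan(
                grid, centers, record, method=method,
                reference_voxel_mm=reference_voxel_mm, pooling=pooling,
                normalize_quantitative=normalize_quantitative,
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
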