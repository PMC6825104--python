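"""Regional analysis of inspiration-related cranio-caudal lung displacement.

A deformable registration of the end-expiratory onto the end-inspiratory
volume yields a dense displacement field (mm per voxel, expiration ->
inspiration). This module consumes such a field: it extracts the
cranio-caudal component over a selected 5-mm slice, averages it within 12
equal-height regions along the gravitational (anterior -> posterior) axis,
and bins slice voxels by how far they move caudally — less than one slice
thickness (< 5 mm), one to two slices (5-10 mm) or more than two
(10-15 mm). Registration itself is out of scope.

Sign convention: positive cranio-caudal component = caudal movement
(toward the diaphragm, increasing index on axis 2). Voxels moving
cranially (negative) are counted in the "< 5 mm" bin; voxels beyond 15 mm
are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DisplacementField",
    "cc_displacement_slice",
    "regional_means",
    "movement_fractions",
    "summarize_by_condition",
]

GRAV_AXIS = 1  # anterior -> posterior
CC_AXIS = 2  # cranial -> caudal
CC_COMPONENT = 2  # index of the cranio-caudal component in the vector


@dataclass
class DisplacementField:
    """Per-voxel displacement 3-vectors (mm), expiration -> inspiration.

    ``vectors`` has shape (nx, ny, nz, 3); component order follows the
    image axes (left-right, anterior-posterior, cranio-caudal).
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement vectors must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)


def cc_displacement_slice(field: DisplacementField, slice_mask: np.ndarray) -> np.ndarray:
    """Cranio-caudal displacement (mm) of masked voxels, NaN elsewhere."""
    slice_mask = np.asarray(slice_mask, dtype=bool)
    if slice_mask.shape != field.vectors.shape[:3]:
        raise ValueError("slice mask grid does not match the field")
    if not slice_mask.any():
        raise ValueError("empty slice mask")
    cc = np.full(slice_mask.shape, np.nan)
    cc[slice_mask] = field.vectors[..., CC_COMPONENT][slice_mask]
    return cc


def region_band_index(mask: np.ndarray, n_regions: int = 12) -> np.ndarray:
    """Assign each masked voxel to an equal-height gravitational band.

    The mask's bounding extent along the anterior -> posterior axis is
    divided into ``n_regions`` bands of equal height (region 0 most
    anterior). Returns an integer map with -1 outside the mask.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    idx = np.where(mask.any(axis=tuple(ax for ax in range(3) if ax != GRAV_AXIS)))[0]
    lo, hi = idx.min(), idx.max() + 1
    edges = np.linspace(lo, hi, n_regions + 1)
    coords = np.arange(mask.shape[GRAV_AXIS])
    band_of_coord = np.clip(np.searchsorted(edges, coords + 0.5, side="right") - 1, 0, n_regions - 1)
    shape = [1, 1, 1]
    shape[GRAV_AXIS] = -1
    bands = np.broadcast_to(band_of_coord.reshape(shape), mask.shape).copy()
    bands[~mask] = -1
    return bands


def regional_means(cc_map: np.ndarray, mask: np.ndarray, n_regions: int = 12) -> np.ndarray:
    """Mean cranio-caudal displacement (mm) per gravitational region.

    Regions are ordered anterior -> posterior and partition the mask;
    bands containing no masked voxel are reported as NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    bands = region_band_index(mask, n_regions)
    cc = np.asarray(cc_map, dtype=float)
    means = np.full(n_regions, np.nan)
    for k in range(n_regions):
        sel = bands == k
        if sel.any():
            means[k] = cc[sel].mean()
    return means


def movement_fractions(
    cc_map: np.ndarray,
    mask: np.ndarray,
    thresholds: tuple[float, float, float] = (5.0, 10.0, 15.0),
) -> dict:
    """Fractions of slice voxels by caudal displacement magnitude.

    Bins: below ``thresholds[0]`` (including all cranial movement),
    [t0, t1), [t1, t2]; voxels beyond t2 are counted separately under
    ``fraction_beyond``. The three fractions sum to 1 when nothing exceeds
    the top threshold.
    """
    t0, t1, t2 = (float(t) for t in thresholds)
    if not t0 < t1 < t2:
        raise ValueError("thresholds must be strictly increasing")
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    d = np.asarray(cc_map, dtype=float)[mask]
    return {
        "fraction_lt_one_slice": float((d < t0).sum()) / n,
        "fraction_one_to_two": float(((d >= t0) & (d < t1)).sum()) / n,
        "fraction_two_to_three": float(((d >= t1) & (d <= t2)).sum()) / n,
        "fraction_beyond": float((d > t2).sum()) / n,
    }


def summarize_by_condition(
    table: pd.DataFrame,
    value_cols: list[str],
    group_cols: list[str] = ("peep_cmh2o", "injured"),
) -> pd.DataFrame:
    """Median and IQR of regional/movement summaries per condition group.

    Quantiles use linear interpolation between order statistics. Returns a
    wide table with ``<col>_median`` and ``<col>_iqr`` per value column.
    """
    group_cols = [c for c in group_cols if c in table.columns]
    if not group_cols:
        raise ValueError("no grouping columns present")

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for c in value_cols:
            q1, q2, q3 = g[c].quantile([0.25, 0.5, 0.75], interpolation="linear")
            out[f"{c}_median"] = q2
            out[f"{c}_iqr"] = q3 - q1
        return pd.Series(out)

    grouped = table.groupby(group_cols, sort=True)
    return grouped.apply(_agg, include_groups=False)
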