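"""Dynamic-CT frame gas volumes and inspiratory/expiratory classification.

A dynamic (1 Hz) acquisition images a fixed thin slab while the lung moves
with ventilation. Each frame's gas volume is the masked slab volume times
the mean gas volume fraction. Per recording, the frames holding the
minimum and maximum gas volumes anchor the tidal range R; frames within a
band (default 30 %) of R from the minimum are expiratory, within the band
of the maximum inspiratory, and mid-cycle frames are excluded. The band is
referenced to the min-to-max range, which makes the rule invariant to
shifting or rescaling all gas volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FrameSeries", "frame_gas_volume", "classify_frames", "DegenerateSeriesError"]

EXPIRATORY = "expiratory"
INSPIRATORY = "inspiratory"
EXCLUDED = "excluded"


class DegenerateSeriesError(ValueError):
    """The series shows no tidal variation (zero gas-volume range)."""


@dataclass
class FrameSeries:
    """An ordered dynamic series of thin-slab gas-fraction maps.

    ``f_gas`` has shape (n_frames, nx, ny, nz) with the slab typically 1-3
    slices thick; all frames share ``mask`` and ``spacing`` (mm).
    ``condition`` carries metadata such as PEEP (cmH2O), tidal volume
    (mL/kg) and an injured flag.
    """

    times_s: np.ndarray
    f_gas: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.f_gas = np.asarray(self.f_gas, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.f_gas.ndim != 4:
            raise ValueError("f_gas must be (n_frames, nx, ny, nz)")
        if len(self.times_s) != self.f_gas.shape[0]:
            raise ValueError("one timestamp per frame required")
        if self.f_gas.shape[0] < 2:
            raise ValueError("a dynamic series needs at least 2 frames")
        if self.mask.shape != self.f_gas.shape[1:]:
            raise ValueError("mask grid does not match frames")

    @property
    def n_frames(self) -> int:
        return self.f_gas.shape[0]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


def frame_gas_volume(f_gas: np.ndarray, mask: np.ndarray, spacing) -> float:
    """Gas volume (mL) of one frame: masked slab volume x mean gas fraction.

    Equivalently the sum of per-voxel gas fraction times voxel volume.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    return float(np.asarray(f_gas, dtype=float)[mask].mean()) * n * voxel_ml


def gas_volumes(series: FrameSeries) -> np.ndarray:
    """Per-frame gas volumes (mL) for a series."""
    return np.array(
        [frame_gas_volume(series.f_gas[i], series.mask, series.spacing) for i in range(series.n_frames)]
    )


def classify_gas_volumes(volumes_ml: np.ndarray, band: float = 0.30) -> list[str]:
    """Apply the tidal band rule to a vector of per-frame gas volumes.

    With g_min, g_max and R = g_max - g_min: a frame is expiratory if its
    gas volume is <= g_min + band*R, inspiratory if >= g_max - band*R, and
    excluded otherwise. band < 0.5 keeps the two sets disjoint.
    """
    g = np.asarray(volumes_ml, dtype=float)
    if g.size < 2:
        raise ValueError("need at least 2 frames")
    if not 0.0 < band < 0.5:
        raise ValueError(f"band must be in (0, 0.5) so phases stay disjoint, got {band}")
    g_min, g_max = float(g.min()), float(g.max())
    r = g_max - g_min
    if r == 0.0:
        raise DegenerateSeriesError("no tidal variation: all frames share one gas volume")
    labels = []
    for v in g:
        if v <= g_min + band * r:
            labels.append(EXPIRATORY)
        elif v >= g_max - band * r:
            labels.append(INSPIRATORY)
        else:
            labels.append(EXCLUDED)
    return labels


def classify_frames(series: FrameSeries, band: float = 0.30) -> pd.DataFrame:
    """Classify every frame of a dynamic series as expiratory/inspiratory/excluded.

    Returns a DataFrame with columns ``time_s``, ``gas_volume_ml`` and
    ``label``, one row per frame in acquisition order.
    """
    g = gas_volumes(series)
    labels = classify_gas_volumes(g, band=band)
    return pd.DataFrame({"time_s": series.times_s, "gas_volume_ml": g, "label": labels})
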