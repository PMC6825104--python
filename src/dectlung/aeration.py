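"""Aeration compartmentalization of lung voxels by gas volume fraction.

Lung parenchyma is divided into four compartments by per-voxel gas volume
fraction: atelectasis (< 10 %), poor aeration (10-50 %), normal aeration
(50-90 %) and overdistension (> 90 %). Classifying the gas-fraction image
rather than the contrast-enhanced source HU prevents iodinated blood from
inflating the atelectatic fraction. On non-contrast scans the same
cut-offs correspond to -100, -500 and -900 HU.

Boundary convention (the printed ranges overlap at their endpoints):
[0, 0.10) atelectasis, [0.10, 0.50) poor, [0.50, 0.90] normal,
(0.90, 1] overdistended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LABELS",
    "AerationMap",
    "CompartmentSummary",
    "classify_aeration",
    "compartment_fractions",
]

#: Integer label -> compartment name; 0 marks voxels outside the mask.
LABELS = {
    0: "outside",
    1: "atelectasis",
    2: "poorly_aerated",
    3: "normally_aerated",
    4: "overdistended",
}
COMPARTMENTS = ("atelectasis", "poorly_aerated", "normally_aerated", "overdistended")


@dataclass
class AerationMap:
    """Integer compartment labels on the voxel grid plus the cutoffs used."""

    labels: np.ndarray
    mask: np.ndarray
    cutoffs: tuple[float, float, float]
    spacing: tuple[float, float, float]


@dataclass
class CompartmentSummary:
    """Compartment volume fractions (%) and the total masked volume (mL)."""

    fractions_pct: dict[str, float]
    total_volume_ml: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return tuple(self.fractions_pct[c] for c in COMPARTMENTS)


def classify_aeration(
    f_gas: np.ndarray,
    mask: np.ndarray,
    cutoffs: tuple[float, float, float] = (0.10, 0.50, 0.90),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> AerationMap:
    """Label each masked voxel with its aeration compartment.

    Parameters
    ----------
    f_gas
        Per-voxel gas volume fraction in [0, 1] (inside the mask).
    mask
        Boolean analysis mask (lung parenchyma with extrapulmonary
        structures excluded).
    cutoffs
        Strictly increasing gas-fraction thresholds, default (0.10, 0.50,
        0.90).
    """
    c1, c2, c3 = (float(c) for c in cutoffs)
    if not (0.0 < c1 < c2 < c3 < 1.0):
        raise ValueError(f"cutoffs must be strictly increasing within (0,1), got {cutoffs}")
    f_gas = np.asarray(f_gas, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = f_gas[mask]
    if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
        raise ValueError("gas fractions outside [0, 1] inside the mask")
    # half-open below the top cutoff, closed at it: 0.10->poor, 0.50->normal,
    # 0.90->normal, >0.90 overdistended.
    labels = np.zeros(f_gas.shape, dtype=np.int8)
    lab = 1 + (vals >= c1).astype(np.int8) + (vals >= c2).astype(np.int8) + (vals > c3).astype(np.int8)
    labels[mask] = lab
    return AerationMap(labels=labels, mask=mask, cutoffs=(c1, c2, c3), spacing=tuple(spacing))


def compartment_fractions(aeration: AerationMap) -> CompartmentSummary:
    """Volume fraction (%) of each aeration compartment within the mask.

    Fractions are labelled-voxel counts over the masked count, times 100;
    they partition the mask and therefore sum to 100 %.
    """
    n = int(aeration.mask.sum())
    if n == 0:
        raise ValueError("empty analysis mask")
    inside = aeration.labels[aeration.mask]
    fracs = {
        name: float((inside == code).sum()) / n * 100.0
        for code, name in LABELS.items()
        if code != 0
    }
    voxel_ml = float(np.prod(aeration.spacing)) / 1000.0
    return CompartmentSummary(fractions_pct=fracs, total_volume_ml=n * voxel_ml)
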