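"""Three-material differentiation of dual-energy CT volumes.

A voxel imaged at two tube energies yields two CT densities (HU). Modelling
the voxel as a mixture of three basis materials — gas, soft tissue and
iodinated blood — whose volume fractions sum to one gives a 3x3 linear
system per voxel:

    HU_low  = f_gas C[gas,low]  + f_tis C[tis,low]  + f_bld C[bld,low]
    HU_high = f_gas C[gas,high] + f_tis C[tis,high] + f_bld C[bld,high]
    1       = f_gas + f_tis + f_bld

The coefficient matrix ``C`` (the CT density of 100 % of each material at
each energy) is calibrated from regions of interest: the descending
thoracic aorta for iodinated blood, the parasternal musculature for soft
tissue, and a fixed -1000 HU at both energies for gas. The system matrix is
voxel-independent, so one shared inverse solves every voxel at once.

Raw per-voxel solutions may fall outside the unit simplex under noise; the
policy here clips negative fractions to zero and renormalizes to unit sum,
recording the distance moved so users can audit the projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "MATERIALS",
    "ENERGIES",
    "CtVolume",
    "DectPair",
    "MaterialBasis",
    "FractionMaps",
    "DegenerateBasisError",
    "calibrate_basis",
    "decompose",
    "decompose_raw",
    "merge_volumes",
    "noncontrast_equivalent_hu",
]

MATERIALS = ("gas", "soft_tissue", "iodinated_blood")
ENERGIES = ("low", "high")

#: Condition-number threshold above which the 3x3 system is rejected.
CONDITION_LIMIT = 1e6

#: Sentinel written outside the analysis mask in fraction maps.
MASK_SENTINEL = np.nan


class DegenerateBasisError(ValueError):
    """The material basis does not identify three distinct materials."""


@dataclass
class CtVolume:
    """A 3-D CT density volume in Hounsfield units.

    Axis convention: axis 0 = left-right, axis 1 = anterior -> posterior
    (posterior, i.e. dependent in a supine subject, at increasing index),
    axis 2 = cranio-caudal (caudal at increasing index).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (spacing is in mm)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class DectPair:
    """Co-registered low/high energy CT volumes on one voxel grid."""

    low: CtVolume
    high: CtVolume
    energy_labels: tuple[str, str] = ("low", "high")

    def __post_init__(self) -> None:
        if self.low.data.shape != self.high.data.shape:
            raise ValueError(
                f"energy volumes differ in shape: {self.low.data.shape} vs {self.high.data.shape}"
            )
        if self.low.spacing != self.high.spacing:
            raise ValueError("energy volumes differ in voxel spacing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.low.data.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.low.spacing


@dataclass
class MaterialBasis:
    """CT densities equivalent to 100 % of each material at each energy.

    ``coefficients[m, e]`` is the HU of pure material ``MATERIALS[m]`` at
    energy ``ENERGIES[e]``. Gas is -1000 HU at both energies unless
    explicitly overridden.
    """

    coefficients: np.ndarray  # shape (3 materials, 2 energies)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (3, 2):
            raise ValueError(
                f"coefficients must be 3 materials x 2 energies, got {self.coefficients.shape}"
            )
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    def system_matrix(self) -> np.ndarray:
        """3x3 matrix: rows = (HU_low, HU_high, unity), columns = materials."""
        return np.vstack([self.coefficients.T, np.ones(3)])

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.system_matrix()))

    def check(self) -> None:
        """Raise :class:`DegenerateBasisError` if the system is ill-conditioned."""
        cond = self.condition_number()
        if not np.isfinite(cond) or cond >= CONDITION_LIMIT:
            i, j = _most_collinear_pair(self.coefficients)
            raise DegenerateBasisError(
                f"material basis is degenerate (condition number {cond:.3g} >= "
                f"{CONDITION_LIMIT:.0e}); materials '{MATERIALS[i]}' and "
                f"'{MATERIALS[j]}' are not distinguishable at these energies"
            )

    def to_dict(self) -> dict:
        return {m: [float(v) for v in self.coefficients[k]] for k, m in enumerate(MATERIALS)}

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialBasis":
        coef = np.array([d[m] for m in MATERIALS], dtype=float)
        return cls(coef, provenance={m: "fixed" for m in MATERIALS})


def _most_collinear_pair(coefficients: np.ndarray) -> tuple[int, int]:
    """Index pair of materials whose energy signatures are closest."""
    best, best_d = (0, 1), np.inf
    for i, j in combinations(range(3), 2):
        d = float(np.linalg.norm(coefficients[i] - coefficients[j]))
        if d < best_d:
            best, best_d = (i, j), d
    return best


@dataclass
class RoiMask:
    """Boolean voxel mask with an anatomical label."""

    data: np.ndarray
    label: str = "lung"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class FractionMaps:
    """Per-voxel volume fractions of gas, soft tissue and iodinated blood.

    Inside ``mask`` each fraction lies in [0, 1] and the three sum to one;
    outside, all maps carry NaN. ``residual`` is the Euclidean distance
    between the raw linear solution and the reported on-simplex fractions
    (zero wherever no projection was needed).
    """

    f_gas: np.ndarray
    f_tissue: np.ndarray
    f_blood: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    residual: np.ndarray | None = None

    def as_stack(self) -> np.ndarray:
        """Fractions stacked on a leading material axis, order ``MATERIALS``."""
        return np.stack([self.f_gas, self.f_tissue, self.f_blood])


def calibrate_basis(pair: DectPair, aorta: RoiMask, muscle: RoiMask) -> MaterialBasis:
    """Calibrate the material basis from aorta and muscle ROI means.

    Iodinated-blood coefficients are the mean aorta HU at each energy,
    soft-tissue coefficients the mean parasternal-muscle HU, and gas is
    fixed at -1000 HU at both energies.

    Raises
    ------
    ValueError
        If either ROI is empty.
    DegenerateBasisError
        If the calibrated 3x3 system has condition number >= 1e6.
    """
    for roi in (aorta, muscle):
        if roi.count == 0:
            raise ValueError(f"calibration ROI '{roi.label}' is empty")
    coef = np.empty((3, 2))
    coef[0] = (-1000.0, -1000.0)
    for e, vol in enumerate((pair.low, pair.high)):
        coef[1, e] = float(vol.data[muscle.data].mean())
        coef[2, e] = float(vol.data[aorta.data].mean())
    basis = MaterialBasis(
        coef,
        provenance={
            "gas": "fixed",
            "soft_tissue": f"ROI mean ({muscle.label}, n={muscle.count})",
            "iodinated_blood": f"ROI mean ({aorta.label}, n={aorta.count})",
        },
    )
    basis.check()
    return basis


def decompose_raw(pair: DectPair, basis: MaterialBasis, mask: RoiMask) -> np.ndarray:
    """Solve the per-voxel 3x3 system without simplex projection.

    Returns a ``(3, nx, ny, nz)`` array of raw fractions (material axis in
    ``MATERIALS`` order), NaN outside the mask. Raw fractions sum to one
    exactly (the unity constraint is part of the system) but may lie
    outside [0, 1] under noise.
    """
    basis.check()
    m = mask.data
    if m.shape != pair.shape:
        raise ValueError(f"mask shape {m.shape} does not match volumes {pair.shape}")
    lo, hi = pair.low.data[m], pair.high.data[m]
    bad = ~(np.isfinite(lo) & np.isfinite(hi))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} masked voxels have non-finite HU values")
    # rhs columns: (HU_low, HU_high, 1) per voxel; one shared inverse.
    inv = np.linalg.inv(basis.system_matrix())
    rhs = np.vstack([lo, hi, np.ones_like(lo)])
    sol = inv @ rhs  # (3, n_masked)
    out = np.full((3,) + pair.shape, MASK_SENTINEL)
    for k in range(3):
        out[k][m] = sol[k]
    return out


def project_to_simplex(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip negative fractions to zero and renormalize to unit sum.

    Operates on a ``(3, ...)`` stack; returns (projected, residual) where
    residual is the Euclidean distance moved per voxel. NaNs pass through.
    """
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        projected = np.where(total > 0, clipped / total, np.nan)
    residual = np.sqrt(((projected - raw) ** 2).sum(axis=0))
    return projected, residual


def decompose(pair: DectPair, basis: MaterialBasis, mask: RoiMask) -> FractionMaps:
    """Per-voxel three-material differentiation of a dual-energy pair.

    Solves the shared 3x3 system at every masked voxel, then projects
    out-of-range solutions onto the unit simplex (clip negatives,
    renormalize). The pre-projection displacement is kept as a diagnostic.
    """
    raw = decompose_raw(pair, basis, mask)
    projected, residual = project_to_simplex(raw)
    return FractionMaps(
        f_gas=projected[0],
        f_tissue=projected[1],
        f_blood=projected[2],
        mask=mask.data.copy(),
        spacing=pair.spacing,
        residual=residual,
    )


def merge_volumes(pair: DectPair, weight_high: float = 0.7) -> CtVolume:
    """Weighted blend of the two energy volumes (default 70 % high energy).

    Used as the display/segmentation volume; the blend is linear per voxel:
    ``weight_high * HU_high + (1 - weight_high) * HU_low``.
    """
    if not 0.0 <= weight_high <= 1.0:
        raise ValueError(f"weight_high must be in [0, 1], got {weight_high}")
    data = weight_high * pair.high.data + (1.0 - weight_high) * pair.low.data
    return CtVolume(data, pair.spacing)


def noncontrast_equivalent_hu(gas_fraction: float) -> float:
    """HU of a gas/soft-tissue mixture on a non-contrast scan.

    With gas at -1000 HU and soft tissue at 0 HU, a gas volume fraction g
    corresponds to -1000 * g HU; e.g. gas fractions 0.10, 0.50 and 0.90 map
    to -100, -500 and -900 HU, the classical aeration cut-offs.
    """
    g = float(gas_fraction)
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"gas_fraction must be in [0, 1], got {gas_fraction}")
    return g * -1000.0 + (1.0 - g) * 0.0
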