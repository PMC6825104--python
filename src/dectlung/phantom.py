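"""Synthetic supine-thorax phantom with known dual-energy ground truth.

The phantom emulates the features a dynamic/whole-lung dual-energy CT
study of a supine, mechanically ventilated subject exercises:

* two lung fields with a gravitational (anterior -> posterior) gradient in
  gas volume fraction — the dependent lung is denser;
* a dependent atelectatic mass (gas fraction below 10 %);
* intrapulmonary vessels running cranio-caudally, carrying iodinated
  blood, which make the density distribution bimodal;
* calibration anatomy outside the lungs: descending aorta (pure iodinated
  blood) and parasternal muscle (pure soft tissue);
* tidal modulation of gas content sampled at 1 Hz, between exact
  end-expiratory and end-inspiratory gas volumes (raised-cosine waveform);
* a smooth displacement field (expiration -> inspiration) from a coarse
  control grid, with caudal movement concentrated mid-gravitationally.

Every stochastic element is driven by the spec's seed, so a fixed spec
reproduces the phantom bit for bit. The forward model for rendering is the
linear mixing model only — per voxel and energy, HU is the
fraction-weighted sum of material coefficients plus independent Gaussian
noise; no beam hardening, scatter or reconstruction effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .aeration import AerationMap, classify_aeration
from .decomposition import (
    CtVolume,
    DectPair,
    FractionMaps,
    MaterialBasis,
    RoiMask,
)
from .displacement import GRAV_AXIS, CC_AXIS, DisplacementField
from .frames import DegenerateSeriesError, FrameSeries

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "default_basis",
    "generate_phantom",
    "render_dect",
    "simulate_tidal_series",
    "generate_displacement_field",
    "field_from_control",
]


def default_basis() -> MaterialBasis:
    """Plausible material coefficients (HU) at a low/high energy pair.

    Gas is -1000 HU at both energies; soft tissue is nearly
    energy-independent; iodinated blood attenuates much more strongly at
    the low energy, which is what makes the three materials separable.
    """
    return MaterialBasis(
        np.array([[-1000.0, -1000.0], [60.0, 55.0], [400.0, 250.0]]),
        provenance={m: "default" for m in ("gas", "soft_tissue", "iodinated_blood")},
    )


@dataclass
class PhantomSpec:
    """Parameters of the synthetic thorax and its dynamics.

    Units: spacing and displacements in mm, volumes in mL, HU noise in
    Hounsfield units. Fractions are unitless in [0, 1]. Axis convention as
    in :class:`~dectlung.decomposition.CtVolume` (axis 1 anterior ->
    posterior, axis 2 cranio-caudal).
    """

    shape: tuple[int, int, int] = (96, 128, 12)
    spacing: tuple[float, float, float] = (0.5, 0.5, 5.0)
    # gravitational aeration gradient (gas fraction at the anterior and
    # posterior lung borders)
    anterior_gas: float = 0.85
    posterior_gas: float = 0.25
    # vasculature
    vessel_fraction: float = 0.03
    vessel_radius_mm: float = 1.0
    vessel_blood_fraction: float = 0.90
    perfusion_blood_fraction: float = 0.08
    # dependent atelectasis
    atelectasis_extent: float = 0.12  # fraction of the lung's AP depth
    atelectasis_gas: float = 0.03
    # rendering noise (HU standard deviation at low/high energy)
    noise_sd_hu: tuple[float, float] = (5.0, 5.0)
    # tidal dynamics (1 Hz sampling)
    end_expiratory_gas_ml: float | None = None  # None -> phantom's native volume
    tidal_amplitude_ml: float | None = None  # None -> 30 % of end-expiratory
    frames_per_cycle: int = 16
    n_cycles: int = 3
    slab_slices: int = 1
    # displacement field
    peak_caudal_mm: float = 12.0
    control_spacing_mm: float = 3.0
    displacement_noise_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.shape) or len(self.shape) != 3:
            raise ValueError(f"shape must be three positive sizes, got {self.shape}")
        if any(float(s) <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        for name in (
            "anterior_gas",
            "posterior_gas",
            "vessel_fraction",
            "vessel_blood_fraction",
            "perfusion_blood_fraction",
            "atelectasis_extent",
            "atelectasis_gas",
        ):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(s < 0 for s in self.noise_sd_hu):
            raise ValueError("noise standard deviations must be >= 0")
        if self.frames_per_cycle < 2 or self.n_cycles < 1:
            raise ValueError("need at least 2 frames per cycle and 1 cycle")
        if self.peak_caudal_mm < 0 or self.control_spacing_mm <= 0:
            raise ValueError("displacement parameters out of range")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class GroundTruth:
    """Everything the phantom knows that the pipeline must recover."""

    spec: PhantomSpec
    fractions: FractionMaps
    lung_mask: np.ndarray
    aorta_mask: np.ndarray
    muscle_mask: np.ndarray
    body_mask: np.ndarray
    vessel_mask: np.ndarray
    aeration: AerationMap
    displacement: DisplacementField | None = None
    region_mean_cc_mm: np.ndarray | None = None
    slice_mask: np.ndarray | None = None
    frame_labels: list[str] | None = None


def _ellipse_mask(shape2d, center, semi_axes) -> np.ndarray:
    x = np.arange(shape2d[0])[:, None]
    y = np.arange(shape2d[1])[None, :]
    return ((x - center[0]) / semi_axes[0]) ** 2 + ((y - center[1]) / semi_axes[1]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Build the ground-truth thorax for a spec.

    Deterministic for a fixed seed; fraction maps sum to one exactly at
    every voxel. The returned truth includes the aeration labels implied
    by the true gas fractions and the smooth displacement field with its
    per-region mean cranio-caudal displacement over the dynamic slice.
    """
    nx, ny, nz = spec.shape
    rng = np.random.default_rng(spec.seed)

    body2d = _ellipse_mask((nx, ny), (0.5 * nx, 0.5 * ny), (0.46 * nx, 0.44 * ny))
    lung_l = _ellipse_mask((nx, ny), (0.30 * nx, 0.50 * ny), (0.16 * nx, 0.34 * ny))
    lung_r = _ellipse_mask((nx, ny), (0.70 * nx, 0.50 * ny), (0.16 * nx, 0.34 * ny))
    lung2d = (lung_l | lung_r) & body2d
    aorta2d = _ellipse_mask((nx, ny), (0.50 * nx, 0.76 * ny), (0.035 * nx, 0.035 * nx)) & body2d & ~lung2d
    muscle2d = np.zeros((nx, ny), dtype=bool)
    muscle2d[int(0.25 * nx) : int(0.75 * nx), int(0.06 * ny) : int(0.11 * ny)] = True
    muscle2d &= body2d & ~lung2d & ~aorta2d

    def extrude(m2d):
        return np.repeat(m2d[:, :, None], nz, axis=2)

    body = extrude(body2d)
    lung = extrude(lung2d)
    aorta = extrude(aorta2d)
    muscle = extrude(muscle2d)

    # gravitational gas gradient over the lung's AP extent
    ap_idx = np.where(lung2d.any(axis=0))[0]
    ap_lo, ap_hi = ap_idx.min(), ap_idx.max()
    y_norm = np.zeros(ny)
    if ap_hi > ap_lo:
        y_norm[ap_lo : ap_hi + 1] = (np.arange(ap_lo, ap_hi + 1) - ap_lo) / (ap_hi - ap_lo)
    grad = spec.anterior_gas + (spec.posterior_gas - spec.anterior_gas) * y_norm

    f_gas = np.zeros(spec.shape)
    f_gas[lung] = np.broadcast_to(grad[None, :, None], spec.shape)[lung]

    # dependent atelectasis: most posterior fraction of the lung depth
    if spec.atelectasis_extent > 0:
        atel_band = y_norm >= 1.0 - spec.atelectasis_extent
        atel = lung & np.broadcast_to(atel_band[None, :, None], spec.shape)
        f_gas[atel] = spec.atelectasis_gas

    # cranio-caudal vessels: seeded in-plane centres inside the lungs
    vessel2d = np.zeros((nx, ny), dtype=bool)
    r_vox = max(spec.vessel_radius_mm / spec.spacing[0], 0.5)
    vessel_area = np.pi * r_vox**2
    n_vessels = int(round(spec.vessel_fraction * lung2d.sum() / vessel_area))
    centers = np.argwhere(lung2d)
    if n_vessels > 0 and len(centers):
        chosen = centers[rng.choice(len(centers), size=n_vessels, replace=True)]
        xg = np.arange(nx)[:, None]
        yg = np.arange(ny)[None, :]
        for cx, cy in chosen:
            vessel2d |= (xg - cx) ** 2 + (yg - cy) ** 2 <= r_vox**2
        vessel2d &= lung2d
    vessels = extrude(vessel2d)

    f_blood = np.zeros(spec.shape)
    f_blood[lung] = spec.perfusion_blood_fraction * (1.0 - f_gas[lung])
    f_gas[vessels] = 0.0
    f_blood[vessels] = spec.vessel_blood_fraction
    f_blood[aorta] = 1.0

    # everything outside the body is air; remaining body is soft tissue
    f_gas[~body] = 1.0
    f_blood[~body] = 0.0
    f_tissue = 1.0 - f_gas - f_blood

    mask_all = np.ones(spec.shape, dtype=bool)
    fractions = FractionMaps(
        f_gas=f_gas,
        f_tissue=f_tissue,
        f_blood=f_blood,
        mask=mask_all,
        spacing=spec.spacing,
        residual=np.zeros(spec.shape),
    )
    analysis = lung & ~vessels  # parenchymal analysis mask (vessels excluded)
    aer = classify_aeration(f_gas, lung, spacing=spec.spacing)

    truth = GroundTruth(
        spec=spec,
        fractions=fractions,
        lung_mask=lung,
        aorta_mask=aorta,
        muscle_mask=muscle,
        body_mask=body,
        vessel_mask=vessels,
        aeration=aer,
    )
    truth.slice_mask = dynamic_slice_mask(truth)
    truth.displacement = generate_displacement_field(spec, truth)
    truth.region_mean_cc_mm = _direct_region_means(truth.displacement, truth.slice_mask)
    return truth


def dynamic_slice_mask(truth: GroundTruth, n_slices: int | None = None) -> np.ndarray:
    """Lung mask restricted to the central cranio-caudal slab."""
    n = n_slices or truth.spec.slab_slices
    nz = truth.spec.shape[CC_AXIS]
    z0 = (nz - n) // 2
    m = np.zeros_like(truth.lung_mask)
    m[:, :, z0 : z0 + n] = truth.lung_mask[:, :, z0 : z0 + n]
    return m


def render_dect(
    truth: GroundTruth,
    basis: MaterialBasis | None = None,
    noise_sd_hu: tuple[float, float] | None = None,
    seed: int | None = None,
) -> DectPair:
    """Forward-render the dual-energy pair from true fractions.

    Per voxel and energy: HU = sum_m fraction_m * coefficient_{m,e} plus
    independent Gaussian noise of the per-energy standard deviation.
    """
    basis = basis or default_basis()
    if noise_sd_hu is None:
        noise_sd_hu = truth.spec.noise_sd_hu
    stack = truth.fractions.as_stack()  # (3, nx, ny, nz)
    sums = stack.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("true fractions must sum to 1 at every voxel")
    rng = np.random.default_rng(truth.spec.seed + 1 if seed is None else seed)
    vols = []
    for e in range(2):
        hu = np.tensordot(basis.coefficients[:, e], stack, axes=(0, 0))
        sd = float(noise_sd_hu[e])
        if sd > 0:
            hu = hu + rng.normal(0.0, sd, size=hu.shape)
        vols.append(CtVolume(hu, truth.spec.spacing))
    return DectPair(low=vols[0], high=vols[1])


def _true_phase_labels(volumes_ml: np.ndarray, band: float = 0.30) -> list[str]:
    # independent, loop-based application of the tidal band rule
    g_min = min(volumes_ml)
    g_max = max(volumes_ml)
    r = g_max - g_min
    if r == 0:
        raise DegenerateSeriesError("flat tidal waveform: no inspiratory/expiratory phases")
    labels = []
    for v in volumes_ml:
        if v <= g_min + band * r:
            labels.append("expiratory")
        elif v >= g_max - band * r:
            labels.append("inspiratory")
        else:
            labels.append("excluded")
    return labels


def simulate_tidal_series(
    truth: GroundTruth, band: float = 0.30
) -> tuple[FrameSeries, list[str]]:
    """Simulate a 1 Hz dynamic series of the central slab with tidal gas.

    Per-frame gas volume follows a raised-cosine waveform from the
    end-expiratory volume to end-expiratory + tidal amplitude, reaching
    both extremes exactly. The tidal gas increment is distributed over
    voxels in proportion to their available gas headroom (1 - blood -
    end-expiratory gas), so fractions stay on the simplex; soft tissue
    absorbs the complement. Returns the series and the true phase labels
    obtained by applying the tidal band rule to the noiseless waveform.
    """
    spec = truth.spec
    slab = dynamic_slice_mask(truth)
    if not slab.any():
        raise ValueError("dynamic slab contains no lung voxels")
    vv = spec.voxel_volume_ml
    base_gas = truth.fractions.f_gas
    blood = truth.fractions.f_blood
    v_native = float(base_gas[slab].sum()) * vv

    v_ee = spec.end_expiratory_gas_ml if spec.end_expiratory_gas_ml is not None else v_native
    scale0 = v_ee / v_native if v_native > 0 else 1.0
    g0 = base_gas * scale0
    if np.any(g0[slab] + blood[slab] > 1.0 + 1e-12):
        raise ValueError("requested end-expiratory gas volume exceeds slab capacity")

    headroom = np.clip(1.0 - blood - g0, 0.0, None)
    h_total_ml = float(headroom[slab].sum()) * vv
    amp = spec.tidal_amplitude_ml if spec.tidal_amplitude_ml is not None else 0.30 * v_ee
    if amp > h_total_ml + 1e-9:
        raise ValueError(
            f"tidal amplitude {amp:.1f} mL exceeds slab gas headroom {h_total_ml:.1f} mL"
        )

    n_frames = spec.frames_per_cycle * spec.n_cycles
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    t = np.arange(n_frames, dtype=float)  # 1 Hz
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / spec.frames_per_cycle))  # 0 at trough, 1 at peak
    volumes = v_ee + amp * w
    labels = _true_phase_labels(volumes, band=band)

    share = amp / h_total_ml if h_total_ml > 0 else 0.0
    frames = np.empty((n_frames,) + tuple(spec.shape))
    for i in range(n_frames):
        frames[i] = g0 + w[i] * share * headroom
    series = FrameSeries(
        times_s=t,
        f_gas=frames,
        mask=slab,
        spacing=spec.spacing,
        condition={"seed": spec.seed},
    )
    return series, labels


def field_from_control(
    control_values: np.ndarray,
    control_spacing_mm: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Linearly interpolate per-axis control-point values to the voxel grid.

    ``control_values`` has shape (ncx, ncy, ncz, 3) on a regular grid of
    ``control_spacing_mm`` starting at the volume origin and covering the
    whole volume. A constant control field is reproduced exactly.
    """
    control_values = np.asarray(control_values, dtype=float)
    axes_mm = [np.arange(control_values.shape[a]) * control_spacing_mm for a in range(3)]
    out = np.empty(tuple(shape) + (3,))
    pts = np.stack(
        np.meshgrid(*[np.arange(shape[a]) * spacing[a] for a in range(3)], indexing="ij"),
        axis=-1,
    )
    for c in range(3):
        interp = RegularGridInterpolator(
            axes_mm, control_values[..., c], method="linear", bounds_error=False, fill_value=None
        )
        out[..., c] = interp(pts.reshape(-1, 3)).reshape(shape)
    return out


def control_grid_shape(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    control_spacing_mm: float,
) -> tuple[int, int, int]:
    """Number of control points per axis needed to cover the volume."""
    return tuple(
        int(np.ceil((shape[a] - 1) * spacing[a] / control_spacing_mm)) + 2 for a in range(3)
    )


def generate_displacement_field(spec: PhantomSpec, truth: GroundTruth | None = None) -> DisplacementField:
    """Smooth expiration -> inspiration displacement field for a spec.

    Control-point cranio-caudal values follow a mid-gravitational bump
    (sin^2 over the lung's AP extent) scaled to the spec's peak caudal
    displacement, optionally perturbed by seeded Gaussian control noise,
    then linearly interpolated to the voxel grid. In-plane components are
    zero: inspiration chiefly displaces lung tissue toward the diaphragm.
    """
    nc = control_grid_shape(spec.shape, spec.spacing, spec.control_spacing_mm)
    control = np.zeros(nc + (3,))

    # AP extent of the lungs in mm, for the gravitational profile
    if truth is not None:
        ap_idx = np.where(truth.lung_mask.any(axis=(0, 2)))[0]
        ap_lo_mm = ap_idx.min() * spec.spacing[GRAV_AXIS]
        ap_hi_mm = ap_idx.max() * spec.spacing[GRAV_AXIS]
    else:
        ap_lo_mm, ap_hi_mm = 0.0, (spec.shape[GRAV_AXIS] - 1) * spec.spacing[GRAV_AXIS]

    y_mm = np.arange(nc[GRAV_AXIS]) * spec.control_spacing_mm
    denom = max(ap_hi_mm - ap_lo_mm, 1e-9)
    y_norm = np.clip((y_mm - ap_lo_mm) / denom, 0.0, 1.0)
    bump = np.sin(np.pi * y_norm) ** 2  # peak caudal movement mid-gravitationally
    cc = spec.peak_caudal_mm * bump
    control[..., CC_AXIS] = cc[None, :, None]

    if spec.displacement_noise_mm > 0:
        rng = np.random.default_rng(spec.seed + 2)
        control[..., CC_AXIS] += rng.normal(0.0, spec.displacement_noise_mm, size=nc)
        np.clip(control[..., CC_AXIS], None, spec.peak_caudal_mm, out=control[..., CC_AXIS])

    vectors = field_from_control(control, spec.control_spacing_mm, spec.shape, spec.spacing)
    return DisplacementField(vectors=vectors, spacing=spec.spacing)


def _direct_region_means(
    fld: DisplacementField, slice_mask: np.ndarray, n_regions: int = 12
) -> np.ndarray:
    """Band means by direct per-voxel averaging (generator-side oracle)."""
    cc = fld.vectors[..., CC_AXIS]
    ap = np.where(slice_mask.any(axis=(0, 2)))[0]
    lo, hi = ap.min(), ap.max() + 1
    edges = np.linspace(lo, hi, n_regions + 1)
    means = np.full(n_regions, np.nan)
    for k in range(n_regions):
        sel = np.zeros_like(slice_mask)
        for y in range(lo, hi):
            band = min(int((y + 0.5 - lo) / (hi - lo) * n_regions), n_regions - 1)
            if band == k:
                sel[:, y, :] = slice_mask[:, y, :]
        if sel.any():
            means[k] = float(cc[sel].mean())
    return means
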