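"""Self-contained synthetic experiments built from the phantom.

These drive the package end to end with known ground truth: a null
agreement experiment in which a pseudo dynamic slice is drawn to share the
whole-lung composition (so every dCT-minus-whole-lung difference should be
statistically indistinguishable from zero), and a Bland-Altman recovery
simulation on Gaussian paired differences with known mean and spread.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aeration import classify_aeration, compartment_fractions
from .agreement import VARIABLES, bland_altman, BlandAltmanResult
from .decomposition import RoiMask, calibrate_basis, decompose, merge_volumes
from .phantom import PhantomSpec, default_basis, generate_phantom, render_dect

__all__ = [
    "variables_from_voxels",
    "null_slice_experiment",
    "simulate_bland_altman",
    "mean_loa_over_replicates",
]


def variables_from_voxels(
    merge_hu: np.ndarray,
    f_gas: np.ndarray,
    f_tissue: np.ndarray,
    f_blood: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
) -> pd.Series:
    """The eight variables of interest from 1-D per-voxel samples."""
    f_gas = np.asarray(f_gas, dtype=float)
    ones = np.ones(f_gas.shape, dtype=bool)
    aer = classify_aeration(np.clip(f_gas, 0.0, 1.0), ones, spacing=spacing)
    comp = compartment_fractions(aer)
    return pd.Series(
        {
            "ct_density_hu": float(np.mean(merge_hu)),
            "fv_soft_tissue_pct": float(np.mean(f_tissue)) * 100.0,
            "fv_gas_pct": float(np.mean(f_gas)) * 100.0,
            "fv_iodinated_blood_pct": float(np.mean(f_blood)) * 100.0,
            "fv_atelectasis_pct": comp.fractions_pct["atelectasis"],
            "fv_poorly_aerated_pct": comp.fractions_pct["poorly_aerated"],
            "fv_normally_aerated_pct": comp.fractions_pct["normally_aerated"],
            "fv_overdistended_pct": comp.fractions_pct["overdistended"],
        }
    ).reindex(list(VARIABLES))


def null_slice_experiment(
    seed: int = 0,
    n_conditions: int = 24,
    shape: tuple[int, int, int] = (48, 64, 6),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired eight-variable summaries under the null of identical composition.

    For each synthetic condition a phantom is generated and rendered with
    HU noise, the basis is calibrated from the aorta and muscle ROIs, and
    the pair is decomposed. The whole-lung context summarizes all lung
    voxels; the pseudo dynamic slice draws the same number of voxels as
    the central 5-mm slab, with replacement, from the whole lung — so its
    composition equals the whole lung's in expectation and all eight
    dCT-minus-whole differences have zero mean by construction.

    Returns (dct_df, whole_df), one row per condition, columns VARIABLES.
    """
    master = np.random.default_rng(seed)
    dct_rows, whole_rows = [], []
    for _ in range(n_conditions):
        s = int(master.integers(0, 2**31 - 1))
        spec = PhantomSpec(shape=shape, seed=s)
        truth = generate_phantom(spec)
        pair = render_dect(truth)
        basis = calibrate_basis(
            pair, RoiMask(truth.aorta_mask, "aorta"), RoiMask(truth.muscle_mask, "parasternal muscle")
        )
        lung = RoiMask(truth.lung_mask, "lung")
        fr = decompose(pair, basis, lung)
        merge = merge_volumes(pair)

        m = truth.lung_mask
        hu = merge.data[m]
        g, ti, bl = fr.f_gas[m], fr.f_tissue[m], fr.f_blood[m]
        whole_rows.append(variables_from_voxels(hu, g, ti, bl, spec.spacing))

        n_slab = int(truth.slice_mask.sum())
        rng = np.random.default_rng(s + 3)
        pick = rng.integers(0, hu.size, size=max(n_slab, 1))
        dct_rows.append(variables_from_voxels(hu[pick], g[pick], ti[pick], bl[pick], spec.spacing))
    return pd.DataFrame(dct_rows).reset_index(drop=True), pd.DataFrame(whole_rows).reset_index(drop=True)


def simulate_bland_altman(
    seed: int = 0,
    n: int = 96,
    mu: float = -30.0,
    sigma: float = 16.0,
    whole_level: float = -500.0,
    whole_spread: float = 60.0,
) -> BlandAltmanResult:
    """Bland-Altman analysis of one simulated paired study.

    Whole-lung values are drawn around ``whole_level``; the paired dynamic
    values add Gaussian differences N(mu, sigma). n defaults to 96, the
    number of ventilatory conditions in a 12-condition x 8-subject design.
    """
    rng = np.random.default_rng(seed)
    whole = rng.normal(whole_level, whole_spread, size=n)
    dct = whole + rng.normal(mu, sigma, size=n)
    return bland_altman(dct, whole)


def mean_loa_over_replicates(
    seed: int = 0,
    replicates: int = 200,
    n: int = 96,
    mu: float = -30.0,
    sigma: float = 16.0,
) -> tuple[float, float]:
    """Mean estimated limits of agreement over replicated paired studies.

    Averaging over replicates checks the calibration of the LoA estimator
    (its expectation) rather than a single draw, whose sampling spread at
    n = 96 is sigma * sqrt(3/n) ~ 0.18 sigma per limit.
    """
    master = np.random.default_rng(seed)
    lowers, uppers = [], []
    for _ in range(replicates):
        ba = simulate_bland_altman(int(master.integers(0, 2**31 - 1)), n=n, mu=mu, sigma=sigma)
        lowers.append(ba.loa_lower)
        uppers.append(ba.loa_upper)
    return float(np.mean(lowers)), float(np.mean(uppers))
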