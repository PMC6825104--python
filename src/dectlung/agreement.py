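"""Agreement statistics between dynamic-slice and whole-lung summaries.

Eight variables of interest summarize each imaging context: mean merged CT
density (HU) and volume fractions (%) of soft tissue, gas and iodinated
blood, plus the four aeration compartments. Paired per-condition means are
compared with linear correlation (r^2), Bland-Altman analysis (mean
difference with 95 % CI and 95 % limits of agreement with their CIs) and a
two-sided paired t test. The difference sign convention is dynamic minus
whole lung throughout. A phase split quantifies how the bias changes from
expiration to inspiration, and an adjacent-slice regression estimates the
per-mm effect of cranio-caudal slice position on each variable.

Bland-Altman formulas: with differences d_i, n of them, mean d and SD s,

    LoA = d +/- 1.96 s
    CI(d)   = d   +/- t_{0.975, n-1} * s / sqrt(n)
    CI(LoA) = LoA +/- t_{0.975, n-1} * s * sqrt(3 / n)

the last using the classical large-sample standard error of a limit of
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aeration import AerationMap, compartment_fractions
from .decomposition import CtVolume, FractionMaps

__all__ = [
    "VARIABLES",
    "summarize_variables",
    "BlandAltmanResult",
    "bland_altman",
    "correlate_means",
    "agreement_report",
    "phase_bias",
    "slice_position_regression",
]

#: The eight variables of interest, in reporting order.
VARIABLES = (
    "ct_density_hu",
    "fv_soft_tissue_pct",
    "fv_gas_pct",
    "fv_iodinated_blood_pct",
    "fv_atelectasis_pct",
    "fv_poorly_aerated_pct",
    "fv_normally_aerated_pct",
    "fv_overdistended_pct",
)


def summarize_variables(
    merge: CtVolume,
    fractions: FractionMaps,
    labels: AerationMap,
    mask: np.ndarray,
) -> pd.Series:
    """Compute the eight variables of interest over one analysis mask.

    Mean merged HU; mean of each material fraction map x 100; aeration
    compartment volume fractions. Material fractions and compartment
    fractions each sum to 100 %.
    """
    mask = np.asarray(mask, dtype=bool)
    if merge.data.shape != mask.shape or fractions.f_gas.shape != mask.shape:
        raise ValueError("merge volume, fraction maps and mask must share one grid")
    if labels.labels.shape != mask.shape:
        raise ValueError("aeration labels grid does not match mask")
    comp = compartment_fractions(labels)
    out = pd.Series(
        {
            "ct_density_hu": float(merge.data[mask].mean()),
            "fv_soft_tissue_pct": float(fractions.f_tissue[mask].mean()) * 100.0,
            "fv_gas_pct": float(fractions.f_gas[mask].mean()) * 100.0,
            "fv_iodinated_blood_pct": float(fractions.f_blood[mask].mean()) * 100.0,
            "fv_atelectasis_pct": comp.fractions_pct["atelectasis"],
            "fv_poorly_aerated_pct": comp.fractions_pct["poorly_aerated"],
            "fv_normally_aerated_pct": comp.fractions_pct["normally_aerated"],
            "fv_overdistended_pct": comp.fractions_pct["overdistended"],
        }
    )
    return out.reindex(list(VARIABLES))


@dataclass
class BlandAltmanResult:
    """Mean difference, limits of agreement and their confidence intervals."""

    n: int
    mean_diff: float
    mean_diff_ci: tuple[float, float]
    loa_lower: float
    loa_lower_ci: tuple[float, float]
    loa_upper: float
    loa_upper_ci: tuple[float, float]
    sd_diff: float


def bland_altman(dct: np.ndarray, whole: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman analysis of paired values (difference = dct - whole)."""
    dct = np.asarray(dct, dtype=float)
    whole = np.asarray(whole, dtype=float)
    if dct.shape != whole.shape:
        raise ValueError("paired vectors differ in length")
    if not (np.all(np.isfinite(dct)) and np.all(np.isfinite(whole))):
        raise ValueError("paired values must be finite")
    d = dct - whole
    n = d.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs for confidence intervals, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    t = float(stats.t.ppf(0.975, n - 1))
    half_mean = t * sd / np.sqrt(n)
    half_loa = t * sd * np.sqrt(3.0 / n)
    lower = mean - 1.96 * sd
    upper = mean + 1.96 * sd
    return BlandAltmanResult(
        n=n,
        mean_diff=mean,
        mean_diff_ci=(mean - half_mean, mean + half_mean),
        loa_lower=lower,
        loa_lower_ci=(lower - half_loa, lower + half_loa),
        loa_upper=upper,
        loa_upper_ci=(upper - half_loa, upper + half_loa),
        sd_diff=sd,
    )


def correlate_means(dct: np.ndarray, whole: np.ndarray) -> float:
    """Squared Pearson correlation (r^2) of paired per-condition means."""
    dct = np.asarray(dct, dtype=float)
    whole = np.asarray(whole, dtype=float)
    if dct.shape != whole.shape:
        raise ValueError("paired vectors differ in length")
    if np.ptp(dct) == 0 or np.ptp(whole) == 0:
        return float("nan")  # undefined for a constant series
    r, _ = stats.pearsonr(dct, whole)
    return float(r) ** 2


def agreement_report(dct: pd.DataFrame, whole: pd.DataFrame) -> pd.DataFrame:
    """Correlation + Bland-Altman + paired t test per variable of interest.

    ``dct`` and ``whole`` hold one row per ventilatory condition and one
    column per entry of :data:`VARIABLES` (extra columns are ignored).
    Returns one row per variable with r^2, mean difference and CI, both
    limits of agreement and CIs, the paired t statistic, p and n.
    """
    rows = []
    for var in VARIABLES:
        x = dct[var].to_numpy(dtype=float)
        y = whole[var].to_numpy(dtype=float)
        ba = bland_altman(x, y)
        tstat, p = stats.ttest_rel(x, y)
        rows.append(
            {
                "variable": var,
                "r2": correlate_means(x, y),
                "mean_diff": ba.mean_diff,
                "mean_diff_ci_low": ba.mean_diff_ci[0],
                "mean_diff_ci_high": ba.mean_diff_ci[1],
                "loa_lower": ba.loa_lower,
                "loa_lower_ci_low": ba.loa_lower_ci[0],
                "loa_lower_ci_high": ba.loa_lower_ci[1],
                "loa_upper": ba.loa_upper,
                "loa_upper_ci_low": ba.loa_upper_ci[0],
                "loa_upper_ci_high": ba.loa_upper_ci[1],
                "t": float(tstat),
                "p": float(p),
                "n": ba.n,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def phase_bias(biases: pd.DataFrame) -> pd.DataFrame:
    """Split the dct-minus-whole bias by respiratory phase.

    ``biases`` holds one row per condition with a ``phase`` column
    ('expiratory' | 'inspiratory') and one column per variable carrying
    the paired bias measured in that phase; conditions appear once per
    phase and are paired by ``condition`` column if present, else by
    order within phase. Reports per variable: mean (SD) bias per phase,
    the inspiratory-minus-expiratory difference as mean with 95 % limits
    (+/- 1.96 x SD of the paired differences), and a paired t-test p.
    """
    exp = biases[biases["phase"] == "expiratory"]
    insp = biases[biases["phase"] == "inspiratory"]
    if "condition" in biases.columns:
        exp = exp.set_index("condition").sort_index()
        insp = insp.set_index("condition").sort_index()
        common = exp.index.intersection(insp.index)
        exp, insp = exp.loc[common], insp.loc[common]
    if len(exp) != len(insp) or len(exp) == 0:
        raise ValueError("phases must contain the same nonempty set of conditions")
    rows = []
    for var in VARIABLES:
        if var not in biases.columns:
            continue
        e = exp[var].to_numpy(dtype=float)
        i = insp[var].to_numpy(dtype=float)
        d = i - e
        sd_d = float(d.std(ddof=1)) if d.size > 1 else 0.0
        if d.size > 1 and sd_d > 0:
            _, p = stats.ttest_rel(i, e)
        else:
            p = np.nan
        rows.append(
            {
                "variable": var,
                "expiratory_mean": float(e.mean()),
                "expiratory_sd": float(e.std(ddof=1)) if e.size > 1 else 0.0,
                "inspiratory_mean": float(i.mean()),
                "inspiratory_sd": float(i.std(ddof=1)) if i.size > 1 else 0.0,
                "difference_mean": float(d.mean()),
                "difference_limit_low": float(d.mean()) - 1.96 * sd_d,
                "difference_limit_high": float(d.mean()) + 1.96 * sd_d,
                "p": float(p) if np.isfinite(p) else np.nan,
                "n_pairs": int(d.size),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def slice_position_regression(per_slice: pd.DataFrame, offset_col: str = "offset_mm") -> pd.DataFrame:
    """Effect of cranio-caudal slice position on each variable.

    ``per_slice`` holds one row per (condition, slice) observation with an
    ``offset_mm`` column giving the cranial distance from the most caudal
    slice (0 for the caudal slice itself) and one column per variable,
    expressed relative to the caudal slice. Ordinary least squares pooled
    over observations gives a slope per mm of cranial displacement and an
    r^2 per variable.
    """
    offsets = per_slice[offset_col].to_numpy(dtype=float)
    if np.unique(offsets).size < 2:
        raise ValueError("need at least 2 distinct slice offsets")
    rows = []
    for var in VARIABLES:
        if var not in per_slice.columns:
            continue
        y = per_slice[var].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            rows.append({"variable": var, "slope_per_mm": 0.0, "r2": 0.0})
            continue
        fit = stats.linregress(offsets, y)
        rows.append({"variable": var, "slope_per_mm": float(fit.slope), "r2": float(fit.rvalue) ** 2})
    return pd.DataFrame(rows).set_index("variable")
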