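"""End-to-end orchestration: simulate, decompose, segment, report.

`run_pipeline` chains the stages in acquisition-processing order —
phantom simulation, dual-energy rendering, basis calibration, three-
material decomposition, aeration segmentation, dynamic-frame
classification, histograms, dCT vs whole-lung agreement and displacement
summaries — and writes a manifest naming every artifact together with the
configuration and seed, so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nifti
from .aeration import classify_aeration, compartment_fractions
from .agreement import agreement_report
from .decomposition import RoiMask, calibrate_basis, decompose, merge_volumes
from .displacement import cc_displacement_slice, movement_fractions, regional_means
from .distributions import density_histogram, fraction_histogram
from .experiments import null_slice_experiment
from .frames import classify_frames
from .phantom import PhantomSpec, generate_phantom, render_dect, simulate_tidal_series

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("dectlung")


@dataclass
class PipelineConfig:
    """Configuration of a full simulate-then-analyze run."""

    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    merge_weight_high: float = 0.7
    aeration_cutoffs: tuple[float, float, float] = (0.10, 0.50, 0.90)
    frame_band: float = 0.30
    n_regions: int = 12
    n_agreement_conditions: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.merge_weight_high <= 1.0:
            raise ValueError("merge_weight_high must be in [0, 1]")
        if not 0.0 < self.frame_band < 0.5:
            raise ValueError("frame_band must be in (0, 0.5)")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        self.aeration_cutoffs = tuple(float(c) for c in self.aeration_cutoffs)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "aeration_cutoffs" in d:
            d["aeration_cutoffs"] = tuple(d["aeration_cutoffs"])
        return cls(**d)


def _write_histogram_csv(path: Path, hist) -> None:
    pd.DataFrame(
        {"bin_left": hist.edges[:-1], "bin_right": hist.edges[1:], "weight": hist.weights}
    ).to_csv(path, index=False)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a simulated phantom and write a report bundle.

    Returns the manifest (also written as ``manifest.json``): the config,
    the seed and the relative path of every artifact produced. Idempotent
    for a fixed seed; all CSV outputs are byte-identical across reruns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    t0 = time.time()

    def _stage(name: str):
        log.info("stage %-14s t=%.2fs", name, time.time() - t0)

    phantom_kwargs = dict(config.phantom)
    phantom_kwargs.setdefault("seed", config.seed)
    if "shape" in phantom_kwargs:
        phantom_kwargs["shape"] = tuple(phantom_kwargs["shape"])
    if "spacing" in phantom_kwargs:
        phantom_kwargs["spacing"] = tuple(phantom_kwargs["spacing"])
    spec = PhantomSpec(**phantom_kwargs)

    _stage("simulate")
    truth = generate_phantom(spec)
    pair = render_dect(truth)
    for name, vol in (("hu_low", pair.low), ("hu_high", pair.high)):
        p = out / f"{name}.nii.gz"
        _nifti.write_volume(p, vol.data, spec.spacing)
        artifacts[name] = p.name
    for name, m in (
        ("lung_mask", truth.lung_mask),
        ("aorta_mask", truth.aorta_mask),
        ("muscle_mask", truth.muscle_mask),
    ):
        p = out / f"{name}.nii.gz"
        _nifti.write_mask(p, m, spec.spacing)
        artifacts[name] = p.name

    _stage("decompose")
    basis = calibrate_basis(
        pair, RoiMask(truth.aorta_mask, "aorta"), RoiMask(truth.muscle_mask, "parasternal muscle")
    )
    (out / "basis.json").write_text(json.dumps(basis.to_dict(), indent=2, sort_keys=True))
    artifacts["basis"] = "basis.json"
    lung = RoiMask(truth.lung_mask, "lung")
    fractions = decompose(pair, basis, lung)
    merge = merge_volumes(pair, config.merge_weight_high)
    for name, arr in (
        ("f_gas", fractions.f_gas),
        ("f_soft_tissue", fractions.f_tissue),
        ("f_iodinated_blood", fractions.f_blood),
        ("merge", merge.data),
    ):
        p = out / f"{name}.nii.gz"
        _nifti.write_volume(p, arr, spec.spacing)
        artifacts[name] = p.name

    _stage("segment")
    aer = classify_aeration(
        np.nan_to_num(fractions.f_gas, nan=0.0), truth.lung_mask, config.aeration_cutoffs, spec.spacing
    )
    p = out / "aeration_labels.nii.gz"
    _nifti.write_volume(p, aer.labels.astype(np.int16), spec.spacing)
    artifacts["aeration_labels"] = p.name
    comp = compartment_fractions(aer)
    p = out / "compartments.csv"
    pd.DataFrame([comp.fractions_pct | {"total_volume_ml": comp.total_volume_ml}]).to_csv(p, index=False)
    artifacts["compartments"] = p.name

    _stage("frames")
    series, _true = simulate_tidal_series(truth, band=config.frame_band)
    frame_table = classify_frames(series, band=config.frame_band)
    p = out / "frames.csv"
    frame_table.to_csv(p, index=False)
    artifacts["frames"] = p.name

    _stage("histograms")
    hu_hist = density_histogram(merge.data, truth.lung_mask)
    _write_histogram_csv(out / "hist_hu.csv", hu_hist)
    artifacts["hist_hu"] = "hist_hu.csv"
    for name, arr in (
        ("gas", fractions.f_gas),
        ("soft_tissue", fractions.f_tissue),
        ("iodinated_blood", fractions.f_blood),
    ):
        h = fraction_histogram(np.nan_to_num(arr, nan=0.0), truth.lung_mask)
        _write_histogram_csv(out / f"hist_{name}.csv", h)
        artifacts[f"hist_{name}"] = f"hist_{name}.csv"

    _stage("agreement")
    dct_df, whole_df = null_slice_experiment(
        seed=config.seed, n_conditions=config.n_agreement_conditions, shape=spec.shape
    )
    report = agreement_report(dct_df, whole_df)
    p = out / "agreement.csv"
    report.to_csv(p)
    artifacts["agreement"] = p.name

    _stage("displacement")
    cc = cc_displacement_slice(truth.displacement, truth.slice_mask)
    means = regional_means(cc, truth.slice_mask, config.n_regions)
    p = out / "displacement_regions.csv"
    pd.DataFrame({"region": np.arange(1, config.n_regions + 1), "mean_cc_mm": means}).to_csv(p, index=False)
    artifacts["displacement_regions"] = p.name
    mf = movement_fractions(cc, truth.slice_mask)
    p = out / "movement_fractions.csv"
    pd.DataFrame([mf]).to_csv(p, index=False)
    artifacts["movement_fractions"] = p.name

    manifest = {
        "config": json.loads(config.to_json()),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = "manifest.json"
    _stage("done")
    return manifest
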