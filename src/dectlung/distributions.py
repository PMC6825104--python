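"""Normalized histograms of CT density and material fractions.

Merge-volume densities are counted in 10 HU bins from -1000 to +500 HU
(150 bins); material volume fractions in 1 % bins from 0 to 100 % (100
bins). Counts are normalized to sum to one so distributions from volumes
with different voxel counts can be compared, and paired distributions are
compared with Pearson's product-moment correlation over the common bins.

Bins are left-closed, right-open, with the final bin closed at the upper
edge. HU values outside [-1000, +500] (e.g. dense contrast or metal) are
excluded from normalization and reported separately rather than clamped
into the extreme bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Histogram",
    "hu_bin_edges",
    "fraction_bin_edges",
    "density_histogram",
    "fraction_histogram",
    "distribution_correlation",
    "mean_histogram",
]


def hu_bin_edges() -> np.ndarray:
    """10 HU-wide bin edges from -1000 to +500 (150 bins)."""
    return np.arange(-1000.0, 500.0 + 10.0, 10.0)


def fraction_bin_edges() -> np.ndarray:
    """1 %-wide bin edges from 0 % to 100 % (100 bins)."""
    return np.arange(0.0, 100.0 + 1.0, 1.0)


@dataclass
class Histogram:
    """A normalized histogram plus out-of-range voxel accounting."""

    edges: np.ndarray
    weights: np.ndarray
    n_masked: int
    n_out_of_range: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.edges) - 1:
            raise ValueError("weights/edges length mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.weights)


def _histogram(values: np.ndarray, edges: np.ndarray) -> Histogram:
    in_range = (values >= edges[0]) & (values <= edges[-1])
    n_out = int((~in_range).sum())
    counts, _ = np.histogram(values[in_range], bins=edges)
    total = counts.sum()
    weights = counts / total if total > 0 else counts.astype(float)
    return Histogram(edges=edges, weights=weights, n_masked=values.size, n_out_of_range=n_out)


def density_histogram(volume: np.ndarray, mask: np.ndarray) -> Histogram:
    """Normalized CT-density histogram of masked voxels (10 HU bins)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return _histogram(np.asarray(volume, dtype=float)[mask], hu_bin_edges())


def fraction_histogram(f: np.ndarray, mask: np.ndarray) -> Histogram:
    """Normalized volume-fraction histogram of masked voxels (1 % bins).

    ``f`` is a unitless fraction map in [0, 1]; values are binned on the
    percentage scale, with f = 100 % assigned to the last bin.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return _histogram(np.asarray(f, dtype=float)[mask] * 100.0, fraction_bin_edges())


def distribution_correlation(a: Histogram, b: Histogram) -> float:
    """Pearson r between two normalized histograms on identical bins.

    All bins enter the correlation, including shared zeros, as implied by
    the fixed-bin design.
    """
    if a.edges.shape != b.edges.shape or not np.allclose(a.edges, b.edges):
        raise ValueError("histograms have different bin edges")
    if np.ptp(a.weights) == 0 or np.ptp(b.weights) == 0:
        raise ValueError("correlation undefined: a histogram has zero variance")
    r, _ = stats.pearsonr(a.weights, b.weights)
    return float(r)


def mean_histogram(histograms: list[Histogram]) -> Histogram:
    """Mean of already-normalized histograms on shared bins.

    Averaging after per-volume normalization keeps each volume's weight
    equal regardless of its voxel count.
    """
    if not histograms:
        raise ValueError("no histograms to average")
    edges = histograms[0].edges
    for h in histograms[1:]:
        if not np.allclose(h.edges, edges):
            raise ValueError("histograms have different bin edges")
    weights = np.mean([h.weights for h in histograms], axis=0)
    return Histogram(
        edges=edges,
        weights=weights,
        n_masked=sum(h.n_masked for h in histograms),
        n_out_of_range=sum(h.n_out_of_range for h in histograms),
    )
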