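"""Normalized-histogram summary characteristics of scalar maps.

A value collection (e.g. skeletonized white-matter voxel values of one DKI
parameter, or per-instance simulation estimates) is summarized by four
characteristics: the median, the height and location (bin center) of the
tallest bin of a 1000-bin density-normalized histogram, and the peak width
defined as the 95th minus the 5th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HistogramSummary", "normalized_histogram", "summarize",
           "values_from_nifti"]


class DegenerateRangeError(ValueError):
    """All values identical: the histogram range collapses."""


@dataclass(frozen=True)
class HistogramSummary:
    median: float
    peak_height: float
    peak_value: float
    peak_width: float
    n_bins: int
    bin_edges: np.ndarray


def _check_values(values, n_bins: int) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if v.min() == v.max():
        raise DegenerateRangeError("all values identical")
    return v


def normalized_histogram(values, n_bins: int = 1000):
    """Equal-width histogram over [min, max], normalized to unit integral.

    Densities are counts divided by (total count × bin width), so
    Σ density · binwidth = 1.
    """
    v = _check_values(values, n_bins)
    densities, bin_edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()),
                                        density=True)
    return bin_edges, densities


def summarize(values, n_bins: int = 1000) -> HistogramSummary:
    """Median, peak height/value (tallest bin; ties → lowest bin), and
    peak width (p95 − p5, linear-interpolated percentiles)."""
    v = _check_values(values, n_bins)
    bin_edges, densities = normalized_histogram(v, n_bins)
    peak = int(np.argmax(densities))  # argmax returns the first (lowest) bin
    p5, p50, p95 = np.percentile(v, [5, 50, 95])
    return HistogramSummary(
        median=float(p50),
        peak_height=float(densities[peak]),
        peak_value=float((bin_edges[peak] + bin_edges[peak + 1]) / 2.0),
        peak_width=float(p95 - p5),
        n_bins=n_bins,
        bin_edges=bin_edges,
    )


def values_from_nifti(image_path, mask_path=None) -> np.ndarray:
    """Voxel values of a NIfTI scalar map, restricted to mask > 0.

    The mask stands in for any voxel selection (e.g. a white-matter
    skeleton produced upstream).
    """
    import nibabel as nib

    data = np.asarray(nib.load(str(image_path)).dataobj, dtype=float)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj)
        if mask.shape != data.shape:
            raise ValueError("mask and image shapes differ")
        data = data[mask > 0]
    return data.ravel()
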