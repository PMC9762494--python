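"""Grayscale-to-binary segmentation of voxel stacks.

Converts micro-CT-like grayscale volumes to two-phase binaries: mean-filter
smoothing, global thresholding (value > TV -> solid), automatic threshold
selection from the histogram valley between the two phase peaks, calibration
of the threshold against a reference solid-area rate (e.g. measured on a
histological section), cubic region-of-interest cropping, and a
representative-volume-element (RVE) size check based on sub-volume porosity
statistics.

Thresholding polarity is fixed: voxels with grayscale strictly greater than
the threshold TV are labeled solid tissue, the rest pore.  The solid-area
rate of a stack is the mean over transverse (z) slices of the 2D solid-pixel
fraction, which is what a stained section measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMicrostructure, GrayscaleVolume


class UnimodalHistogramError(ValueError):
    """The grayscale histogram has no two separated peaks; pick TV manually."""


def mean_filter_smooth(gray: GrayscaleVolume, radius: int) -> GrayscaleVolume:
    """Cubic mean filter of half-width ``radius`` voxels.

    Each voxel is replaced by the mean of its (2r+1)^3 neighborhood; at the
    volume boundary the neighborhood shrinks to the voxels actually present
    (no padding values are invented), so boundary slices are not biased
    toward any fill value.  ``radius=0`` is the identity.
    """
    if radius < 0 or int(radius) != radius:
        raise ValueError("radius must be a non-negative integer")
    if radius == 0:
        return GrayscaleVolume(gray.values.copy(), gray.voxel_size)
    size = 2 * int(radius) + 1
    vals = gray.values.astype(np.float64)
    summed = ndimage.uniform_filter(vals, size=size, mode="constant", cval=0.0)
    weight = ndimage.uniform_filter(
        np.ones_like(vals), size=size, mode="constant", cval=0.0
    )
    out = summed / weight
    if np.issubdtype(gray.values.dtype, np.integer):
        out = np.rint(out).astype(gray.values.dtype)
    return GrayscaleVolume(out, gray.voxel_size)


def segment_by_threshold(gray: GrayscaleVolume, tv: float) -> BinaryMicrostructure:
    """Global threshold: grayscale value > ``tv`` -> solid, <= ``tv`` -> pore."""
    return BinaryMicrostructure(gray.values > tv, gray.voxel_size, threshold_used=tv)


def _smoothed_histogram(values: np.ndarray, smooth_width: int = 5):
    vmin = int(values.min())
    vmax = int(values.max())
    bins = np.arange(vmin, vmax + 2)
    counts, _ = np.histogram(values, bins=bins)
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    else:
        smoothed = counts.astype(float)
    return bins[:-1], counts, smoothed


def histogram_minimum_threshold(gray: GrayscaleVolume, smooth_width: int = 5) -> int:
    """Threshold at the histogram minimum between the two phase peaks.

    The histogram is smoothed with a moving average (``smooth_width`` bins)
    before peak finding; the two highest distinct local maxima are taken as
    the phase peaks and the bin of minimum smoothed count strictly between
    them is returned (ties resolved toward the lower grayscale).

    Raises :class:`UnimodalHistogramError` when fewer than two separated
    peaks exist (e.g. a constant image), in which case a manual TV is needed.
    """
    levels, _, smoothed = _smoothed_histogram(gray.values.ravel(), smooth_width)
    n = smoothed.size
    if n < 3:
        raise UnimodalHistogramError(
            "histogram spans fewer than 3 levels; set the threshold manually"
        )
    # local maxima (plateau-aware: strictly greater than one side, >= other)
    peaks = []
    for i in range(n):
        left = smoothed[i - 1] if i > 0 else -np.inf
        right = smoothed[i + 1] if i < n - 1 else -np.inf
        if smoothed[i] > left and smoothed[i] >= right:
            peaks.append(i)
    if len(peaks) < 2:
        raise UnimodalHistogramError(
            "histogram is unimodal after smoothing; set the threshold manually"
        )
    peaks.sort(key=lambda i: smoothed[i], reverse=True)
    p1, p2 = sorted(peaks[:2])
    if p2 - p1 < 2:
        raise UnimodalHistogramError(
            "the two highest peaks are adjacent; no valley to search"
        )
    valley = smoothed[p1 + 1 : p2]
    rel = int(np.argmin(valley))  # argmin takes the first (lowest bin) on ties
    return int(levels[p1 + 1 + rel])


def solid_area_rate(binary: BinaryMicrostructure) -> float:
    """Mean per-transverse-slice (z) solid-pixel fraction."""
    return float(binary.solid.mean(axis=(1, 2)).mean())


@dataclass
class CalibrationResult:
    """Threshold calibration against a reference solid-area rate."""

    chosen_tv: float
    achieved_rate: float
    target_rate: float
    area_rate_by_tv: list  # (tv, rate) pairs, for plotting

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(self.area_rate_by_tv, columns=["tv", "area_rate"])


def calibrate_threshold_to_area_rate(
    gray: GrayscaleVolume, target_rate: float, tv_candidates
) -> CalibrationResult:
    """Choose the threshold whose solid-area rate best matches a reference.

    For every candidate TV the stack is segmented and its mean per-slice
    solid fraction computed; the TV minimizing |rate - target_rate| is
    chosen (lowest TV on ties).  The full (TV, rate) table is returned so
    the rate-vs-threshold curve can be plotted and inspected.
    """
    if not (0.0 < target_rate < 1.0) and target_rate != 0.0 and target_rate != 1.0:
        raise ValueError("target_rate must be within [0, 1]")
    tvs = sorted(tv_candidates)
    if not tvs:
        raise ValueError("need at least one candidate threshold")
    table = []
    for tv in tvs:
        rate = solid_area_rate(segment_by_threshold(gray, tv))
        table.append((tv, rate))
    best_tv, best_rate = min(table, key=lambda tr: (abs(tr[1] - target_rate), tr[0]))
    return CalibrationResult(
        chosen_tv=best_tv,
        achieved_rate=best_rate,
        target_rate=target_rate,
        area_rate_by_tv=table,
    )


def crop_cubic_roi(vol, origin: tuple, edge: int):
    """Cubic subvolume of side ``edge`` voxels starting at ``origin`` (z, y, x).

    Works on grayscale and binary volumes alike; the voxel size is preserved.
    Rejects out-of-bounds requests naming the offending axis.
    """
    if edge <= 0:
        raise ValueError("edge must be positive")
    arr = vol.values if isinstance(vol, GrayscaleVolume) else vol.solid
    for ax, (o, n) in enumerate(zip(origin, arr.shape)):
        if o < 0 or o + edge > n:
            raise ValueError(
                f"ROI [{o}, {o + edge}) exceeds volume extent {n} along axis "
                f"{'zyx'[ax]}"
            )
    sl = tuple(slice(o, o + edge) for o in origin)
    if isinstance(vol, GrayscaleVolume):
        return GrayscaleVolume(arr[sl].copy(), vol.voxel_size)
    return BinaryMicrostructure(
        arr[sl].copy(), vol.voxel_size, threshold_used=vol.threshold_used
    )


@dataclass
class RVEReport:
    """Porosity convergence of cubic sub-volumes of increasing edge size."""

    edge_sizes: list
    porosity_mean: list
    porosity_sd: list
    recommended_edge: int | None  # None -> not converged
    sd_tol: float
    mean_tol: float


def assess_rve_convergence(
    binary: BinaryMicrostructure,
    edge_sizes,
    n_positions: int = 10,
    seed: int = 0,
    sd_tol: float = 0.01,
    mean_tol: float = 0.01,
) -> RVEReport:
    """Representative-volume-element size check from sub-cube porosity.

    For each candidate edge size, ``n_positions`` random cubic sub-volumes
    are sampled and their porosities pooled.  The recommended RVE edge is
    the smallest one whose porosity SD is <= ``sd_tol`` and whose mean is
    within ``mean_tol`` of the largest edge's mean; ``recommended_edge`` is
    None when no candidate satisfies the criterion.
    """
    edges = sorted(int(e) for e in edge_sizes)
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    shape = binary.shape
    if edges[-1] > min(shape):
        raise ValueError("largest edge exceeds the volume extent")
    rng = np.random.default_rng(seed)
    pore = binary.pore
    means, sds = [], []
    for edge in edges:
        phis = []
        for _ in range(n_positions):
            origin = [rng.integers(0, n - edge + 1) for n in shape]
            sub = pore[tuple(slice(o, o + edge) for o in origin)]
            phis.append(float(sub.mean()))
        means.append(float(np.mean(phis)))
        sds.append(float(np.std(phis)))
    ref_mean = means[-1]
    recommended = None
    for edge, m, s in zip(edges, means, sds):
        if s <= sd_tol and abs(m - ref_mean) <= mean_tol:
            recommended = edge
            break
    return RVEReport(
        edge_sizes=edges,
        porosity_mean=means,
        porosity_sd=sds,
        recommended_edge=recommended,
        sd_tol=sd_tol,
        mean_tol=mean_tol,
    )
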