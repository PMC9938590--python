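"""Reference-point binned signal matrices and meta-profiles around peaks.

For each region the reference point is the interval midpoint (floor for
even lengths); the window ``[midpoint - flank, midpoint + flank)`` is split
into fixed-size bins and each bin takes the coverage-weighted mean of the
signal over its bases (bases beyond chromosome ends, or with no signal
line, contribute 0). Defaults — 2 kb flanks with 5 bp bins, a 4 kb window —
match common practice for ChIP-seq binding profiles. The meta-profile
(column mean) is classified as flat, unimodal or bimodal from its smoothed
local maxima: a bait flanking a factor's sites from adjacent divergent
promoters shows two symmetric maxima, a coincident factor a single central
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ValidationError
from .genome import PeakSet, SignalTrack


@dataclass
class ProfileMatrix:
    """Region x bin matrix of mean signal around region midpoints."""

    regions: PeakSet
    flank: int
    bin_size: int
    values: np.ndarray
    sort_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sort_order is None:
            self.sort_order = np.arange(len(self.regions))
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_offsets(self) -> np.ndarray:
        """Offset (bp) of each bin center relative to the reference point."""
        return -self.flank + (np.arange(self.n_bins) + 0.5) * self.bin_size


def compute_matrix(signal: SignalTrack, regions: PeakSet,
                   flank: int = 2000, bin_size: int = 5) -> ProfileMatrix:
    """Binned signal around each region midpoint.

    Bin values are exact coverage-weighted means computed from the track's
    prefix integral, so the result is invariant to bedGraph line order and
    to splitting a constant run into multiple lines.
    """
    if flank <= 0 or bin_size <= 0:
        raise ValidationError("flank and bin_size must be positive")
    if flank % bin_size != 0:
        raise ValidationError(
            f"flank {flank} is not divisible by bin_size {bin_size}"
        )
    n_bins = 2 * flank // bin_size
    n_regions = len(regions)
    values = np.zeros((n_regions, n_bins))
    mids = regions.midpoints
    chroms = regions.chroms.astype(str)
    rel_edges = np.arange(n_bins + 1) * bin_size - flank
    for chrom in sorted(set(chroms)):
        sel = np.where(chroms == chrom)[0]
        edges = mids[sel][:, None] + rel_edges[None, :]
        F = signal.integral(chrom, edges.ravel().astype(float))
        F = F.reshape(len(sel), n_bins + 1)
        values[sel] = np.diff(F, axis=1) / bin_size
    return ProfileMatrix(regions=regions, flank=flank, bin_size=bin_size,
                         values=values)


@dataclass
class ProfileSummary:
    mean_profile: np.ndarray
    smoothed: np.ndarray
    bin_offsets: np.ndarray
    shape: str                      # flat | unimodal | bimodal
    peak_offsets_bp: np.ndarray     # bin-center offsets of detected maxima
    baseline: float


def summarize_profile(matrix: ProfileMatrix, smooth_bins: int = 5,
                      prominence: float = 0.5) -> ProfileSummary:
    """Column-mean meta-profile plus a peak-shape classification.

    The mean profile is smoothed with a centered moving average of
    ``smooth_bins`` bins; maxima (plateau-aware) must rise ``prominence``
    signal units above the flat baseline (the smoothed profile's median)
    to count. 0 qualifying maxima -> flat, 1 -> unimodal, >= 2 -> bimodal.
    The heuristic's parameters are deliberately exposed: bimodality is a
    qualitative judgement and the defaults suit peak-over-background
    tracks with O(1)-unit contrast.
    """
    if matrix.values.size == 0:
        raise ValidationError("cannot summarize an empty profile matrix")
    mean_profile = matrix.values.mean(axis=0)
    w = max(1, int(smooth_bins))
    kernel = np.ones(w) / w
    smoothed = np.convolve(mean_profile, kernel, mode="same")
    baseline = float(np.median(smoothed))
    peaks, _ = find_peaks(smoothed, height=baseline + prominence,
                          prominence=prominence)
    if len(peaks) == 0:
        shape = "flat"
    elif len(peaks) == 1:
        shape = "unimodal"
    else:
        shape = "bimodal"
    return ProfileSummary(
        mean_profile=mean_profile, smoothed=smoothed,
        bin_offsets=matrix.bin_offsets, shape=shape,
        peak_offsets_bp=matrix.bin_offsets[peaks], baseline=baseline,
    )


def sort_regions(matrix: ProfileMatrix, by: str = "mean_signal"
                 ) -> ProfileMatrix:
    """Reorder matrix rows (descending mean signal, or original order).

    The sort is stable, the row multiset is unchanged and the applied
    order is recorded in ``sort_order``.
    """
    if by == "mean_signal":
        order = np.argsort(-matrix.values.mean(axis=1), kind="stable")
    elif by == "region_order":
        order = np.arange(len(matrix.regions))
    else:
        raise ValidationError(f"unknown sort key {by!r}")
    regions = PeakSet(matrix.regions.chroms[order],
                      matrix.regions.starts[order],
                      matrix.regions.ends[order],
                      label=matrix.regions.label)
    return ProfileMatrix(regions=regions, flank=matrix.flank,
                         bin_size=matrix.bin_size,
                         values=matrix.values[order],
                         sort_order=order)
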