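"""Log-spaced, per-cell-averaged intensity histograms and their local maxima.

Each (donor, inducer) condition contributes one *curve*: intensity densities
from all of its cells are binned into ``n_bins`` (default 30,000) log-spaced
intervals and counts are averaged across cells, giving counts per bin per
cell.  On log-log axes these curves are multimodal; each local maximum
(detected by prominence and minimum distance on the raw curve) marks a
lysosomal subpopulation, and its position ``log10(X_peak)`` feeds the peak
statistics stage.

Log spacing cannot start at zero, so the lower edge sits just below the
smallest positive observed value and zero-valued events are excluded (their
count is retained on the profile for audit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .errors import DegenerateInputError

__all__ = ["HistogramProfile", "PeakSet", "build_profile", "detect_peaks"]

#: relative margin placing the lower bin edge just below the smallest
#: positive event so that every positive event falls inside a bin
_LOWER_MARGIN = 1e-6


@dataclass(frozen=True)
class HistogramProfile:
    """Log-spaced histogram averaged across cells (counts per bin per cell)."""

    bin_edges: np.ndarray  # n_bins + 1 strictly increasing edges, a.u./µm²
    mean_counts: np.ndarray  # length n_bins
    n_cells: int
    n_zero_excluded: int = 0
    curve_id: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.mean_counts)

    @property
    def log10_centres(self) -> np.ndarray:
        """Bin centres on the log10 intensity axis (geometric midpoints)."""
        log_edges = np.log10(self.bin_edges)
        return 0.5 * (log_edges[:-1] + log_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "mean_count": self.mean_counts,
        })


@dataclass(frozen=True)
class PeakSet:
    """Ordered local maxima of one curve.

    ``positions`` are log10(X_peak) values, strictly increasing; ``peak_ids``
    are ordinals starting at 1.
    """

    curve_id: str
    positions: np.ndarray
    prominences: np.ndarray
    peak_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "prominences",
                           np.asarray(self.prominences, dtype=float))
        if self.peak_ids is None:
            object.__setattr__(self, "peak_ids",
                               np.arange(1, len(positions) + 1))
        if len(positions) > 1 and not np.all(np.diff(positions) > 0):
            raise ValueError("peak positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "curve_id": self.curve_id,
            "peak_id": self.peak_ids,
            "log10_position": self.positions,
            "prominence": self.prominences,
        })


def build_profile(cells: Sequence[np.ndarray] | Iterable[np.ndarray],
                  n_bins: int = 30_000,
                  curve_id: str = "") -> HistogramProfile:
    """Bin per-cell intensity values into a shared log-spaced histogram.

    ``cells`` is a sequence of 1-D arrays, one per cell (per-pixel densities
    for the lysosomal arm, or length-1 arrays of per-cell mean densities for
    the mitochondrial arm).  Counts are pooled then divided by the number of
    cells, which equals the per-cell average because every cell shares the
    same bin edges.
    """
    cells = [np.asarray(c, dtype=float).ravel() for c in cells]
    if len(cells) == 0:
        raise DegenerateInputError("no cells supplied")
    pooled = np.concatenate(cells) if len(cells) > 1 else cells[0]
    positive = pooled[pooled > 0]
    n_zero = int(pooled.size - positive.size)
    if positive.size == 0:
        raise DegenerateInputError("no strictly positive intensity values")

    lo = positive.min() * (1.0 - _LOWER_MARGIN)
    hi = positive.max()
    if not hi > lo:  # all values identical up to the margin
        hi = lo * (1.0 + 2 * _LOWER_MARGIN)
    edges = np.geomspace(lo, hi, n_bins + 1)
    # geomspace end points are exact; guard rounding in between
    edges[0], edges[-1] = lo, max(hi, positive.max())
    counts, _ = np.histogram(positive, bins=edges)
    return HistogramProfile(
        bin_edges=edges,
        mean_counts=counts / len(cells),
        n_cells=len(cells),
        n_zero_excluded=n_zero,
        curve_id=curve_id,
    )


def detect_peaks(profile: HistogramProfile,
                 prominence: float | None = None,
                 min_distance: int | None = None,
                 smooth_window: int | None = None) -> PeakSet:
    """Local maxima of ``mean_counts`` by prominence and minimum distance.

    Defaults: prominence = 2% of the curve maximum; minimum distance = 1% of
    the bin count.  ``smooth_window`` (bins) applies a moving average before
    detection; by default the raw curve is used.  Plateaus resolve to their
    left-most bin.  Positions are bin centres on the log10 intensity axis,
    ascending, with ordinal ``peak_id`` starting at 1.
    """
    counts = np.asarray(profile.mean_counts, dtype=float)
    if smooth_window is not None and smooth_window > 1:
        counts = uniform_filter1d(counts, size=int(smooth_window), mode="nearest")
    if min_distance is None:
        min_distance = max(1, round(0.01 * profile.n_bins))
    if prominence is None:
        prominence = 0.02 * counts.max() if counts.max() > 0 else 0.0

    if counts.max() == counts.min():  # flat profile: no local maxima
        return PeakSet(curve_id=profile.curve_id, positions=np.empty(0),
                       prominences=np.empty(0))

    indices, props = signal.find_peaks(
        counts,
        prominence=max(prominence, np.finfo(float).tiny),
        distance=max(1, int(min_distance)),
        plateau_size=(1, None),
    )
    # left-most bin of a maximal plateau is the reported peak
    left = props["left_edges"]
    order = np.argsort(left)
    positions = profile.log10_centres[left[order]]
    return PeakSet(
        curve_id=profile.curve_id,
        positions=positions,
        prominences=props["prominences"][order],
    )
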