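"""Numeric substrate of boundary detection.

Cubic-spline smoothing, histogram-mode background estimation with
downstream windows, background correction, ratio derivatives and local
minimum finding, all operating on a gene's concatenated intron-bin vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import peak_prominences

__all__ = [
    "SmoothingSpec",
    "BackgroundTrack",
    "smooth",
    "mode_estimate",
    "background_track",
    "background_correct",
    "ratio_derivative",
    "local_minima",
]

#: minimum number of downstream bins for a direct background estimate
MIN_BG_WINDOW = 10


@dataclass(frozen=True)
class SmoothingSpec:
    """Smoothing and pseudocount parameters.

    ``smoothing_param`` is the classic cubic-smoothing-spline weight *p* in
    the objective ``p * sum(residual^2) + (1 - p) * integral(f'')^2`` over
    the concatenated intron-bin index; ``p -> 1`` interpolates, ``p -> 0``
    tends to the least-squares line.  Other spline parameterizations rescale
    this value.  ``pseudocount_zero`` is added to every 0-min bin before the
    smoothing that produces the ratio denominator, keeping it strictly
    positive.
    """

    smoothing_param: float = 1e-5
    pseudocount_zero: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.smoothing_param <= 1.0):
            raise ValueError("smoothing_param must be in (0, 1]")
        if self.pseudocount_zero <= 0:
            raise ValueError("pseudocount_zero must be positive")

    @property
    def lam(self) -> float:
        """Equivalent penalty weight for the residual-unweighted objective."""
        return (1.0 - self.smoothing_param) / self.smoothing_param


@dataclass
class BackgroundTrack:
    """Per-bin background estimate (same length as the signal)."""

    estimate: np.ndarray
    method: str = "downstream-mode"

    def __post_init__(self) -> None:
        self.estimate = np.asarray(self.estimate, dtype=float)


def smooth(values: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    """Cubic smoothing spline evaluated at the input abscissae.

    The abscissa is the concatenated intron-bin index (equally spaced), not
    the genomic coordinate; boundary positions are mapped back to genomic
    offsets afterwards.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 4:
        raise ValueError("too short to smooth (need at least 4 bins)")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values cannot be smoothed")
    x = np.arange(y.size, dtype=float)
    if spec.smoothing_param >= 1.0:
        return y.copy()
    return make_smoothing_spline(x, y, lam=spec.lam)(x)


def mode_estimate(values: np.ndarray) -> float:
    """Center of the highest-count histogram bin (ties toward the lower bin).

    The histogram uses ``ceil(sqrt(n))`` equal-width bins over the data
    range, a scale-free rule that is stable for the 10-500-value windows
    background estimation operates on.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mode of empty vector")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 1e-9 * max(1.0, abs(lo), abs(hi)):
        return lo
    n_bins = int(np.ceil(np.sqrt(v.size)))
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    i = int(np.argmax(counts))  # argmax returns the first (lowest) tie
    return float(0.5 * (edges[i] + edges[i + 1]))


def background_track(values: np.ndarray) -> BackgroundTrack:
    """Background level per bin, estimated from the bins downstream of it.

    For bin *i* the estimate is the histogram mode of ``values[i+1:]``.
    The final bins, with fewer than ``MIN_BG_WINDOW`` downstream values,
    inherit the nearest upstream estimate; degenerate (very short) signals
    get a constant track from the whole vector's mode.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return BackgroundTrack(np.empty(0))
    est = np.empty(n)
    current = None
    for i in range(n):
        downstream = v[i + 1:]
        if downstream.size >= MIN_BG_WINDOW:
            current = mode_estimate(downstream)
        elif current is None:
            current = mode_estimate(v)
        est[i] = current
    return BackgroundTrack(est)


def background_correct(values: np.ndarray, bg: BackgroundTrack) -> np.ndarray:
    """Element-wise ``values - background``, floored at 0."""
    v = np.asarray(values, dtype=float)
    if v.shape != bg.estimate.shape:
        raise ValueError("signal and background track have different lengths")
    return np.maximum(0.0, v - bg.estimate)


def ratio_derivative(sample: np.ndarray, zero: np.ndarray) -> np.ndarray:
    """First difference of the sample/zero ratio.

    ``zero`` is the smoothed, pseudocounted 0-min profile and must be
    strictly positive; output ``d[i] = r[i+1] - r[i]`` has length ``n - 1``.
    """
    s = np.asarray(sample, dtype=float)
    z = np.asarray(zero, dtype=float)
    if s.shape != z.shape:
        raise ValueError("sample and zero profiles have different lengths")
    if np.any(z <= 0):
        raise ValueError("zero profile must be strictly positive (pseudocount contract)")
    return np.diff(s / z)


def local_minima(
    values: np.ndarray,
    depth_threshold: float,
    prominence: float = 0.0,
) -> np.ndarray:
    """Indices of strict local minima deeper than ``depth_threshold``.

    With ``prominence == 0`` this is a pure sign-change detector; a positive
    prominence additionally requires the dip to stand out from its
    surroundings by that amount.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return np.empty(0, dtype=int)
    interior = np.arange(1, v.size - 1)
    strict = (v[1:-1] < v[:-2]) & (v[1:-1] < v[2:])
    idx = interior[strict & (v[1:-1] < depth_threshold)]
    if prominence > 0 and idx.size:
        prom = peak_prominences(-v, idx)[0]
        idx = idx[prom >= prominence]
    return idx
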