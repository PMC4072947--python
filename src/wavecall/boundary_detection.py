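"""Per-gene, per-sample transcription-wave front location.

Two sequential steps against the averaged 0-min reference:

1. *Rough estimate* — the first bin past TSS + 2.5 Kb where the
   background-corrected sample signal has dropped back to the 0-min level
   (within a 10% relative tolerance).  A hit at the very first eligible
   position, or no hit at all, yields no boundary.
2. *Refinement* — on the derivative of the sample/0-min ratio, find the
   most downstream sufficiently deep local minimum upstream of the rough
   estimate, then the point where the decline has leveled off (derivative
   back above -0.002).  The refined front is placed between that last dip
   and the plateau onset; if no usable dip exists the rough estimate stands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_io import IntronSignal
from .signal_model import (
    SmoothingSpec,
    background_correct,
    background_track,
    local_minima,
    ratio_derivative,
    smooth,
)

__all__ = [
    "BoundaryCall",
    "ZeroProfile",
    "average_zero_profile",
    "rough_boundary",
    "refine_boundary",
    "call_boundary",
]

START_OFFSET_KB = 2.5
ROUGH_TOLERANCE = 0.10
MIN_DERIVATIVE = -0.01
ZERO_DERIVATIVE = -0.002
REFINE_WINDOW_KB = 2.0


@dataclass
class BoundaryCall:
    """Rough and refined wave-front positions for one gene in one sample."""

    gene_id: str
    timepoint_min: int
    replicate: int
    rough_kb: float | None
    refined_kb: float | None
    status: str  # ok | no-boundary | first-position | refine-fallback

    @property
    def position_kb(self) -> float | None:
        """The position used downstream (refined, falling back to rough)."""
        return self.refined_kb if self.refined_kb is not None else self.rough_kb


@dataclass
class ZeroProfile:
    """Averaged 0-min reference profile for one gene.

    ``corrected`` is the smoothed, background-corrected average used in the
    rough comparison; ``denominator`` is the pseudocounted smoothed average
    used to normalize post-release profiles for the derivative step.
    """

    gene_id: str
    offsets_kb: np.ndarray
    raw_mean: np.ndarray
    corrected: np.ndarray
    denominator: np.ndarray
    n_replicates: int


def average_zero_profile(
    zero_signals: list[IntronSignal], spec: SmoothingSpec | None = None
) -> ZeroProfile:
    """Element-wise mean of the 0-min replicates, smoothed both ways.

    All replicates must share the same intron-bin grid.  The mean is
    smoothed once as-is (for background correction and the rough
    comparison) and once after adding the 0.01 pseudocount per bin (the
    strictly positive ratio denominator).
    """
    if not zero_signals:
        raise ValueError("at least one 0-min replicate is required")
    spec = spec or SmoothingSpec()
    first = zero_signals[0]
    for sig in zero_signals[1:]:
        if not np.array_equal(sig.offsets_kb, first.offsets_kb):
            raise ValueError(f"{first.gene_id}: 0-min replicates on mismatched bin grids")
    if len(zero_signals) == 1:
        warnings.warn(
            f"{first.gene_id}: single 0-min replicate; reference profile is unaveraged",
            stacklevel=2,
        )
    raw_mean = np.mean([s.values for s in zero_signals], axis=0)
    smoothed = smooth(raw_mean, spec)
    corrected = background_correct(smoothed, background_track(smoothed))
    denominator = smooth(raw_mean + spec.pseudocount_zero, spec)
    return ZeroProfile(
        gene_id=first.gene_id,
        offsets_kb=first.offsets_kb.copy(),
        raw_mean=raw_mean,
        corrected=corrected,
        denominator=denominator,
        n_replicates=len(zero_signals),
    )


def rough_boundary(
    sample_corrected: np.ndarray,
    zero_corrected: np.ndarray,
    offsets_kb: np.ndarray,
    start_offset_kb: float = START_OFFSET_KB,
    tolerance: float = ROUGH_TOLERANCE,
) -> tuple[int | None, str]:
    """First bin past the start offset where the sample is back at 0-min level.

    Returns ``(bin_index, "ok")``, or ``(None, status)`` when the very first
    eligible bin matches (``first-position``: the wave is not distinguishable
    from the start offset) or no bin matches (``no-boundary``).
    """
    eligible = np.nonzero(offsets_kb >= start_offset_kb)[0]
    if eligible.size == 0:
        return None, "no-boundary"
    hit = eligible[sample_corrected[eligible] <= (1.0 + tolerance) * zero_corrected[eligible]]
    if hit.size == 0:
        return None, "no-boundary"
    if hit[0] == eligible[0]:
        return None, "first-position"
    return int(hit[0]), "ok"


def refine_boundary(
    deriv: np.ndarray,
    rough_idx: int,
    offsets_kb: np.ndarray,
    min_threshold: float = MIN_DERIVATIVE,
    zero_threshold: float = ZERO_DERIVATIVE,
    window_kb: float = REFINE_WINDOW_KB,
    mode: str = "midpoint",
    prominence: float = 0.0,
) -> tuple[int, str]:
    """Sharpen the rough front using the ratio derivative.

    Among local minima of ``deriv`` deeper than ``min_threshold`` and
    upstream of ``rough_idx``, take the most downstream one; scan downstream
    from it (no further than ``window_kb`` past the rough estimate) for the
    first bin whose derivative has recovered to ``zero_threshold`` or above
    — the onset of the plateau.  ``mode="midpoint"`` places the front midway
    between the dip and the plateau onset, compensating the symmetric blur
    the smoothing spline puts on the wave's leading edge; ``mode="plateau"``
    returns the plateau onset itself.  Without a usable dip or plateau the
    rough estimate stands.
    """
    if mode not in ("midpoint", "plateau"):
        raise ValueError(f"unknown refine mode {mode!r}")
    minima = local_minima(deriv, min_threshold, prominence=prominence)
    minima = minima[minima < rough_idx]
    if minima.size == 0:
        return rough_idx, "refine-fallback"
    dip = int(minima[-1])
    limit_kb = offsets_kb[rough_idx] + window_kb
    j_max = int(np.searchsorted(offsets_kb, limit_kb, side="right")) - 1
    j_max = min(j_max, deriv.size - 1)
    candidates = np.nonzero(deriv[dip + 1 : j_max + 1] >= zero_threshold)[0]
    if candidates.size == 0:
        return rough_idx, "refine-fallback"
    plateau = dip + 1 + int(candidates[0])
    if mode == "plateau":
        return plateau, "ok"
    return int(round((dip + plateau) / 2)), "ok"


def call_boundary(
    sample_signal: IntronSignal,
    zero: ZeroProfile,
    spec: SmoothingSpec | None = None,
    timepoint_min: int = 8,
    replicate: int = 1,
    start_offset_kb: float = START_OFFSET_KB,
    tolerance: float = ROUGH_TOLERANCE,
    min_threshold: float = MIN_DERIVATIVE,
    zero_threshold: float = ZERO_DERIVATIVE,
    window_kb: float = REFINE_WINDOW_KB,
    refine_mode: str = "midpoint",
) -> BoundaryCall:
    """Full boundary call for one post-release sample of one gene."""
    spec = spec or SmoothingSpec()
    gid = sample_signal.gene_id

    def _call(rough, refined, status):
        return BoundaryCall(gid, timepoint_min, replicate, rough, refined, status)

    if sample_signal.is_empty or sample_signal.n_bins < 4:
        return _call(None, None, "no-boundary")
    if not np.array_equal(sample_signal.offsets_kb, zero.offsets_kb):
        raise ValueError(f"{gid}: sample and 0-min profiles on mismatched bin grids")
    smoothed = smooth(sample_signal.values, spec)
    corrected = background_correct(smoothed, background_track(smoothed))
    rough_idx, status = rough_boundary(
        corrected, zero.corrected, zero.offsets_kb, start_offset_kb, tolerance
    )
    if rough_idx is None:
        return _call(None, None, status)
    deriv = ratio_derivative(corrected, zero.denominator)
    refined_idx, refine_status = refine_boundary(
        deriv,
        rough_idx,
        zero.offsets_kb,
        min_threshold,
        zero_threshold,
        window_kb,
        mode=refine_mode,
    )
    return _call(
        float(zero.offsets_kb[rough_idx]),
        float(zero.offsets_kb[refined_idx]),
        "ok" if refine_status == "ok" else "refine-fallback",
    )
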