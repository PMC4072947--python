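"""Per-gene elongation rates from replicate boundary calls.

The wave-front position is linearly related to time after release,
``position = V * (t - D)``: an ordinary least-squares fit of the replicate
boundary positions against time gives the elongation rate *V* (slope,
Kb/min) and the delay time *D* (the time-axis intercept, min) — the
apparent lag before elongation effectively resumes.  The fit uses every
replicate point rather than the two per-timepoint means so that replicate
dispersion propagates into the slope's 50% confidence interval, the
quantity the quality filters cut on.  When replicate counts are balanced
the slope equals the averaged-point slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .boundary_detection import BoundaryCall

__all__ = [
    "ElongationRateResult",
    "thompson_tau_filter",
    "fit_rate",
    "qc_filter",
    "results_table",
]

CI_LEVEL = 0.50
MAX_CI_HALF_WIDTH = 0.5  # Kb/min
DELAY_RANGE_MIN = (-1.0, 4.0)
REQUIRED_4MIN = 2
REQUIRED_8MIN = 3


@dataclass
class ElongationRateResult:
    gene_id: str
    rate_kb_per_min: float
    ci_half_width: float
    delay_min: float
    n_4min_used: int
    n_8min_used: int
    outlier_removed: bool
    pass_qc: bool = False
    fail_reason: str = ""


def thompson_tau_filter(
    values: np.ndarray, max_removals: int = 1, alpha: float = 0.05
) -> np.ndarray:
    """Modified Thompson tau rejection of at most one outlier.

    The single most deviant value is removed iff its absolute deviation from
    the mean exceeds ``tau * s``, with ``s`` the sample standard deviation
    and ``tau = t * (n-1) / (sqrt(n) * sqrt(n - 2 + t^2))`` for the
    two-sided t critical value at ``alpha`` with ``n - 2`` degrees of
    freedom.  Vectors shorter than 3 are returned unchanged.
    """
    v = np.asarray(values, dtype=float)
    if max_removals not in (0, 1):
        raise ValueError("at most one removal is supported")
    if v.size < 3:
        if v.size > 0:
            warnings.warn("fewer than 3 values: outlier test not applicable", stacklevel=2)
        return v.copy()
    if max_removals == 0:
        return v.copy()
    s = v.std(ddof=1)
    if s == 0:
        return v.copy()
    n = v.size
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    tau = t_crit * (n - 1) / (np.sqrt(n) * np.sqrt(n - 2 + t_crit**2))
    dev = np.abs(v - v.mean())
    worst = int(np.argmax(dev))
    if dev[worst] > tau * s:
        return np.delete(v, worst)
    return v.copy()


def _positions(calls: list[BoundaryCall], timepoint: int) -> list[float]:
    return [
        c.position_kb
        for c in calls
        if c.timepoint_min == timepoint and c.position_kb is not None
    ]


def fit_rate(calls: list[BoundaryCall], tau_alpha: float = 0.05) -> ElongationRateResult:
    """Fit one gene's boundary positions against time.

    Requires boundaries in both 4-min replicates and in at least three 8-min
    replicates; the 8-min set first passes the Thompson tau filter (at most
    one removal).  Raises ``ValueError`` when replicates are insufficient.
    """
    if not calls:
        raise ValueError("no boundary calls supplied")
    gene_id = calls[0].gene_id
    b4 = _positions(calls, 4)
    b8 = np.asarray(_positions(calls, 8), dtype=float)
    if len(b4) < REQUIRED_4MIN:
        raise ValueError(
            f"{gene_id}: boundaries required in both 4-min replicates (got {len(b4)})"
        )
    if b8.size < REQUIRED_8MIN:
        raise ValueError(
            f"{gene_id}: boundaries required in at least {REQUIRED_8MIN} "
            f"8-min replicates (got {b8.size})"
        )
    b8_kept = thompson_tau_filter(b8, max_removals=1, alpha=tau_alpha)
    t = np.array([4.0] * len(b4) + [8.0] * b8_kept.size)
    y = np.concatenate([np.asarray(b4, dtype=float), b8_kept])
    n = t.size
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    sxx = float(np.sum((t - t.mean()) ** 2))
    dof = n - 2
    se_slope = np.sqrt(float(resid @ resid) / dof / sxx) if dof > 0 else 0.0
    ci_half = float(stats.t.ppf(0.5 + CI_LEVEL / 2.0, dof) * se_slope) if dof > 0 else 0.0
    delay = float(-intercept / slope) if slope != 0 else np.inf
    return ElongationRateResult(
        gene_id=gene_id,
        rate_kb_per_min=float(slope),
        ci_half_width=ci_half,
        delay_min=delay,
        n_4min_used=len(b4),
        n_8min_used=int(b8_kept.size),
        outlier_removed=b8_kept.size < b8.size,
    )


def qc_filter(
    results: list[ElongationRateResult],
    calls_by_gene: dict[str, list[BoundaryCall]],
    max_ci: float = MAX_CI_HALF_WIDTH,
    delay_range: tuple[float, float] = DELAY_RANGE_MIN,
) -> list[ElongationRateResult]:
    """Apply the printed quality rules, annotating every result.

    A gene passes iff its mean 8-min boundary is not below the mean 4-min
    boundary, the slope's 50% CI half-width is at most ``max_ci`` Kb/min,
    the delay time falls in ``delay_range`` and the rate is positive.  All
    genes stay in the table with a pass flag and failure reason.
    """
    lo, hi = delay_range
    for res in results:
        calls = calls_by_gene.get(res.gene_id, [])
        mean4 = np.mean(_positions(calls, 4)) if _positions(calls, 4) else np.nan
        b8 = thompson_tau_filter(np.asarray(_positions(calls, 8), dtype=float))
        mean8 = b8.mean() if b8.size else np.nan
        reasons = []
        if np.isfinite(mean4) and np.isfinite(mean8) and mean8 < mean4:
            reasons.append("8min-mean-below-4min")
        if res.ci_half_width > max_ci:
            reasons.append("ci-too-wide")
        if not (lo <= res.delay_min <= hi):
            reasons.append("delay-out-of-range")
        if res.rate_kb_per_min <= 0:
            reasons.append("nonpositive-rate")
        res.pass_qc = not reasons
        res.fail_reason = ";".join(reasons)
    return results


def results_table(results: list[ElongationRateResult]):
    """Results as a DataFrame mirroring the per-gene rate listing."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "rate_kb_per_min": r.rate_kb_per_min,
                "ci_half_width": r.ci_half_width,
                "delay_min": r.delay_min,
                "n_replicates": r.n_4min_used + r.n_8min_used,
                "outlier_removed": r.outlier_removed,
                "pass_qc": r.pass_qc,
                "fail_reason": r.fail_reason,
            }
            for r in results
        ]
    )
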