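"""End-to-end orchestration: signals -> boundaries -> rates -> initiation.

The pipeline consumes either per-sample intron-signal TSVs (e.g. simulator
output) or per-sample coverage (bedGraph/SAM/BAM) plus a gene annotation,
and produces the boundary, rate, initiation and metagene tables together
with a per-stage attrition log.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import genome_io
from .genome_io import (
    GeneModel,
    IntronSignal,
    SampleSheet,
    eligible_genes,
    read_sample_sheet,
    read_intron_signal_tsv,
)
from .signal_model import SmoothingSpec
from .boundary_detection import (
    BoundaryCall,
    ZeroProfile,
    average_zero_profile,
    call_boundary,
)
from .elongation_rates import fit_rate, qc_filter, results_table
from .initiation_frequency import (
    aggregate_initiation,
    fit_initiation_slope,
    relative_initiation,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "metagene_profile"]


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, defaulted to the printed values."""

    annotation: str | None = None
    samples: str | None = None
    outdir: str | None = None
    bin_size: int = 100
    min_gene_kb_rates: float = 25.0
    min_positive_bins: int = 20
    min_gene_kb_metagene: float = 20.0
    smoothing_param: float = 1e-5
    pseudocount_zero: float = 0.01
    pseudocount_ratio: float = 1.0
    rough_tolerance: float = 0.10
    start_offset_kb: float = 2.5
    min_derivative: float = -0.01
    zero_derivative: float = -0.002
    refine_window_kb: float = 2.0
    refine_mode: str = "midpoint"
    max_ci: float = 0.5
    delay_min_lo: float = -1.0
    delay_max_hi: float = 4.0
    t_total_min: float = 8.0
    exclude_first_kb: float = 0.0
    seed: int = 0

    def smoothing(self) -> SmoothingSpec:
        return SmoothingSpec(self.smoothing_param, self.pseudocount_zero)

    def to_yaml(self, path: str | os.PathLike) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    boundaries: pd.DataFrame
    rates: pd.DataFrame
    initiation: pd.DataFrame
    metagene: pd.DataFrame
    attrition: pd.DataFrame
    zero_profiles: dict[str, ZeroProfile] = field(default_factory=dict)
    calls: dict[str, list[BoundaryCall]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# input loading


def _signals_from_sheet(
    sheet: SampleSheet, base_dir: str, config: PipelineConfig
) -> tuple[dict[tuple[int, int], dict[str, IntronSignal]], dict[str, GeneModel] | None]:
    """Load per-sample signals; from TSVs directly or via coverage + annotation."""
    first = sheet.entries[0].path
    if first.endswith((".tsv", ".txt")):
        samples = {}
        for e in sheet.entries:
            path = e.path if os.path.isabs(e.path) else os.path.join(base_dir, e.path)
            samples[(e.timepoint_min, e.replicate)] = read_intron_signal_tsv(path)
        return samples, None
    if not config.annotation:
        raise ValueError("coverage input requires an annotation file")
    genes = genome_io.load_gene_models(config.annotation)
    gene_map = {g.gene_id: g for g in genes}
    samples = {}
    for e in sheet.entries:
        path = e.path if os.path.isabs(e.path) else os.path.join(base_dir, e.path)
        cov = genome_io.normalize_coverage(
            genome_io.bin_coverage(path, bin_size=config.bin_size)
        )
        samples[(e.timepoint_min, e.replicate)] = {
            g.gene_id: genome_io.extract_intron_signal(g, cov)
            for g in genes
            if g.chrom in cov.values
        }
    return samples, gene_map


def _gene_length_kb(
    gid: str, gene_map: dict[str, GeneModel] | None, sig: IntronSignal
) -> float:
    if gene_map is not None and gid in gene_map:
        return gene_map[gid].length_kb
    if sig.is_empty:
        return 0.0
    return float(sig.offsets_kb[-1]) + 0.1  # span of the intron grid


# ---------------------------------------------------------------------------
# stages


def call_all_boundaries(
    samples: dict[tuple[int, int], dict[str, IntronSignal]],
    gene_ids: list[str],
    config: PipelineConfig,
) -> tuple[dict[str, list[BoundaryCall]], dict[str, ZeroProfile]]:
    spec = config.smoothing()
    zero_keys = sorted(k for k in samples if k[0] == 0)
    if not zero_keys:
        raise ValueError("no 0-min samples: boundary calling requires the 0-min reference")
    post_keys = sorted(k for k in samples if k[0] in (4, 8))
    calls: dict[str, list[BoundaryCall]] = {}
    zeros: dict[str, ZeroProfile] = {}
    for gid in gene_ids:
        zero_sigs = [samples[k][gid] for k in zero_keys if gid in samples[k]]
        if not zero_sigs or zero_sigs[0].is_empty:
            continue
        try:
            zero = average_zero_profile(zero_sigs, spec)
        except ValueError:
            continue
        zeros[gid] = zero
        gene_calls = []
        for timepoint, rep in post_keys:
            sig = samples[(timepoint, rep)].get(gid)
            if sig is None:
                continue
            gene_calls.append(
                call_boundary(
                    sig,
                    zero,
                    spec,
                    timepoint_min=timepoint,
                    replicate=rep,
                    start_offset_kb=config.start_offset_kb,
                    tolerance=config.rough_tolerance,
                    min_threshold=config.min_derivative,
                    zero_threshold=config.zero_derivative,
                    window_kb=config.refine_window_kb,
                    refine_mode=config.refine_mode,
                )
            )
        calls[gid] = gene_calls
    return calls, zeros


def boundaries_table(calls: dict[str, list[BoundaryCall]]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "timepoint_min": c.timepoint_min,
            "replicate": c.replicate,
            "rough_kb": np.nan if c.rough_kb is None else round(c.rough_kb, 1),
            "refined_kb": np.nan if c.refined_kb is None else round(c.refined_kb, 1),
            "status": c.status,
        }
        for gene_calls in calls.values()
        for c in gene_calls
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "timepoint_min", "replicate", "rough_kb", "refined_kb", "status"],
    )


def fit_all_rates(
    calls: dict[str, list[BoundaryCall]], config: PipelineConfig
) -> tuple[pd.DataFrame, dict[str, object], dict[str, str]]:
    results = []
    by_gene = {}
    skipped: dict[str, str] = {}
    for gid, gene_calls in calls.items():
        usable = [c for c in gene_calls if c.position_kb is not None]
        try:
            res = fit_rate(usable)
        except ValueError as exc:
            skipped[gid] = str(exc)
            continue
        results.append(res)
        by_gene[gid] = res
    qc_filter(
        results,
        {gid: [c for c in calls[gid] if c.position_kb is not None] for gid in by_gene},
        max_ci=config.max_ci,
        delay_range=(config.delay_min_lo, config.delay_max_hi),
    )
    return results_table(results), by_gene, skipped


def compute_initiation(
    samples: dict[tuple[int, int], dict[str, IntronSignal]],
    calls: dict[str, list[BoundaryCall]],
    zeros: dict[str, ZeroProfile],
    rates: pd.DataFrame,
    config: PipelineConfig,
    exclude_first_kb: float | None = None,
) -> pd.DataFrame:
    """Per-gene relative initiation frequency over the 8-min replicates.

    Each 8-min replicate is fit within its own refined boundary B; the
    consensus (QC-passing) rate V enters I = b*V/B for all replicates.
    """
    if exclude_first_kb is None:
        exclude_first_kb = config.exclude_first_kb
    passing = rates[rates["pass_qc"]] if "pass_qc" in rates else rates
    v_by_gene = dict(zip(passing["gene_id"], passing["rate_kb_per_min"]))
    rows = []
    for gid, v_rate in v_by_gene.items():
        zero = zeros.get(gid)
        if zero is None:
            continue
        per_rep = []
        for c in calls.get(gid, []):
            if c.timepoint_min != 8 or c.position_kb is None:
                continue
            sig = samples.get((8, c.replicate), {}).get(gid)
            if sig is None:
                continue
            fit = fit_initiation_slope(sig, zero, c.position_kb, exclude_first_kb)
            if fit is None:
                continue
            _, intercept = fit
            per_rep.append(relative_initiation(intercept, v_rate, c.position_kb))
        agg = aggregate_initiation(gid, per_rep)
        if agg is None:
            continue
        rows.append(
            {
                "gene_id": gid,
                "relative_I": agg.relative_I,
                "n_replicates": agg.n_used,
                "outlier_removed": agg.outlier_removed,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "relative_I", "n_replicates", "outlier_removed"])


def metagene_profile(
    samples: dict[tuple[int, int], dict[str, IntronSignal]],
    gene_lengths_kb: dict[str, float],
    min_length_kb: float = 20.0,
    max_offset_kb: float = 60.0,
    bin_kb: float = 0.1,
) -> pd.DataFrame:
    """TSS-anchored average intron signal per timepoint.

    Genes longer than ``min_length_kb`` contribute their intron bins on a
    common offset grid; at each offset the mean is taken over every
    (gene, replicate) observation present there.
    """
    keep = {g for g, L in gene_lengths_kb.items() if L > min_length_kb}
    if not keep:
        raise ValueError("no genes pass the metagene length filter")
    n_grid = int(round(max_offset_kb / bin_kb))
    rows = []
    for timepoint in sorted({t for t, _ in samples}):
        total = np.zeros(n_grid)
        count = np.zeros(n_grid, dtype=int)
        for (t, _), signals in samples.items():
            if t != timepoint:
                continue
            for gid, sig in signals.items():
                if gid not in keep or sig.is_empty:
                    continue
                idx = np.round(sig.offsets_kb / bin_kb).astype(int)
                ok = idx < n_grid
                np.add.at(total, idx[ok], sig.values[ok])
                np.add.at(count, idx[ok], 1)
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        offs = np.arange(n_grid) * bin_kb
        rows.append(
            pd.DataFrame(
                {"timepoint_min": timepoint, "offset_kb": offs, "mean_signal": mean,
                 "n_obs": count}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# driver


def run_pipeline(
    config: PipelineConfig,
    samples: dict[tuple[int, int], dict[str, IntronSignal]] | None = None,
    gene_map: dict[str, GeneModel] | None = None,
) -> PipelineResult:
    """Run every stage; deterministic given config and inputs.

    ``samples`` may be supplied directly (e.g. from the simulator); otherwise
    they are loaded per the config's sample sheet.
    """
    if samples is None:
        if not config.samples:
            raise ValueError("config.samples (sample sheet) is required")
        sheet = read_sample_sheet(config.samples)
        sheet.require_zero()
        samples, gene_map = _signals_from_sheet(
            sheet, os.path.dirname(os.path.abspath(config.samples)), config
        )

    zero_keys = [k for k in samples if k[0] == 0]
    if not zero_keys:
        raise ValueError("no 0-min samples present")
    n4 = sum(1 for k in samples if k[0] == 4)
    n8 = sum(1 for k in samples if k[0] == 8)
    if n4 < 2 or n8 < 3:
        raise ValueError(
            "replicate design requires boundaries in both of the 2 4-min samples "
            f"and at least 3 of the 8-min samples (got {n4} 4-min, {n8} 8-min files)"
        )

    all_gene_ids = sorted({gid for sigs in samples.values() for gid in sigs})
    # eligibility on the averaged 0-min profile
    zero_mean: dict[str, IntronSignal] = {}
    for gid in all_gene_ids:
        sigs = [samples[k][gid] for k in zero_keys if gid in samples[k]]
        sigs = [s for s in sigs if not s.is_empty]
        if not sigs:
            continue
        zero_mean[gid] = IntronSignal(
            gid, sigs[0].offsets_kb, np.mean([s.values for s in sigs], axis=0)
        )
    lengths = {
        gid: _gene_length_kb(gid, gene_map, sig) for gid, sig in zero_mean.items()
    }
    pseudo_models = [
        gene_map[gid]
        if gene_map is not None and gid in gene_map
        else GeneModel(gid, "chrS", "+", 0, int(lengths[gid] * 1000) or 1, ())
        for gid in zero_mean
    ]
    eligible = eligible_genes(
        pseudo_models,
        zero_mean,
        min_length_kb=config.min_gene_kb_rates,
        min_positive_bins=config.min_positive_bins,
    )

    calls, zeros = call_all_boundaries(samples, eligible, config)
    bounds_df = boundaries_table(calls)
    rates_df, fitted, skipped = fit_all_rates(calls, config)
    init_df = compute_initiation(samples, calls, zeros, rates_df, config)
    meta_df = metagene_profile(
        samples, lengths, min_length_kb=config.min_gene_kb_metagene
    )

    n_called = bounds_df[bounds_df["status"].isin(["ok", "refine-fallback"])][
        "gene_id"
    ].nunique() if not bounds_df.empty else 0
    attrition = pd.DataFrame(
        [
            {"stage": "input_genes", "count": len(all_gene_ids)},
            {"stage": "with_zero_profile", "count": len(zero_mean)},
            {"stage": "eligible", "count": len(eligible)},
            {"stage": "with_boundary", "count": n_called},
            {"stage": "rate_fitted", "count": len(fitted)},
            {"stage": "rate_pass_qc", "count": int(rates_df["pass_qc"].sum()) if not rates_df.empty else 0},
            {"stage": "initiation", "count": len(init_df)},
        ]
    )

    result = PipelineResult(
        boundaries=bounds_df,
        rates=rates_df,
        initiation=init_df,
        metagene=meta_df,
        attrition=attrition,
        zero_profiles=zeros,
        calls=calls,
    )
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        fmt = {"sep": "\t", "index": False, "float_format": "%.6g"}
        bounds_df.to_csv(os.path.join(config.outdir, "boundaries.tsv"), **fmt)
        rates_df.to_csv(os.path.join(config.outdir, "rates.tsv"), **fmt)
        init_df.to_csv(os.path.join(config.outdir, "initiation.tsv"), **fmt)
        meta_df.to_csv(os.path.join(config.outdir, "metagene.tsv"), **fmt)
        attrition.to_csv(os.path.join(config.outdir, "attrition.tsv"), **fmt)
        config.to_yaml(os.path.join(config.outdir, "config.yaml"))
    return result
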