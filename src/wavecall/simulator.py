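"""Generative model for multi-sample nascent-RNA intron coverage.

Each gene's expected intron signal at time *t* after release of the
elongation block is a truncated triangular wave riding on a leaky-inhibition
background:

    mu(x) = bg_mean + I * max(0, t - D - x / V)

with initiation frequency *I* (signal units/min), elongation rate *V*
(Kb/min), delay *D* (min) and offset *x* (Kb from the TSS).  Realized bin
values are drawn from an over-dispersed count distribution with mean ``mu``
and variance ``mu + mu^2 / k`` (gamma-Poisson mixture); an infinite
dispersion ``k`` yields the deterministic, noiseless wave itself.  0-min
samples contain background only; exon bins additionally carry a
steady-state mature-mRNA contamination term so that exon masking is
exercised end to end.

The default parameter distributions are the cohort conditions used
throughout the test-suite and acceptance checks; the replicate design is
four 0-min, two 4-min and four 8-min samples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GeneModel, IntronSignal

__all__ = [
    "SimGeneParams",
    "SimTruth",
    "CohortDesign",
    "simulate_gene",
    "simulate_cohort",
    "write_cohort",
    "REPLICATE_DESIGN",
]

BIN_KB = 0.1
T_TOTAL_MIN = 8.0
#: samples per timepoint: four 0-min, two 4-min, four 8-min
REPLICATE_DESIGN = {0: 4, 4: 2, 8: 4}


@dataclass(frozen=True)
class SimGeneParams:
    """Generative parameters of one simulated gene."""

    gene_id: str
    length_kb: float
    I_true: float
    V_true: float
    D_true: float
    bg_mean: float = 0.3
    bg_dispersion: float = 2.0
    intron_fraction: float = 0.97
    exon_leak: float = 1.0

    def __post_init__(self) -> None:
        if self.V_true <= 0 or self.D_true < 0 or self.bg_mean < 0:
            raise ValueError(f"{self.gene_id}: invalid generative parameters")
        if not (0.0 < self.intron_fraction <= 1.0):
            raise ValueError(f"{self.gene_id}: intron_fraction must be in (0, 1]")

    def front_kb(self, timepoint_min: float) -> float:
        """Wave-front position V*(t - D), clipped to the gene."""
        return float(np.clip(self.V_true * (timepoint_min - self.D_true), 0.0, self.length_kb))

    def expected_signal(self, offsets_kb: np.ndarray, timepoint_min: float) -> np.ndarray:
        x = np.asarray(offsets_kb, dtype=float)
        return self.bg_mean + self.I_true * np.maximum(
            0.0, timepoint_min - self.D_true - x / self.V_true
        )


@dataclass
class SimTruth:
    """Per-gene generative parameters plus derived front positions."""

    table: pd.DataFrame

    @classmethod
    def from_params(cls, params: list[SimGeneParams]) -> "SimTruth":
        rows = [
            {
                "gene_id": p.gene_id,
                "length_kb": p.length_kb,
                "I_true": p.I_true,
                "V_true": p.V_true,
                "D_true": p.D_true,
                "bg_mean": p.bg_mean,
                "bg_dispersion": p.bg_dispersion,
                "front_4min_kb": p.front_kb(4),
                "front_8min_kb": p.front_kb(8),
            }
            for p in params
        ]
        return cls(pd.DataFrame(rows))


@dataclass(frozen=True)
class CohortDesign:
    """Parameter distributions for a simulated cohort.

    Elongation rates are uniform on 2-6 Kb/min (the range the method is
    meant to resolve); delays up to 2 min; initiation frequencies and the
    leaky-inhibition background are set so that the wave stands clearly
    above, but is not free of, over-dispersed count noise.
    """

    v_range: tuple[float, float] = (2.0, 6.0)
    d_range: tuple[float, float] = (0.0, 2.0)
    i_range: tuple[float, float] = (0.5, 4.0)
    length_range_kb: tuple[float, float] = (55.0, 120.0)
    bg_mean: float = 0.3
    bg_dispersion: float = 2.0
    replicate_design: dict[int, int] = field(
        default_factory=lambda: dict(REPLICATE_DESIGN)
    )


def _overdispersed_counts(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    """Gamma-Poisson draws with mean mu and variance mu + mu^2/k."""
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(k):
        return mu.copy()
    lam = np.where(mu > 0, rng.gamma(k, np.maximum(mu, 1e-300) / k), 0.0)
    return rng.poisson(lam).astype(float)


def _gene_model(params: SimGeneParams, chrom: str = "chrS", offset_bp: int = 0) -> GeneModel:
    """Synthetic exon/intron structure: short exons evenly spread over the gene."""
    length_bp = int(round(params.length_kb * 1000))
    exon_bp = max(200, int(round((1.0 - params.intron_fraction) * length_bp)))
    n_exons = max(2, exon_bp // 200)
    exon_len = 200
    positions = np.linspace(0, length_bp - exon_len, n_exons).astype(int)
    # snap away from bin boundaries is unnecessary; exon-overlapping bins are masked
    exons = tuple(
        (offset_bp + int(p), offset_bp + int(p) + exon_len) for p in positions
    )
    return GeneModel(
        gene_id=params.gene_id,
        chrom=chrom,
        strand="+",
        tss=offset_bp,
        tes=offset_bp + length_bp,
        exons=exons,
    )


def simulate_gene(
    params: SimGeneParams,
    timepoint_min: float,
    rng: np.random.Generator | int,
    full_profile: bool = False,
) -> IntronSignal | tuple[IntronSignal, np.ndarray, GeneModel]:
    """One sample's intron signal for one gene.

    With ``full_profile`` the complete per-bin vector (exon bins included,
    with mature-mRNA leakage added) and the synthetic gene model are also
    returned, for exercising the coverage-extraction path.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_bins = int(round(params.length_kb / BIN_KB))
    offsets = np.arange(n_bins) * BIN_KB
    mu = params.expected_signal(offsets, timepoint_min)
    values = _overdispersed_counts(rng, mu, params.bg_dispersion)

    gene = _gene_model(params)
    starts = (offsets * 1000).astype(int)
    ends = starts + int(BIN_KB * 1000)
    exonic = np.zeros(n_bins, dtype=bool)
    for es, ee in gene.exons:
        exonic |= (starts < ee) & (es < ends)

    if full_profile:
        full = values.copy()
        steady = params.exon_leak * params.I_true * T_TOTAL_MIN
        full[exonic] += _overdispersed_counts(
            rng, np.full(int(exonic.sum()), steady), params.bg_dispersion
        )
        sig = IntronSignal(params.gene_id, offsets[~exonic], values[~exonic])
        return sig, full, gene
    return IntronSignal(params.gene_id, offsets[~exonic], values[~exonic])


def simulate_cohort(
    n_genes: int,
    seed: int,
    design: CohortDesign | None = None,
    noiseless: bool = False,
) -> tuple[dict[tuple[int, int], dict[str, IntronSignal]], SimTruth]:
    """Draw a cohort of genes and all replicate samples.

    Returns ``(samples, truth)`` where ``samples[(timepoint, replicate)]``
    maps gene ids to intron signals.  Fully reproducible from ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    params = []
    for g in range(n_genes):
        params.append(
            SimGeneParams(
                gene_id=f"SIM{g:04d}",
                length_kb=float(rng.uniform(*design.length_range_kb)),
                I_true=float(rng.uniform(*design.i_range)),
                V_true=float(rng.uniform(*design.v_range)),
                D_true=float(rng.uniform(*design.d_range)),
                bg_mean=design.bg_mean,
                bg_dispersion=np.inf if noiseless else design.bg_dispersion,
            )
        )
    samples: dict[tuple[int, int], dict[str, IntronSignal]] = {}
    for timepoint, n_reps in sorted(design.replicate_design.items()):
        for rep in range(1, n_reps + 1):
            samples[(timepoint, rep)] = {
                p.gene_id: simulate_gene(p, timepoint, rng) for p in params
            }
    return samples, SimTruth.from_params(params)


def write_cohort(
    n_genes: int,
    seed: int,
    out_dir: str | os.PathLike,
    design: CohortDesign | None = None,
    noiseless: bool = False,
    bedgraph: bool = False,
) -> SimTruth:
    """Write a cohort as per-sample signal TSVs plus sample sheet and truth table.

    With ``bedgraph`` the samples are additionally emitted as bedGraph
    tracks over a synthetic chromosome together with a BED12 annotation, so
    the coverage-binning path can be exercised end to end.
    """
    from .genome_io import write_intron_signal_tsv

    design = design or CohortDesign()
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    samples, truth = simulate_cohort(n_genes, seed, design, noiseless=noiseless)
    sheet_rows = []
    for (timepoint, rep), signals in sorted(samples.items()):
        name = f"t{timepoint}_rep{rep}.signal.tsv"
        write_intron_signal_tsv(signals, os.path.join(out, name))
        sheet_rows.append(
            {"path": name, "timepoint_min": timepoint, "replicate": rep,
             "label": f"t{timepoint}_rep{rep}"}
        )
    pd.DataFrame(sheet_rows).to_csv(
        os.path.join(out, "samples.tsv"), sep="\t", index=False
    )
    truth.table.to_csv(
        os.path.join(out, "truth.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    if bedgraph:
        _write_bedgraph_cohort(samples, truth, out, seed, design, noiseless)
    return truth


def _write_bedgraph_cohort(samples, truth, out, seed, design, noiseless):
    """Synthetic-genome bedGraph + BED12 emission (genes laid head to tail)."""
    gap_bp = 20_000
    rng = np.random.default_rng(seed)
    offsets_bp: dict[str, int] = {}
    pos = gap_bp
    params: dict[str, SimGeneParams] = {}
    for row in truth.table.itertuples(index=False):
        p = SimGeneParams(
            gene_id=row.gene_id, length_kb=row.length_kb, I_true=row.I_true,
            V_true=row.V_true, D_true=row.D_true, bg_mean=row.bg_mean,
            bg_dispersion=np.inf if noiseless else row.bg_dispersion,
        )
        params[row.gene_id] = p
        offsets_bp[row.gene_id] = pos
        pos += int(round(row.length_kb * 1000)) + gap_bp
    with open(os.path.join(out, "genes.bed12"), "w") as bed:
        for gid, off in offsets_bp.items():
            gene = _gene_model(params[gid], offset_bp=off)
            sizes = ",".join(str(e - s) for s, e in gene.exons)
            starts = ",".join(str(s - off) for s, _ in gene.exons)
            lo, hi = gene.span
            bed.write(
                f"chrS\t{lo}\t{hi}\t{gid}\t0\t+\t{lo}\t{hi}\t0\t"
                f"{len(gene.exons)}\t{sizes}\t{starts}\n"
            )
    bin_bp = int(BIN_KB * 1000)
    for (timepoint, rep), signals in sorted(samples.items()):
        path = os.path.join(out, f"t{timepoint}_rep{rep}.bedgraph")
        with open(path, "w") as bg:
            for gid, off in offsets_bp.items():
                p = params[gid]
                sig, full, _ = simulate_gene(p, timepoint, rng, full_profile=True)
                for i, v in enumerate(full):
                    if v != 0:
                        s = off + i * bin_bp
                        bg.write(f"chrS\t{s}\t{s + bin_bp}\t{v:.6g}\n")
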