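"""Annotation and coverage I/O: binned genome-wide profiles and per-gene intron signals.

Coverage is accumulated in disjoint adjacent bins (100 bp by default) per
chromosome, normalized so the genome-wide sum is 10^6, and then reduced per
gene to a strand-oriented vector of *intronic* bin values anchored at the
TSS.  Restricting to introns avoids the confounding signal of contaminating
mature (spliced) mRNA, which carries exons only.

Coordinates are 0-based half-open throughout; offsets are reported in Kb
with 0 at the TSS on the annotated strand.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORMALIZATION_TARGET = 1_000_000.0
DEFAULT_BIN_SIZE = 100
#: ribosomal-RNA decoy contig excluded from all profiles
DEFAULT_EXCLUDED_CONTIGS = frozenset({"chrUn_gl000220"})

__all__ = [
    "GeneModel",
    "BinnedCoverage",
    "IntronSignal",
    "SampleSheet",
    "SampleEntry",
    "load_gene_models",
    "bin_coverage",
    "normalize_coverage",
    "extract_intron_signal",
    "eligible_genes",
    "read_sample_sheet",
    "write_intron_signal_tsv",
    "read_intron_signal_tsv",
    "write_bedgraph",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene (its longest annotated variant).

    ``tss``/``tes`` are the 5' and 3' transcript ends on the annotated
    strand: for a minus-strand gene ``tss > tes``.  ``exons`` are sorted,
    non-overlapping half-open genomic intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.length <= 0:
            raise ValueError(f"{self.gene_id}: zero-length transcript")
        lo, hi = self.span
        prev_end = lo
        for start, end in self.exons:
            if start < prev_end or end > hi or end <= start:
                raise ValueError(f"{self.gene_id}: malformed exon structure")
            prev_end = end

    @property
    def length(self) -> int:
        """Primary-transcript length in bp."""
        return abs(self.tes - self.tss)

    @property
    def length_kb(self) -> float:
        return self.length / 1000.0

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the transcript, half-open."""
        return min(self.tss, self.tes), max(self.tss, self.tes)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons (genomic order)."""
        gaps = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                gaps.append((e0, s1))
        return tuple(gaps)


@dataclass
class BinnedCoverage:
    """Genome-wide signal in disjoint adjacent bins for one sample.

    ``values[chrom][i]`` covers genomic interval ``[i*bin_size, (i+1)*bin_size)``.
    """

    bin_size: int = DEFAULT_BIN_SIZE
    values: dict[str, np.ndarray] = field(default_factory=dict)
    total_raw: float = 0.0
    normalized: bool = False
    excluded_contigs: frozenset[str] = DEFAULT_EXCLUDED_CONTIGS

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


@dataclass
class IntronSignal:
    """A gene's strand-oriented vector of intronic bin values.

    ``offsets_kb[i]`` is the distance (Kb) of bin *i*'s 5'-most edge from the
    TSS, measured in the direction of transcription; strictly increasing.
    """

    gene_id: str
    offsets_kb: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_kb = np.asarray(self.offsets_kb, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.offsets_kb.shape != self.values.shape:
            raise ValueError(f"{self.gene_id}: offsets/values length mismatch")
        if self.offsets_kb.size and (
            np.any(np.diff(self.offsets_kb) <= 0) or self.offsets_kb[0] < 0
        ):
            raise ValueError(f"{self.gene_id}: offsets must be non-negative and increasing")

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0


@dataclass(frozen=True)
class SampleEntry:
    path: str
    timepoint_min: int
    replicate: int
    label: str = ""


@dataclass
class SampleSheet:
    """Assignment of coverage files to time points and replicate indices."""

    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.timepoint_min not in (0, 4, 8):
                raise ValueError(f"{e.path}: timepoint_min must be 0, 4 or 8")
            key = (e.timepoint_min, e.replicate)
            if key in seen:
                raise ValueError(f"duplicate replicate {e.replicate} at t={e.timepoint_min}")
            seen.add(key)

    def at(self, timepoint_min: int) -> list[SampleEntry]:
        return [e for e in self.entries if e.timepoint_min == timepoint_min]

    def require_zero(self) -> None:
        if not self.at(0):
            raise ValueError("at least one 0-min sample is required for boundary calling")


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    df = pd.read_csv(path, sep="\t")
    required = {"path", "timepoint_min", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    entries = [
        SampleEntry(
            path=str(r.path),
            timepoint_min=int(r.timepoint_min),
            replicate=int(r.replicate),
            label=str(getattr(r, "label", "") or ""),
        )
        for r in df.itertuples(index=False)
    ]
    return SampleSheet(entries)


# ---------------------------------------------------------------------------
# annotation parsing


def _parse_exon_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x != "")


def _record_to_gene(fields: list[str], lineno: int) -> tuple[str, GeneModel]:
    """Parse one annotation record (refFlat, genePred or BED12)."""
    n = len(fields)
    try:
        if n >= 12 and fields[5] in "+-." and fields[1].isdigit() and fields[9].isdigit():
            # BED12: chrom start end name score strand thickStart thickEnd rgb
            #        blockCount blockSizes blockStarts
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            sizes = _parse_exon_list(fields[10])
            offs = _parse_exon_list(fields[11])
            if len(sizes) != int(fields[9]) or len(offs) != int(fields[9]):
                raise ValueError("block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
        elif n >= 11 and fields[3] in "+-":
            # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd
            #          exonCount exonStarts exonEnds
            name, chrom, strand = fields[0], fields[2], fields[3]
            start, end = int(fields[4]), int(fields[5])
            starts, ends = _parse_exon_list(fields[9]), _parse_exon_list(fields[10])
            exons = tuple(zip(starts, ends))
        elif n >= 10 and fields[2] in "+-":
            # genePred: name chrom strand txStart txEnd cdsStart cdsEnd
            #           exonCount exonStarts exonEnds
            name, chrom, strand = fields[0], fields[1], fields[2]
            start, end = int(fields[3]), int(fields[4])
            starts, ends = _parse_exon_list(fields[8]), _parse_exon_list(fields[9])
            exons = tuple(zip(starts, ends))
        else:
            raise ValueError("unrecognized annotation format")
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed annotation record at line {lineno}: {exc}") from exc
    if strand == ".":
        raise ValueError(f"malformed annotation record at line {lineno}: missing strand")
    tss, tes = (start, end) if strand == "+" else (end, start)
    return name, GeneModel(name, chrom, strand, tss, tes, exons)


def load_gene_models(
    annotation: str | os.PathLike | io.TextIOBase,
    min_length_kb: float = 0.0,
) -> list[GeneModel]:
    """Read gene models from refFlat/genePred or BED12 text.

    For genes with multiple annotated variants only the longest primary
    transcript is kept; genes shorter than ``min_length_kb`` are dropped.
    """
    if min_length_kb < 0:
        raise ValueError("min_length_kb must be >= 0")
    close = False
    if isinstance(annotation, (str, os.PathLike)):
        handle = open(annotation)
        close = True
    else:
        handle = annotation
    best: dict[str, GeneModel] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            name, gene = _record_to_gene(line.split("\t"), lineno)
            prev = best.get(name)
            if prev is not None and prev.chrom != gene.chrom:
                raise ValueError(
                    f"gene {name!r} annotated on both {prev.chrom} and {gene.chrom}"
                )
            if prev is None or gene.length > prev.length:
                best[name] = gene
    finally:
        if close:
            handle.close()
    return [g for g in best.values() if g.length_kb >= min_length_kb]


# ---------------------------------------------------------------------------
# coverage binning


def _is_bedgraph(path: str) -> bool:
    return str(path).endswith((".bedgraph", ".bedGraph", ".bg", ".bedgraph.txt"))


def bin_coverage(
    path: str | os.PathLike,
    bin_size: int = DEFAULT_BIN_SIZE,
    excluded_contigs: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CONTIGS,
    min_mapq: int = 10,
    overlap_weighted: bool = False,
) -> BinnedCoverage:
    """Bin an aligned (SAM/BAM) or pre-binned (bedGraph) sample into raw coverage.

    SAM/BAM: only uniquely mapped reads count (primary alignments with
    MAPQ >= ``min_mapq``).  By default each read adds 1 to the bin holding
    its 5' end; with ``overlap_weighted`` it instead distributes 1 across the
    bins it overlaps, proportionally to the overlap.  bedGraph intervals are
    rebinned by length-weighted averaging onto the bin grid.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    excluded = frozenset(excluded_contigs)
    if _is_bedgraph(str(path)):
        values = _bin_bedgraph(str(path), bin_size, excluded)
    else:
        values = _bin_alignments(str(path), bin_size, excluded, min_mapq, overlap_weighted)
    cov = BinnedCoverage(
        bin_size=bin_size,
        values=values,
        excluded_contigs=excluded,
    )
    cov.total_raw = cov.total()
    return cov


def _bin_alignments(
    path: str,
    bin_size: int,
    excluded: frozenset[str],
    min_mapq: int,
    overlap_weighted: bool,
) -> dict[str, np.ndarray]:
    import pysam

    values: dict[str, np.ndarray] = {}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as af:
        sizes = {name: (length + bin_size - 1) // bin_size
                 for name, length in zip(af.references, af.lengths)}
        last_pos: dict[str, int] = {}
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            if chrom is None:
                continue
            if chrom not in sizes:
                raise ValueError(f"read on contig {chrom!r} absent from header")
            if read.reference_start < last_pos.get(chrom, -1):
                raise ValueError(f"input {path!r} is not coordinate-sorted")
            last_pos[chrom] = read.reference_start
            if chrom in excluded:
                continue
            arr = values.get(chrom)
            if arr is None:
                arr = values[chrom] = np.zeros(sizes[chrom], dtype=float)
            if overlap_weighted:
                start, end = read.reference_start, read.reference_end
                span = end - start
                b0, b1 = start // bin_size, (end - 1) // bin_size
                for b in range(b0, b1 + 1):
                    lo = max(start, b * bin_size)
                    hi = min(end, (b + 1) * bin_size)
                    arr[b] += (hi - lo) / span
            else:
                five_prime = read.reference_end - 1 if read.is_reverse else read.reference_start
                arr[five_prime // bin_size] += 1.0
    return values


def _bin_bedgraph(
    path: str, bin_size: int, excluded: frozenset[str]
) -> dict[str, np.ndarray]:
    chunks: dict[str, list[tuple[int, int, float]]] = {}
    last_pos: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed bedGraph line {lineno}")
            chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if start < last_pos.get(chrom, -1):
                raise ValueError(f"input {path!r} is not coordinate-sorted (line {lineno})")
            last_pos[chrom] = start
            if chrom in excluded:
                continue
            chunks.setdefault(chrom, []).append((start, end, val))
    values: dict[str, np.ndarray] = {}
    for chrom, ivals in chunks.items():
        n_bins = (max(e for _, e, _ in ivals) + bin_size - 1) // bin_size
        arr = np.zeros(n_bins, dtype=float)
        for start, end, val in ivals:
            b0, b1 = start // bin_size, (end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                arr[b] += val * (hi - lo) / bin_size
        values[chrom] = arr
    return values


def normalize_coverage(cov: BinnedCoverage) -> BinnedCoverage:
    """Scale so the genome-wide sum over retained contigs equals 10^6."""
    total = cov.total()
    if total <= 0:
        raise ValueError("empty experiment: all-zero coverage cannot be normalized")
    scale = NORMALIZATION_TARGET / total
    return BinnedCoverage(
        bin_size=cov.bin_size,
        values={c: v * scale for c, v in cov.values.items()},
        total_raw=cov.total_raw if cov.total_raw else total,
        normalized=True,
        excluded_contigs=cov.excluded_contigs,
    )


# ---------------------------------------------------------------------------
# per-gene intron signal


def extract_intron_signal(gene: GeneModel, cov: BinnedCoverage) -> IntronSignal:
    """TSS-anchored intronic bin values for one gene.

    A bin is retained iff it lies entirely within the transcript and
    overlaps no exon (bins straddling an exon edge count as exonic, which is
    conservative against mature-mRNA leakage).  For minus-strand genes the
    vector is reversed so offsets increase away from the 5' end.
    """
    if gene.chrom not in cov.values:
        raise KeyError(f"chromosome {gene.chrom!r} absent from coverage")
    arr = cov.values[gene.chrom]
    bs = cov.bin_size
    lo, hi = gene.span
    b0 = (lo + bs - 1) // bs  # first bin fully inside the transcript
    b1 = hi // bs  # one past the last fully contained bin
    b1 = min(b1, arr.size)
    if b1 <= b0:
        return IntronSignal(gene.gene_id, np.empty(0), np.empty(0))
    bins = np.arange(b0, b1)
    starts = bins * bs
    ends = starts + bs
    intronic = np.ones(bins.size, dtype=bool)
    for es, ee in gene.exons:
        intronic &= (ends <= es) | (starts >= ee)
    starts, ends = starts[intronic], ends[intronic]
    vals = arr[bins[intronic]]
    if gene.strand == "+":
        offs = (starts - gene.tss) / 1000.0
    else:
        offs = (gene.tss - ends) / 1000.0
        offs, vals = offs[::-1], vals[::-1]
    return IntronSignal(gene.gene_id, offs, vals)


def eligible_genes(
    genes: list[GeneModel],
    signals: dict[str, IntronSignal],
    min_length_kb: float = 25.0,
    min_positive_bins: int = 20,
) -> list[str]:
    """Genes long enough and with enough informative intron bins.

    Retained iff transcript length strictly exceeds ``min_length_kb`` and the
    reference signal has at least ``min_positive_bins`` strictly positive
    intron bins.
    """
    keep = []
    for gene in genes:
        sig = signals.get(gene.gene_id)
        if sig is None or sig.is_empty:
            continue
        if gene.length_kb > min_length_kb and int((sig.values > 0).sum()) >= min_positive_bins:
            keep.append(gene.gene_id)
    return keep


# ---------------------------------------------------------------------------
# text formats


def write_intron_signal_tsv(signals: dict[str, IntronSignal], path: str | os.PathLike) -> None:
    rows = [
        (gid, o, v)
        for gid, sig in signals.items()
        for o, v in zip(sig.offsets_kb, sig.values)
    ]
    pd.DataFrame(rows, columns=["gene_id", "offset_kb", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_intron_signal_tsv(path: str | os.PathLike) -> dict[str, IntronSignal]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, IntronSignal] = {}
    for gid, grp in df.groupby("gene_id", sort=False):
        out[str(gid)] = IntronSignal(
            str(gid), grp["offset_kb"].to_numpy(float), grp["value"].to_numpy(float)
        )
    return out


def write_bedgraph(cov: BinnedCoverage, path: str | os.PathLike) -> None:
    """Write non-zero bins as a sorted bedGraph track."""
    with open(path, "w") as fh:
        for chrom in sorted(cov.values):
            arr = cov.values[chrom]
            (nz,) = np.nonzero(arr)
            for b in nz:
                fh.write(
                    f"{chrom}\t{b * cov.bin_size}\t{(b + 1) * cov.bin_size}\t{arr[b]:.6g}\n"
                )
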