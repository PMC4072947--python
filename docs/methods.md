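# Methods

## The measurement model

After a reversible elongation inhibitor is washed out, RNA polymerase II
re-enters productive elongation quasi-synchronously across the genome.
Nascent-RNA coverage at time *t* (min) after release then forms a wave
advancing from each gene's TSS.  With constant initiation frequency *I*
(signal units/min), elongation rate *V* (Kb/min) and an effective
re-initiation delay *D* (min), the expected nascent signal at offset *x*
(Kb downstream of the TSS) is

    Signal(x, t) = I * max(0, t - D - x / V)

a triangular wave truncated at the front `front(t) = V * (t - D)`.  Because
inhibition is leaky, the wave rides on a low, over-dispersed
(negative-binomial-like) background that is present already at *t* = 0.
Only intronic coverage is analyzed: intron signal decays quickly after
splicing, so it is a proxy for nascent transcription and is insensitive to
contaminating mature mRNA.

The pipeline estimates, per gene:

* the wave-front position ("boundary") in each 4-min and 8-min sample;
* *V* as the slope of boundary position against time, with a 50% confidence
  interval, and *D* as the time-axis intercept of the same line;
* the relative initiation frequency *I = b·V/B*, where `a·x + b` is the
  least-squares line through the background-normalized 8-min intron signal
  up to its boundary *B* (the model above implies `a·B + b ≈ 0` and
  `b = I·(T − D)` with *T* = 8 min).

## Processing chain and parameters

| step | parameter | default | notes |
|---|---|---|---|
| binning | bin size | 100 bp | disjoint adjacent bins, 0-based half-open |
| normalization | target sum | 10^6 | per sample, over retained contigs |
| contig filter | excluded | chrUn_gl000220 | rRNA decoy |
| gene filter | min length | 25 Kb (exclusive) | plus ≥ 20 positive intron bins on the averaged 0-min profile |
| smoothing | spline parameter p | 10^-5 | cubic smoothing spline, objective `p·Σr² + (1−p)·∫f″²` |
| 0-min pseudocount | per bin | 0.01 | added before the smoothing that builds the ratio denominator |
| rough call | start offset | 2.5 Kb | first eligible position |
| rough call | tolerance | 10% | sample ≤ 1.1 × 0-min, both background-corrected |
| refinement | dip threshold | −0.01 | local minima of the ratio derivative |
| refinement | plateau threshold | −0.002 | derivative "close to zero" |
| refinement | window | 2 Kb | cap downstream of the rough estimate |
| rate QC | CI half-width | ≤ 0.5 Kb/min | 50% two-sided CI of the slope |
| rate QC | delay window | [−1, 4] min | time-axis intercept |
| initiation | ratio pseudocount | +1 | on the averaged 0-min signal before division |
| initiation | fit floor | 5 bins | minimum usable bins per replicate |

All constants are fields of `PipelineConfig` and serialize to a flat YAML
mapping (unknown keys are rejected to guard against typos).

## Smoothing convention

The smoothing parameter follows the classic penalized-spline weighting in
which `p → 1` interpolates and `p → 0` tends to the least-squares line.
The abscissa is the *concatenated intron-bin index* — equally spaced, with
exon gaps closed — not the genomic coordinate; boundary positions are
mapped back to genomic offsets afterwards.  Under this convention
`p = 10^-5` corresponds to an equivalent-kernel half-length of roughly
18 bins (1.8 Kb at 100-bp bins): strong enough to suppress the
over-dispersed bin noise that otherwise dominates single-bin comparisons.
Other spline parameterizations rescale `p`; with a genomic-bp abscissa the
same numeric value is nearly interpolating, which preserves sharp wave
knees but leaves every downstream comparison at the mercy of raw count
noise.

A consequence worth stating plainly: the spline blurs the wave's leading
edge, so the detected front carries a systematic *downstream* offset of
about 1.4–2.2 Kb (measured on deterministic waves across V ∈ [2,6],
D ∈ [0,2]; see `wavecall.evaluation.noiseless_front_grid`).  The offset is
nearly constant in V, D and timepoint, so it cancels in the rate slope —
rates are recovered essentially unbiased — and propagates only into the
delay estimate as a shift of about −offset/V (a few tenths of a minute).
Single-sample boundary positions should therefore be read as front
positions plus a method constant, not as exact front coordinates.

## Boundary refinement

The refinement scans the derivative of the (background-corrected, smoothed)
sample profile divided by the pseudocounted smoothed 0-min profile.  Among
local minima deeper than −0.01 upstream of the rough estimate, the most
downstream one anchors the search; scanning downstream from it, the first
bin whose derivative has recovered to ≥ −0.002 marks the onset of the
post-front plateau.  The refined front is placed midway between the dip
and the plateau onset (`refine_mode="midpoint"`, the default), which
partially compensates the symmetric spline blur; `refine_mode="plateau"`
returns the plateau onset itself.  Without a usable dip or plateau the
rough estimate stands (`refine-fallback`).

Local minima are strict sign changes (prominence 0 by default); a
prominence knob exists because published peak finders apply a selectivity
heuristic with no canonical parameterization.

## Background estimation

For each bin the background level is the *histogram mode* of all values
downstream of it (the wave cannot contribute there, leaky-inhibition
counts can).  The histogram uses `ceil(sqrt(n))` equal-width bins over the
data range, ties resolved toward the lower bin, and the estimate is the
winning bin's center — so a "zero" background is reported as up to half a
bin width.  The final bins of a gene (fewer than 10 downstream values)
inherit the nearest upstream estimate; degenerate short signals get a
constant track.  No negative-binomial fit is performed: the mode is the
only statistic used, which is robust to the wave tail and to outliers.
Background estimation operates on the smoothed profile, matching the order
of the processing chain; correction subtracts the track and floors at
zero.

## Rate fitting and outlier handling

Rates require boundaries in both 4-min replicates and in at least three of
the four 8-min replicates.  The 8-min boundary set first passes a modified
Thompson tau test (two-sided t critical value at α = 0.05, df = n − 2,
`τ = t(n−1)/(√n·√(n−2+t²))`), removing at most the single most deviant
value.  The line is fit by ordinary least squares over *all* replicate
points rather than the two per-timepoint means: with only two averaged
points the slope has no residual degrees of freedom, while replicate-level
fitting makes the 50% CI a measure of replicate dispersion.  When
replicate counts are balanced the two slopes coincide.

## Initiation frequencies

Each 8-min replicate is normalized by the averaged raw 0-min signal plus 1
and fit linearly over offsets in `[exclude_first_kb, B]`, with *B* that
replicate's own refined boundary; the consensus QC-passing *V* enters
`I = b·V/B` for all replicates of a gene.  Replicate estimates pass the
same Thompson tau filter (max one removal) and are averaged.  Values are
relative: only ratios between genes are meaningful.  Recomputing with the
first 2 Kb excluded (guarding against promoter-proximal pausing signal)
is available via `exclude_first_kb=2`.

## The simulator, and what passing tests do not show

`wavecall.simulator` draws per-gene parameters — V ~ U[2,6] Kb/min,
D ~ U[0,2] min, I ~ U[0.5,4] signal units/min, lengths U[55,120] Kb — and
emits already-normalized intron signals with gamma-Poisson noise
(variance `μ + μ²/k`, background mean 0.3, dispersion k = 2), in the
replicate design four 0-min / two 4-min / four 8-min.  An infinite
dispersion yields the deterministic expected wave.  Exon bins carry a
steady-state mature-mRNA leakage term so exon masking is exercised.

Deliberately *not* modeled: promoter-proximal pausing peaks (the 2-Kb
exclusion exists to test robustness against them, and a pause-free
generator makes that check a clean identity), splicing kinetics and
intron degradation, sequence/GC bias, fragment-length effects, mappability
gaps, and gene-to-gene background variation.  Parameter-recovery results
on this generator therefore demonstrate the estimator's correctness under
its own model assumptions, not performance on real libraries, where
boundary jitter and background structure are less benign.

Benchmark problem sizes are package choices balancing statistical
resolution against desk-scale runtimes: a 200-gene cohort for noisy
recovery (roughly 95% of QC-passing genes within ±0.5 Kb/min of truth at
the default noise level) and a 36-point (V, D) grid for the deterministic
front analysis.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open; offsets are Kb from the TSS on the
  annotated strand; positions are reported at bin starts and rounded to
  0.1 Kb only at output.
* A bin overlapping both exon and intron counts as exonic (conservative
  against mature-mRNA leakage).
* Reads count once, into the bin holding the alignment's 5′ end;
  an overlap-weighted mode is available.  "Uniquely mapped" means primary
  alignments with MAPQ ≥ 10.
* Multiple annotation variants of a gene: the longest primary transcript
  wins; conflicting chromosomes are an error.
* Smoothing requires ≥ 4 bins; empty or too-short intron signals yield a
  `no-boundary` call rather than an exception.
* Ties at the plateau threshold resolve to the first qualifying bin; ties
  in the mode histogram resolve to the lower bin.
* All randomness flows through a single integer seed; equal seeds give
  byte-identical outputs.

## Known limitations

* Single-sample boundary positions carry the smoothing offset discussed
  above; compare them across timepoints, not to external annotations.
* Genes whose 8-min front runs past the annotated 3′ end have no interior
  boundary; background estimated from wave-occupied bins can then produce
  an edge-pinned call, which the delay-window QC removes.
* The 50% CI cut is a reproducibility filter, not a coverage guarantee;
  at the default noise level roughly 5% of passing genes still miss truth
  by more than 0.5 Kb/min.
* Delay times inherit any region-level rate variation near the TSS; with
  a slower start, delays are overestimated.
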