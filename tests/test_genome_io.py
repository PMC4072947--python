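import io

import numpy as np
import pytest

from wavecall.genome_io import (
    BinnedCoverage,
    GeneModel,
    IntronSignal,
    SampleEntry,
    SampleSheet,
    bin_coverage,
    eligible_genes,
    extract_intron_signal,
    load_gene_models,
    normalize_coverage,
    read_intron_signal_tsv,
    write_intron_signal_tsv,
)

REFFLAT_TWO_VARIANTS = "\n".join(
    [
        # gene G: 30 Kb and 40 Kb variants
        "G\tNM_1\tchr1\t+\t1000\t31000\t1000\t31000\t2\t1000,30000,\t2000,31000,",
        "G\tNM_2\tchr1\t+\t1000\t41000\t1000\t41000\t2\t1000,40000,\t2000,41000,",
        # minus-strand gene
        "M\tNM_3\tchr2\t-\t1000\t31000\t1000\t31000\t2\t1000,30000,\t2000,31000,",
        # single-exon gene
        "S\tNM_4\tchr1\t+\t5000\t35000\t5000\t35000\t1\t5000,\t35000,",
    ]
)


class TestLoadGeneModels:
    def test_longest_variant_wins(self):
        genes = {g.gene_id: g for g in load_gene_models(io.StringIO(REFFLAT_TWO_VARIANTS))}
        assert genes["G"].length == 40_000

    def test_min_length_filter(self):
        genes = load_gene_models(io.StringIO(REFFLAT_TWO_VARIANTS), min_length_kb=35)
        assert {g.gene_id for g in genes} == {"G"}

    def test_minus_strand_tss_is_transcript_five_prime(self):
        genes = {g.gene_id: g for g in load_gene_models(io.StringIO(REFFLAT_TWO_VARIANTS))}
        assert genes["M"].tss == 31_000
        assert genes["M"].tes == 1_000

    def test_single_exon_gene_has_no_introns(self):
        genes = {g.gene_id: g for g in load_gene_models(io.StringIO(REFFLAT_TWO_VARIANTS))}
        assert genes["S"].introns == ()

    def test_bed12_parsing(self):
        bed = "chr1\t1000\t31000\tB\t0\t+\t1000\t31000\t0\t2\t1000,1000,\t0,29000,"
        (gene,) = load_gene_models(io.StringIO(bed))
        assert gene.exons == ((1000, 2000), (30_000, 31_000))
        assert gene.length == 30_000

    def test_malformed_record_names_line(self):
        bad = REFFLAT_TWO_VARIANTS + "\nG\tNM_9\tchr1\t+\tnot_an_int\t1\t1\t1\t1\t1,\t2,"
        with pytest.raises(ValueError, match="line 5"):
            load_gene_models(io.StringIO(bad))

    def test_conflicting_chrom_rejected(self):
        dup = (
            "G\tNM_1\tchr1\t+\t0\t30000\t0\t30000\t1\t0,\t30000,\n"
            "G\tNM_2\tchr9\t+\t0\t40000\t0\t40000\t1\t0,\t40000,"
        )
        with pytest.raises(ValueError, match="chr"):
            load_gene_models(io.StringIO(dup))


def _write_sam(path, reads, contigs=(("chr1", 10_000), ("chrUn_gl000220", 10_000))):
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in contigs:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for i, (chrom, pos, mapq, flag) in enumerate(reads):
            fh.write(
                f"r{i}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t50M\t*\t0\t0\t"
                f"{'A' * 50}\t{'I' * 50}\n"
            )


class TestBinCoverage:
    def test_read_counts_into_five_prime_bin(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(sam, [("chr1", 310, 42, 0)])
        cov = bin_coverage(sam)
        assert cov.values["chr1"][3] == 1.0
        assert cov.total() == 1.0

    def test_reverse_read_uses_alignment_five_prime(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(sam, [("chr1", 310, 42, 16)])  # spans [310, 360): 5' end at 359
        cov = bin_coverage(sam)
        assert cov.values["chr1"][3] == 1.0

    def test_low_mapq_and_secondary_excluded(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(sam, [("chr1", 100, 3, 0), ("chr1", 200, 42, 256), ("chr1", 300, 42, 0)])
        cov = bin_coverage(sam)
        assert cov.total() == 1.0

    def test_rrna_contig_excluded(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(sam, [("chrUn_gl000220", 100, 42, 0), ("chr1", 100, 42, 0)])
        cov = bin_coverage(sam)
        assert "chrUn_gl000220" not in cov.values
        assert cov.total() == 1.0

    def test_unsorted_input_rejected(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(sam, [("chr1", 500, 42, 0), ("chr1", 100, 42, 0)])
        with pytest.raises(ValueError, match="sorted"):
            bin_coverage(sam)

    def test_mass_conservation_random_reads(self, tmp_path, rng):
        positions = np.sort(rng.integers(0, 9000, size=50))
        sam = tmp_path / "a.sam"
        _write_sam(sam, [("chr1", int(p), 42, 0) for p in positions])
        cov = bin_coverage(sam)
        assert cov.total() == 50.0

    def test_bedgraph_constant_rebinning(self, tmp_path):
        bg = tmp_path / "a.bedgraph"
        bg.write_text("chr1\t0\t300\t6\n")
        cov = bin_coverage(bg)
        assert np.allclose(cov.values["chr1"][:3], 6.0)

    def test_bedgraph_partial_overlap_weighting(self, tmp_path):
        bg = tmp_path / "a.bedgraph"
        bg.write_text("chr1\t50\t150\t10\n")
        cov = bin_coverage(bg)
        assert np.allclose(cov.values["chr1"][:2], [5.0, 5.0])


class TestNormalize:
    def _cov(self, values):
        cov = BinnedCoverage(values={"chr1": np.asarray(values, float)})
        cov.total_raw = cov.total()
        return cov

    def test_sum_becomes_one_million(self):
        norm = normalize_coverage(self._cov([5.0, 15.0]))
        assert norm.total() == pytest.approx(1e6)
        assert norm.values["chr1"][0] == pytest.approx(0.25e6)

    def test_single_bin_becomes_total(self):
        norm = normalize_coverage(self._cov([5.0]))
        assert norm.values["chr1"][0] == pytest.approx(1e6)

    def test_idempotent(self):
        once = normalize_coverage(self._cov([3.0, 7.0, 2.0]))
        twice = normalize_coverage(once)
        np.testing.assert_allclose(twice.values["chr1"], once.values["chr1"])

    def test_empty_experiment_rejected(self):
        with pytest.raises(ValueError, match="empty experiment"):
            normalize_coverage(self._cov([0.0, 0.0]))


class TestExtractIntronSignal:
    def _coverage(self, n=400, value=1.0):
        return BinnedCoverage(values={"chr1": np.full(n, value)})

    def test_exonic_bins_dropped(self, plus_gene):
        cov = self._coverage()
        sig = extract_intron_signal(plus_gene, cov)
        # exons cover [0,500) and [29500,30000): bins 0-4 and 295-299 out
        assert sig.n_bins == 290
        assert sig.offsets_kb[0] == pytest.approx(0.5)
        assert sig.offsets_kb[-1] == pytest.approx(29.4)

    def test_minus_strand_offsets_anchor_at_tss(self, minus_gene):
        n = 400
        cov = BinnedCoverage(values={"chr1": np.arange(n, dtype=float)})
        sig = extract_intron_signal(minus_gene, cov)
        assert sig.offsets_kb[0] == pytest.approx(0.5)
        # offset 0.5 Kb from the minus-strand TSS (30 Kb) is genomic bin 294
        assert sig.values[0] == 294.0

    def test_strand_flip_reverses_values_same_offsets(self, plus_gene, minus_gene, rng):
        cov = BinnedCoverage(values={"chr1": rng.random(400)})
        fwd = extract_intron_signal(plus_gene, cov)
        rev = extract_intron_signal(minus_gene, cov)
        np.testing.assert_allclose(fwd.offsets_kb, rev.offsets_kb)
        np.testing.assert_allclose(fwd.values, rev.values[::-1])

    def test_single_exon_gene_empty(self):
        gene = GeneModel("S", "chr1", "+", 0, 30_000, ((0, 30_000),))
        sig = extract_intron_signal(gene, self._coverage())
        assert sig.is_empty

    def test_intron_and_exon_bins_tile_transcript(self, plus_gene):
        cov = self._coverage()
        sig = extract_intron_signal(plus_gene, cov)
        n_transcript_bins = 300
        starts = np.arange(300) * 100
        exonic = np.zeros(300, dtype=bool)
        for es, ee in plus_gene.exons:
            exonic |= (starts < ee) & (es < starts + 100)
        assert sig.n_bins + int(exonic.sum()) == n_transcript_bins


class TestEligibility:
    def _gene(self, length_kb):
        return GeneModel("G", "chr1", "+", 0, int(length_kb * 1000), ())

    def _sig(self, n_positive, n_total=50):
        vals = np.zeros(n_total)
        vals[:n_positive] = 1.0
        return IntronSignal("G", np.arange(n_total) * 0.1, vals)

    @pytest.mark.parametrize(
        "length_kb,n_pos,expected",
        [(30, 25, True), (30, 19, False), (24, 50, False), (25, 25, False), (26, 20, True)],
    )
    def test_rules(self, length_kb, n_pos, expected):
        keep = eligible_genes([self._gene(length_kb)], {"G": self._sig(n_pos)})
        assert (keep == ["G"]) is expected


class TestSampleSheet:
    def test_duplicate_replicate_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SampleSheet([SampleEntry("a", 4, 1), SampleEntry("b", 4, 1)])

    def test_zero_required_for_boundaries(self):
        sheet = SampleSheet([SampleEntry("a", 4, 1), SampleEntry("b", 8, 1)])
        with pytest.raises(ValueError, match="0-min"):
            sheet.require_zero()


def test_signal_tsv_round_trip(tmp_path, rng):
    sig = IntronSignal("G1", np.arange(30) * 0.1, rng.random(30).round(6))
    path = tmp_path / "sig.tsv"
    write_intron_signal_tsv({"G1": sig}, path)
    back = read_intron_signal_tsv(path)
    np.testing.assert_allclose(back["G1"].values, sig.values, rtol=1e-5)
    np.testing.assert_allclose(back["G1"].offsets_kb, sig.offsets_kb)
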