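"""Antisense/intergenic classification, binding-region binning and overlap
statistics, checked against per-base brute force."""

import statistics

import numpy as np
import pytest

from halosrna.classify import (
    CisPair,
    bin_binding_region,
    classify_transcript,
    find_cis_targets,
    overlap_stats,
)
from halosrna.genome_model import (
    GeneFeature,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptRecord,
)
from halosrna.synthetic_data import simulate_genome

from conftest import small_params


def T(tid, start, end, strand, chrom="chr"):
    return TranscriptRecord(tid, GenomicInterval(chrom, start, end, strand))


class TestClassifyTranscript:
    def test_opposite_strand_overlap_is_antisense(self, toy_annotation):
        rec = classify_transcript(T("t", 300, 600, "-"), toy_annotation)
        assert rec.srna_class == "antisense"
        assert rec.primary_target.gene_id == "geneA"
        assert rec.primary_target.overlap_nt == 200

    def test_no_gene_overlap_is_intergenic(self, toy_annotation):
        assert classify_transcript(T("t", 600, 700, "+"), toy_annotation).srna_class == (
            "intergenic"
        )

    def test_seven_nt_overlap_is_subthreshold(self, toy_annotation):
        # opposite-strand overlap of 7 nt sits below the 8 nt minimum
        rec = classify_transcript(T("t", 493, 600, "-"), toy_annotation)
        assert rec.srna_class == "excluded-subthreshold"
        assert classify_transcript(T("t", 492, 600, "-"), toy_annotation).srna_class == (
            "antisense"
        )

    def test_same_strand_overlap_is_excluded(self, toy_annotation):
        assert classify_transcript(T("t", 300, 600, "+"), toy_annotation).srna_class == (
            "excluded-sense"
        )
        # same-strand exclusion wins even with an opposite-strand gene nearby
        assert classify_transcript(T("t", 400, 1000, "+"), toy_annotation).srna_class == (
            "excluded-sense"
        )

    def test_antisense_takes_precedence_over_intergenic_extension(self, toy_annotation):
        rec = classify_transcript(T("t", 450, 800, "-"), toy_annotation)
        assert rec.srna_class == "antisense"

    def test_unknown_replicon_raises(self, toy_annotation):
        with pytest.raises(KeyError):
            classify_transcript(T("t", 0, 100, "+", chrom="nope"), toy_annotation)


class TestCisTargets:
    def test_straddling_two_adjacent_genes_yields_two_pairs(self):
        a = GeneFeature(
            "gA",
            GenomicInterval("chr", 100, 400, "+"),
            GenomicInterval("chr", 100, 360, "+"),
            utr3=GenomicInterval("chr", 360, 400, "+"),
        )
        b = GeneFeature(
            "gB",
            GenomicInterval("chr", 420, 800, "+"),
            GenomicInterval("chr", 450, 800, "+"),
            utr5=GenomicInterval("chr", 420, 450, "+"),
        )
        ann = GenomeAnnotation([a, b], {"chr": 1000})
        asrna = T("as", 350, 500, "-")
        pairs = find_cis_targets(asrna, ann, 8)
        assert [p.gene_id for p in pairs] == ["gB", "gA"]  # 80 nt > 50 nt
        assert pairs[0].overlap_nt == 80 and pairs[1].overlap_nt == 50
        assert pairs[1].binding_region == "3'UTR"

    def test_list_matches_brute_force_scan(self):
        ann, _ = simulate_genome(small_params(seed=11))
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(300):
            start = int(rng.integers(0, 68_000))
            iv = GenomicInterval("chr1", start, start + int(rng.integers(20, 1500)),
                                 "+" if rng.random() < 0.5 else "-")
            t = TranscriptRecord("t", iv)
            got = find_cis_targets(t, ann, 8)
            opp = "+" if iv.strand == "-" else "-"
            want = sorted(
                (
                    g.gene_id
                    for g in ann.genes
                    if g.strand == opp and iv.overlap_nt(g.interval) >= 8
                ),
            )
            assert sorted(p.gene_id for p in got) == want
            checked += len(want)
        assert checked > 50  # the random placements actually exercised overlaps


class TestBindingRegion:
    @pytest.mark.parametrize(
        "u5,cds,u3,label",
        [
            (30, 10, 0, "5'UTR"),
            (0, 200, 0, "CDS"),
            (20, 20, 0, "5'UTR"),  # tie -> UTR precedence
            (0, 15, 15, "3'UTR"),
            (5, 0, 5, "5'UTR"),
        ],
    )
    def test_max_share_with_utr_precedence(self, u5, cds, u3, label):
        assert bin_binding_region(u5, cds, u3) == label

    def test_all_zero_breakdown_is_an_error(self):
        with pytest.raises(ValueError):
            bin_binding_region(0, 0, 0)

    def test_breakdown_sums_to_overlap(self, toy_annotation):
        pairs = find_cis_targets(T("t", 90, 480, "-"), toy_annotation, 8)
        (p,) = pairs
        assert p.utr5_nt + p.cds_nt + p.utr3_nt == p.overlap_nt
        assert p.utr5_nt == 30 and p.cds_nt == 330 and p.utr3_nt == 20


class TestPerBaseBruteForce:
    def test_classification_equals_per_base_counting(self):
        """Indexed interval classification must agree with literal per-base
        strand occupancy arrays on random genomes."""
        for seed in range(5):
            params = small_params(seed=seed, n_genes=15, replicon_length=40_000)
            ann, _ = simulate_genome(params)
            L = params.replicon_length
            occupancy = {s: np.zeros(L, dtype=bool) for s in "+-"}
            region = {  # per-base region code arrays per strand
                s: {r: np.zeros(L, dtype=bool) for r in ("utr5", "cds", "utr3")}
                for s in "+-"
            }
            for g in ann.genes:
                occupancy[g.strand][g.interval.start: g.interval.end] = True
                for r, sub in (("utr5", g.utr5), ("cds", g.cds), ("utr3", g.utr3)):
                    if sub is not None:
                        region[g.strand][r][sub.start: sub.end] = True
            rng = np.random.default_rng(seed + 99)
            for _ in range(60):
                start = int(rng.integers(0, L - 1))
                end = start + int(rng.integers(10, 1200))
                end = min(end, L)
                strand = "+" if rng.random() < 0.5 else "-"
                opp = "+" if strand == "-" else "-"
                t = TranscriptRecord("t", GenomicInterval("chr1", start, end, strand))
                rec = classify_transcript(t, ann, 8)
                same_bases = int(occupancy[strand][start:end].sum())
                opp_bases = int(occupancy[opp][start:end].sum())
                if same_bases > 0:
                    assert rec.srna_class == "excluded-sense"
                elif opp_bases == 0:
                    assert rec.srna_class == "intergenic"
                else:
                    # per-gene brute-force overlap governs antisense vs subthreshold
                    per_gene = [
                        iv_overlap
                        for g in ann.genes
                        if g.strand == opp
                        and (iv_overlap := t.interval.overlap_nt(g.interval)) > 0
                    ]
                    if max(per_gene) >= 8:
                        assert rec.srna_class == "antisense"
                        p = rec.primary_target
                        gene = ann.gene(p.gene_id)
                        for r, nt in (
                            ("utr5", p.utr5_nt),
                            ("cds", p.cds_nt),
                            ("utr3", p.utr3_nt),
                        ):
                            base_count = int(
                                (
                                    region[opp][r][start:end]
                                    & _gene_mask(gene, start, end)
                                ).sum()
                            )
                            assert nt == base_count
                    else:
                        assert rec.srna_class == "excluded-subthreshold"


def _gene_mask(gene, start, end):
    mask = np.zeros(end - start, dtype=bool)
    lo = max(start, gene.interval.start)
    hi = min(end, gene.interval.end)
    if hi > lo:
        mask[lo - start: hi - start] = True
    return mask


class TestInvariances:
    def _random_case(self, seed):
        params = small_params(seed=seed, n_genes=12, replicon_length=35_000)
        ann, _ = simulate_genome(params)
        rng = np.random.default_rng(seed + 7)
        ts = [
            TranscriptRecord(
                f"t{i}",
                GenomicInterval(
                    "chr1",
                    int(s := rng.integers(0, 33_000)),
                    int(s + rng.integers(10, 1200)),
                    "+" if rng.random() < 0.5 else "-",
                ),
            )
            for i in range(40)
        ]
        return ann, ts

    def test_translation_invariance(self):
        ann, ts = self._random_case(3)
        delta = 1000
        shifted_genes = [
            GeneFeature(
                g.gene_id,
                g.interval.shifted(delta),
                g.cds.shifted(delta),
                g.utr5.shifted(delta) if g.utr5 else None,
                g.utr3.shifted(delta) if g.utr3 else None,
                g.product,
            )
            for g in ann.genes
        ]
        shifted_ann = GenomeAnnotation(
            shifted_genes, {"chr1": ann.replicon_lengths["chr1"] + delta}
        )
        for t in ts:
            orig = classify_transcript(t, ann)
            moved = classify_transcript(
                TranscriptRecord(t.transcript_id, t.interval.shifted(delta)), shifted_ann
            )
            assert moved.srna_class == orig.srna_class

    def test_global_strand_flip_preserves_class_labels(self):
        ann, ts = self._random_case(4)
        flipped_genes = [
            GeneFeature(
                g.gene_id,
                g.interval.flipped(),
                g.cds.flipped(),
                # flipping transcription direction swaps the UTR roles
                utr5=g.utr3.flipped() if g.utr3 else None,
                utr3=g.utr5.flipped() if g.utr5 else None,
                product=g.product,
            )
            for g in ann.genes
        ]
        flipped_ann = GenomeAnnotation(flipped_genes, ann.replicon_lengths)
        for t in ts:
            orig = classify_transcript(t, ann)
            flip = classify_transcript(
                TranscriptRecord(t.transcript_id, t.interval.flipped()), flipped_ann
            )
            assert flip.srna_class == orig.srna_class


class TestOverlapStats:
    def test_small_examples(self):
        def P(ov):
            return CisPair("s", "g", ov, 0, ov, 0, "CDS")

        stats_ = overlap_stats([P(8), P(221), P(992)])
        assert stats_.median_nt == 221 and stats_.min_nt == 8 and stats_.max_nt == 992
        one = overlap_stats([P(100)])
        assert one.median_nt == one.mean_nt == one.min_nt == one.max_nt == 100

    def test_even_count_median_and_histogram_conservation(self):
        rng = np.random.default_rng(5)
        ovs = [int(v) for v in rng.integers(8, 1000, size=500)]
        pairs = [CisPair("s", "g", ov, 0, ov, 0, "CDS") for ov in ovs]
        st = overlap_stats(pairs)
        assert st.median_nt == statistics.median(ovs)
        assert st.mean_nt == pytest.approx(statistics.fmean(ovs))
        assert sum(st.histogram) == len(pairs)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            overlap_stats([])
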