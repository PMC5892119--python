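"""Window extraction conventions, PWM scanning and centroid recovery."""

import numpy as np
import pytest
from Bio.Seq import Seq

from halosrna.motifs import (
    BRE_CONSENSUS,
    TATA_CONSENSUS,
    MotifModel,
    Window,
    centroid,
    default_models,
    extract_window,
    fraction_with_promoter,
    scan_motif,
    scan_promoters,
)
from halosrna.synthetic_data import plant_motifs, plant_srnas, simulate_genome

from conftest import small_params


def random_genome(length=1000, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr": "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))}


class TestExtractWindow:
    def test_plus_strand_covers_up_and_downstream(self):
        genome = random_genome()
        w = extract_window(genome, "chr", 500, "+", 100, 100)
        assert w.seq == genome["chr"][400:600]
        assert w.position_of(0) == -100
        assert w.seq[w.index_of(0)] == genome["chr"][500]

    def test_minus_strand_is_reverse_complement_with_tss_at_zero(self):
        genome = random_genome()
        w = extract_window(genome, "chr", 500, "-", 100, 100)
        assert w.seq == str(Seq(genome["chr"][401:601]).reverse_complement())
        # the TSS base, read on the minus strand
        assert w.seq[w.index_of(0)] == str(Seq(genome["chr"][500]).complement())
        # one base upstream on the minus strand = genomic position 501
        assert w.seq[w.index_of(-1)] == str(Seq(genome["chr"][501]).complement())

    def test_truncation_near_replicon_edge(self):
        w = extract_window(random_genome(), "chr", 20, "+", 100, 100)
        assert w.upstream_len == 20 and w.truncated_upstream
        assert not w.truncated_downstream

    def test_out_of_range_tss_rejected(self):
        with pytest.raises(ValueError):
            extract_window(random_genome(), "chr", 5000, "+")
        with pytest.raises(KeyError):
            extract_window(random_genome(), "nope", 10, "+")


class TestScanMotif:
    def test_exact_consensus_found_at_planted_position(self):
        models = default_models()
        tata = models["TATA"]
        seq = "C" * 71 + TATA_CONSENSUS + "C" * (200 - 71 - len(TATA_CONSENSUS))
        w = Window(seq=seq, upstream_len=100, downstream_len=100)
        hit = scan_motif(w, tata)
        assert hit is not None
        assert hit.position == -29
        assert hit.score == pytest.approx(tata.max_score)

    def test_tie_resolves_most_upstream(self):
        tata = default_models()["TATA"]
        seq = "C" * 10 + TATA_CONSENSUS + "C" * 30 + TATA_CONSENSUS + "C" * 30
        w = Window(seq=seq, upstream_len=50, downstream_len=len(seq) - 50)
        assert scan_motif(w, tata).position == 10 - 50

    def test_window_shorter_than_motif_is_absent(self):
        tata = default_models()["TATA"]
        assert scan_motif(Window("ACG", 1, 2), tata) is None

    def test_scan_equals_exhaustive_scoring(self):
        """The vectorized scan must equal per-offset brute-force scoring."""
        rng = np.random.default_rng(3)
        model = default_models()["BRE"]
        lowered = MotifModel(
            "BRE", model.pwm, threshold=-1e9, expected_centroid=-38, scan_range=None
        )
        idx = {b: i for i, b in enumerate("ACGT")}
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
            w = Window(seq, 75, 75)
            hit = scan_motif(w, lowered)
            scores = [
                sum(lowered.pwm[j, idx[seq[i + j]]] for j in range(lowered.width))
                for i in range(len(seq) - lowered.width + 1)
            ]
            best = int(np.argmax(scores))
            assert hit.position == w.position_of(best)
            assert hit.score == pytest.approx(scores[best])

    def test_stringent_threshold_rarely_hits_random_sequence(self):
        rng = np.random.default_rng(4)
        model = default_models()["BRE"]
        hits = 0
        n = 300
        for _ in range(n):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
            if scan_motif(Window(seq, 100, 100), model) is not None:
                hits += 1
        # expected ~ (200-7) * 4^-8 ~ 0.003 per window
        assert hits / n < 0.03


class TestCentroidAndFractions:
    def test_centroid_of_constant_and_symmetric_hits(self):
        models = default_models()
        tata = models["TATA"]

        def scan_for(pos):
            seq = "C" * (100 + pos) + TATA_CONSENSUS + "C" * (100 - pos - tata.width)
            w = Window(seq, 100, 100)
            from halosrna.motifs import PromoterScan

            return PromoterScan("s", w, {"TATA": scan_motif(w, tata)})

        same = [scan_for(-29), scan_for(-29)]
        c = centroid(same, "TATA")
        assert c["mean"] == -29 and c["sd"] == 0
        sym = [scan_for(-27), scan_for(-31)]
        assert centroid(sym, "TATA")["mean"] == -29

    def test_zero_hits_is_empty_not_error(self):
        assert centroid([], "TATA") == {"n": 0, "mean": None, "sd": None}


class TestPlantedRecovery:
    def _planted_scans(self, seed, motif_fraction=0.3):
        params = small_params(seed=seed, motif_fraction=motif_fraction)
        rng = np.random.default_rng(seed)
        ann, genome = simulate_genome(params, rng)
        transcripts, truth = plant_srnas(ann, params, rng)
        genome = plant_motifs(genome, transcripts, truth, params, rng)
        models = default_models()
        eligible = [
            t
            for t in transcripts
            if truth.class_of[t.transcript_id] in ("antisense", "intergenic")
        ]
        tss_list = [
            (
                t.transcript_id,
                t.chrom,
                t.interval.start if t.strand == "+" else t.interval.end - 1,
                t.strand,
            )
            for t in eligible
        ]
        return scan_promoters(genome, tss_list, models), models, truth

    def test_planted_centroids_recovered(self):
        """Pooled over seeds, hit centroids sit at the planted offsets;
        occasional chance background 8-mers cannot move them by > 1 nt."""
        pooled = []
        for seed in range(6):
            scans, models, truth = self._planted_scans(seed)
            pooled.extend(scans)
        assert centroid(pooled, "BRE")["mean"] == pytest.approx(-38, abs=1)
        assert centroid(pooled, "TATA")["mean"] == pytest.approx(-29, abs=1)

    def test_minus_strand_srnas_recover_motifs(self):
        scans, models, truth = self._planted_scans(1, motif_fraction=1.0)
        with_hits = [s for s in scans if s.hits["TATA"] is not None]
        assert len(with_hits) == len(scans)  # planted for every sRNA
        assert all(s.hits["TATA"].position == -29 for s in scans)

    def test_fraction_matches_planted_and_relaxed_is_monotone(self):
        for seed in range(5):
            scans, models, truth = self._planted_scans(seed)
            frac = fraction_with_promoter(scans, models)
            planted = len(truth.motif_position_of) / len(scans)
            assert frac["strict"] == pytest.approx(planted, abs=0.06)
            assert frac["relaxed"] >= frac["strict"]

    def test_no_planting_gives_near_zero_fraction(self):
        scans, models, _ = self._planted_scans(2, motif_fraction=0.0)
        frac = fraction_with_promoter(scans, models)
        assert frac["strict"] <= 0.05


class TestStrandSymmetry:
    def test_reverse_complementing_genome_preserves_hits(self):
        params = small_params(seed=3, motif_fraction=1.0)
        rng = np.random.default_rng(3)
        ann, genome = simulate_genome(params, rng)
        transcripts, truth = plant_srnas(ann, params, rng)
        genome = plant_motifs(genome, transcripts, truth, params, rng)
        models = default_models()
        L = len(genome["chr1"])
        flipped = {"chr1": str(Seq(genome["chr1"]).reverse_complement())}
        for t in transcripts[:10]:
            tss = t.interval.start if t.strand == "+" else t.interval.end - 1
            fl_strand = "-" if t.strand == "+" else "+"
            fl_tss = L - 1 - tss
            for name, model in models.items():
                orig = scan_motif(extract_window(genome, "chr1", tss, t.strand), model)
                mirr = scan_motif(
                    extract_window(flipped, "chr1", fl_tss, fl_strand), model
                )
                if orig is None:
                    assert mirr is None
                else:
                    assert mirr is not None and mirr.position == orig.position
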