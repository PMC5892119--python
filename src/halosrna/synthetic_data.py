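"""Synthetic genomes, planted sRNAs, replicate counts and promoter motifs.

Every downstream stage of the pipeline is exercised against data generated
here with known ground truth: an annotated single-replicon genome with
non-overlapping genes (a configurable fraction leaderless, i.e. without a
5' UTR, as is typical of haloarchaea), planted antisense sRNAs opposite
chosen gene regions, intergenic sRNAs strictly between genes, decoy
transcripts that the classifier or the expression filter must remove,
negative-binomial replicate counts under a two-condition five-replicate
design with deliberate library-size heterogeneity, and basal promoter
motifs written at fixed TSS-relative offsets.

The negative binomial is parameterized by (mean, dispersion):
Var = mu + alpha * mu^2, matching the differential-expression model.

All generators are deterministic given ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import REGION_LABELS
from .genome_model import (
    GeneFeature,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptRecord,
)
from .quantify import CountMatrix, TPMMatrix

__all__ = [
    "SimParams",
    "SimTruth",
    "SimDataset",
    "GenerationError",
    "simulate_genome",
    "plant_srnas",
    "plant_fold_changes",
    "simulate_counts",
    "plant_motifs",
    "simulate_dataset",
    "nb_draw",
    "make_filter_fixture",
]

_PRODUCT_VOCAB = (
    "IS4 family transposase",
    "ABC transporter ATP-binding protein",
    "universal stress protein",
    "catalase",
    "superoxide dismutase",
    "ribosomal protein",
    "DNA repair protein",
    "halocyanin",
    "hypothetical protein",
    "peptidase",
)


class GenerationError(RuntimeError):
    """The requested synthetic construct cannot be placed."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic study (two conditions x 5 replicates)."""

    n_genes: int = 60
    replicon_name: str = "chr1"
    replicon_length: int = 150_000
    n_asrna: int = 30
    n_intergenic: int = 10
    n_decoy_sense: int = 5
    n_decoy_subthreshold: int = 5
    n_replicates: int = 5
    conditions: tuple[str, str] = ("control", "stress")
    # expression (relative abundance, log-uniform draws; TPM after the
    # per-million normalization built into simulate_counts)
    nb_mean_range: tuple[float, float] = (50.0, 5000.0)  # genes + intergenic sRNAs
    srna_target_ratio_range: tuple[float, float] = (2.0, 20.0)  # asRNA / cis target
    decoy_tpm_range: tuple[float, float] = (1.0, 5.0)  # final TPM of low decoys
    nb_dispersion: float = 0.05
    total_reads: int = 300_000
    library_scale_spread: float = 2.0  # max/min library scale factor
    # planted regulation
    planted_lfc: Optional[Mapping[str, float]] = None
    srna_lfc: float = 2.0
    anti_corr_fraction: float = 0.25
    # sRNA geometry
    srna_length_range: tuple[int, int] = (50, 1000)
    min_overlap: int = 8
    region_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"utr5": 0.07, "utr3": 0.26, "cds": 0.67}
    )
    # gene geometry
    cds_length_range: tuple[int, int] = (600, 1500)
    utr5_length_range: tuple[int, int] = (20, 100)
    utr3_length_range: tuple[int, int] = (30, 150)
    gap_range: tuple[int, int] = (300, 1500)
    leaderless_fraction: float = 0.5
    # promoter motifs
    motif_offsets: Mapping[str, int] = field(
        default_factory=lambda: {"BRE": -38, "TATA": -29}
    )
    motif_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_asrna",
            "n_intergenic",
            "n_decoy_sense",
            "n_decoy_subthreshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.anti_corr_fraction <= 1.0:
            raise ValueError("anti_corr_fraction must lie in [0, 1]")
        if not 0.0 <= self.motif_fraction <= 1.0:
            raise ValueError("motif_fraction must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if abs(sum(self.region_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("region_proportions must sum to 1")
        mean_gene = (
            np.mean(self.cds_length_range)
            + np.mean(self.utr5_length_range) * (1 - self.leaderless_fraction)
            + np.mean(self.utr3_length_range)
        )
        if self.n_genes * mean_gene > self.replicon_length / 2:
            raise ValueError(
                "infeasible packing: n_genes x mean gene length exceeds half "
                "the replicon; increase replicon_length"
            )


@dataclass
class SimTruth:
    """Planted ground truth against which every stage is scored."""

    class_of: dict[str, str] = field(default_factory=dict)
    cis_target_of: dict[str, tuple[str, str]] = field(default_factory=dict)
    true_lfc: dict[str, float] = field(default_factory=dict)
    anti_corr_targets: set[str] = field(default_factory=set)
    motif_position_of: dict[str, dict[str, int]] = field(default_factory=dict)
    lib_scales: dict[str, float] = field(default_factory=dict)
    base_tpm: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        ids = list(self.class_of)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ids in class_of")


@dataclass
class SimDataset:
    params: SimParams
    annotation: GenomeAnnotation
    genome: dict[str, str]
    transcripts: list[TranscriptRecord]
    counts: CountMatrix
    truth: SimTruth


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + alpha*mu^2 (vectorized)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("NB mean must be non-negative")
    if alpha <= 0:
        raise ValueError("NB dispersion must be > 0")
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    params: SimParams, rng: Optional[np.random.Generator] = None
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Random background sequence plus non-overlapping gene models.

    Genes are laid left to right with random inter-gene gaps; strands are
    random, and a ``leaderless_fraction`` of genes lack a 5' UTR.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    chrom = params.replicon_name
    genes: list[GeneFeature] = []
    cursor = 0
    for i in range(params.n_genes):
        gap = int(rng.integers(params.gap_range[0], params.gap_range[1] + 1))
        cds_len = int(rng.integers(params.cds_length_range[0], params.cds_length_range[1] + 1))
        leaderless = rng.random() < params.leaderless_fraction
        utr5_len = (
            0
            if leaderless
            else int(rng.integers(params.utr5_length_range[0], params.utr5_length_range[1] + 1))
        )
        utr3_len = int(rng.integers(params.utr3_length_range[0], params.utr3_length_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor + gap
        end = start + utr5_len + cds_len + utr3_len
        if end > params.replicon_length:
            raise GenerationError(
                f"could not place gene {i + 1}/{params.n_genes}; "
                "increase replicon_length or reduce n_genes"
            )
        if strand == "+":
            utr5 = (
                GenomicInterval(chrom, start, start + utr5_len, strand) if utr5_len else None
            )
            cds = GenomicInterval(chrom, start + utr5_len, start + utr5_len + cds_len, strand)
            utr3 = GenomicInterval(chrom, cds.end, end, strand) if utr3_len else None
        else:
            # transcription right-to-left: 3' UTR at low coordinates
            utr3 = GenomicInterval(chrom, start, start + utr3_len, strand) if utr3_len else None
            cds = GenomicInterval(chrom, start + utr3_len, start + utr3_len + cds_len, strand)
            utr5 = GenomicInterval(chrom, cds.end, end, strand) if utr5_len else None
        product = _PRODUCT_VOCAB[int(rng.integers(0, len(_PRODUCT_VOCAB)))]
        genes.append(
            GeneFeature(
                gene_id=f"HSR_{i + 1:04d}",
                interval=GenomicInterval(chrom, start, end, strand),
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                product=product,
            )
        )
        cursor = end
    seq_codes = rng.integers(0, 4, size=params.replicon_length)
    seq = np.frombuffer(b"ACGT", dtype="S1")[seq_codes].tobytes().decode()
    ann = GenomeAnnotation(genes, {chrom: params.replicon_length})
    return ann, {chrom: seq}


# ---------------------------------------------------------------------------
# sRNA placement


# keep planted transcripts this far from replicon edges so promoter windows
# and motif offsets never run off the sequence
EDGE_MARGIN = 150


def _neighbor_bounds(sorted_genes: Sequence[GeneFeature], idx: int, replicon_length: int):
    left = sorted_genes[idx - 1].interval.end if idx > 0 else EDGE_MARGIN
    right = (
        sorted_genes[idx + 1].interval.start
        if idx + 1 < len(sorted_genes)
        else replicon_length - EDGE_MARGIN
    )
    return left, right


def _place_asrna(
    gene: GeneFeature,
    region: str,
    left_bound: int,
    right_bound: int,
    params: SimParams,
    rng: np.random.Generator,
) -> Optional[GenomicInterval]:
    """One attempt to place an antisense transcript over ``region`` of ``gene``.

    The transcript sits on the opposite strand, overlaps only the intended
    region of the gene, and may extend outward into the flanking gap
    (never reaching a neighboring gene).  Returns None when the draw does
    not fit.
    """
    lmin, lmax = params.srna_length_range
    sub = {"utr5": gene.utr5, "utr3": gene.utr3, "cds": gene.cds}[region]
    if sub is None:
        return None
    opp = "-" if gene.strand == "+" else "+"
    chrom = gene.chrom
    if region == "cds":
        max_len = min(lmax, sub.length)
        if max_len < max(lmin, params.min_overlap):
            return None
        length = int(rng.integers(max(lmin, params.min_overlap), max_len + 1))
        start = int(rng.integers(sub.start, sub.end - length + 1))
        return GenomicInterval(chrom, start, start + length, opp)
    # UTR regions sit at a gene edge; overlap the UTR by `ov` nt and extend
    # outward into the gap, keeping >= 1 nt clear of the neighboring gene.
    at_right_edge = sub.end == gene.interval.end
    ov_max = sub.length
    if ov_max < params.min_overlap:
        return None
    ov = int(rng.integers(params.min_overlap, ov_max + 1))
    if at_right_edge:
        room = (right_bound - 1) - gene.interval.end
        max_len = min(lmax, ov + max(room, 0))
        if max_len < lmin:
            return None
        length = int(rng.integers(lmin, max_len + 1))
        start = gene.interval.end - ov
        return GenomicInterval(chrom, start, start + length, opp)
    room = gene.interval.start - (left_bound + 1)
    max_len = min(lmax, ov + max(room, 0))
    if max_len < lmin:
        return None
    length = int(rng.integers(lmin, max_len + 1))
    end = gene.interval.start + ov
    return GenomicInterval(chrom, end - length, end, opp)


def plant_srnas(
    ann: GenomeAnnotation,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[TranscriptRecord], SimTruth]:
    """Plant antisense/intergenic sRNAs plus decoy transcripts.

    Antisense sRNAs target distinct genes, opposite strand, with the
    intended binding region drawn from ``region_proportions``; intergenic
    sRNAs fall strictly between genes; decoy-sense transcripts overlap a
    gene on its own strand; sub-threshold decoys are genomically valid
    asRNAs that will be planted at low expression.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    truth = SimTruth()
    chrom = params.replicon_name
    sorted_genes = sorted(ann.genes, key=lambda g: g.interval.start)
    idx_of = {g.gene_id: i for i, g in enumerate(sorted_genes)}
    records: list[TranscriptRecord] = []

    regions = list(params.region_proportions)
    probs = np.array([params.region_proportions[r] for r in regions], dtype=float)

    def place_antisense(n: int, id_prefix: str, cls: str) -> None:
        # the intended region is drawn first (preserving the configured
        # proportions) and only the target gene is re-drawn on failure
        used: set[int] = set()
        for placed in range(1, n + 1):
            region = regions[int(rng.choice(len(regions), p=probs))]
            iv = None
            gene = None
            for _attempt in range(200):
                candidates = [i for i in range(len(sorted_genes)) if i not in used]
                if not candidates:
                    raise GenerationError(f"ran out of target genes for {cls} transcripts")
                gi = candidates[int(rng.integers(0, len(candidates)))]
                gene = sorted_genes[gi]
                left, right = _neighbor_bounds(
                    sorted_genes, gi, ann.replicon_lengths[chrom]
                )
                iv = _place_asrna(gene, region, left, right, params, rng)
                if iv is not None:
                    used.add(gi)
                    break
            if iv is None:
                raise GenerationError(f"no room to place {cls} transcript {placed}/{n}")
            tid = f"{id_prefix}{placed:04d}"
            records.append(TranscriptRecord(tid, iv))
            truth.class_of[tid] = cls
            truth.cis_target_of[tid] = (gene.gene_id, REGION_LABELS[region])

    place_antisense(params.n_asrna, "asRNA_", "antisense")

    # intergenic sRNAs: strictly inside gaps, >= 1 nt clear of both genes
    gaps = []
    prev_end = EDGE_MARGIN
    for g in sorted_genes:
        if g.interval.start - prev_end >= params.srna_length_range[0] + 2:
            gaps.append((prev_end, g.interval.start))
        prev_end = g.interval.end
    tail_end = ann.replicon_lengths[chrom] - EDGE_MARGIN
    if tail_end - prev_end >= params.srna_length_range[0] + 2:
        gaps.append((prev_end, tail_end))
    for j in range(params.n_intergenic):
        if not gaps:
            raise GenerationError("no intergenic gap large enough for an sRNA")
        lo, hi = gaps[int(rng.integers(0, len(gaps)))]
        avail = hi - lo - 2
        length = int(
            rng.integers(
                params.srna_length_range[0],
                min(params.srna_length_range[1], avail) + 1,
            )
        )
        start = int(rng.integers(lo + 1, hi - 1 - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tid = f"igRNA_{j + 1:04d}"
        records.append(TranscriptRecord(tid, GenomicInterval(chrom, start, start + length, strand)))
        truth.class_of[tid] = "intergenic"

    # decoy sense transcripts: inside a gene's CDS on the SAME strand
    for j in range(params.n_decoy_sense):
        gene = sorted_genes[int(rng.integers(0, len(sorted_genes)))]
        max_len = min(params.srna_length_range[1], gene.cds.length)
        length = int(rng.integers(params.srna_length_range[0], max_len + 1))
        start = int(rng.integers(gene.cds.start, gene.cds.end - length + 1))
        tid = f"decoySense_{j + 1:03d}"
        records.append(
            TranscriptRecord(tid, GenomicInterval(chrom, start, start + length, gene.strand))
        )
        truth.class_of[tid] = "decoy-sense"

    # sub-threshold decoys: genomically valid asRNAs planted at low expression
    place_antisense(params.n_decoy_subthreshold, "decoyLow_", "sub-threshold-decoy")

    truth.validate()
    return records, truth


def plant_fold_changes(
    truth: SimTruth, params: SimParams, rng: Optional[np.random.Generator] = None
) -> SimTruth:
    """Assign planted log2 fold changes (stress vs control).

    Every antisense sRNA is differentially expressed by ``srna_lfc`` with
    a random sign (up and down in balance, as in stress-response data); a
    fraction ``anti_corr_fraction`` of cis pairs gets an opposite-sign
    fold change planted on the target — the negative-regulation signature.
    Intergenic sRNAs are up/down/unchanged with probabilities 0.3/0.3/0.4;
    everything else is flat.  An explicit ``params.planted_lfc`` overrides
    all of this.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.planted_lfc is not None:
        truth.true_lfc = dict(params.planted_lfc)
        return truth
    lfc: dict[str, float] = {}
    for tid, cls in truth.class_of.items():
        if cls == "antisense":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc[tid] = sign * params.srna_lfc
            gene_id, _ = truth.cis_target_of[tid]
            if rng.random() < params.anti_corr_fraction:
                lfc[gene_id] = -sign * params.srna_lfc
                truth.anti_corr_targets.add(gene_id)
        elif cls == "intergenic":
            u = rng.random()
            lfc[tid] = params.srna_lfc if u < 0.3 else (-params.srna_lfc if u < 0.6 else 0.0)
        else:
            lfc[tid] = 0.0
    truth.true_lfc = lfc
    return truth


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    ann: GenomeAnnotation,
    transcripts: Sequence[TranscriptRecord],
    truth: SimTruth,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> CountMatrix:
    """Negative-binomial replicate counts for genes + planted transcripts.

    Expression levels are drawn as relative abundances: genes and
    intergenic sRNAs log-uniformly over ``nb_mean_range``; each antisense
    sRNA as a multiple (``srna_target_ratio_range``) of its cis target, so
    that the sRNA-above-target expression pattern is planted; low decoys
    end up at a final TPM inside ``decoy_tpm_range``.  Abundances are
    normalized to one million (control condition), so draws double as true
    TPM.  Per-sample library scales vary within ``library_scale_spread``
    so size-factor estimation is non-trivial, and planted log2 fold
    changes multiply the stress-condition means.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    gene_ids = [g.gene_id for g in ann.genes]
    t_ids = [t.transcript_id for t in transcripts]
    gene_raw = dict(zip(gene_ids, _loguniform(rng, *params.nb_mean_range, len(gene_ids))))
    t_raw: dict[str, float] = {}
    low_ids: list[str] = []
    for tid in t_ids:
        cls = truth.class_of[tid]
        if cls == "antisense":
            gene_id, _ = truth.cis_target_of[tid]
            ratio = _loguniform(rng, *params.srna_target_ratio_range, 1)[0]
            t_raw[tid] = gene_raw[gene_id] * ratio
        elif cls in ("intergenic", "decoy-sense"):
            t_raw[tid] = _loguniform(rng, *params.nb_mean_range, 1)[0]
        else:  # sub-threshold decoy: final TPM fixed after normalization
            t_raw[tid] = float("nan")
            low_ids.append(tid)
    main_total = sum(gene_raw.values()) + sum(v for v in t_raw.values() if v == v)
    for tid in low_ids:
        desired = _loguniform(rng, *params.decoy_tpm_range, 1)[0]
        t_raw[tid] = desired * main_total / 1e6  # ~desired TPM after normalization

    ids = gene_ids + t_ids
    raw = np.array([gene_raw.get(f, t_raw.get(f)) for f in ids])
    tpm = raw * 1e6 / raw.sum()
    lengths = np.array(
        [ann.gene(g).interval.length for g in gene_ids]
        + [t.length_nt for t in transcripts],
        dtype=float,
    )
    lfc = np.array([truth.true_lfc.get(f, 0.0) for f in ids])
    truth.base_tpm = dict(zip(ids, tpm))

    half = np.log2(params.library_scale_spread) / 2.0
    sample_ids, cond_labels, scales = [], [], []
    for cond in params.conditions:
        for r in range(1, params.n_replicates + 1):
            sample_ids.append(f"{cond}_{r}")
            cond_labels.append(cond)
            scales.append(float(2.0 ** rng.uniform(-half, half)))
    truth.lib_scales = dict(zip(sample_ids, scales))

    depth = params.total_reads / float((tpm * lengths).sum() / 1e6)
    counts = np.zeros((len(ids), len(sample_ids)), dtype=np.int64)
    stress_name = params.conditions[1]
    for s, (sid, cond, scale) in enumerate(zip(sample_ids, cond_labels, scales)):
        fold = np.where(cond == stress_name, 2.0**lfc, 1.0)
        mu = scale * depth * (tpm / 1e6) * fold * lengths
        counts[:, s] = nb_draw(rng, mu, params.nb_dispersion)

    samples = pd.DataFrame(
        {
            "condition": cond_labels,
            "replicate": [int(s.split("_")[-1]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    df = pd.DataFrame(counts, index=pd.Index(ids, name="feature"), columns=sample_ids)
    return CountMatrix(df, pd.Series(lengths, index=df.index, name="length"), samples)


# ---------------------------------------------------------------------------
# motifs


def plant_motifs(
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptRecord],
    truth: SimTruth,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
    consensus: Optional[Mapping[str, str]] = None,
) -> dict[str, str]:
    """Write promoter consensus strings upstream of a fraction of sRNA TSSs.

    Offsets are TSS-relative motif start positions (upstream negative) in
    transcription orientation; on the minus strand the reverse complement
    is written at the mirrored genomic coordinates.  Returns the modified
    genome; planted positions are recorded in ``truth.motif_position_of``.
    """
    from .motifs import BRE_CONSENSUS, TATA_CONSENSUS

    if rng is None:
        rng = np.random.default_rng(params.seed)
    if consensus is None:
        consensus = {"BRE": BRE_CONSENSUS, "TATA": TATA_CONSENSUS}
    seqs = {chrom: np.frombuffer(s.encode(), dtype="S1").copy() for chrom, s in genome.items()}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    eligible = [
        t
        for t in transcripts
        if truth.class_of.get(t.transcript_id) in ("antisense", "intergenic")
    ]
    n_pick = int(round(params.motif_fraction * len(eligible)))
    picked_idx = rng.choice(len(eligible), size=n_pick, replace=False) if n_pick else []
    for i in sorted(int(j) for j in np.atleast_1d(picked_idx)):
        t = eligible[i]
        iv = t.interval
        tss = iv.start if iv.strand == "+" else iv.end - 1
        arr = seqs[iv.chrom]
        for name, offset in params.motif_offsets.items():
            motif = consensus[name]
            w = len(motif)
            if iv.strand == "+":
                gstart = tss + offset
                gend = gstart + w
                written = motif
            else:
                gstart = tss - offset - w + 1
                gend = tss - offset + 1
                written = "".join(comp[b] for b in reversed(motif))
            if gstart < 0 or gend > len(arr):
                raise GenerationError(
                    f"motif {name} for {t.transcript_id} falls outside the replicon"
                )
            arr[gstart:gend] = np.frombuffer(written.encode(), dtype="S1")
        truth.motif_position_of[t.transcript_id] = dict(params.motif_offsets)
    return {chrom: arr.tobytes().decode() for chrom, arr in seqs.items()}


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(params: SimParams) -> SimDataset:
    """Full synthetic study: genome, planted sRNAs, fold changes, counts,
    and promoter motifs, all driven by ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    ann, genome = simulate_genome(params, rng)
    transcripts, truth = plant_srnas(ann, params, rng)
    plant_fold_changes(truth, params, rng)
    counts = simulate_counts(ann, transcripts, truth, params, rng)
    genome = plant_motifs(genome, transcripts, truth, params, rng)
    return SimDataset(params, ann, genome, transcripts, counts, truth)


# ---------------------------------------------------------------------------
# deterministic filter fixture


def make_filter_fixture() -> tuple[TPMMatrix, dict[str, str], set[str]]:
    """A deterministic TPM matrix exercising the presence/expression filter.

    Ten antisense and ten intergenic sRNAs sit at or above their class
    thresholds (40 / 14 TPM condition mean) with 5/5 nonzero replicates;
    decoys fail either the expression or the detection criterion.  Returns
    (matrix, class map, ids expected to pass).
    """
    rows: dict[str, list[float]] = {}
    classes: dict[str, str] = {}
    expected: set[str] = set()
    for i in range(10):
        tid = f"as_pass_{i}"
        rows[tid] = [40.0 + i, 45.0 + i, 41.0, 44.0, 52.0]
        classes[tid] = "antisense"
        expected.add(tid)
        tid = f"ig_pass_{i}"
        rows[tid] = [14.0, 14.0 + i, 15.0, 16.0, 14.0]
        classes[tid] = "intergenic"
        expected.add(tid)
    for i in range(5):
        # expression decoys: detected 5/5 but mean below threshold
        tid = f"as_low_{i}"
        rows[tid] = [30.0, 35.0, 32.0, 31.0, 30.0]
        classes[tid] = "antisense"
        tid = f"ig_low_{i}"
        rows[tid] = [5.0, 6.0, 5.0, 7.0, 6.0]
        classes[tid] = "intergenic"
        # detection decoys: high TPM but present in only 3/5 replicates
        tid = f"as_sparse_{i}"
        rows[tid] = [500.0, 400.0, 450.0, 0.0, 0.0]
        classes[tid] = "antisense"
    # bulk features so TPM values are plausible fractions of a library
    for i in range(20):
        rows[f"gene_{i}"] = [40_000.0 + 100 * i] * 5
    samples = pd.DataFrame(
        {"condition": ["control"] * 5, "replicate": [1, 2, 3, 4, 5]},
        index=pd.Index([f"control_{r}" for r in range(1, 6)], name="sample"),
    )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples.index)
    df.index.name = "feature"
    return TPMMatrix(df, samples), classes, expected
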