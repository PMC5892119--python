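"""Strand-aware sRNA classification, cis-target pairing and overlap statistics.

An assembled transcript is called an *antisense* sRNA when it overlaps at
least one gene on the opposite strand by at least ``min_overlap``
nucleotides (8 by default) while overlapping no gene on its own strand; it
is *intergenic* when it overlaps no gene on either strand.  Transcripts
overlapping a same-strand gene are excluded outright — with a strand-specific
library they cannot be separated from the gene's own transcript — and
opposite-strand overlaps shorter than the minimum are excluded as
sub-threshold.

The "gene" here is the annotated gene span including UTRs, i.e. the gene
and its annotated regulatory elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_model import GeneFeature, GenomeAnnotation, GenomicInterval, TranscriptRecord

__all__ = [
    "SRnaClass",
    "CisPair",
    "SRnaRecord",
    "OverlapStats",
    "classify_transcript",
    "classify_all",
    "find_cis_targets",
    "bin_binding_region",
    "overlap_stats",
]

DEFAULT_MIN_OVERLAP = 8

# Binding-region tie-break precedence: UTR contact is the mechanistically
# informative call, and 5' precedes 3'.
_REGION_PRECEDENCE = ("utr5", "utr3", "cds")
REGION_LABELS = {"utr5": "5'UTR", "utr3": "3'UTR", "cds": "CDS"}


class SRnaClass(str, Enum):
    ANTISENSE = "antisense"
    INTERGENIC = "intergenic"
    EXCLUDED_SENSE = "excluded-sense"
    EXCLUDED_SUBTHRESHOLD = "excluded-subthreshold"

    def __str__(self) -> str:  # serialize as the plain label
        return self.value


@dataclass(frozen=True)
class CisPair:
    """One asRNA paired with one opposite-strand (cis) target gene."""

    srna_id: str
    gene_id: str
    overlap_nt: int
    utr5_nt: int
    cds_nt: int
    utr3_nt: int
    binding_region: str

    def __post_init__(self) -> None:
        if self.overlap_nt != self.utr5_nt + self.cds_nt + self.utr3_nt:
            raise ValueError(
                f"pair {self.srna_id}/{self.gene_id}: overlap {self.overlap_nt} != "
                f"region breakdown sum"
            )


@dataclass
class SRnaRecord:
    """A classified sRNA with its cis targets (empty for intergenic sRNAs)."""

    transcript: TranscriptRecord
    srna_class: str
    cis_targets: list[CisPair] = field(default_factory=list)

    @property
    def primary_target(self) -> Optional[CisPair]:
        return self.cis_targets[0] if self.cis_targets else None


@dataclass(frozen=True)
class OverlapStats:
    median_nt: float
    mean_nt: float
    min_nt: int
    max_nt: int
    bin_edges: tuple[int, ...]
    histogram: tuple[int, ...]


def _region_breakdown(t_iv: GenomicInterval, gene: GeneFeature) -> dict[str, int]:
    out = {}
    for name, sub in (("utr5", gene.utr5), ("cds", gene.cds), ("utr3", gene.utr3)):
        out[name] = 0 if sub is None else t_iv.overlap_nt(sub)
    return out


def bin_binding_region(utr5_nt: int, cds_nt: int, utr3_nt: int) -> str:
    """Assign the binding-region label from the per-region overlap breakdown.

    The label is the region holding the maximal overlap share; exact ties
    break by precedence 5'UTR > 3'UTR > CDS.
    """
    breakdown = {"utr5": utr5_nt, "cds": cds_nt, "utr3": utr3_nt}
    if all(v <= 0 for v in breakdown.values()):
        raise ValueError("all-zero region breakdown: pair has no overlap with the gene")
    best = max(_REGION_PRECEDENCE, key=lambda r: (breakdown[r], -_REGION_PRECEDENCE.index(r)))
    return REGION_LABELS[best]


def _make_pair(t: TranscriptRecord, gene: GeneFeature) -> CisPair:
    breakdown = _region_breakdown(t.interval, gene)
    return CisPair(
        srna_id=t.transcript_id,
        gene_id=gene.gene_id,
        overlap_nt=sum(breakdown.values()),
        utr5_nt=breakdown["utr5"],
        cds_nt=breakdown["cds"],
        utr3_nt=breakdown["utr3"],
        binding_region=bin_binding_region(**{f"{k}_nt": v for k, v in breakdown.items()}),
    )


def find_cis_targets(
    asrna: TranscriptRecord,
    ann: GenomeAnnotation,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[CisPair]:
    """All opposite-strand genes overlapping ``asrna`` by >= min_overlap nt.

    Sorted by descending overlap (ties by gene start, then id); the first
    entry is the primary target.  An asRNA straddling two adjacent genes —
    e.g. the 3' UTR of one and the 5' UTR of the next — yields two pairs.
    """
    iv = asrna.interval
    opposite = "+" if iv.strand == "-" else "-"
    pairs = []
    for gene in ann.overlapping(iv.chrom, iv.start, iv.end, opposite):
        if iv.overlap_nt(gene.interval) >= min_overlap:
            pairs.append(_make_pair(asrna, gene))
    genes = {p.gene_id: ann.gene(p.gene_id) for p in pairs}
    pairs.sort(key=lambda p: (-p.overlap_nt, genes[p.gene_id].interval.start, p.gene_id))
    return pairs


def classify_transcript(
    t: TranscriptRecord,
    ann: GenomeAnnotation,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> SRnaRecord:
    """Classify one transcript against the annotation.

    Precedence: any same-strand gene overlap excludes the transcript;
    otherwise an opposite-strand overlap >= ``min_overlap`` makes it
    antisense (even if it also extends into intergenic space); an
    opposite-strand overlap in [1, min_overlap) is excluded as
    sub-threshold; no overlap at all is intergenic.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    iv = t.interval
    if iv.chrom not in ann.replicon_lengths:
        raise KeyError(f"unknown replicon {iv.chrom!r}")
    same = [
        g
        for g in ann.overlapping(iv.chrom, iv.start, iv.end, iv.strand)
        if iv.overlap_nt(g.interval) > 0
    ]
    if same:
        return SRnaRecord(t, SRnaClass.EXCLUDED_SENSE.value)
    opposite = "+" if iv.strand == "-" else "-"
    opp = [
        g
        for g in ann.overlapping(iv.chrom, iv.start, iv.end, opposite)
        if iv.overlap_nt(g.interval) > 0
    ]
    if not opp:
        return SRnaRecord(t, SRnaClass.INTERGENIC.value)
    pairs = find_cis_targets(t, ann, min_overlap)
    if pairs:
        return SRnaRecord(t, SRnaClass.ANTISENSE.value, pairs)
    return SRnaRecord(t, SRnaClass.EXCLUDED_SUBTHRESHOLD.value)


def classify_all(
    transcripts: Iterable[TranscriptRecord],
    ann: GenomeAnnotation,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[SRnaRecord]:
    return [classify_transcript(t, ann, min_overlap) for t in transcripts]


def overlap_stats(pairs: Sequence[CisPair], bin_width: int = 50) -> OverlapStats:
    """Summary statistics of primary-target overlap lengths.

    ``pairs`` should hold one (primary) pair per asRNA; the histogram uses
    fixed-width bins starting at 0.
    """
    if len(pairs) == 0:
        raise ValueError("overlap_stats requires at least one pair")
    lengths = np.array([p.overlap_nt for p in pairs], dtype=float)
    hi = int(np.ceil(lengths.max() / bin_width)) * bin_width
    hi = max(hi, bin_width)
    edges = np.arange(0, hi + bin_width, bin_width)
    hist, _ = np.histogram(lengths, bins=edges)
    return OverlapStats(
        median_nt=float(np.median(lengths)),
        mean_nt=float(np.mean(lengths)),
        min_nt=int(lengths.min()),
        max_nt=int(lengths.max()),
        bin_edges=tuple(int(e) for e in edges),
        histogram=tuple(int(h) for h in hist),
    )
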