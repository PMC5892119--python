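"""Genomic coordinate types and annotation / transcript I/O.

Internally every interval is 0-based half-open ``[start, end)`` so that the
overlap between two intervals is simply ``min(ends) - max(starts)`` with no
off-by-one corrections.  GFF3/GTF files use 1-based inclusive coordinates;
the converters at the I/O boundary are the only place the two conventions
meet.

Gene models are deliberately simple: one (unspliced) CDS per gene with
optional 5'/3' UTR sub-features, which is adequate for archaeal and
bacterial annotations.  UTRs are taken from the annotation — they are not
predicted here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import gffutils
from gffutils.iterators import DataIterator
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneFeature",
    "GenomeAnnotation",
    "TranscriptRecord",
    "AnnotationError",
    "ParseError",
    "read_annotation",
    "write_annotation",
    "read_transcripts",
    "write_transcripts",
    "read_srna_gff",
    "write_srna_gff",
]

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Invalid or inconsistent annotation content."""


class ParseError(ValueError):
    """Malformed annotation/transcript file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a replicon, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_nt(self, other: "GenomicInterval") -> int:
        """Strand-agnostic overlap length in nucleotides (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, delta: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + delta, self.end + delta, self.strand)

    def flipped(self) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start, self.end, "+" if self.strand == "-" else "-"
        )


@dataclass(frozen=True)
class GeneFeature:
    """A gene with its CDS and optional UTR sub-intervals.

    The gene ``interval`` spans CDS plus any annotated UTRs; a missing UTR
    means the gene is leaderless (5') or has no annotated trailer (3') and
    contributes zero length to region binning.
    """

    gene_id: str
    interval: GenomicInterval
    cds: GenomicInterval
    utr5: Optional[GenomicInterval] = None
    utr3: Optional[GenomicInterval] = None
    product: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.cds):
            raise AnnotationError(f"{self.gene_id}: CDS not contained in gene interval")
        if self.cds.strand != self.interval.strand:
            raise AnnotationError(f"{self.gene_id}: CDS strand differs from gene strand")
        fwd = self.interval.strand == "+"
        for name, utr, upstream in (("utr5", self.utr5, True), ("utr3", self.utr3, False)):
            if utr is None:
                continue
            if not self.interval.contains(utr):
                raise AnnotationError(f"{self.gene_id}: {name} not contained in gene interval")
            # 5' UTR abuts the CDS on the upstream side in transcription direction.
            before_cds = upstream == fwd
            if before_cds and utr.end != self.cds.start:
                raise AnnotationError(f"{self.gene_id}: {name} does not abut CDS start")
            if not before_cds and utr.start != self.cds.end:
                raise AnnotationError(f"{self.gene_id}: {name} does not abut CDS end")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class TranscriptRecord:
    """A single-exon assembled transcript."""

    transcript_id: str
    interval: GenomicInterval

    @property
    def length_nt(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class GenomeAnnotation:
    """A collection of gene models with a per-(replicon, strand) interval index.

    Parameters
    ----------
    genes
        Gene features; ids must be unique.
    replicon_lengths
        Map replicon name -> length in bp.  Missing replicons are inferred
        from the maximum feature end.
    """

    def __init__(
        self,
        genes: Iterable[GeneFeature],
        replicon_lengths: Mapping[str, int] | None = None,
    ):
        self.genes: list[GeneFeature] = list(genes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        lengths = dict(replicon_lengths or {})
        for g in self.genes:
            need = g.interval.end
            if g.chrom not in lengths:
                lengths[g.chrom] = need
            elif lengths[g.chrom] < need:
                raise AnnotationError(
                    f"gene {g.gene_id} extends past replicon {g.chrom} "
                    f"({need} > {lengths[g.chrom]})"
                )
        self.replicon_lengths: dict[str, int] = lengths
        self._by_id = {g.gene_id: g for g in self.genes}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in self.genes:
            key = (g.chrom, g.strand)
            self._trees.setdefault(key, IntervalTree())[g.interval.start: g.interval.end] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.genes)

    def gene(self, gene_id: str) -> GeneFeature:
        return self._by_id[gene_id]

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneFeature]:
        """Genes whose span overlaps [start, end) on ``strand`` (both if None).

        Results are sorted by (start, gene_id) for determinism.
        """
        strands = STRANDS if strand is None else (strand,)
        hits: list[GeneFeature] = []
        for s in strands:
            tree = self._trees.get((chrom, s))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(start, end))
        hits.sort(key=lambda g: (g.interval.start, g.gene_id))
        return hits


# ---------------------------------------------------------------------------
# I/O helpers


def _check_columns(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError("expected 9 tab-separated columns", lineno)


def _attr_first(feature: gffutils.Feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return None


def _to_interval(feature: gffutils.Feature) -> GenomicInterval:
    # GFF/GTF is 1-based inclusive: [start, end] -> [start-1, end).
    return GenomicInterval(feature.seqid, feature.start - 1, feature.end, feature.strand)


def read_annotation(path: str | os.PathLike, dialect: str = "gff3") -> GenomeAnnotation:
    """Read a GFF3 (or GTF) gene annotation into a :class:`GenomeAnnotation`.

    Genes are ``gene`` features; ``CDS``, ``five_prime_UTR`` and
    ``three_prime_UTR`` children (linked by ``Parent``) populate the
    sub-intervals.  A gene without a CDS child is treated as CDS-only over
    its full span.  Replicon lengths come from ``##sequence-region``
    pragmas when present.
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_columns(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    replicon_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            replicon_lengths[parts[1]] = int(parts[3])

    genes: list[GeneFeature] = []
    seen_ids: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = _attr_first(feat, "ID", "gene_id") or feat.id
        if gid in seen_ids:
            raise AnnotationError(f"duplicate gene_id {gid!r}")
        seen_ids.add(gid)
        interval = _to_interval(feat)
        cds = utr5 = utr3 = None
        for child in db.children(feat.id):
            civ = _to_interval(child)
            if child.featuretype == "CDS":
                if cds is None:
                    cds = civ
                else:  # merged span across (unexpected) multiple CDS rows
                    cds = GenomicInterval(
                        civ.chrom, min(cds.start, civ.start), max(cds.end, civ.end), civ.strand
                    )
            elif child.featuretype == "five_prime_UTR":
                utr5 = civ
            elif child.featuretype == "three_prime_UTR":
                utr3 = civ
        if cds is None:
            cds = interval
        product = _attr_first(feat, "product") or ""
        genes.append(GeneFeature(gid, interval, cds, utr5, utr3, product))
    return GenomeAnnotation(genes, replicon_lengths)


def _gff_attrs(pairs: Sequence[tuple[str, str]]) -> str:
    def esc(v: str) -> str:
        return v.replace(";", "%3B").replace("=", "%3D").replace("\t", "%09")

    return ";".join(f"{k}={esc(v)}" for k, v in pairs if v != "")


def write_annotation(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Serialize a :class:`GenomeAnnotation` back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.replicon_lengths):
            fh.write(f"##sequence-region {chrom} 1 {ann.replicon_lengths[chrom]}\n")
        for g in ann.genes:
            iv = g.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "halosrna",
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        _gff_attrs([("ID", g.gene_id), ("product", g.product)]),
                    ]
                )
                + "\n"
            )
            children = [("CDS", g.cds), ("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)]
            for ftype, sub in children:
                if sub is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            sub.chrom,
                            "halosrna",
                            ftype,
                            str(sub.start + 1),
                            str(sub.end),
                            ".",
                            sub.strand,
                            "0" if ftype == "CDS" else ".",
                            _gff_attrs(
                                [("ID", f"{g.gene_id}.{ftype}"), ("Parent", g.gene_id)]
                            ),
                        ]
                    )
                    + "\n"
                )


def read_transcripts(path: str | os.PathLike) -> list[TranscriptRecord]:
    """Read assembled transcripts from a GTF, preserving file order.

    Only single-exon transcripts are supported; a transcript with more than
    one ``exon`` row raises :class:`AnnotationError`.
    """
    _check_columns(path)
    records: list[TranscriptRecord] = []
    exon_counts: dict[str, int] = {}
    order_seen: set[str] = set()
    for feat in DataIterator(str(path)):
        tid = _attr_first(feat, "transcript_id", "ID")
        if tid is None:
            raise AnnotationError(f"feature at {feat.seqid}:{feat.start} lacks transcript_id")
        if feat.featuretype == "transcript":
            if tid in order_seen:
                raise AnnotationError(f"duplicate transcript_id {tid!r}")
            order_seen.add(tid)
            records.append(TranscriptRecord(tid, _to_interval(feat)))
        elif feat.featuretype == "exon":
            exon_counts[tid] = exon_counts.get(tid, 0) + 1
            if exon_counts[tid] > 1:
                raise AnnotationError(
                    f"transcript {tid!r} has multiple exons; only single-exon "
                    "transcripts are supported"
                )
    return records


def write_transcripts(records: Iterable[TranscriptRecord], path: str | os.PathLike) -> None:
    """Write transcripts as GTF (transcript + single exon rows)."""
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            attrs = f'gene_id "{rec.transcript_id}"; transcript_id "{rec.transcript_id}";'
            for ftype in ("transcript", "exon"):
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            "halosrna",
                            ftype,
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_srna_gff(records, path: str | os.PathLike) -> None:
    """Write classified sRNA records (see :mod:`halosrna.classify`) as GFF3.

    The sRNA class, primary cis target, binding region and overlap length
    are stored as GFF3 attributes so downstream tools (and
    :func:`read_srna_gff`) can recover the classification.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            iv = rec.transcript.interval
            attrs = [("ID", rec.transcript.transcript_id), ("srna_class", rec.srna_class)]
            primary = rec.primary_target
            if primary is not None:
                attrs += [
                    ("cis_target", primary.gene_id),
                    ("binding_region", primary.binding_region),
                    ("overlap_nt", str(primary.overlap_nt)),
                    ("utr5_nt", str(primary.utr5_nt)),
                    ("cds_nt", str(primary.cds_nt)),
                    ("utr3_nt", str(primary.utr3_nt)),
                ]
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "halosrna",
                        "ncRNA",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        _gff_attrs(attrs),
                    ]
                )
                + "\n"
            )


def read_srna_gff(path: str | os.PathLike):
    """Read sRNA calls written by :func:`write_srna_gff`.

    Returns a list of :class:`halosrna.classify.SRnaRecord` with the primary
    target only (secondary targets are not serialized).
    """
    from .classify import CisPair, SRnaRecord  # local import avoids a cycle

    _check_columns(path)
    records = []
    for feat in DataIterator(str(path)):
        tid = _attr_first(feat, "ID")
        iv = _to_interval(feat)
        srna_class = _attr_first(feat, "srna_class") or ""
        target = _attr_first(feat, "cis_target")
        pairs = []
        if target is not None:
            u5 = int(_attr_first(feat, "utr5_nt"))
            cds = int(_attr_first(feat, "cds_nt"))
            u3 = int(_attr_first(feat, "utr3_nt"))
            pairs = [
                CisPair(
                    srna_id=tid,
                    gene_id=target,
                    overlap_nt=int(_attr_first(feat, "overlap_nt")),
                    utr5_nt=u5,
                    cds_nt=cds,
                    utr3_nt=u3,
                    binding_region=_attr_first(feat, "binding_region"),
                )
            ]
        records.append(
            SRnaRecord(
                transcript=TranscriptRecord(tid, iv),
                srna_class=srna_class,
                cis_targets=pairs,
            )
        )
    return records
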