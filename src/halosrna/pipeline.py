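"""End-to-end orchestration: fixture generation, the full analysis run, and
the self-auditing landscape report.

``run_pipeline`` chains the stages classify -> quantify -> pairs -> de ->
effects -> motifs on files in the standard formats, writes one TSV/GFF3
artifact per stage plus a single ``report.json``, and is fully
deterministic given the configuration (the report embeds the parameters
and SHA-256 checksums of every input).  ``audit_report`` recomputes every
summary count in the report from the stage artifacts and reports any
mismatch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import classify as _classify
from . import cis_pairs as _cis
from . import diffexpr as _de
from . import motifs as _motifs
from . import quantify as _quant
from . import regulatory_effects as _reg
from .genome_model import (
    read_annotation,
    read_transcripts,
    write_annotation,
    write_srna_gff,
    write_transcripts,
)
from .synthetic_data import SimParams, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "audit_report", "make_fixture"]


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    Defaults are the analysis defaults throughout the package: minimum
    antisense overlap 8 nt, presence in >= 4 of 5 replicates, TPM
    thresholds 40 (antisense) / 14 (intergenic), pair-test alpha 0.05, DE
    FDR 0.05, 100 nt promoter windows with BRE/TATA centroids at -38/-29.
    """

    annotation: str
    transcripts: str
    counts: str
    samples: str
    genome: str
    outdir: str
    category_map: Optional[str] = None
    min_overlap: int = 8
    min_replicates: int = 4
    tpm_thresholds: dict = field(
        default_factory=lambda: dict(_quant.DEFAULT_TPM_THRESHOLDS)
    )
    filter_mode: str = "mean"
    alpha: float = 0.05
    paired: bool = True
    fdr: float = 0.05
    control: str = "control"
    stress: str = "stress"
    window_upstream: int = 100
    window_downstream: int = 100
    motif_centroids: dict = field(default_factory=lambda: {"BRE": -38, "TATA": -29})
    motif_tolerance: int = 5
    relaxed_shift: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise ValueError("window sizes must be >= 0")
        if self.motif_tolerance < 0 or self.relaxed_shift < 0:
            raise ValueError("motif tolerances must be >= 0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        base = Path(path).parent
        for key in ("annotation", "transcripts", "counts", "samples", "genome",
                    "outdir", "category_map"):
            if data.get(key) and not os.path.isabs(str(data[key])):
                data[key] = str(base / data[key])
        return cls.from_dict(data)


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _tss_of(record) -> int:
    iv = record.interval
    return iv.start if iv.strand == "+" else iv.end - 1


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write per-stage artifacts plus ``report.json``.

    Returns the report as a dict (exactly what ``report.json`` contains).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ann = read_annotation(config.annotation)
    transcripts = read_transcripts(config.transcripts)
    counts = _quant.read_counts_tsv(config.counts, config.samples)
    genome = _read_fasta(config.genome)

    # --- classify -----------------------------------------------------------
    records = _classify.classify_all(transcripts, ann, config.min_overlap)
    srnas = [r for r in records if r.srna_class in ("antisense", "intergenic")]
    excluded = [r for r in records if r.srna_class not in ("antisense", "intergenic")]
    write_srna_gff(srnas, outdir / "srnas.gff3")
    pd.DataFrame(
        [
            {"transcript_id": r.transcript.transcript_id, "reason": r.srna_class}
            for r in excluded
        ]
    ).to_csv(outdir / "excluded.tsv", sep="\t", index=False)

    classes = {r.transcript.transcript_id: r.srna_class for r in srnas}
    primary_pairs = [r.primary_target for r in srnas if r.primary_target is not None]

    # --- quantify -----------------------------------------------------------
    tpm_mat = _quant.tpm(counts)
    missing = [t for t in classes if t not in tpm_mat.tpm.index]
    if missing:
        raise KeyError(f"classified sRNAs missing from the count table: {missing[:5]}")
    filters: dict[str, pd.DataFrame] = {}
    passed: dict[str, set[str]] = {}
    for cond in (config.control, config.stress):
        dec = _quant.filter_srnas(
            tpm_mat,
            classes,
            cond,
            min_replicates=config.min_replicates,
            thresholds=config.tpm_thresholds,
            mode=config.filter_mode,
        )
        dec.to_csv(outdir / f"filter_{cond}.tsv", sep="\t")
        filters[cond] = dec
        passed[cond] = set(dec.index[dec["passed"]])
    passed_any = passed[config.control] | passed[config.stress]

    srnas_kept = [r for r in srnas if r.transcript.transcript_id in passed_any]
    pairs_kept = [r.primary_target for r in srnas_kept if r.primary_target is not None]

    # --- overlap statistics / binding regions -------------------------------
    region_dist = {"5'UTR": 0, "3'UTR": 0, "CDS": 0}
    for p in pairs_kept:
        region_dist[p.binding_region] += 1
    ostats = (
        dataclasses.asdict(_classify.overlap_stats(pairs_kept)) if pairs_kept else None
    )

    # --- cis pair tests -----------------------------------------------------
    pair_summaries = {}
    for cond in (config.control, config.stress):
        cond_pairs = [
            p for p in pairs_kept if p.srna_id in passed[cond]
        ]
        results, summary = _cis.run_all_pairs(
            tpm_mat, cond_pairs, cond, alpha=config.alpha, paired=config.paired
        )
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            outdir / f"pairs_{cond}.tsv", sep="\t", index=False
        )
        pair_summaries[cond] = summary

    # --- differential expression -------------------------------------------
    de = _de.run_de(
        counts, control=config.control, stress=config.stress, fdr_threshold=config.fdr
    )
    de.to_csv(outdir / "de.tsv", sep="\t", index_label="feature")
    srna_de = de.loc[[t for t in classes if t in de.index]]
    de_summary = {}
    for cls in ("antisense", "intergenic"):
        ids = [t for t, c in classes.items() if c == cls and t in passed_any]
        sub = de.loc[ids]
        de_summary[cls] = {
            "n": len(sub),
            "up": int((sub["call"] == "up").sum()),
            "down": int((sub["call"] == "down").sum()),
        }

    # --- regulatory effects -------------------------------------------------
    tab = _reg.cross_tabulate(srna_de, de, pairs_kept)
    pd.DataFrame(
        [
            {"srna_call": k[0], "target_call": k[1], "n_pairs": v}
            for k, v in sorted(tab.counts.items())
        ]
    ).to_csv(outdir / "crosstab.tsv", sep="\t", index=False)

    enrichment_rows = None
    category_map = _load_categories(config, ann)
    gene_ids = {g.gene_id for g in ann.genes}
    universe = [g for g in de.index if g in gene_ids]
    up_targets = sorted(
        {
            p.gene_id
            for p in pairs_kept
            if p.srna_id in srna_de.index
            and srna_de.loc[p.srna_id, "call"] == "up"
            and p.gene_id in de.index
        }
    )
    if category_map and up_targets:
        enr = _reg.hypergeom_enrichment(up_targets, category_map, universe)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t")
        enrichment_rows = int(len(enr))

    # --- promoter motifs ----------------------------------------------------
    models = {
        name: _motifs.MotifModel.from_consensus(
            name,
            {"BRE": _motifs.BRE_CONSENSUS, "TATA": _motifs.TATA_CONSENSUS}[name],
            expected_centroid=config.motif_centroids[name],
            tolerance=config.motif_tolerance,
            scan_range=_motifs.PROMOTER_SCAN_RANGE,
        )
        for name in ("BRE", "TATA")
    }
    tss_list = [
        (r.transcript.transcript_id, r.transcript.chrom, _tss_of(r.transcript),
         r.transcript.strand)
        for r in srnas_kept
    ]
    scans = _motifs.scan_promoters(
        genome, tss_list, models, config.window_upstream, config.window_downstream
    )
    motif_rows = []
    for s in scans:
        row = {"srna_id": s.srna_id}
        for name in models:
            hit = s.hits.get(name)
            row[f"{name}_pos"] = "" if hit is None else hit.position
            row[f"{name}_score"] = "" if hit is None else round(hit.score, 4)
        row["has_promoter"] = s.has_promoter(models)
        motif_rows.append(row)
    pd.DataFrame(motif_rows).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    centroids = {name: _motifs.centroid(scans, name) for name in models}
    fractions = _motifs.fraction_with_promoter(scans, models, config.relaxed_shift)

    # --- report -------------------------------------------------------------
    per_condition = {}
    for cond in (config.control, config.stress):
        dec = filters[cond]
        ok = dec[dec["passed"]]
        per_condition[cond] = {
            "n_srnas": int(len(ok)),
            "n_antisense": int((ok["srna_class"] == "antisense").sum()),
            "n_intergenic": int((ok["srna_class"] == "intergenic").sum()),
        }
    report = {
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("outdir",)
        },
        "input_checksums": {
            name: _sha256(getattr(config, name))
            for name in ("annotation", "transcripts", "counts", "samples", "genome")
        },
        "classification": {
            "n_transcripts": len(records),
            "n_antisense": sum(r.srna_class == "antisense" for r in srnas),
            "n_intergenic": sum(r.srna_class == "intergenic" for r in srnas),
            "n_excluded_sense": sum(
                r.srna_class == "excluded-sense" for r in excluded
            ),
            "n_excluded_subthreshold": sum(
                r.srna_class == "excluded-subthreshold" for r in excluded
            ),
        },
        "filtering": per_condition,
        "binding_regions": region_dist,
        "overlap_stats": ostats,
        "pair_tests": pair_summaries,
        "differential_expression": de_summary,
        "cross_tab": {
            "counts": {f"{k[0]}/{k[1]}": v for k, v in sorted(tab.counts.items())},
            "n_pairs": tab.n_pairs,
            "discordant_fraction": tab.discordant_fraction,
            "n_excluded": len(tab.excluded),
        },
        "enrichment": {"n_categories": enrichment_rows},
        "promoters": {
            "centroids": centroids,
            "fractions": fractions,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return report


def _load_categories(config: PipelineConfig, ann) -> dict[str, str]:
    if config.category_map:
        df = pd.read_csv(config.category_map, sep="\t")
        if not {"gene_id", "category"} <= set(df.columns):
            raise ValueError("category map needs 'gene_id' and 'category' columns")
        return dict(zip(df["gene_id"], df["category"]))
    return {g.gene_id: g.product for g in ann.genes if g.product}


def audit_report(outdir: str | os.PathLike) -> list[str]:
    """Recompute every summary in ``report.json`` from the stage artifacts.

    Returns a list of mismatch descriptions (empty = audit passed).
    """
    outdir = Path(outdir)
    with open(outdir / "report.json") as fh:
        report = json.load(fh)
    problems: list[str] = []

    def check(name: str, expected, actual) -> None:
        if expected != actual:
            problems.append(f"{name}: report={expected!r} recomputed={actual!r}")

    from .genome_model import read_srna_gff

    srnas = read_srna_gff(outdir / "srnas.gff3")
    cls_counts = {"antisense": 0, "intergenic": 0}
    for r in srnas:
        cls_counts[r.srna_class] += 1
    check("classification.n_antisense", report["classification"]["n_antisense"],
          cls_counts["antisense"])
    check("classification.n_intergenic", report["classification"]["n_intergenic"],
          cls_counts["intergenic"])

    params = report["parameters"]
    for cond in (params["control"], params["stress"]):
        dec = pd.read_csv(outdir / f"filter_{cond}.tsv", sep="\t", index_col="feature")
        ok = dec[dec["passed"]]
        rep = report["filtering"][cond]
        check(f"filtering.{cond}.n_srnas", rep["n_srnas"], int(len(ok)))
        check(
            f"filtering.{cond}.n_antisense",
            rep["n_antisense"],
            int((ok["srna_class"] == "antisense").sum()),
        )
        pairs_df = pd.read_csv(outdir / f"pairs_{cond}.tsv", sep="\t")
        rep_pairs = report["pair_tests"][cond]
        if len(pairs_df):
            sig_hi = int(
                (pairs_df["significant"] & (pairs_df["direction"] == "sRNA-higher")).sum()
            )
        else:
            sig_hi = 0
        check(
            f"pair_tests.{cond}.significant_srna_higher",
            rep_pairs["significant_srna_higher"],
            sig_hi,
        )
        check(f"pair_tests.{cond}.total", rep_pairs["total"], int(len(pairs_df)))

    ct = pd.read_csv(outdir / "crosstab.tsv", sep="\t")
    total = int(ct["n_pairs"].sum()) if len(ct) else 0
    check("cross_tab.n_pairs", report["cross_tab"]["n_pairs"], total)
    rep_counts = report["cross_tab"]["counts"]
    recomputed = {
        f"{row.srna_call}/{row.target_call}": int(row.n_pairs) for row in ct.itertuples()
    }
    check("cross_tab.counts", rep_counts, recomputed)

    de = pd.read_csv(outdir / "de.tsv", sep="\t", index_col="feature")
    for cls in ("antisense", "intergenic"):
        rep = report["differential_expression"][cls]
        # membership of the filtered sRNA set comes from the filter tables
        kept = set()
        for cond in (params["control"], params["stress"]):
            dec = pd.read_csv(outdir / f"filter_{cond}.tsv", sep="\t", index_col="feature")
            kept |= set(dec.index[(dec["passed"]) & (dec["srna_class"] == cls)])
        sub = de.loc[sorted(kept)]
        check(f"de.{cls}.n", rep["n"], int(len(sub)))
        check(f"de.{cls}.up", rep["up"], int((sub["call"] == "up").sum()))
        check(f"de.{cls}.down", rep["down"], int((sub["call"] == "down").sum()))

    mot = pd.read_csv(outdir / "motifs.tsv", sep="\t")
    frac = report["promoters"]["fractions"]
    if len(mot):
        check(
            "promoters.fractions.strict",
            round(frac["strict"], 12),
            round(float(mot["has_promoter"].mean()), 12),
        )
        check("promoters.fractions.n", frac["n"], int(len(mot)))
    return problems


def make_fixture(params: SimParams, outdir: str | os.PathLike) -> PipelineConfig:
    """Write a complete on-disk fixture bundle from a synthetic dataset.

    The bundle (GFF3 annotation, GTF transcripts, FASTA genome, counts TSV,
    sample sheet, category map, ground-truth JSON and ``config.yaml``) is
    directly consumable by :func:`run_pipeline`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(params)
    write_annotation(ds.annotation, outdir / "annotation.gff3")
    write_transcripts(ds.transcripts, outdir / "transcripts.gtf")
    SeqIO.write(
        [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in ds.genome.items()],
        str(outdir / "genome.fa"),
        "fasta",
    )
    _quant.write_counts_tsv(ds.counts, outdir / "counts.tsv", outdir / "samples.tsv")
    pd.DataFrame(
        [{"gene_id": g.gene_id, "category": g.product} for g in ds.annotation.genes]
    ).to_csv(outdir / "categories.tsv", sep="\t", index=False)
    truth = {
        "class_of": ds.truth.class_of,
        "cis_target_of": {k: list(v) for k, v in ds.truth.cis_target_of.items()},
        "true_lfc": ds.truth.true_lfc,
        "anti_corr_targets": sorted(ds.truth.anti_corr_targets),
        "motif_position_of": ds.truth.motif_position_of,
        "lib_scales": ds.truth.lib_scales,
        "base_tpm": ds.truth.base_tpm,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=2)
        fh.write("\n")
    rel = dict(
        annotation="annotation.gff3",
        transcripts="transcripts.gtf",
        counts="counts.tsv",
        samples="samples.tsv",
        genome="genome.fa",
        category_map="categories.tsv",
        outdir="results",
    )
    config = PipelineConfig(
        **{k: str(outdir / v) for k, v in rel.items()}, seed=params.seed
    )
    # the YAML keeps bundle-relative paths so the bundle is relocatable;
    # from_yaml resolves them against the config file's directory
    cfg = dataclasses.asdict(config)
    cfg.update(rel)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return config
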