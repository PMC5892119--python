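"""TSS-proximal window extraction and BRE/TATA promoter motif scanning.

Archaeal basal promoters carry a TATA box bound by TBP and, immediately
upstream of it, the purine-rich transcription-factor-B recognition element
(BRE).  Given sRNA transcription start sites, this module extracts windows
around each TSS (100 nt up- and downstream by default), scans them with a
position weight matrix (log-odds vs a uniform background), and summarizes
hits as TSS-relative positions: position 0 is the TSS base, upstream is
negative, and every window is reported 5'->3' in the sRNA's transcription
direction (reverse-complemented for minus-strand sRNAs).

A hit's reported position is the motif's first (most 5') base.  The
"centroid" of a motif is the mean hit position over all sRNAs with a hit.
An sRNA "has a promoter" when both BRE and TATA hits fall within each
model's tolerance of its expected centroid; the relaxed mode widens the
tolerances by a few nucleotides.

The default models are synthetic archaeal-style consensus strings (the
matrices are user-replaceable): they capture the A/T-rich TATA box and the
purine-rich BRE without claiming to be organism-calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "MotifModel",
    "Window",
    "MotifHit",
    "PromoterScan",
    "default_models",
    "extract_window",
    "scan_motif",
    "scan_promoters",
    "centroid",
    "fraction_with_promoter",
    "BRE_CONSENSUS",
    "TATA_CONSENSUS",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_MISMATCH_LOGODDS = -10.0

# Synthetic default consensus strings (archaeal-style promoter elements).
BRE_CONSENSUS = "CGAAACGT"
TATA_CONSENSUS = "TTTATATA"
DEFAULT_CENTROIDS = {"BRE": -38, "TATA": -29}
DEFAULT_TOLERANCE = 5


@dataclass(frozen=True)
class MotifModel:
    """A promoter element model: log-odds PWM, score threshold, expected
    TSS-relative centroid and a positional tolerance around it.

    ``scan_range`` restricts where the motif may start (TSS-relative,
    inclusive); the default confines hits to the region upstream of the
    TSS, where basal promoter elements live.
    """

    name: str
    pwm: np.ndarray  # shape (width, 4), log-odds vs uniform background
    threshold: float
    expected_centroid: int
    tolerance: int = DEFAULT_TOLERANCE
    scan_range: Optional[tuple[int, int]] = (-100, -1)

    def __post_init__(self) -> None:
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("PWM must have shape (width, 4)")
        if not np.all(np.isfinite(self.pwm)):
            raise ValueError("PWM entries must be finite")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.pwm.max(axis=1).sum())

    @classmethod
    def from_consensus(
        cls,
        name: str,
        consensus: str,
        expected_centroid: int,
        tolerance: int = DEFAULT_TOLERANCE,
        threshold: Optional[float] = None,
        scan_range: Optional[tuple[int, int]] = (-100, -1),
    ) -> "MotifModel":
        """Build a PWM from an IUPAC consensus.

        Allowed bases at a position share probability uniformly; others get
        a flat mismatch log-odds.  The default threshold admits only
        full-consensus matches (max score minus a small epsilon).
        """
        rows = []
        for ch in consensus.upper():
            if ch not in _IUPAC:
                raise ValueError(f"invalid IUPAC symbol {ch!r}")
            allowed = _IUPAC[ch]
            row = np.full(4, _MISMATCH_LOGODDS)
            for b in allowed:
                row[_BASE_INDEX[b]] = np.log((1.0 / len(allowed)) / 0.25)
            rows.append(row)
        pwm = np.array(rows)
        if threshold is None:
            threshold = float(pwm.max(axis=1).sum()) - 1e-9
        return cls(name, pwm, threshold, expected_centroid, tolerance, scan_range)


# where basal promoter elements are searched for, TSS-relative: archaeal
# BRE/TATA boxes sit a few tens of nt upstream of the start site
PROMOTER_SCAN_RANGE = (-60, -10)


def default_models(tolerance: int = DEFAULT_TOLERANCE) -> dict[str, MotifModel]:
    return {
        "BRE": MotifModel.from_consensus(
            "BRE", BRE_CONSENSUS, DEFAULT_CENTROIDS["BRE"], tolerance,
            scan_range=PROMOTER_SCAN_RANGE,
        ),
        "TATA": MotifModel.from_consensus(
            "TATA", TATA_CONSENSUS, DEFAULT_CENTROIDS["TATA"], tolerance,
            scan_range=PROMOTER_SCAN_RANGE,
        ),
    }


@dataclass(frozen=True)
class Window:
    """A TSS-centred sequence window in transcription orientation.

    ``seq[i]`` sits at TSS-relative position ``i - upstream_len``; the TSS
    base is position 0.  ``truncated_upstream/downstream`` record clipping
    at replicon edges.
    """

    seq: str
    upstream_len: int
    downstream_len: int
    truncated_upstream: bool = False
    truncated_downstream: bool = False

    def position_of(self, index: int) -> int:
        return index - self.upstream_len

    def index_of(self, position: int) -> int:
        return position + self.upstream_len


@dataclass(frozen=True)
class MotifHit:
    position: int  # TSS-relative position of the motif's first base
    score: float


@dataclass
class PromoterScan:
    srna_id: str
    window: Window
    hits: dict[str, Optional[MotifHit]] = field(default_factory=dict)

    def has_promoter(self, models: Mapping[str, MotifModel], extra_tolerance: int = 0) -> bool:
        """True when every model has a hit within (tolerance + extra) nt of
        its expected centroid."""
        for name, model in models.items():
            hit = self.hits.get(name)
            if hit is None:
                return False
            if abs(hit.position - model.expected_centroid) > model.tolerance + extra_tolerance:
                return False
        return True


def extract_window(
    genome: Mapping[str, str],
    chrom: str,
    tss: int,
    strand: str,
    upstream: int = 100,
    downstream: int = 100,
) -> Window:
    """Extract the sequence around a TSS in transcription orientation.

    ``tss`` is the 0-based genomic position of the first transcribed base.
    Plus strand: genomic [tss-upstream, tss+downstream); minus strand: the
    reverse complement of genomic (tss-downstream, tss+upstream], so that
    position 0 is the TSS base on both strands.  Windows are truncated at
    replicon edges and the truncation recorded.
    """
    if chrom not in genome:
        raise KeyError(f"unknown replicon {chrom!r}")
    seq = genome[chrom]
    L = len(seq)
    if not (0 <= tss < L):
        raise ValueError(f"TSS {tss} outside replicon {chrom!r} (length {L})")
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
        clo, chi = max(lo, 0), min(hi, L)
        window = seq[clo:chi]
        up_len = tss - clo
        down_len = chi - tss
    elif strand == "-":
        lo, hi = tss - downstream + 1, tss + upstream + 1
        clo, chi = max(lo, 0), min(hi, L)
        window = str(Seq(seq[clo:chi]).reverse_complement())
        up_len = chi - 1 - tss
        down_len = tss - clo + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return Window(
        seq=window,
        upstream_len=up_len,
        downstream_len=down_len,
        truncated_upstream=up_len < upstream,
        truncated_downstream=down_len < downstream,
    )


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype="S1") == b.encode()] = i
    return arr


def scan_motif(window: Window, model: MotifModel) -> Optional[MotifHit]:
    """Best-scoring placement of the motif in the window (one orientation).

    Returns the maximal-score hit if it reaches the model threshold, else
    None; score ties resolve to the most-upstream position.  Candidate
    start positions are limited to the model's ``scan_range``.  Non-ACGT
    bases score the mismatch penalty.
    """
    w = model.width
    n = len(window.seq)
    if n < w:
        return None
    lo_idx, hi_idx = 0, n - w  # inclusive index bounds for motif starts
    if model.scan_range is not None:
        lo_idx = max(lo_idx, window.index_of(model.scan_range[0]))
        hi_idx = min(hi_idx, window.index_of(model.scan_range[1]))
    if hi_idx < lo_idx:
        return None
    enc = _encode(window.seq)
    n_pos = hi_idx - lo_idx + 1
    scores = np.zeros(n_pos)
    for j in range(w):
        col = enc[lo_idx + j: lo_idx + j + n_pos]
        vals = np.where(col >= 0, model.pwm[j, np.clip(col, 0, 3)], _MISMATCH_LOGODDS)
        scores += vals
    best_off = int(np.argmax(scores))  # argmax takes the first (most upstream) tie
    best = float(scores[best_off])
    if best < model.threshold:
        return None
    return MotifHit(position=window.position_of(lo_idx + best_off), score=best)


def scan_promoters(
    genome: Mapping[str, str],
    tss_list: Iterable[tuple[str, str, int, str]],
    models: Mapping[str, MotifModel],
    upstream: int = 100,
    downstream: int = 100,
) -> list[PromoterScan]:
    """Scan every sRNA TSS with every model.

    ``tss_list`` holds (srna_id, chrom, tss, strand) tuples.
    """
    scans = []
    for srna_id, chrom, tss, strand in tss_list:
        window = extract_window(genome, chrom, tss, strand, upstream, downstream)
        hits = {name: scan_motif(window, model) for name, model in models.items()}
        scans.append(PromoterScan(srna_id=srna_id, window=window, hits=hits))
    return scans


def centroid(scans: Sequence[PromoterScan], motif_name: str) -> dict:
    """Mean +- sd TSS-relative position of a motif's hits across sRNAs."""
    positions = [
        s.hits[motif_name].position for s in scans if s.hits.get(motif_name) is not None
    ]
    if not positions:
        return {"n": 0, "mean": None, "sd": None}
    arr = np.array(positions, dtype=float)
    return {
        "n": len(arr),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    }


def fraction_with_promoter(
    scans: Sequence[PromoterScan],
    models: Mapping[str, MotifModel],
    relaxed_shift: int = 3,
) -> dict[str, float]:
    """Fraction of sRNAs carrying both promoter elements near their expected
    positions, in strict and relaxed (tolerance + relaxed_shift) modes."""
    if not scans:
        return {"strict": 0.0, "relaxed": 0.0, "n": 0}
    strict = sum(s.has_promoter(models) for s in scans)
    relaxed = sum(s.has_promoter(models, extra_tolerance=relaxed_shift) for s in scans)
    n = len(scans)
    return {"strict": strict / n, "relaxed": relaxed / n, "n": n}
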