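"""Paired expression comparison between antisense sRNAs and cis mRNA targets.

For each asRNA/target pair the per-replicate TPM values are compared with a
paired two-sided t-test on the replicate-wise differences
``d_r = srna_r - target_r`` (t = mean(d)/(sd(d)/sqrt(n)), df = n-1).  A
significantly positive difference — the sRNA expressed above its target —
is the pattern consistent with negative regulation of the target in cis.

No multiple-testing correction is applied at this stage; significance is a
raw p < alpha call per pair (FDR control belongs to the differential
expression stage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .classify import CisPair
from .quantify import TPMMatrix

__all__ = ["PairTestResult", "paired_expression_test", "run_all_pairs"]


@dataclass(frozen=True)
class PairTestResult:
    srna_id: str
    gene_id: str
    srna_mean: float
    srna_sd: float
    target_mean: float
    target_sd: float
    mean_ratio: float
    t_stat: float
    p_value: float
    direction: str  # 'sRNA-higher' | 'target-higher' | 'none'
    significant: bool


def _paired_t(d: np.ndarray) -> tuple[float, float]:
    n = d.size
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0.0:
        if m == 0.0:
            return 0.0, 1.0
        return float(np.sign(m) * np.inf), 0.0
    t = m / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def paired_expression_test(
    srna_tpm: Sequence[float],
    target_tpm: Sequence[float],
    alpha: float = 0.05,
    paired: bool = True,
    log_transform: bool = False,
    srna_id: str = "",
    gene_id: str = "",
) -> PairTestResult:
    """Two-sided t-test between an sRNA's and its target's replicate TPMs.

    ``paired=True`` (default) tests the replicate-wise differences;
    ``paired=False`` falls back to an unpaired two-sample (Welch) test.
    ``log_transform`` applies log2(x+1) before testing.
    """
    x = np.asarray(srna_tpm, dtype=float)
    y = np.asarray(target_tpm, dtype=float)
    if paired and x.size != y.size:
        raise ValueError(f"replicate vectors differ in length ({x.size} vs {y.size})")
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 replicates per member")
    if log_transform:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    if paired:
        t, p = _paired_t(x - y)
    else:
        t, p = stats.ttest_ind(x, y, equal_var=False)
        t, p = float(t), float(p)
        if np.isnan(t):  # both vectors constant and equal
            t, p = 0.0, 1.0
    diff = x.mean() - y.mean()
    direction = "none" if diff == 0 else ("sRNA-higher" if diff > 0 else "target-higher")
    tm = y.mean()
    return PairTestResult(
        srna_id=srna_id,
        gene_id=gene_id,
        srna_mean=float(x.mean()),
        srna_sd=float(x.std(ddof=1)),
        target_mean=float(tm),
        target_sd=float(y.std(ddof=1)),
        mean_ratio=float(x.mean() / tm) if tm > 0 else float("inf"),
        t_stat=t,
        p_value=p,
        direction=direction,
        significant=bool(p < alpha),
    )


def run_all_pairs(
    mat: TPMMatrix,
    pairs: Iterable[CisPair],
    condition: str,
    alpha: float = 0.05,
    paired: bool = True,
    log_transform: bool = False,
) -> tuple[list[PairTestResult], dict[str, int]]:
    """Run the paired test for every (primary) cis pair in one condition.

    Returns the per-pair results plus summary counts of significant
    sRNA-higher / target-higher and non-significant pairs.
    """
    cols = mat.condition_samples(condition)
    results: list[PairTestResult] = []
    for pair in pairs:
        for member in (pair.srna_id, pair.gene_id):
            if member not in mat.tpm.index:
                raise KeyError(
                    f"pair {pair.srna_id}/{pair.gene_id}: feature {member!r} "
                    "missing from TPM matrix"
                )
        res = paired_expression_test(
            mat.tpm.loc[pair.srna_id, cols].to_numpy(),
            mat.tpm.loc[pair.gene_id, cols].to_numpy(),
            alpha=alpha,
            paired=paired,
            log_transform=log_transform,
            srna_id=pair.srna_id,
            gene_id=pair.gene_id,
        )
        results.append(res)
    summary = {
        "significant_srna_higher": sum(
            r.significant and r.direction == "sRNA-higher" for r in results
        ),
        "significant_target_higher": sum(
            r.significant and r.direction == "target-higher" for r in results
        ),
        "not_significant": sum(not r.significant for r in results),
        "total": len(results),
    }
    return results, summary
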