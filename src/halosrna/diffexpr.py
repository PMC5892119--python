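"""Two-condition negative-binomial differential expression.

A deliberately transparent count-based pipeline: median-of-ratios size
factors (depth + composition normalization against a geometric-mean
reference), a method-of-moments negative-binomial dispersion per feature,
a Wald test on the log2 fold change of normalized condition means, and
Benjamini-Hochberg FDR control with an inclusive q <= threshold call.

The NB model is parameterized by (mean, dispersion): Var = mu + alpha*mu^2,
so alpha -> 0 recovers Poisson.  There is no dispersion shrinkage or
empirical-Bayes machinery; the contract of this module is statistical
calibration (type-I error / FDR control) and recovery of planted fold
changes, not emulation of any particular DE package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

__all__ = [
    "size_factors",
    "normalize_counts",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "call_de",
    "run_de",
]

DISPERSION_FLOOR = 1e-8
LFC_PSEUDOCOUNT = 0.5


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-feature geometric mean across samples over
    features with no zero count; each sample's factor is the median ratio
    of its counts to the reference.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = df.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; cannot form the "
            "geometric-mean reference (consider a pseudo-reference)"
        )
    sub = mat[nonzero]
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    log_factors = np.median(ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=df.columns, name="size_factor")


def normalize_counts(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts.counts / factors


def estimate_dispersion(
    norm_counts: pd.DataFrame, conditions: pd.Series, floor: float = DISPERSION_FLOOR
) -> pd.Series:
    """Per-feature NB dispersion by pooled within-condition method of moments.

    For each condition c with mean m_c and sample variance s2_c, the moment
    estimate is (s2_c - m_c) / m_c^2; estimates are averaged across
    conditions (weighted by residual degrees of freedom) and floored.
    """
    conditions = conditions.loc[norm_counts.columns]
    num = np.zeros(len(norm_counts))
    den = 0.0
    for cond in conditions.unique():
        cols = conditions.index[conditions == cond]
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has < 2 replicates")
        sub = norm_counts[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        w = len(cols) - 1
        num += w * a
        den += w
    alpha = np.maximum(num / den, floor)
    return pd.Series(alpha, index=norm_counts.index, name="dispersion")


def nb_wald_test(
    norm_counts: pd.DataFrame,
    conditions: pd.Series,
    dispersion: pd.Series,
    control: str = "control",
    stress: str = "stress",
    pseudocount: float = LFC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Wald test of log2(stress/control) on normalized condition means.

    The fold change uses a pseudo-count for stability at zero; its standard
    error comes from the delta method with NB variance mu + alpha*mu^2 per
    sample, and the two-sided p-value from the normal reference.
    """
    conditions = conditions.loc[norm_counts.columns]
    cols_c = conditions.index[conditions == control]
    cols_s = conditions.index[conditions == stress]
    if len(cols_c) < 2 or len(cols_s) < 2:
        raise ValueError("each condition needs >= 2 replicates")
    mc = norm_counts[cols_c].mean(axis=1).to_numpy()
    ms = norm_counts[cols_s].mean(axis=1).to_numpy()
    alpha = dispersion.loc[norm_counts.index].to_numpy()
    lfc = np.log2((ms + pseudocount) / (mc + pseudocount))
    ln2 = np.log(2.0)

    def se_log2_mean(m: np.ndarray, n: int) -> np.ndarray:
        var_mean = (m + alpha * m**2) / n
        return np.sqrt(var_mean) / ((m + pseudocount) * ln2)

    se = np.sqrt(se_log2_mean(mc, len(cols_c)) ** 2 + se_log2_mean(ms, len(cols_s)) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.maximum(se, 1e-300), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    base_mean = norm_counts.mean(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": lfc,
            "se_log2fc": se,
            "wald_p": p,
        },
        index=norm_counts.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Attach BH q-values and up/down/ns calls (inclusive q <= threshold)."""
    out = results.copy()
    out["fdr_q"] = bh_adjust(out["wald_p"].to_numpy())
    sig = out["fdr_q"] <= fdr_threshold
    out["call"] = np.where(
        sig & (out["log2fc"] > 0), "up", np.where(sig & (out["log2fc"] < 0), "down", "ns")
    )
    return out


def run_de(
    counts: CountMatrix,
    control: str = "control",
    stress: str = "stress",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full DE pipeline: size factors -> dispersion -> Wald -> BH calls."""
    factors = size_factors(counts)
    norm = normalize_counts(counts, factors)
    conditions = counts.samples["condition"]
    disp = estimate_dispersion(norm, conditions)
    res = nb_wald_test(norm, conditions, disp, control=control, stress=stress)
    res["dispersion"] = disp
    return call_de(res, fdr_threshold)
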