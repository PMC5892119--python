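"""Cross-tabulation of sRNA vs cis-target DE calls, and set enrichment.

An upregulated asRNA whose cis target is downregulated (or vice versa) is
a discordant pair — the expression pattern expected under negative
regulation in cis.  ``cross_tabulate`` counts the concordant/discordant
combinations of differential-expression calls across all cis pairs.

``hypergeom_enrichment`` tests functional categories for over-representation
in a target gene set with a one-sided hypergeometric upper tail, BH-adjusted
across categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .classify import CisPair
from .diffexpr import bh_adjust

__all__ = ["RegulatoryCrossTab", "cross_tabulate", "hypergeom_enrichment"]

_DISCORDANT = {("up", "down"), ("down", "up")}
_CONCORDANT = {("up", "up"), ("down", "down")}


@dataclass
class RegulatoryCrossTab:
    """Counts of (sRNA call, target call) combinations over cis pairs."""

    counts: dict[tuple[str, str], int]
    n_pairs: int
    excluded: list[str] = field(default_factory=list)

    @property
    def n_discordant(self) -> int:
        return sum(v for k, v in self.counts.items() if k in _DISCORDANT)

    @property
    def n_concordant(self) -> int:
        return sum(v for k, v in self.counts.items() if k in _CONCORDANT)

    @property
    def n_srna_called(self) -> int:
        return sum(v for k, v in self.counts.items() if k[0] in ("up", "down"))

    def fraction(self, srna_call: str, target_call: str) -> float:
        if self.n_pairs == 0:
            return 0.0
        return self.counts.get((srna_call, target_call), 0) / self.n_pairs

    @property
    def discordant_fraction(self) -> float:
        """Discordant pairs as a fraction of pairs whose sRNA has a DE call."""
        called = self.n_srna_called
        return self.n_discordant / called if called else 0.0

    def subset(self, srna_call: str, target_call: str) -> list[str]:
        return self._subsets.get((srna_call, target_call), [])

    _subsets: dict[tuple[str, str], list[str]] = field(default_factory=dict)


def cross_tabulate(
    srna_de: pd.DataFrame, mrna_de: pd.DataFrame, pairs: Iterable[CisPair]
) -> RegulatoryCrossTab:
    """Assign every cis pair its (sRNA call, target call) combination.

    ``srna_de`` / ``mrna_de`` are DE tables indexed by feature id with a
    ``call`` column (up/down/ns).  Pairs with a member absent from its DE
    table are excluded and listed, not silently dropped; pairs with an
    ``ns`` member are counted in their own cells.
    """
    counts: dict[tuple[str, str], int] = {}
    subsets: dict[tuple[str, str], list[str]] = {}
    excluded: list[str] = []
    n = 0
    for pair in pairs:
        if pair.srna_id not in srna_de.index or pair.gene_id not in mrna_de.index:
            excluded.append(f"{pair.srna_id}/{pair.gene_id}")
            continue
        key = (
            str(srna_de.loc[pair.srna_id, "call"]),
            str(mrna_de.loc[pair.gene_id, "call"]),
        )
        counts[key] = counts.get(key, 0) + 1
        subsets.setdefault(key, []).append(pair.srna_id)
        n += 1
    tab = RegulatoryCrossTab(counts=counts, n_pairs=n, excluded=excluded)
    tab._subsets = subsets
    return tab


def hypergeom_enrichment(
    target_set: Iterable[str],
    category_map: Mapping[str, Sequence[str]] | Mapping[str, str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of categories in a target set.

    ``category_map`` maps gene -> category (string) or gene -> list of
    categories.  For each category with size K in a universe of size N and
    a target set of size n containing k category members, the p-value is
    P[X >= k] with X ~ Hypergeom(N, K, n); q-values are BH across
    categories.
    """
    universe = set(universe)
    targets = set(target_set)
    outside = targets - universe
    if outside:
        raise ValueError(f"target genes outside the universe: {sorted(outside)[:5]}")
    by_cat: dict[str, set[str]] = {}
    for gene, cats in category_map.items():
        if gene not in universe:
            continue
        if isinstance(cats, str):
            cats = [cats]
        for cat in cats:
            by_cat.setdefault(cat, set()).add(gene)
    if not by_cat:
        raise ValueError("no categories intersect the universe")
    rows = []
    N, n = len(universe), len(targets)
    for cat in sorted(by_cat):
        members = by_cat[cat]
        K = len(members)
        k = len(members & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": cat, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("category")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
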