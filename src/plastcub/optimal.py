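"""Optimal codon identification from high/low-expression gene libraries.

Genes are ranked by an expression proxy (default: the MILC value, which in
this analysis tracks expression level), the top and bottom tails form the
high- and low-expression libraries, RSCU is computed on each library's
pooled counts, and a codon is called optimal when
dRSCU = RSCU_high - RSCU_low >= 0.08 and RSCU_high >= 1.  Entries carry the
conventional star tiers: * dRSCU >= 0.08, ** >= 0.3, *** >= 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import (AA_THREE_LETTER, DEFAULT_CODE, CodonCountTable,
                           GeneticCode)
from .indices import rscu

__all__ = ["ExpressionLibraries", "OptimalCodonSet", "build_libraries",
           "optimal_codon_set"]

STAR_TIERS = (0.08, 0.3, 0.5)


@dataclass
class ExpressionLibraries:
    """Disjoint high/low gene-id lists with the ranking metadata."""

    high: list
    low: list
    ranking_metric: str
    fraction: float

    def __post_init__(self):
        if set(self.high) & set(self.low):
            raise ValueError("high and low libraries overlap")
        if not self.high or not self.low:
            raise ValueError("both libraries must be non-empty")


def build_libraries(profiles, metric: str = "milc", fraction: float = 0.1,
                    min_genes: int = 5) -> ExpressionLibraries:
    """Rank genes by an expression proxy and take the two tails.

    Each tail holds ``max(min_genes, round(fraction * n))`` genes; ties on
    the metric are broken by gene id so the split is deterministic.
    """
    n = len(profiles)
    if n < 2 * min_genes:
        raise ValueError(
            f"need at least {2 * min_genes} genes to build libraries, got {n}")
    keyed = sorted(((getattr(p, metric), p.gene_id) for p in profiles),
                   key=lambda t: (-t[0], t[1]))
    values = [v for v, _ in keyed]
    if len(set(values)) == 1:
        warnings.warn("all metric values equal; tails are id-ordered")
    tail = max(min_genes, round(fraction * n))
    if 2 * tail > n:
        raise ValueError(f"tail size {tail} too large for {n} genes")
    high = [g for _, g in keyed[:tail]]
    low = [g for _, g in keyed[-tail:]]
    return ExpressionLibraries(high=high, low=low, ranking_metric=metric,
                               fraction=fraction)


@dataclass
class OptimalCodonSet:
    """Codons over-used in the high-expression library."""

    entries: pd.DataFrame  # aa, codon, RSCU_high, RSCU_low, dRSCU, tier
    delta_min: float = STAR_TIERS[0]
    rscu_min: float = 1.0

    def __len__(self):
        return len(self.entries)

    @property
    def codons(self) -> set:
        return set(self.entries["codon"])

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False, float_format="%.4f")


def _tier(delta: float) -> str:
    if delta >= STAR_TIERS[2]:
        return "***"
    if delta >= STAR_TIERS[1]:
        return "**"
    return "*"


def optimal_codon_set(high_counts: CodonCountTable,
                      low_counts: CodonCountTable,
                      code: GeneticCode = DEFAULT_CODE,
                      delta_min: float = STAR_TIERS[0],
                      rscu_min: float = 1.0) -> OptimalCodonSet:
    """Identify optimal codons from pooled library counts.

    RSCU is computed on each pooled library; a codon enters the set iff
    dRSCU >= ``delta_min`` and its high-library RSCU >= ``rscu_min``.
    Raising either threshold can only shrink the set.
    """
    hi = rscu(high_counts, code)
    lo = rscu(low_counts, code)
    rows = []
    for aa, codons in code.multi_codon_families.items():
        for c in codons:
            delta = hi.values[c] - lo.values[c]
            if delta >= delta_min and hi.values[c] >= rscu_min:
                rows.append({"aa": AA_THREE_LETTER[aa], "codon": c,
                             "RSCU_high": hi.values[c],
                             "RSCU_low": lo.values[c],
                             "dRSCU": delta, "tier": _tier(delta)})
    entries = pd.DataFrame(
        rows, columns=["aa", "codon", "RSCU_high", "RSCU_low", "dRSCU", "tier"])
    if len(entries):
        entries = entries.sort_values(["aa", "codon"]).reset_index(drop=True)
    return OptimalCodonSet(entries=entries, delta_min=delta_min,
                           rscu_min=rscu_min)
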