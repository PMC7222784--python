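"""Quantitative-genetic effect decomposition per locus x trait.

From the three genotype means (least-squares means by default) the classical
single-locus decomposition is

    a     = (AA - BB) / 2          additive effect,
    d     = AB - (AA + BB) / 2     dominance deviation,
    alpha = a + d (q - p)          average allele-substitution effect,

with p the frequency of the first-listed (major) allele A and q = 1 - p.
Gene action is classified from |d/a|: values above 1.2 are called
overdominance; the finer bins below that cut-off (additive < 0.2, partial
dominance 0.2-0.8, dominance 0.8-1.2) are a reporting convention and can be
overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class GeneActionBins:
    """|d/a| cut-offs for the gene-action labels. Only ``overdominance`` is
    grounded in the overdominance-threshold literature; the rest are a
    reporting convention."""

    additive: float = 0.2
    partial_dominance: float = 0.8
    dominance: float = 1.2  # >= this -> overdominance


@dataclass(frozen=True)
class EffectDecomposition:
    locus: str
    trait: str
    a: float
    d: float
    alpha: float
    p: float
    q: float
    d_over_a: float | None      # None when a == 0
    gene_action: str
    orientation: str = ""       # e.g. "p = f(C); alpha = effect of C-for-T substitution"


def classify_gene_action(
    a: float, d: float, bins: GeneActionBins = GeneActionBins()
) -> str:
    """Gene-action label from the |d/a| ratio.

    Degenerate cases: a = 0 with d != 0 is overdominance (infinite ratio);
    a = d = 0 is called additive by convention.
    """
    if not (math.isfinite(a) and math.isfinite(d)):
        raise ValueError("a and d must be finite")
    if a == 0:
        return "additive" if d == 0 else "overdominance"
    ratio = abs(d / a)
    if ratio >= bins.dominance:
        return "overdominance"
    if ratio >= bins.partial_dominance:
        return "dominance"
    if ratio >= bins.additive:
        return "partial dominance"
    return "additive"


def decompose(
    mean_aa: float, mean_ab: float, mean_bb: float,
    p: float, q: float | None = None,
    locus: str = "", trait: str = "",
    bins: GeneActionBins = GeneActionBins(),
    orientation: str = "",
) -> EffectDecomposition:
    """Effect decomposition from genotype means and allele frequencies.

    ``mean_aa`` is the mean of the major-allele homozygote (the allele whose
    frequency is ``p``); alpha's sign is the average effect of substituting
    the major for the minor allele.
    """
    if q is None:
        q = 1.0 - p
    if not math.isclose(p + q, 1.0, abs_tol=1e-9):
        raise ValueError(f"allele frequencies must sum to 1, got p={p}, q={q}")
    if not (0 < p < 1):
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    a = (mean_aa - mean_bb) / 2.0
    d = mean_ab - (mean_aa + mean_bb) / 2.0
    alpha = a + d * (q - p)
    return EffectDecomposition(
        locus=locus, trait=trait, a=a, d=d, alpha=alpha, p=p, q=q,
        d_over_a=abs(d / a) if a != 0 else None,
        gene_action=classify_gene_action(a, d, bins),
        orientation=orientation,
    )


def relative_difference(mean_1: float, mean_2: float) -> float:
    """Percent difference of mean_1 relative to mean_2: 100 (m1 - m2) / m2."""
    if mean_2 == 0:
        raise ValueError("reference mean is zero; relative difference undefined")
    return 100.0 * (mean_1 - mean_2) / mean_2
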