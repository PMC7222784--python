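"""Single-locus descriptive genetics: allele/genotype frequencies, MAF and
Hardy-Weinberg equilibrium.

Allele frequencies are taken from exact integer allele counts, never from
rounded genotype frequencies, so expected genotype counts always sum to n.
The HWE test is a chi-square goodness of fit with 1 degree of freedom
(3 genotype classes - 1 - 1 estimated allele frequency), no continuity
correction; a small-sample exact test (conditional on allele counts) is
available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .model import GenotypeCall, Locus


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts at one locus; AA is the major-allele homozygote."""

    locus: str
    n_aa: int
    n_ab: int
    n_bb: int

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb


@dataclass(frozen=True)
class HweResult:
    """Allele frequencies, HWE expected counts and the chi-square test."""

    locus: str
    n: int
    p: float                      # frequency of the major (first-listed) allele
    q: float
    maf: float
    e_aa: float
    e_ab: float
    e_bb: float
    chi2: float
    df: int
    p_value: float
    exact_p_value: float | None = None


def genotype_counts(
    calls: Sequence[GenotypeCall], locus: Locus
) -> GenotypeCounts:
    """Tally calls at one locus into AA/AB/BB counts (A = major allele)."""
    tallies = [0, 0, 0]
    for c in calls:
        if c.locus == locus.name:
            tallies[c.minor_allele_count(locus)] += 1
    return GenotypeCounts(locus.name, *tallies)


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """(p, q) with p = (2*n_AA + n_AB) / 2n, the major-allele frequency."""
    if counts.n == 0:
        raise ValueError(f"locus {counts.locus!r}: no genotyped animals")
    p = (2 * counts.n_aa + counts.n_ab) / (2 * counts.n)
    return p, 1.0 - p


def maf(counts: GenotypeCounts) -> float:
    p, q = allele_frequencies(counts)
    return min(p, q)


def hwe_expected(counts: GenotypeCounts) -> tuple[float, float, float]:
    """Expected genotype counts (n p^2, 2 n p q, n q^2) under random mating."""
    p, q = allele_frequencies(counts)
    n = counts.n
    return n * p * p, 2 * n * p * q, n * q * q


def hwe_exact_p(counts: GenotypeCounts) -> float:
    """Exact HWE p-value, conditioning on the observed allele counts.

    Sums the probabilities of all heterozygote counts no more likely than the
    observed one, over the distribution of heterozygote number given the
    minor-allele count.
    """
    n = counts.n
    n_minor = 2 * counts.n_bb + counts.n_ab
    n_minor = min(n_minor, 2 * n - n_minor)
    parity = n_minor % 2
    het_values = range(parity, n_minor + 1, 2)

    def log_prob(nab: int) -> float:
        nbb = (n_minor - nab) // 2
        naa = n - nab - nbb
        return (
            math.lgamma(n + 1)
            - math.lgamma(naa + 1) - math.lgamma(nab + 1) - math.lgamma(nbb + 1)
            + nab * math.log(2.0)
            + math.lgamma(n_minor + 1) + math.lgamma(2 * n - n_minor + 1)
            - math.lgamma(2 * n + 1)
        )

    probs = {nab: math.exp(log_prob(nab)) for nab in het_values}
    p_obs = probs[counts.n_ab]  # heterozygote count is orientation-free
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def hwe_chi_square(counts: GenotypeCounts, exact: bool = False) -> HweResult:
    """Chi-square HWE goodness-of-fit test (df = 1) on one locus.

    Raises if any expected count is zero (monomorphic locus), where the test
    is undefined. With ``exact=True`` the conditional exact p-value is also
    reported.
    """
    p, q = allele_frequencies(counts)
    e = hwe_expected(counts)
    if min(e) <= 0:
        raise ValueError(
            f"locus {counts.locus!r}: expected count of zero (monomorphic?); "
            "HWE chi-square undefined"
        )
    obs = (counts.n_aa, counts.n_ab, counts.n_bb)
    chi2 = sum((o - x) ** 2 / x for o, x in zip(obs, e))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(
        locus=counts.locus, n=counts.n, p=p, q=q, maf=min(p, q),
        e_aa=e[0], e_ab=e[1], e_bb=e[2],
        chi2=chi2, df=1, p_value=p_value,
        exact_p_value=hwe_exact_p(counts) if exact else None,
    )


def hwe_table(all_counts: Sequence[GenotypeCounts], exact: bool = False):
    """One HweResult per locus, in input order (Table-1-style summary)."""
    return [hwe_chi_square(c, exact=exact) for c in all_counts]
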