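"""Two-locus linkage disequilibrium from unphased genotypes.

With unphased biallelic genotypes only the double heterozygote is phase
ambiguous: it is either AB/ab or Ab/aB. Haplotype frequencies are estimated
by expectation-maximization on the two-locus multinomial under random union
of gametes: the E-step splits the double-heterozygote count between the two
phase configurations in proportion to the current haplotype-frequency
products (2 f_AB f_ab vs 2 f_Ab f_aB), the M-step renormalizes haplotype
counts. The log-likelihood is non-decreasing across iterations. D, D' and
r^2 follow from the converged frequencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GenotypeCall, Locus

# haplotype order used throughout: AB, Ab, aB, ab
# (capital = major allele at that locus)
HAPLOTYPES = ("AB", "Ab", "aB", "ab")


@dataclass(frozen=True)
class TwoLocusCounts:
    """3x3 joint genotype counts, indexed by minor-allele copies (0/1/2) at each locus."""

    locus1: str
    locus2: str
    table: tuple[tuple[int, ...], ...]  # table[i][j], i = copies at locus1

    def __post_init__(self) -> None:
        arr = np.asarray(self.table)
        if arr.shape != (3, 3) or (arr < 0).any():
            raise ValueError("two-locus table must be 3x3 with non-negative counts")

    @property
    def n(self) -> int:
        return int(np.asarray(self.table).sum())


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Estimated two-locus haplotype frequencies and derived LD statistics."""

    f_ab_major: float   # f(AB): major-major haplotype
    f_a_major: float    # f(Ab)
    f_b_major: float    # f(aB)
    f_minor: float      # f(ab)
    d: float
    d_prime: float
    r2: float
    log_likelihood: float
    iterations: int
    converged: bool
    ll_trajectory: tuple[float, ...] = ()

    @property
    def freqs(self) -> tuple[float, float, float, float]:
        return (self.f_ab_major, self.f_a_major, self.f_b_major, self.f_minor)

    @property
    def p_a(self) -> float:
        """Major-allele frequency at locus 1."""
        return self.f_ab_major + self.f_a_major

    @property
    def p_b(self) -> float:
        """Major-allele frequency at locus 2."""
        return self.f_ab_major + self.f_b_major


def two_locus_counts(
    calls: Sequence[GenotypeCall], locus1: Locus, locus2: Locus
) -> TwoLocusCounts:
    """Cross-tabulate minor-allele dosages; animals missing either call are excluded."""
    dos1 = {c.animal_id: c.minor_allele_count(locus1)
            for c in calls if c.locus == locus1.name}
    dos2 = {c.animal_id: c.minor_allele_count(locus2)
            for c in calls if c.locus == locus2.name}
    table = np.zeros((3, 3), dtype=int)
    for animal, i in dos1.items():
        j = dos2.get(animal)
        if j is not None:
            table[i, j] += 1
    return TwoLocusCounts(locus1.name, locus2.name,
                          tuple(tuple(int(x) for x in row) for row in table))


def _log_likelihood(table: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table at haplotype freqs f.

    Genotype cell (i, j) = minor-dosage pair; its probability is the sum over
    unordered haplotype pairs consistent with it.
    """
    f_ab, f_a, f_b, f_mm = f  # AB, Ab, aB, ab
    # dosage contributed by each haplotype at (locus1, locus2): AB->(0,0),
    # Ab->(0,1)? no: capital = MAJOR, dosage counts MINOR copies.
    dosage = {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (1, 1)}
    probs = np.zeros((3, 3))
    for h1, h2 in itertools.product(range(4), repeat=2):
        i = dosage[h1][0] + dosage[h2][0]
        j = dosage[h1][1] + dosage[h2][1]
        probs[i, j] += f[h1] * f[h2]
    with np.errstate(divide="ignore"):
        logp = np.where(table > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float((table * logp).sum())


def em_haplotype_frequencies(
    counts: TwoLocusCounts, tol: float = 1e-8, max_iter: int = 1000
) -> HaplotypeFreqs:
    """EM estimate of the four haplotype frequencies from a 3x3 genotype table.

    Initialization is at linkage equilibrium (products of observed allele
    frequencies). Stops when the max absolute frequency change falls below
    ``tol``; a run hitting ``max_iter`` is returned flagged, not hidden.
    Raises for a monomorphic locus, where r^2 is undefined.
    """
    table = np.asarray(counts.table, dtype=float)
    n = table.sum()
    if n <= 0:
        raise ValueError("empty two-locus table")
    # minor-allele frequencies at each locus (observed, fixed by the data)
    q1 = (table.sum(axis=1) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    q2 = (table.sum(axis=0) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    if q1 <= 0 or q1 >= 1 or q2 <= 0 or q2 >= 1:
        raise ValueError(
            f"monomorphic locus in pair ({counts.locus1!r}, {counts.locus2!r}); "
            "r^2 undefined"
        )
    p1, p2 = 1 - q1, 1 - q2

    # unambiguous haplotype counts from all cells except the double heterozygote;
    # cell (i, j): locus1 contributes alleles by dosage i, locus2 by dosage j.
    base = np.zeros(4)  # AB, Ab, aB, ab
    for i in range(3):
        for j in range(3):
            c = table[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            # phase determined: each individual contributes two haplotypes
            if i == 1:  # heterozygous only at locus 1
                hb = "B" if j == 0 else "b"
                base[HAPLOTYPES.index("A" + hb)] += c
                base[HAPLOTYPES.index("a" + hb)] += c
            elif j == 1:  # heterozygous only at locus 2
                ha = "A" if i == 0 else "a"
                base[HAPLOTYPES.index(ha + "B")] += c
                base[HAPLOTYPES.index(ha + "b")] += c
            else:  # double homozygote
                ha = "A" if i == 0 else "a"
                hb = "B" if j == 0 else "b"
                base[HAPLOTYPES.index(ha + hb)] += 2 * c

    n_dh = table[1, 1]
    f = np.array([p1 * p2, p1 * q2, q1 * p2, q1 * q2])  # linkage equilibrium start
    converged = False
    trajectory: list[float] = [_log_likelihood(table, f)]
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between AB/ab and Ab/aB phases
        w_cis = f[0] * f[3]
        w_trans = f[1] * f[2]
        total = w_cis + w_trans
        share_cis = 0.5 if total == 0 else w_cis / total
        hap_counts = base.copy()
        hap_counts[0] += n_dh * share_cis
        hap_counts[3] += n_dh * share_cis
        hap_counts[1] += n_dh * (1 - share_cis)
        hap_counts[2] += n_dh * (1 - share_cis)
        # M-step
        f_new = hap_counts / (2 * n)
        delta = np.abs(f_new - f).max()
        f = f_new
        trajectory.append(_log_likelihood(table, f))
        if delta < tol:
            converged = True
            break
    d, d_prime, r2 = ld_from_freqs(tuple(f))
    return HaplotypeFreqs(
        f_ab_major=float(f[0]), f_a_major=float(f[1]),
        f_b_major=float(f[2]), f_minor=float(f[3]),
        d=d, d_prime=d_prime, r2=r2,
        log_likelihood=trajectory[-1], iterations=it, converged=converged,
        ll_trajectory=tuple(trajectory),
    )


def ld_from_freqs(freqs: tuple[float, float, float, float]) -> tuple[float, float, float]:
    """(D, D', r^2) from haplotype frequencies (f_AB, f_Ab, f_aB, f_ab).

    D = f_AB - p_A p_B; D' normalizes D by its admissible extreme given the
    allele frequencies; r^2 = D^2 / (p_A q_A p_B q_B). Raises when either
    locus is fixed.
    """
    f_ab, f_a, f_b, f_mm = freqs
    total = sum(freqs)
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"haplotype frequencies must sum to 1, got {total}")
    p_a = f_ab + f_a
    p_b = f_ab + f_b
    q_a, q_b = 1 - p_a, 1 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0:
        raise ValueError("marginal allele frequency of 0 or 1: LD undefined")
    d = f_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    d_prime = 0.0 if d == 0 else d / d_max
    r2 = d * d / (p_a * q_a * p_b * q_b)
    return float(d), float(d_prime), float(r2)


def ld_statistics(freqs: HaplotypeFreqs) -> tuple[float, float, float]:
    """(D, D', r^2) recomputed from a HaplotypeFreqs estimate."""
    return ld_from_freqs(freqs.freqs)


def r2_permutation_p(
    counts: TwoLocusCounts, n_perm: int = 10_000, seed: int = 0,
    tol: float = 1e-8, max_iter: int = 1000,
) -> float:
    """Permutation p-value for r^2: shuffle locus-2 genotypes across animals.

    Breaks the between-locus association while preserving both single-locus
    genotype distributions.
    """
    rng = np.random.default_rng(seed)
    observed = em_haplotype_frequencies(counts, tol, max_iter).r2
    table = np.asarray(counts.table, dtype=int)
    dos1 = np.repeat([0, 1, 2], table.sum(axis=1))
    dos2 = np.repeat([0, 1, 2], table.sum(axis=0))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(dos2)
        t = np.zeros((3, 3), dtype=int)
        np.add.at(t, (dos1, perm), 1)
        tc = TwoLocusCounts(counts.locus1, counts.locus2,
                            tuple(tuple(int(x) for x in row) for row in t))
        if em_haplotype_frequencies(tc, tol, max_iter).r2 >= observed - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def pairwise_ld(
    calls: Sequence[GenotypeCall], loci: Sequence[Locus],
    tol: float = 1e-8, max_iter: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Symmetric r^2 matrix over all locus pairs, diagonal 1.

    Animals missing either genotype are excluded pairwise. Per-pair failures
    (e.g. a monomorphic locus) leave a NaN cell and are reported in the
    details dict rather than aborting the matrix.
    """
    if len(loci) < 2:
        raise ValueError("pairwise LD needs at least two loci")
    names = [l.name for l in loci]
    mat = pd.DataFrame(np.eye(len(loci)), index=names, columns=names)
    details: dict = {}
    for (i, l1), (j, l2) in itertools.combinations(enumerate(loci), 2):
        counts = two_locus_counts(calls, l1, l2)
        try:
            est = em_haplotype_frequencies(counts, tol, max_iter)
            mat.iloc[i, j] = mat.iloc[j, i] = est.r2
            details[(l1.name, l2.name)] = {
                "n": counts.n, "r2": est.r2, "d": est.d, "d_prime": est.d_prime,
                "iterations": est.iterations, "converged": est.converged,
            }
        except ValueError as e:
            mat.iloc[i, j] = mat.iloc[j, i] = np.nan
            details[(l1.name, l2.name)] = {"n": counts.n, "error": str(e)}
    return mat, details
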