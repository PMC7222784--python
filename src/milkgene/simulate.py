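"""Synthetic-herd generator.

Emulates the study design the analysis modules expect: ~841 cows that are
daughters of ~162 sires (2-43 daughters each), parities 1-5, monthly
test-day recording (up to 10 tests per lactation), biallelic SNP genotypes
drawn by random union of gametes (so Hardy-Weinberg holds at each locus,
with optional pairwise LD between consecutive loci), and trait values built
generatively from the fixed-effects association model: overall mean + sire
+ year-season + parity class + lactation-stage curve + genotype value
(AA -> +a, AB -> d, BB -> -a) + normal residual. SCC is lognormal with a
genotype-shiftable median, so a configured SCS effect is additive on the
log2 scale.

Everything is driven by one numpy Generator seeded from the config, so the
same seed reproduces the herd byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import GenotypeCall, Locus, ValidationError, TestDayRecord

TRAITS = ("milk_kg", "fat_pct", "protein_pct")

DEFAULT_LOCI = (
    Locus("snp1", "C", "T"),
    Locus("snp2", "G", "A"),
    Locus("snp3", "A", "G"),
)


def _dict_field(**kwargs):
    return field(default_factory=lambda: dict(kwargs))


@dataclass
class SimulationConfig:
    """Herd-simulation parameters with study-scale defaults.

    Trait units: milk kg/day, fat and protein in %, SCC in cells/mL.
    ``genotype_effects[locus][trait] = (a, d)`` in trait units;
    ``scs_genotype_effects[locus] = (a, d)`` on the SCS (log2) scale.
    ``pair_r2`` sets a target r^2 between consecutive loci (sign of D
    positive); omitted pairs segregate independently.
    """

    n_cows: int = 841
    n_sires: int = 162
    daughters_min: int = 2
    daughters_max: int = 43
    max_parity: int = 5
    tests_per_lactation: int = 10
    test_interval_days: int = 30
    year_seasons: tuple[str, ...] = (
        "2011-cold", "2011-warm", "2012-cold", "2012-warm",
        "2013-cold", "2013-warm", "2014-cold", "2014-warm",
    )
    loci: tuple[Locus, ...] = DEFAULT_LOCI
    minor_freqs: tuple[float, ...] = (0.407, 0.107, 0.181)
    pair_r2: dict = field(default_factory=dict)
    trait_means: dict = _dict_field(milk_kg=30.0, fat_pct=4.2, protein_pct=3.3)
    residual_sd: dict = _dict_field(milk_kg=4.0, fat_pct=0.6, protein_pct=0.25)
    sire_sd: dict = _dict_field(milk_kg=1.2, fat_pct=0.15, protein_pct=0.08)
    year_season_sd: dict = _dict_field(milk_kg=1.0, fat_pct=0.10, protein_pct=0.05)
    parity_sd: dict = _dict_field(milk_kg=0.8, fat_pct=0.05, protein_pct=0.04)
    # total change from first to last DIM bin (positive = decline)
    dim_total_drop: dict = _dict_field(milk_kg=6.0, fat_pct=-0.4, protein_pct=-0.3)
    genotype_effects: dict = field(default_factory=dict)
    scs_genotype_effects: dict = field(default_factory=dict)
    scc_median: float = 1e5
    scc_sigma_ln: float = 1.1
    scs_sire_sd: float = 0.15
    scs_year_season_sd: float = 0.10
    scs_parity_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.minor_freqs):
            raise ValidationError("one minor frequency per locus required")
        for f in self.minor_freqs:
            if not (0 < f < 1):
                raise ValidationError(f"allele frequency must be in (0,1), got {f}")
        if not (0 < self.daughters_min <= self.daughters_max):
            raise ValidationError("daughter range must be positive and ordered")
        if self.n_sires * self.daughters_min > self.n_cows:
            raise ValidationError("too few cows for the daughter range")
        if self.n_sires * self.daughters_max < self.n_cows:
            raise ValidationError("too many cows for the daughter range")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["loci"] = [dataclasses.asdict(l) for l in self.loci]
        d["pair_r2"] = {f"{k[0]}|{k[1]}": v for k, v in self.pair_r2.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "loci" in d:
            d["loci"] = tuple(Locus(**l) for l in d["loci"])
        for key in ("minor_freqs", "year_seasons"):
            if key in d:
                d[key] = tuple(d[key])
        if "pair_r2" in d:
            d["pair_r2"] = {tuple(k.split("|")): v for k, v in d["pair_r2"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# haplotype machinery
# ---------------------------------------------------------------------------

def haplotype_freqs_for_r2(
    q1: float, q2: float, r2: float
) -> tuple[float, float, float, float]:
    """Four haplotype frequencies (AB, Ab, aB, ab; capitals = major) giving a
    target r^2 between two loci with minor-allele frequencies q1, q2.

    D is taken positive (major alleles co-occur in excess). Raises when the
    target is not attainable at these frequencies.
    """
    p1, p2 = 1 - q1, 1 - q2
    d = math.sqrt(r2 * p1 * q1 * p2 * q2)
    freqs = (p1 * p2 + d, p1 * q2 - d, q1 * p2 - d, q1 * q2 + d)
    if min(freqs) < -1e-12:
        raise ValidationError(
            f"target r^2={r2} not attainable at minor freqs ({q1}, {q2})"
        )
    return tuple(max(0.0, f) for f in freqs)


def _sample_haplotypes(config: SimulationConfig, rng: np.random.Generator,
                       n_gametes: int) -> np.ndarray:
    """Gametes as (n_gametes, n_loci) minor-allele indicator matrix.

    Loci form a Markov chain: the first is drawn from its allele frequency,
    each subsequent one from its distribution conditional on the previous
    locus, derived from the configured pairwise haplotype table (or
    independence when no r^2 target is set for that pair). This realizes the
    target LD exactly for each consecutive pair.
    """
    n_loci = len(config.loci)
    out = np.empty((n_gametes, n_loci), dtype=np.int8)
    out[:, 0] = rng.random(n_gametes) < config.minor_freqs[0]
    for k in range(1, n_loci):
        prev_name = config.loci[k - 1].name
        name = config.loci[k].name
        q_prev, q = config.minor_freqs[k - 1], config.minor_freqs[k]
        r2 = config.pair_r2.get((prev_name, name),
                                config.pair_r2.get((name, prev_name)))
        if r2:
            f_ab, f_a, f_b, f_mm = haplotype_freqs_for_r2(q_prev, q, r2)
            # P(minor at k | state at k-1)
            p_minor_given_major = f_a / (f_ab + f_a)
            p_minor_given_minor = f_mm / (f_b + f_mm)
        else:
            p_minor_given_major = p_minor_given_minor = q
        probs = np.where(out[:, k - 1] == 1, p_minor_given_minor,
                         p_minor_given_major)
        out[:, k] = rng.random(n_gametes) < probs
    return out


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None,
    n_cows: int | None = None,
) -> list[GenotypeCall]:
    """Unphased genotype calls for every cow at every configured locus.

    Each cow receives two independent gametes (random union), so every locus
    is in Hardy-Weinberg proportions in expectation.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n_cows if n_cows is not None else config.n_cows
    maternal = _sample_haplotypes(config, rng, n)
    paternal = _sample_haplotypes(config, rng, n)
    calls = []
    for i in range(n):
        animal = f"cow{i + 1:05d}"
        for k, locus in enumerate(config.loci):
            a1 = locus.allele_minor if maternal[i, k] else locus.allele_major
            a2 = locus.allele_minor if paternal[i, k] else locus.allele_major
            calls.append(GenotypeCall(animal, locus.name, a1, a2))
    return calls


# ---------------------------------------------------------------------------
# herd structure and records
# ---------------------------------------------------------------------------

def _daughter_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Daughters per sire, within [min, max], summing exactly to n_cows."""
    counts = rng.integers(config.daughters_min, config.daughters_max + 1,
                          size=config.n_sires)
    diff = config.n_cows - counts.sum()
    while diff != 0:
        i = int(rng.integers(config.n_sires))
        if diff > 0 and counts[i] < config.daughters_max:
            counts[i] += 1
            diff -= 1
        elif diff < 0 and counts[i] > config.daughters_min:
            counts[i] -= 1
            diff += 1
    return counts


def _genotype_value(dosage: int, a: float, d: float) -> float:
    """Genotypic value from minor-allele dosage: AA -> +a, AB -> d, BB -> -a."""
    return (a, d, -a)[dosage]


def simulate_records(
    config: SimulationConfig,
    genotypes: Sequence[GenotypeCall],
    rng: np.random.Generator | None = None,
) -> list[TestDayRecord]:
    """Test-day records for every genotyped cow under the generative model.

    Raises when a cow in the herd lacks a genotype at any configured locus.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    loci = {l.name: l for l in config.loci}
    dosage: dict[str, dict[str, int]] = {}
    for c in genotypes:
        dosage.setdefault(c.animal_id, {})[c.locus] = \
            c.minor_allele_count(loci[c.locus])
    animals = sorted(dosage)
    for a in animals:
        missing = set(loci) - set(dosage[a])
        if missing:
            raise ValidationError(f"animal {a!r} lacks genotypes at {sorted(missing)}")
    if len(animals) != config.n_cows:
        raise ValidationError(
            f"genotypes cover {len(animals)} cows, config expects {config.n_cows}"
        )

    counts = _daughter_counts(config, rng)
    sire_of: dict[str, str] = {}
    idx = 0
    for s, c in enumerate(counts):
        for _ in range(c):
            sire_of[animals[idx]] = f"sire{s + 1:03d}"
            idx += 1

    # effect draws, one per level per trait
    sire_ids = sorted(set(sire_of.values()))
    sire_eff = {t: dict(zip(sire_ids,
                            rng.normal(0, config.sire_sd[t], len(sire_ids))))
                for t in TRAITS}
    ys_eff = {t: dict(zip(config.year_seasons,
                          rng.normal(0, config.year_season_sd[t],
                                     len(config.year_seasons))))
              for t in TRAITS}
    parity_classes = ("P1", "P2", "P3+")
    par_eff = {t: dict(zip(parity_classes,
                           rng.normal(0, config.parity_sd[t], 3)))
               for t in TRAITS}
    scs_sire = dict(zip(sire_ids, rng.normal(0, config.scs_sire_sd, len(sire_ids))))
    scs_ys = dict(zip(config.year_seasons,
                      rng.normal(0, config.scs_year_season_sd,
                                 len(config.year_seasons))))
    scs_par = dict(zip(parity_classes, rng.normal(0, config.scs_parity_sd, 3)))

    def dim_effect(trait: str, test_index: int) -> float:
        # smooth linear decline across the lactation (a stylized curve)
        n = config.tests_per_lactation
        frac = test_index / max(1, n - 1)
        return -config.dim_total_drop[trait] * frac

    def parity_class(p: int) -> str:
        return "P1" if p == 1 else ("P2" if p == 2 else "P3+")

    records: list[TestDayRecord] = []
    ln2 = math.log(2.0)
    for animal in animals:
        sire = sire_of[animal]
        n_lact = int(rng.integers(1, config.max_parity + 1))
        for parity in range(1, n_lact + 1):
            ys = str(rng.choice(np.asarray(config.year_seasons)))
            pc = parity_class(parity)
            n_tests = int(rng.integers(max(1, config.tests_per_lactation - 2),
                                       config.tests_per_lactation + 1))
            for t_idx in range(n_tests):
                dim = 15 + config.test_interval_days * t_idx
                values = {}
                for trait in TRAITS:
                    g = 0.0
                    for k, locus in enumerate(config.loci):
                        eff = config.genotype_effects.get(locus.name, {}).get(trait)
                        if eff:
                            g += _genotype_value(dosage[animal][locus.name], *eff)
                    values[trait] = (
                        config.trait_means[trait]
                        + sire_eff[trait][sire] + ys_eff[trait][ys]
                        + par_eff[trait][pc] + dim_effect(trait, t_idx) + g
                        + rng.normal(0, config.residual_sd[trait])
                    )
                g_scs = 0.0
                for locus in config.loci:
                    eff = config.scs_genotype_effects.get(locus.name)
                    if eff:
                        g_scs += _genotype_value(dosage[animal][locus.name], *eff)
                # lognormal SCC: genotype/factor effects shift the median on
                # the log2 scale so the induced SCS effect is additive
                log_scc = (
                    math.log(config.scc_median)
                    + ln2 * (g_scs + scs_sire[sire] + scs_ys[ys] + scs_par[pc])
                    + rng.normal(0, config.scc_sigma_ln)
                )
                records.append(TestDayRecord(
                    animal_id=animal, sire_id=sire, year_season=ys,
                    parity=parity, dim=dim,
                    milk_kg=round(values["milk_kg"], 4),
                    fat_pct=round(values["fat_pct"], 4),
                    protein_pct=round(values["protein_pct"], 4),
                    scc=round(math.exp(log_scc), 1),
                ))
    return records


def simulate_herd(
    config: SimulationConfig,
) -> tuple[tuple[Locus, ...], list[GenotypeCall], list[TestDayRecord]]:
    """Loci, genotypes and test-day records for one synthetic herd."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    records = simulate_records(config, genotypes, rng)
    return config.loci, genotypes, records
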