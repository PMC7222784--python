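"""Domain types shared by every analysis stage.

The data model mirrors a monthly milk-recording (Dairy Herd Improvement)
dataset of a sire-structured cow population genotyped at a handful of
biallelic SNPs: each cow has one genotype call per locus and many test-day
records, each carrying the fixed-effect covariates of the association model
(sire, calving year-season, parity, days in milk) and the recorded traits
(milk yield, fat %, protein %, somatic cell count, optional 305-day yields).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence


class ValidationError(ValueError):
    """A record or configuration violates a domain invariant."""


# ---------------------------------------------------------------------------
# loci and genotype calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A biallelic SNP with named alleles.

    ``allele_major`` / ``allele_minor`` are single-character allele codes;
    "major" fixes the orientation used for allele frequency *p* and for the
    sign of additive and substitution effects downstream.
    """

    name: str
    allele_major: str
    allele_minor: str
    dbsnp_id: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("locus name must be non-empty")
        for a in (self.allele_major, self.allele_minor):
            if len(a) != 1:
                raise ValidationError(
                    f"locus {self.name!r}: allele code {a!r} must be one character"
                )
        if self.allele_major == self.allele_minor:
            raise ValidationError(f"locus {self.name!r}: allele codes must differ")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele_major, self.allele_minor))

    def genotype_label(self, n_minor: int) -> str:
        """Genotype string for 0/1/2 copies of the minor allele, e.g. ``CC``/``CT``/``TT``."""
        if n_minor == 0:
            return self.allele_major * 2
        if n_minor == 1:
            return self.allele_major + self.allele_minor
        if n_minor == 2:
            return self.allele_minor * 2
        raise ValueError(f"minor-allele count must be 0, 1 or 2, got {n_minor}")


@dataclass(frozen=True)
class GenotypeCall:
    """One unphased genotype for one animal at one locus."""

    animal_id: str
    locus: str
    allele1: str
    allele2: str

    def validate(self, locus: Locus) -> None:
        for a in (self.allele1, self.allele2):
            if a not in locus.alleles:
                raise ValidationError(
                    f"animal {self.animal_id!r}, locus {self.locus!r}: "
                    f"allele {a!r} not in {sorted(locus.alleles)}"
                )

    def minor_allele_count(self, locus: Locus) -> int:
        """Copies of the minor allele (0, 1 or 2)."""
        self.validate(locus)
        return (self.allele1 == locus.allele_minor) + (self.allele2 == locus.allele_minor)


# ---------------------------------------------------------------------------
# phenotype records
# ---------------------------------------------------------------------------

#: trait columns always present on a test-day record
TEST_DAY_TRAITS = ("milk_kg", "fat_pct", "protein_pct", "scc")
#: optional whole-lactation traits
LACTATION_TRAITS = ("milk305_kg", "fat305_kg", "protein305_kg")


@dataclass
class TestDayRecord:
    """One monthly milk-recording observation.

    ``scc`` is in cells/mL and must be positive; the SCS transform and the
    retention filter both operate on it. ``year_season`` is an opaque label
    for the combined calving year-season effect.
    """

    __test__ = False  # domain type, not a test case despite the name

    animal_id: str
    sire_id: str
    year_season: str
    parity: int
    dim: int
    milk_kg: float
    fat_pct: float
    protein_pct: float
    scc: float
    milk305_kg: float | None = None
    fat305_kg: float | None = None
    protein305_kg: float | None = None

    def __post_init__(self) -> None:
        if not self.animal_id or not self.sire_id:
            raise ValidationError("animal_id and sire_id are mandatory")
        if not self.year_season:
            raise ValidationError(f"animal {self.animal_id!r}: year_season is mandatory")
        if self.parity < 1:
            raise ValidationError(f"animal {self.animal_id!r}: parity must be >= 1")
        if self.dim < 1:
            raise ValidationError(f"animal {self.animal_id!r}: DIM must be >= 1")
        if not (self.scc > 0) or not math.isfinite(self.scc):
            raise ValidationError(
                f"animal {self.animal_id!r}: SCC must be positive, got {self.scc}"
            )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis configuration with the study defaults.

    Defaults: SCC retention window [1e3, 5e5] cells/mL (bounds inclusive);
    parity collapsed to three classes {1}, {2}, {3-5}; lactation stage as ten
    30-day DIM bins; Bonferroni family = all locus x trait tests of the run;
    significance at 0.05/0.01; EM stopping at 1e-8 or 1000 iterations.
    """

    scc_lower: float = 1e3
    scc_upper: float = 5e5
    parity_classes: tuple[tuple[int, ...], ...] = ((1,), (2,), (3, 4, 5))
    dim_bin_width: int = 30
    dim_n_bins: int = 10
    dim_overflow: str = "last_bin"  # or "drop"
    bonferroni_family: str = "run"  # "run" (loci x traits) or "trait"
    alpha: float = 0.05
    alpha_strict: float = 0.01
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.scc_lower < self.scc_upper):
            raise ValidationError("SCC bounds must be positive and ordered")
        if self.dim_bin_width < 1 or self.dim_n_bins < 1:
            raise ValidationError("DIM binning must use positive width and count")
        if self.dim_overflow not in ("last_bin", "drop"):
            raise ValidationError("dim_overflow must be 'last_bin' or 'drop'")
        seen: set[int] = set()
        for cls in self.parity_classes:
            for p in cls:
                if p in seen:
                    raise ValidationError(f"parity {p} assigned to two classes")
                seen.add(p)

    @property
    def dim_max(self) -> int:
        return self.dim_bin_width * self.dim_n_bins

    def parity_class_label(self, parity: int) -> str:
        for cls in self.parity_classes:
            if parity in cls:
                lo, hi = min(cls), max(cls)
                return f"P{lo}" if lo == hi else f"P{lo}-{hi}"
        # parities above the last class fold into it, mirroring "3-5"
        last = self.parity_classes[-1]
        if parity > max(last):
            lo, hi = min(last), max(last)
            return f"P{lo}" if lo == hi else f"P{lo}-{hi}"
        raise ValidationError(f"parity {parity} not covered by parity classes")

    def dim_bin(self, dim: int) -> int | None:
        """1-based DIM bin; bins are closed on the right ([1,30], [31,60], ...).

        DIM beyond the last bin goes to the last bin (default) or is dropped,
        per ``dim_overflow``. Returns None for a dropped record.
        """
        if dim < 1:
            raise ValidationError(f"DIM must be >= 1, got {dim}")
        b = (dim - 1) // self.dim_bin_width + 1
        if b > self.dim_n_bins:
            return self.dim_n_bins if self.dim_overflow == "last_bin" else None
        return b

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["parity_classes"] = [list(c) for c in self.parity_classes]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "parity_classes" in d:
            d["parity_classes"] = tuple(tuple(c) for c in d["parity_classes"])
        return cls(**d)


def check_unique_calls(calls: Sequence[GenotypeCall]) -> None:
    """Reject duplicate (animal, locus) genotype calls."""
    seen: set[tuple[str, str]] = set()
    for c in calls:
        key = (c.animal_id, c.locus)
        if key in seen:
            raise ValidationError(f"duplicate genotype call for animal {c.animal_id!r} "
                                  f"at locus {c.locus!r}")
        seen.add(key)
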