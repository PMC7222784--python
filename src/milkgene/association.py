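"""Fixed-effects association model for test-day traits.

The model is, for each trait and locus,

    y = mu + sire + year_season + parity_class + dim_class + genotype + e,

all factors fixed and the residual iid with common variance. The design is
unbalanced, so genotype comparisons use least-squares means: the model
prediction for a genotype averaged over the levels of every other factor
with equal weights. The genotype effect is judged by a Type-III (marginal)
F-test; pairwise genotype contrasts get t-tests and a compact letter
display (lowercase at 0.05, uppercase at 0.01); the genotype p-value can be
Bonferroni-adjusted over the run's locus x trait family.

Repeated records of a cow are treated as conditionally independent given the
fixed effects (no permanent-environment term) — a documented limitation. An
optional random-sire mixed model is available but off by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import records_to_frame
from .model import GenotypeCall, Locus, RunConfig, TestDayRecord
from .scs import compute_scs

FACTORS = ("sire", "year_season", "parity_class", "dim_class")


# ---------------------------------------------------------------------------
# analysis frame and design matrix
# ---------------------------------------------------------------------------

def association_frame(
    records: Sequence[TestDayRecord],
    calls: Sequence[GenotypeCall],
    locus: Locus,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """One row per usable test-day record at ``locus``.

    Joins genotype labels onto the phenotype records; cows without a call at
    this locus are excluded (from this locus's analysis only). Adds the
    derived ``scs`` column and the factor-class columns from the config.
    Records whose DIM falls outside the binning range are dropped when the
    config says so.
    """
    config = config or RunConfig()
    genotype = {
        c.animal_id: locus.genotype_label(c.minor_allele_count(locus))
        for c in calls if c.locus == locus.name
    }
    df = records_to_frame(records)
    df = df[df["animal_id"].isin(genotype)].copy()
    if df.empty:
        raise ValueError(f"no records with a genotype at locus {locus.name!r}")
    df["locus"] = locus.name
    df["genotype"] = df["animal_id"].map(genotype)
    df["sire"] = df["sire_id"]
    df["parity_class"] = df["parity"].map(config.parity_class_label)
    bins = df["dim"].map(config.dim_bin)
    df["dim_overflow"] = df["dim"] > config.dim_max
    df = df[bins.notna()].copy()
    df["dim_class"] = bins[bins.notna()].astype(int).map("D{:02d}".format)
    df["scs"] = compute_scs(df["scc"].to_numpy())
    return df


@dataclass
class Design:
    """Full-rank dummy design for one trait x locus fit."""

    trait: str
    locus: str
    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    factor_levels: dict[str, list[str]]         # factor -> observed levels, ref first
    factor_cols: dict[str, list[int]]           # factor -> design column indices
    frame: pd.DataFrame
    dropped_levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def genotypes(self) -> list[str]:
        return self.factor_levels["genotype"]


def build_design(
    frame: pd.DataFrame, trait: str, config: RunConfig | None = None,
    factors: Sequence[str] = FACTORS,
) -> Design:
    """Categorical dummy coding (reference level absorbed in the intercept).

    Levels unobserved after filtering are dropped. A design where the
    genotype columns are linearly dependent on the remaining factors
    (genotype confounded) raises, because genotype contrasts would not be
    estimable.
    """
    del config  # class mappings were applied in association_frame
    frame = frame[frame[trait].notna()].copy()
    if frame.empty:
        raise ValueError(f"no non-missing observations for trait {trait!r}")
    all_factors = list(factors) + ["genotype"]
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    factor_levels: dict[str, list[str]] = {}
    factor_cols: dict[str, list[int]] = {}
    for f in all_factors:
        levels = sorted(frame[f].astype(str).unique())
        if len(levels) < 2 and f == "genotype":
            raise ValueError(
                f"trait {trait!r}: fewer than two genotype levels observed"
            )
        factor_levels[f] = levels
        idx = []
        for lev in levels[1:]:
            idx.append(len(names))
            names.append(f"{f}[{lev}]")
            cols.append((frame[f].astype(str) == lev).to_numpy(float))
        factor_cols[f] = idx
    X = np.column_stack(cols)
    y = frame[trait].to_numpy(float)

    rank_full = np.linalg.matrix_rank(X)
    if rank_full < X.shape[1]:
        keep = [i for i in range(X.shape[1]) if i not in factor_cols["genotype"]]
        rank_wo_g = np.linalg.matrix_rank(X[:, keep])
        if rank_full - rank_wo_g < len(factor_cols["genotype"]):
            raise ValueError(
                f"trait {trait!r}: genotype is confounded with other model "
                "factors (rank-deficient design touching genotype)"
            )
        raise ValueError(
            f"trait {trait!r}: rank-deficient design "
            f"(rank {rank_full} < {X.shape[1]} columns); "
            "some non-genotype factors are aliased"
        )
    locus_name = str(frame["locus"].iloc[0]) if "locus" in frame else ""
    return Design(trait=trait, locus=locus_name, X=X, y=y, columns=names,
                  factor_levels=factor_levels, factor_cols=factor_cols,
                  frame=frame)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class OlsFit:
    design: Design
    result: "sm.regression.linear_model.RegressionResultsWrapper"

    @property
    def df_resid(self) -> float:
        return self.result.df_resid


def fit_ols(design: Design) -> OlsFit:
    """Ordinary least squares via statsmodels (QR-based, numerically stable)."""
    if design.X.shape[0] - design.X.shape[1] <= 0:
        raise ValueError(
            f"no residual degrees of freedom "
            f"(n={design.X.shape[0]}, columns={design.X.shape[1]})"
        )
    res = sm.OLS(design.y, design.X).fit()
    return OlsFit(design=design, result=res)


def _ls_mean_contrast(design: Design, genotype: str) -> np.ndarray:
    """Contrast vector whose inner product with beta is the genotype LS mean.

    Every other factor's non-reference dummies are weighted 1/k (k = number
    of levels), the equal-weight average over that factor's levels.
    """
    L = np.zeros(design.X.shape[1])
    L[0] = 1.0
    for f, levels in design.factor_levels.items():
        if f == "genotype":
            continue
        k = len(levels)
        for lev, col in zip(levels[1:], design.factor_cols[f]):
            L[col] = 1.0 / k
    levels = design.factor_levels["genotype"]
    if genotype not in levels:
        raise ValueError(f"genotype {genotype!r} not in design")
    for lev, col in zip(levels[1:], design.factor_cols["genotype"]):
        if lev == genotype:
            L[col] = 1.0
    return L


def genotype_ls_means(fit: OlsFit) -> pd.DataFrame:
    """Per-genotype least-squares mean, standard error and record count."""
    design = fit.design
    cov = fit.result.cov_params()
    beta = fit.result.params
    rows = []
    counts = design.frame["genotype"].value_counts()
    for g in design.genotypes:
        L = _ls_mean_contrast(design, g)
        mean = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        rows.append({"genotype": g, "ls_mean": mean, "se": se,
                     "n": int(counts.get(g, 0))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotype test, pairwise comparisons, letters
# ---------------------------------------------------------------------------

@dataclass
class AssociationFit:
    """Genotype-effect summary for one locus x trait."""

    locus: str
    trait: str
    ls_means: pd.DataFrame            # genotype, ls_mean, se, n
    f_stat: float
    df_num: int
    df_den: float
    p_value: float
    pairwise: pd.DataFrame            # g1, g2, diff, se, t, p
    letters_05: dict[str, str]        # lowercase letters at alpha = 0.05
    letters_01: dict[str, str]        # uppercase letters at alpha = 0.01
    p_bonferroni: float | None = None


def compact_letter_display(
    levels: Sequence[str], means: dict[str, float],
    sig_pairs: set[frozenset[str]], alphabet: str,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Levels sharing a letter are not significantly different; the letter
    ordering follows descending mean.
    """
    order = sorted(levels, key=lambda g: -means[g])
    groups: list[set[str]] = [set(order)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        new_groups: list[set[str]] = []
        for grp in groups:
            if a in grp and b in grp:
                new_groups.extend([grp - {a}, grp - {b}])
            else:
                new_groups.append(grp)
        # absorb: drop any group contained in another
        groups = [g for g in new_groups if g and
                  not any(g < h for h in new_groups)]
        # deduplicate
        uniq: list[set[str]] = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    groups.sort(key=lambda g: min(order.index(x) for x in g))
    letters: dict[str, list[str]] = {g: [] for g in levels}
    for letter, grp in zip(alphabet, groups):
        for g in grp:
            letters[g].append(letter)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def genotype_test(
    fit: OlsFit, alpha: float = 0.05, alpha_strict: float = 0.01,
    protected: bool = False,
) -> AssociationFit:
    """Type-III F-test for the genotype factor plus pairwise LS-mean t-tests.

    ``protected=True`` reports letters only when the overall F-test is
    significant at ``alpha`` (Fisher-protected comparisons); the default is
    unconditional pairwise testing.
    """
    design = fit.design
    g_cols = design.factor_cols["genotype"]
    if len(design.genotypes) < 2:
        raise ValueError("genotype test needs at least two genotype levels")
    R = np.zeros((len(g_cols), design.X.shape[1]))
    for r, c in enumerate(g_cols):
        R[r, c] = 1.0
    ftest = fit.result.f_test(R)
    f_stat = float(np.squeeze(ftest.fvalue))
    p_value = float(np.squeeze(ftest.pvalue))

    cov = fit.result.cov_params()
    beta = fit.result.params
    lsm = genotype_ls_means(fit)
    means = dict(zip(lsm["genotype"], lsm["ls_mean"]))
    rows = []
    sig05: set[frozenset[str]] = set()
    sig01: set[frozenset[str]] = set()
    for g1, g2 in itertools.combinations(design.genotypes, 2):
        L = _ls_mean_contrast(design, g1) - _ls_mean_contrast(design, g2)
        diff = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t = diff / se
        p = float(2 * stats.t.sf(abs(t), fit.df_resid))
        rows.append({"g1": g1, "g2": g2, "diff": diff, "se": se, "t": t, "p": p})
        if p < alpha:
            sig05.add(frozenset((g1, g2)))
        if p < alpha_strict:
            sig01.add(frozenset((g1, g2)))
    if protected and p_value >= alpha:
        sig05 = set()
        sig01 = set()
    letters_05 = compact_letter_display(design.genotypes, means, sig05,
                                        "abcdefgh")
    letters_01 = compact_letter_display(design.genotypes, means, sig01,
                                        "ABCDEFGH")
    return AssociationFit(
        locus=design.locus, trait=design.trait, ls_means=lsm,
        f_stat=f_stat, df_num=len(g_cols), df_den=float(fit.df_resid),
        p_value=p_value, pairwise=pd.DataFrame(rows),
        letters_05=letters_05, letters_01=letters_01,
    )


def bonferroni(p_value: float, m: int) -> float:
    """min(1, p * m); the family size m defaults to loci x traits per run."""
    if not (0 <= p_value <= 1):
        raise ValueError(f"p-value outside [0, 1]: {p_value}")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p_value * m)


# ---------------------------------------------------------------------------
# optional random-sire mixed model
# ---------------------------------------------------------------------------

def fit_mixed_sire(frame: pd.DataFrame, trait: str) -> "sm.regression.mixed_linear_model.MixedLMResults":
    """Variant of the model with sire as a random intercept (off by default).

    Fixed part: year_season + parity_class + dim_class + genotype; sire
    enters as the grouping factor. Returned as the raw statsmodels result
    for inspection; the main pipeline uses the all-fixed model.
    """
    frame = frame[frame[trait].notna()]
    fixed = "C(year_season) + C(parity_class) + C(dim_class) + C(genotype)"
    model = sm.MixedLM.from_formula(
        f"{trait} ~ {fixed}", groups=frame["sire"], data=frame
    )
    return model.fit(reml=True, method="lbfgs")


# ---------------------------------------------------------------------------
# 305-day yields by the test-interval method
# ---------------------------------------------------------------------------

def add_305day_yields(records: Sequence[TestDayRecord]) -> None:
    """Fill missing 305-day milk/fat/protein yields in place, per lactation.

    Test-interval method: each test day represents the interval from the
    midpoint with the previous test to the midpoint with the next, the first
    interval starting at calving and the last truncated at 305 days. Daily fat
    and protein yields are milk x percentage / 100. Lactations whose records
    already carry 305-day values are left untouched.
    """
    lactations: dict[tuple[str, int], list[TestDayRecord]] = {}
    for r in records:
        lactations.setdefault((r.animal_id, r.parity), []).append(r)
    for recs in lactations.values():
        if all(r.milk305_kg is not None for r in recs):
            continue
        recs.sort(key=lambda r: r.dim)
        dims = [r.dim for r in recs]
        bounds = [0.0]  # credited from calving
        for a, b in zip(dims, dims[1:]):
            bounds.append((a + b) / 2.0)
        bounds.append(305.0)
        milk = fat = protein = 0.0
        for r, lo, hi in zip(recs, bounds, bounds[1:]):
            days = max(0.0, min(hi, 305.0) - min(lo, 305.0))
            milk += r.milk_kg * days
            fat += r.milk_kg * r.fat_pct / 100.0 * days
            protein += r.milk_kg * r.protein_pct / 100.0 * days
        for r in recs:
            if r.milk305_kg is None:
                r.milk305_kg = milk
            if r.fat305_kg is None:
                r.fat305_kg = fat
            if r.protein305_kg is None:
                r.protein305_kg = protein
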