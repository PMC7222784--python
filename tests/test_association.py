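import numpy as np
import pandas as pd
import pytest

from milkgene.association import (
    add_305day_yields,
    association_frame,
    bonferroni,
    build_design,
    compact_letter_display,
    fit_ols,
    genotype_ls_means,
    genotype_test,
)
from milkgene.model import Locus, RunConfig, TestDayRecord


def _frame(genotypes, y, factor=None, factor_name="sire"):
    df = pd.DataFrame({"genotype": genotypes, "y": y})
    df[factor_name] = factor if factor is not None else "s1"
    return df


class TestFactorMapping:
    @pytest.mark.parametrize("parity,label", [
        (1, "P1"), (2, "P2"), (3, "P3-5"), (4, "P3-5"), (5, "P3-5"),
    ])
    def test_parity_classes(self, parity, label):
        assert RunConfig().parity_class_label(parity) == label

    @pytest.mark.parametrize("dim,expected", [
        (1, 1), (30, 1), (31, 2), (60, 2), (271, 10), (300, 10),
    ])
    def test_dim_bins_closed_on_the_right(self, dim, expected):
        assert RunConfig().dim_bin(dim) == expected

    def test_dim_overflow_default_last_bin(self):
        cfg = RunConfig()
        assert cfg.dim_bin(305) == 10
        assert RunConfig(dim_overflow="drop").dim_bin(305) is None


class TestDesignAndFit:
    def test_balanced_noiseless_recovery(self):
        """Balanced 2-sire x 3-genotype design with additive truth and no
        noise: the fit reproduces every cell mean exactly."""
        rows = []
        truth = {"CC": 1.0, "CT": 0.0, "TT": -1.0}
        sire_eff = {"s1": 0.5, "s2": -0.5}
        for sire in ("s1", "s2"):
            for g in ("CC", "CT", "TT"):
                for _ in range(2):
                    rows.append({"sire": sire, "genotype": g,
                                 "y": 10 + sire_eff[sire] + truth[g]})
        df = pd.DataFrame(rows)
        design = build_design(df, "y", factors=("sire",))
        fit = fit_ols(design)
        lsm = genotype_ls_means(fit)
        means = dict(zip(lsm["genotype"], lsm["ls_mean"]))
        for g, t in truth.items():
            assert means[g] == pytest.approx(10 + t, abs=1e-10)
        # balance: LS means equal raw genotype means
        raw = df.groupby("genotype")["y"].mean()
        for g in means:
            assert means[g] == pytest.approx(raw[g], abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """Coefficients and LS means must agree with an explicit
        (X'X)^-1 X'y solution built independently from the same dummies."""
        n = 120
        df = pd.DataFrame({
            "sire": rng.choice(["s1", "s2", "s3"], n),
            "year_season": rng.choice(["y1", "y2"], n),
            "genotype": rng.choice(["AA", "AB", "BB"], n),
        })
        df["y"] = (rng.normal(size=n)
                   + df["genotype"].map({"AA": 1.0, "AB": 0.3, "BB": 0.0}))
        design = build_design(df, "y", factors=("sire", "year_season"))
        fit = fit_ols(design)
        X, y = design.X, design.y
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.result.params, beta, atol=1e-10)
        # residual orthogonality to every design column
        resid = y - X @ beta
        assert np.max(np.abs(X.T @ resid)) < 1e-8

    def test_unbalanced_ls_means_match_contrast_oracle(self, rng):
        """On an unbalanced two-factor design the LS mean equals the
        explicit contrast: intercept + genotype dummy + mean of factor
        dummies over ALL factor levels (reference included as zero)."""
        df = pd.DataFrame({
            "sire": ["s1"] * 30 + ["s2"] * 10 + ["s3"] * 20,
            "genotype": rng.choice(["AA", "AB", "BB"], 60, p=[0.5, 0.3, 0.2]),
        })
        df["y"] = rng.normal(size=60) + (df["sire"] == "s1") * 2.0
        design = build_design(df, "y", factors=("sire",))
        fit = fit_ols(design)
        lsm = genotype_ls_means(fit)
        beta = fit.result.params
        cols = design.columns
        for _, row in lsm.iterrows():
            g = row["genotype"]
            expected = beta[0]
            for k, name in enumerate(cols):
                if name.startswith("sire["):
                    expected += beta[k] / 3.0  # 3 sire levels
                if name == f"genotype[{g}]":
                    expected += beta[k]
            assert row["ls_mean"] == pytest.approx(expected, abs=1e-12)

    def test_singular_design_errors(self):
        # genotype perfectly confounded with sire
        df = pd.DataFrame({
            "sire": ["s1"] * 10 + ["s2"] * 10,
            "genotype": ["AA"] * 10 + ["BB"] * 10,
            "y": np.arange(20.0),
        })
        with pytest.raises(ValueError, match="confounded"):
            build_design(df, "y", factors=("sire",))

    def test_single_genotype_errors(self):
        df = _frame(["AA"] * 10, np.arange(10.0))
        with pytest.raises(ValueError, match="genotype"):
            build_design(df, "y", factors=("sire",))

    def test_fit_invariant_to_row_order_and_level_labels(self, rng):
        df = pd.DataFrame({
            "sire": rng.choice(["s1", "s2"], 50),
            "genotype": rng.choice(["AA", "AB"], 50),
            "y": rng.normal(size=50),
        })
        f1 = fit_ols(build_design(df, "y", factors=("sire",)))
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f2 = fit_ols(build_design(shuffled, "y", factors=("sire",)))
        m1 = genotype_ls_means(f1).set_index("genotype")["ls_mean"]
        m2 = genotype_ls_means(f2).set_index("genotype")["ls_mean"]
        assert np.allclose(m1, m2, atol=1e-10)
        relabeled = df.assign(sire=df["sire"].map({"s1": "zebra", "s2": "ant"}))
        f3 = fit_ols(build_design(relabeled, "y", factors=("sire",)))
        m3 = genotype_ls_means(f3).set_index("genotype")["ls_mean"]
        assert np.allclose(m1, m3, atol=1e-10)


class TestGenotypeTest:
    def test_no_difference_same_letter(self, rng):
        df = _frame(rng.permutation(["AA"] * 30 + ["BB"] * 30),
                    np.full(60, 10.0) + rng.normal(0, 1e-6, 60))
        fit = fit_ols(build_design(df, "y", factors=("sire",)))
        af = genotype_test(fit)
        assert af.letters_05["AA"] == af.letters_05["BB"]

    def test_large_shift_gets_distinct_letter(self, rng):
        """One genotype shifted by 10 residual SD at n = 50/group: power is
        essentially 1, so it must receive its own letter at both levels."""
        g = ["AA"] * 50 + ["AB"] * 50 + ["BB"] * 50
        y = rng.normal(0, 1, 150)
        y[100:] += 10.0
        fit = fit_ols(build_design(_frame(g, y), "y", factors=("sire",)))
        af = genotype_test(fit)
        assert af.letters_05["BB"] not in (af.letters_05["AA"],
                                           af.letters_05["AB"])
        assert af.letters_01["BB"] not in (af.letters_01["AA"],
                                           af.letters_01["AB"])
        assert af.p_value < 1e-10
        # letters consistent with pairwise p-values
        for _, row in af.pairwise.iterrows():
            shared = set(af.letters_05[row["g1"]]) & set(af.letters_05[row["g2"]])
            assert (row["p"] < 0.05) == (not shared)

    def test_protected_mode_suppresses_letters_when_f_ns(self, rng):
        df = _frame(rng.permutation(["AA"] * 40 + ["BB"] * 40),
                    rng.normal(size=80))
        fit = fit_ols(build_design(df, "y", factors=("sire",)))
        af = genotype_test(fit, protected=True)
        if af.p_value >= 0.05:
            assert af.letters_05["AA"] == af.letters_05["BB"]

    def test_f_test_matches_nested_model_comparison(self, rng):
        """The Type-III genotype F equals the explicit extra-sum-of-squares
        F between the model with and without the genotype columns."""
        df = pd.DataFrame({
            "sire": rng.choice(["s1", "s2", "s3"], 90),
            "genotype": rng.choice(["AA", "AB", "BB"], 90),
        })
        df["y"] = rng.normal(size=90) + (df["genotype"] == "AA") * 0.8
        design = build_design(df, "y", factors=("sire",))
        fit = fit_ols(design)
        af = genotype_test(fit)
        X, y = design.X, design.y
        keep = [i for i in range(X.shape[1])
                if i not in design.factor_cols["genotype"]]
        rss_full = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        X0 = X[:, keep]
        rss_red = np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2)
        q = len(design.factor_cols["genotype"])
        df_den = len(y) - X.shape[1]
        f_oracle = ((rss_red - rss_full) / q) / (rss_full / df_den)
        assert af.f_stat == pytest.approx(f_oracle, rel=1e-9)
        assert af.df_num == q and af.df_den == df_den


class TestCompactLetters:
    def test_chain_structure(self):
        # A > B > C with A vs C significant only: letters must overlap in B
        means = {"A": 3.0, "B": 2.0, "C": 1.0}
        letters = compact_letter_display(
            ["A", "B", "C"], means, {frozenset(("A", "C"))}, "abc")
        assert set(letters["B"]) & set(letters["A"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])

    def test_all_distinct(self):
        means = {"A": 3.0, "B": 2.0, "C": 1.0}
        sig = {frozenset(p) for p in (("A", "B"), ("A", "C"), ("B", "C"))}
        letters = compact_letter_display(["A", "B", "C"], means, sig, "abc")
        assert len({letters[g] for g in "ABC"}) == 3


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 24, 0.24), (0.5, 3, 1.0), (0.2, 1, 0.2),
    ])
    def test_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestAssociationFrame:
    def test_missing_genotype_excluded(self, small_herd):
        loci, calls, records = small_herd
        some_animal = records[0].animal_id
        reduced = [c for c in calls if c.animal_id != some_animal]
        frame = association_frame(records, reduced, loci[0])
        assert some_animal not in set(frame["animal_id"])

    def test_scs_column_added(self, small_herd):
        loci, calls, records = small_herd
        frame = association_frame(records, calls, loci[0])
        assert np.allclose(frame["scs"],
                           np.log2(frame["scc"] / 1e5) + 3)


class TestInterval305:
    def test_constant_yield_lactation(self):
        """A cow milking a constant 20 kg/day over 10 monthly tests must get
        a 305-day yield of exactly 20 x 305 kg."""
        recs = [
            TestDayRecord(animal_id="c1", sire_id="s1", year_season="y",
                          parity=1, dim=15 + 30 * k, milk_kg=20.0,
                          fat_pct=4.0, protein_pct=3.0, scc=1e5)
            for k in range(10)
        ]
        add_305day_yields(recs)
        assert recs[0].milk305_kg == pytest.approx(20.0 * 305)
        assert recs[0].fat305_kg == pytest.approx(20.0 * 305 * 0.04)

    def test_existing_values_untouched(self):
        rec = TestDayRecord(animal_id="c1", sire_id="s1", year_season="y",
                            parity=1, dim=30, milk_kg=20.0, fat_pct=4.0,
                            protein_pct=3.0, scc=1e5, milk305_kg=6000.0,
                            fat305_kg=240.0, protein305_kg=180.0)
        add_305day_yields([rec])
        assert rec.milk305_kg == 6000.0
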