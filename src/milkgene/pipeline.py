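"""End-to-end pipeline: filter -> popgen/HWE -> LD -> association -> effects.

Produces the full result bundle as TSV tables plus a JSON run manifest whose
record counts reconcile across stages (read = kept + dropped).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .association import (
    AssociationFit,
    add_305day_yields,
    association_frame,
    bonferroni,
    build_design,
    fit_ols,
    genotype_test,
)
from .effects import EffectDecomposition, decompose
from .io import (
    read_genotypes,
    read_phenotypes,
    write_report,
    write_run_summary,
)
from .ld import pairwise_ld
from .model import Locus, RunConfig
from .popgen import GenotypeCounts, genotype_counts, hwe_chi_square

DEFAULT_TRAITS = ("milk_kg", "fat_pct", "protein_pct", "scs",
                  "milk305_kg", "fat305_kg", "protein305_kg")


@dataclass
class RunManifest:
    inputs: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = __version__
    seed: int = 0
    counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"inputs": self.inputs, "config": self.config,
                "version": self.version, "seed": self.seed,
                "counts": self.counts}


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    hwe: pd.DataFrame
    ld_r2: pd.DataFrame
    association: pd.DataFrame
    pairwise: pd.DataFrame
    effects: pd.DataFrame
    manifest: RunManifest
    fits: dict = field(default_factory=dict)          # (locus, trait) -> AssociationFit
    decompositions: list = field(default_factory=list)


def run_pipeline(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    loci: Sequence[Locus],
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    traits: Sequence[str] = DEFAULT_TRAITS,
) -> PipelineResult:
    """Run every analysis stage and (optionally) write the result bundle."""
    config = config or RunConfig()
    manifest = RunManifest(
        inputs={
            "genotypes": {"path": str(genotype_path),
                          "sha256": _checksum(genotype_path)},
            "phenotypes": {"path": str(phenotype_path),
                           "sha256": _checksum(phenotype_path)},
        },
        config=__import__("json").loads(config.to_json()),
        seed=config.seed,
    )

    calls = read_genotypes(genotype_path, loci)
    records = read_phenotypes(phenotype_path)
    if not records:
        raise ValueError(f"{phenotype_path}: no phenotype records")
    manifest.counts["genotype_calls"] = len(calls)
    manifest.counts["records_read"] = len(records)

    # stage 1: SCC retention filter
    from .scs import filter_records
    kept, dropped = filter_records(records, config)
    manifest.counts["records_kept"] = len(kept)
    manifest.counts["records_dropped"] = len(dropped)
    manifest.counts["drop_reasons"] = {
        "below_lower_bound": sum(1 for _, r in dropped if "below" in r),
        "above_upper_bound": sum(1 for _, r in dropped if "above" in r),
    }
    if not kept:
        raise ValueError("no records survive the SCC filter")

    # stage 2: per-locus frequencies and HWE
    hwe_rows = []
    counts_by_locus: dict[str, GenotypeCounts] = {}
    for locus in loci:
        c = genotype_counts(calls, locus)
        counts_by_locus[locus.name] = c
        res = hwe_chi_square(c)
        hwe_rows.append({
            "locus": locus.name,
            "allele_major": locus.allele_major, "allele_minor": locus.allele_minor,
            "n": c.n, "n_AA": c.n_aa, "n_AB": c.n_ab, "n_BB": c.n_bb,
            "p": res.p, "q": res.q, "maf": res.maf,
            "e_AA": res.e_aa, "e_AB": res.e_ab, "e_BB": res.e_bb,
            "chi2": res.chi2, "df": res.df, "p_value": res.p_value,
        })
        manifest.counts.setdefault("genotyped_per_locus", {})[locus.name] = c.n
    hwe_df = pd.DataFrame(hwe_rows)

    # stage 3: pairwise LD
    if len(loci) >= 2:
        ld_mat, ld_details = pairwise_ld(calls, loci, config.em_tol,
                                         config.em_max_iter)
        manifest.counts["ld_pairs"] = {
            f"{k[0]}|{k[1]}": v for k, v in ld_details.items()
        }
    else:
        ld_mat = pd.DataFrame()

    # stage 4+5: association and effect decomposition
    add_305day_yields(kept)
    family = 0
    assoc_fits: dict[tuple[str, str], AssociationFit] = {}
    errors: dict[str, str] = {}
    for locus in loci:
        try:
            frame = association_frame(kept, calls, locus, config)
        except ValueError as e:
            errors[locus.name] = str(e)
            continue
        manifest.counts.setdefault("records_used_per_locus", {})[locus.name] = \
            len(frame)
        for trait in traits:
            if trait not in frame.columns or frame[trait].isna().all():
                continue
            try:
                design = build_design(frame, trait, config)
                fit = fit_ols(design)
                assoc_fits[(locus.name, trait)] = genotype_test(
                    fit, config.alpha, config.alpha_strict
                )
                family += 1
            except ValueError as e:
                errors[f"{locus.name}:{trait}"] = str(e)
    if errors:
        manifest.counts["stage_errors"] = errors
    m = family if config.bonferroni_family == "run" else None

    assoc_rows, pair_rows, effect_rows = [], [], []
    decomps: list[EffectDecomposition] = []
    per_trait_m: dict[str, int] = {}
    for (locus_name, trait) in assoc_fits:
        per_trait_m[trait] = per_trait_m.get(trait, 0) + 1
    for (locus_name, trait), af in assoc_fits.items():
        fam = m if m is not None else per_trait_m[trait]
        af.p_bonferroni = bonferroni(af.p_value, fam)
        for _, row in af.ls_means.iterrows():
            g = row["genotype"]
            assoc_rows.append({
                "locus": locus_name, "trait": trait, "genotype": g,
                "n": row["n"], "ls_mean": row["ls_mean"], "se": row["se"],
                "letter_05": af.letters_05[g], "letter_01": af.letters_01[g],
                "F": af.f_stat, "df_num": af.df_num, "df_den": af.df_den,
                "p_value": af.p_value, "p_bonferroni": af.p_bonferroni,
            })
        for _, row in af.pairwise.iterrows():
            pair_rows.append({"locus": locus_name, "trait": trait, **row})
        # effect decomposition from the LS means
        locus = next(l for l in loci if l.name == locus_name)
        c = counts_by_locus[locus_name]
        from .popgen import allele_frequencies
        p, q = allele_frequencies(c)
        means = dict(zip(af.ls_means["genotype"], af.ls_means["ls_mean"]))
        labels = [locus.genotype_label(k) for k in (0, 1, 2)]
        if all(lbl in means for lbl in labels):
            dec = decompose(
                means[labels[0]], means[labels[1]], means[labels[2]], p, q,
                locus=locus_name, trait=trait,
                orientation=(f"p = f({locus.allele_major}); alpha = effect of "
                             f"{locus.allele_major}-for-{locus.allele_minor} "
                             "substitution"),
            )
            decomps.append(dec)
            effect_rows.append({
                "locus": locus_name, "trait": trait,
                "a": dec.a, "d": dec.d, "alpha": dec.alpha,
                "p": dec.p, "q": dec.q,
                "d_over_a": "" if dec.d_over_a is None else dec.d_over_a,
                "gene_action": dec.gene_action,
                "orientation": dec.orientation,
            })

    result = PipelineResult(
        hwe=hwe_df,
        ld_r2=ld_mat,
        association=pd.DataFrame(assoc_rows),
        pairwise=pd.DataFrame(pair_rows),
        effects=pd.DataFrame(effect_rows),
        manifest=manifest,
        fits=assoc_fits,
        decompositions=decomps,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(result.hwe, out / "hwe.tsv")
        if not ld_mat.empty:
            ld_mat.round(6).to_csv(out / "ld_r2.tsv", sep="\t")
        write_report(result.association, out / "association.tsv")
        write_report(result.pairwise, out / "pairwise.tsv")
        write_report(result.effects, out / "effects.tsv")
        if not result.association.empty:
            pmat = result.association.drop_duplicates(["locus", "trait"]) \
                .pivot(index="locus", columns="trait", values="p_value")
            pmat.to_csv(out / "p_values.tsv", sep="\t")
        write_run_summary(manifest.as_dict(), out / "run_summary.json")
    return result
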