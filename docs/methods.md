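# Methods

## Scope and data model

`milkgene` analyses a candidate-gene study design common in dairy cattle
genetics: one genotype call per cow at each of a few biallelic SNPs, and
repeated monthly test-day records per cow carrying the covariates of a
fixed-effects model (sire, calving year-season, parity, days in milk) and
the recorded traits (milk kg, fat %, protein %, SCC in cells/mL, optional
305-day yields). Each locus fixes a *major/minor* allele orientation; every
downstream frequency `p` and effect sign refers to the major allele. The
year-season factor is an opaque label carried in the data: season
definitions vary by study and the package deliberately does not derive them
from dates.

## SCS and filtering

`SCS = log2(SCC / 100,000) + 3`, so SCC = 100,000 maps to 3 and each
doubling of SCC adds one point. The retention filter keeps records with raw
SCC in `[scc_lower, scc_upper]` (defaults `10^3` and `5x10^5` cells/mL).
The bounds are treated as **inclusive** — "between x and y" is ambiguous,
so inclusivity is declared and configurable — and filtering operates on raw
SCC before any transform. Filtering is a partition: every input record is
returned either as kept or as dropped with a reason; nothing is silently
discarded.

## Hardy–Weinberg statistics

Allele frequencies come from exact integer allele counts,
`p = (2 n_AA + n_AB) / 2n`; expected genotype counts are `np²`, `2npq`,
`nq²`. Computing `2npq` from exact counts (rather than from frequencies
rounded for display) guarantees the invariant `e_AA + e_AB + e_BB = n`.
This matters in practice: published tables sometimes print expected counts
derived from rounded frequencies — the reference table used in the test
fixtures prints an expected heterozygote count of 406.31 where the
constraint-respecting value is ≈406.04 (295.48 + 406.31 + 139.48 ≠ 841) —
and the package follows the definition, not the printed cell.

The HWE test is chi-square, `Σ (O − E)²/E` over the three genotype classes
with df = 1 (three classes, minus one, minus one estimated allele
frequency) and no continuity correction. For small minor-allele counts the
chi-square approximation is poor, so a conditional exact test (enumerating
heterozygote counts given the observed allele counts) is offered via
`hwe_chi_square(..., exact=True)`.

## EM haplotype frequencies and LD

For two biallelic loci genotyped without phase, all 3×3 genotype cells
except the double heterozygote determine their two haplotypes. The EM
treats the double-heterozygote count as the only latent variable: with
current haplotype frequencies `f = (f_AB, f_Ab, f_aB, f_ab)` the E-step
assigns the coupling phase (AB/ab) weight
`f_AB f_ab / (f_AB f_ab + f_Ab f_aB)` — the random-union-of-gametes
(Hardy–Weinberg) weighting standard for this estimator — and the M-step
renormalizes the completed haplotype counts. Initialization is at linkage
equilibrium (products of observed allele frequencies); iteration stops when
the largest absolute frequency change falls below `tol` (default 1e-8,
maximum 1000 iterations; hitting the cap returns a result flagged
`converged=False`, never a silent answer). The observed allele frequencies
are invariant under the M-step, so the marginals always reproduce the
single-locus frequencies. The log-likelihood trajectory is recorded and is
non-decreasing — asserted in the tests.

From the converged frequencies: `D = f_AB − p_A p_B`;
`D′ = D / D_max` with `D_max = min(p_A q_B, q_A p_B)` for positive `D` and
`min(p_A p_B, q_A q_B)` otherwise; `r² = D² / (p_A q_A p_B q_B)`. Both are
undefined at a fixed locus, which raises. The pairwise matrix excludes
animals missing either genotype pair by pair, and records per-pair failures
as missing cells with reasons instead of aborting.

No significance test accompanies `r²` by default; an optional seeded
permutation p-value (shuffling one locus's genotypes across animals) is
provided for users who want one.

In the test suite the EM is checked against an independent maximizer of the
same multinomial likelihood: hierarchical grid refinement over the full
3-parameter haplotype simplex. The oracle deliberately does not use the
fact that the ML marginals equal the observed allele frequencies, so it
shares no analytic shortcut with the EM.

## Association model

Per trait and locus the model is

```
y = μ + sire_i + yearseason_j + parityclass_k + dimclass_l + genotype_m + e
```

with every factor **fixed** and `e` iid with common variance. Two modelling
choices deserve emphasis because they depart from common quantitative-
genetics practice and are deliberate:

- **Sire is fixed**, matching the model as specified; treating sire as
  random (a sire model in the BLUP sense) is the more usual choice, and a
  random-sire variant (`fit_mixed_sire`, statsmodels `MixedLM`) is exposed
  but not used by the pipeline.
- **Repeated records per cow are treated as conditionally independent**
  given the fixed effects; the model has no permanent-environment or
  cow-level random term. Standard errors for traits with strong repeated
  structure (notably the 305-day yields, which are constant within a
  lactation) are therefore anti-conservative. This is a known limitation
  of the model form itself, not of the implementation.

Parity maps to classes {1}, {2}, {3–5} (parities above 5 fold into the last
class); DIM maps to ten 30-day bins closed on the right ([1,30], [31,60],
…, [271,300]); DIM beyond 300 goes to the last bin by default (flagged per
record) or is dropped per config. Factor levels unobserved after filtering
are dropped. The design is dummy-coded with the reference level absorbed
into the intercept, fit by QR-based least squares (statsmodels OLS). A
rank-deficient design raises — with a specific message when the deficiency
touches the genotype columns, since genotype contrasts are then
non-estimable.

Genotype comparisons are **least-squares means**: the model prediction for
a genotype averaged with equal weights over the levels of every other
factor, computed as a contrast vector against the coefficient vector with
variance from the coefficient covariance. In a balanced design these equal
raw genotype means (asserted in the tests). The genotype factor is judged
by a Type-III (marginal) F-test — with only main effects in the model this
is the joint test that all genotype coefficients vanish. Pairwise genotype
differences get t-tests on LS-mean contrasts and a compact letter display
(insert-and-absorb algorithm), lowercase at α = 0.05 and uppercase at
α = 0.01. Pairwise letters are unconditional by default; a Fisher-protected
mode (letters only when the overall F-test is significant) is available,
since published reports rarely state which convention they used.

Bonferroni correction is `min(1, p·m)` with the family defaulting to all
locus × trait tests actually fit in the run; a within-trait family is
configurable because the appropriate family is a judgement call the
analysis cannot make for the user.

**305-day yields**: used as provided when present; otherwise computed per
lactation by the test-interval method (each test day credited with the
interval from the midpoint with the previous test to the midpoint with the
next, the first interval starting at calving, truncated at 305 days; fat
and protein dailies are milk × percentage / 100). The pipeline then carries
them per record, i.e. the association model for a 305-day trait sees one
repeated value per record of the lactation, mirroring how per-genotype
record counts are reported in this literature.

## Effect decomposition

`a = (AA − BB)/2`, `d = AB − (AA + BB)/2`, `α = a + d(q − p)`, computed
from LS means by default (matching the covariate-adjusted comparisons; a
raw-means mode is just passing raw means). `p` is the major-allele
frequency, and each output row records the orientation (`alpha = effect of
C-for-T substitution`) so the sign is interpretable. Gene action is
classified from `|d/a|`: ≥ 1.2 → overdominance (the threshold with support
in the quantitative-genetics literature); below that, < 0.2 additive,
0.2–0.8 partial dominance, 0.8–1.2 dominance — explicitly labelled a
reporting convention and overridable (`GeneActionBins`). Degenerate cases:
`a = 0, d ≠ 0` is overdominance (infinite ratio); `a = d = 0` is additive.
Label-swap symmetry (negating `a` and `α`, preserving `d` and the class) is
property-tested.

## Synthetic herds

The generator emulates the study design the analysis assumes, with
defaults at the design's scale: 841 cows, 162 sires with 2–43 daughters
each (counts drawn in range, then adjusted to sum exactly), 1–5 lactations
per cow at monthly recording (8–10 tests per lactation at DIM 15, 45, …),
year-season labels drawn per lactation from eight defaults spanning four
years × two seasons.

Genotypes: each cow is the random union of two gametes drawn from the
configured haplotype distribution, so HWE holds per locus by construction.
Loci form a Markov chain — each locus is drawn conditional on the previous
one via a pairwise haplotype table derived from a target `r²` (D taken
positive), which realizes the target LD exactly for consecutive pairs and
keeps arbitrary numbers of loci internally consistent (a full multi-locus
haplotype table cannot generally satisfy independent pairwise targets).

Records: trait value = mean + sire + year-season + parity class + a smooth
declining DIM curve (a stylized lactation curve rather than iid bin
effects — irrelevant to estimator correctness, closer to real data) +
genotype value (AA → +a, AB → d, BB → −a) + normal residual, every effect
drawn once per level from configured SDs. Default magnitudes are chosen to
be realistic for Holstein test-day data: mean milk 30 kg/day with residual
SD 4 kg, fat 4.2% (SD 0.6), protein 3.3% (SD 0.25), sire/year-season/parity
SDs smaller than the residual. SCC is lognormal (median 10^5 cells/mL,
σ_ln = 1.1); genotype and factor effects on SCC shift the median on the
log2 scale, so a configured SCS effect is exactly additive after the SCS
transform. One genotype per cow is constant across her records (no
genotyping-error model). Same seed ⇒ identical herd, byte for byte.

What the generator does **not** emulate: pedigree beyond the sire, culling
and selection across lactations, genotype × environment interaction,
autocorrelated within-lactation residuals, and missing-at-random genotype
patterns. Tests passing on these herds therefore validate the estimators
under the model's own assumptions; they do not certify behaviour under
model misspecification.

## Simulation sizes used in the checks

The calibration and recovery checks pick sizes that make the statistical
assertion sharp at desk scale: null calibration of the genotype F-test uses
1,000 replicates of a reduced herd (60 cows × 12 sires, ≤ 2 parities, 4
tests per lactation — about 270 records per replicate), asserting the
empirical type-I error at α = 0.05 inside the binomial 99% band; `r²`
recovery uses 200 genotype-only replicates at the full 841-cow scale
against a 0.15 target (three Monte-Carlo SEs); additive-effect recovery
simulates one full-scale herd (~22,000 records) with `a` = half a residual
SD and requires recovery within two standard errors. The acceptance script
repeats these at 500 and 100 replicates respectively.

## Numerical notes

- Frequencies are carried at full precision internally and rounded only for
  display (reports default to 4 decimals; round-trip through the TSV
  writers reproduces values at the declared precision).
- The EM tolerance applies to frequency changes, not log-likelihood
  changes; 1e-8 leaves the estimate well inside the 1e-4 agreement band
  checked against the grid oracle.
- `relative_difference(m1, m2) = 100 (m1 − m2)/m2` errors on a zero
  reference rather than returning ±inf.
- Genotype tables accept either a long-format delimited table or a minimal
  VCF (biallelic SNPs with GT; `./.` is a missing call, which excludes the
  animal from that locus's analyses only). VCF support is read-only.
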