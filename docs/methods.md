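# Methods

`nilqtl` implements the analysis path for a multi-parent near-isogenic line
(NIL) library segregating donor (e.g. teosinte) alleles in a recurrent
inbred background: simulation of the library with known truth, reduction of
plot data to entry means, variance-component heritability, joint-linkage
QTL mapping with family-nested marker effects, and the NIR/NMR calibration
stage that produces the phenotypes in the first place. This note records
the models, the defaults and why, and what the synthetic data do and do not
establish.

## Pedigree simulation

A line is simulated as an independent descent through a BCₙSₘ pedigree
(default BC₄S₂): the F1 between donor and recurrent parent is backcrossed
to the recurrent parent n times, then selfed m times. Meiosis uses the
Haldane model — crossover count per chromosome ~ Poisson(L/100) for length
L cM, positions uniform, no interference — giving recombination fraction
r = ½(1 − e^(−2d/100)) at distance d. Genotypes are read off at marker
positions and coded B (homozygous recurrent), H (heterozygous), D
(homozygous donor).

Under neutral Mendelian transmission the per-locus state is a Markov chain
started at H: each backcross maps H→{B:½, H:½}; each selfing maps
H→{B:¼, H:½, D:¼}. For BC₄S₂ this gives (P_B, P_H, P_D) =
(0.96094, 0.01563, 0.02344), i.e. ≈3.9% of each line's genome
donor-derived — the "~4% introgression" regime of real backcross NIL
libraries. Real libraries built with visual selection show somewhat more
residual heterozygosity than this expectation; the simulator is
deliberately neutral (no selection among progeny, no forced introgression,
no segregation distortion), so lines carrying zero donor segments occur.

The default map has 728 markers on 10 chromosomes (1510 cM total, markers
evenly spaced in proportion to chromosome length); the default library has
10 donor families of 58–185 lines, 961 in total.

## Phenotype generation

A plot value is

    intercept + Σ_q effect(q, family) · dose + polygene + env + g×e + plot error

with dose 0/0.5/1 for B/H/D (so an "effect" is the homozygous-substitution
effect of the donor allele), polygene ~ N(0, σ²_G) per line, g×e ~
N(0, σ²_GE) per line × environment, and plot error ~ N(0, σ²_e). The trial
structure defaults to 2 environments × 2 replicates. Trait intercepts
default to 71.41 / 10.77 / 3.89 (% dry matter) for starch / protein / oil,
and per-trait default variance components are set so the entry-mean
heritabilities land near 0.70 / 0.76 / 0.94. An optional correlation matrix
makes the polygenic deviates of several traits correlated, which is how
the starch–protein phenotypic correlation (≈ −0.8 in real kernel data) is
emulated.

For the QTL-recovery experiments, per-family allele effects span −2.56 to
+0.61 trait units (the range reported for teosinte kernel-composition
alleles) and the nuisance components (σ²_G = 0.353, σ²_GE = 0.116,
σ²_e = 0.463) are chosen so that one such QTL explains ≈9% of entry-mean
variance — the per-QTL share implied by two starch QTL explaining 18% —
at total H² = 0.70. These two anchors (per-QTL R² and H²) are what the
generator reproduces; it does not simultaneously reproduce the full
phenotypic range of the real data, which reflects more QTL and a
non-neutral introgression history.

## Entry means and heritability

LSmeans come from the two-way fixed-effects model value = line + env +
error, evaluated at the average of the environment effects; replicate is
nested in environment and absorbs into the error for entry means. The
implementation absorbs the line effects (within-line demeaning) and solves
only for the environment contrasts, which reproduces the normal-equation
solution for connected designs; on balanced data the LSmean is exactly the
line's arithmetic mean.

Variance components come from the random-effects model value = μ + line +
env + line×env + error (env fixed; line, line×env random). For balanced
data the closed-form expected-mean-squares solution is used (it coincides
with REML there, and is exact and fast); unbalanced data are fit by
numerical REML (statsmodels MixedLM). Negative estimates are truncated at
zero. A method-of-moments estimator is exposed separately as a
cross-check. Broad-sense heritability on an entry-mean basis is

    H² = σ²_G / (σ²_G + σ²_GE/e + σ²_e/(e·r)),

with e and r replaced by harmonic means of the per-line environment and
replicate counts when unbalanced. Missing plots are dropped, not imputed.

Phenotypic correlations are pairwise-complete Pearson correlations of the
LSmeans with t-distribution p-values; constant traits or pairs with fewer
than 3 complete observations are reported missing with a warning.

## Joint-linkage mapping

Donor dose is coded additively (B=0, H=0.5, D=1; heterozygote midpoint), so
a nested coefficient is on the homozygous-substitution scale. Missing
calls are imputed with the family-specific mean dose at the marker
(optionally 0). The base model always contains family main effects. A
marker enters as the *group* of its family-nested dose columns, one per
family in which it segregates (within-family dose variance > 0); the entry
test is the grouped F-test of those columns, with the numerator df equal
to the retained column rank.

The genome-wide entry threshold is found by permutation: trait values are
shuffled across lines *within* each family (genotypes fixed), the minimum
nested-marker p-value over all markers against the family-only model is
recorded per permutation, and the threshold is the gwer-quantile (default
gwer = 0.05, 1000 permutations) of those minima. Shuffling within family
preserves the family main effects, so the family term cannot inflate the
null. The permutation scheme and the absence of backward elimination are
deliberate protocol choices; both are exposed as parameters (an explicit
`threshold` overrides the permutations).

Forward selection repeatedly adds the marker with the smallest entry
p-value while it is below the threshold, breaking ties by chromosome then
cM, and skipping markers whose dose vector is perfectly correlated with an
already-selected one. The final model is refit by OLS (family effects +
all nested columns); per-coefficient two-sided t-tests compare each
family's donor allele to the recurrent-parent 0-dose baseline, and the
model R² is reported. Rank-deficient columns are dropped with a log
message. A negative coefficient means the donor allele lowers the trait.

Each selected QTL gets a conditional LOD profile over its chromosome: with
all other selected QTL held fixed, every marker m is substituted into the
profiled slot and LOD(m) = (n/2)·log₁₀(RSS_without/RSS_with), where
RSS_without lacks any marker in the slot and n is the per-trait
complete-case entry count. The support interval walks outward from the
profile peak while markers stay within 1 LOD (configurable) of the peak,
and reports those markers' cM positions (closed interval). The
allelic-effect table marks raw p < 0.05 (*) and p < 0.01 (**), with "–"
for families carrying no donor introgression at the marker; no
multiple-testing correction is applied to these final-model t-tests.

Internally all scans run on a shared engine that residualizes each
marker's nested block against the base model once and reduces a scan of
any response vector to one matrix product; permutation thresholds and
many-dataset null studies reuse the same precomputation. The engine is
verified against dense normal-equation brute force (p-values,
coefficients, R², LOD) to 1e-8 relative error in the test suite.

### What the recovery experiments show

With effects spanning the published range planted at a single marker, the
selection peak lands within 10 cM of truth in ≥90% of seeds, the 1-LOD
interval covers truth in ≥80%, and final-model effect estimates at the
causal marker cover truth within ±2 SE at the nominal ≈95% rate. Effect
estimates read off at the *selected* marker instead are very slightly
anticonservative (observed coverage ≈93%): when the peak settles on a
neighbouring marker, within-family dose mismatches attenuate individual
estimates. This is an intrinsic property of marker-based mapping in
low-recombination material, not an estimation bug.

## Chemometric calibration

**MSC.** Each spectrum x is regressed on a reference spectrum m (default:
the mean training spectrum), x ≈ a + b·m, and corrected to (x−a)/b. With
the reference held fixed the correction is exactly idempotent (the second
regression returns a=0, b=1); re-estimating the reference from corrected
spectra perturbs the result at the 1e-2 level, so the transformer stores
its fitted reference.

**Savitzky–Golay.** Local least-squares polynomial differentiation
(default window 11 points, polyorder 2, first derivative), edges handled
by evaluating the polynomial fitted to the first/last window (no padding);
implemented via scipy's filter with the grid spacing honoured so output is
absorbance per nm. Exact on polynomials up to the fitted order.

**PLS1.** NIPALS on column-centered X and centered y: w ∝ Xᵀy, t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflation X ← X − tpᵀ, y ← y − qt;
coefficients B = W(PᵀW)⁻¹q assembled for raw-scale prediction. With full
rank it equals OLS. The component count defaults to leave-one-out
cross-validation (capped at 15), computed with one incremental NIPALS pass
per left-out sample. SEC uses n − 1 − A degrees of freedom for A
components — conventions differ across chemometrics software, so this is
stated explicitly. The preprocessing chain is configuration-driven
(protein: MSC only; starch: derivative + MSC is typical), and a seeded
190/20 calibration/validation split utility mirrors standard practice.

**NMR.** Single-predictor least squares of the reference oil content on
the mean of replicate resonance readings, with r and SE reported
(n_params = 1).

**Synthetic spectra.** Beer–Lambert mixtures of three latent constituents
with Gaussian NIR bands (carbohydrate, amide and C–H stretch regions),
linear baseline, per-sample multiplicative/additive scatter, and white
noise of 0.003 absorbance units per channel — the repeatability scale of a
scanning NIR instrument after scan averaging. Oil is embryo-localised, so
its observable band amplitude is multiplied by a random per-sample
attenuation (log-normal, unit mean, σ = 0.35) emulating kernel
orientation; this caps the achievable oil correlation near 0.7 while
protein and starch calibrate to r > 0.95, reproducing qualitatively why
intact-kernel NIR oil models fail and an NMR model is needed. The
generator idealises real spectra: constituent bands are few and Gaussian,
reference chemistry is error-free, and no wavelength-dependent scatter or
instrument drift is included — passing tests therefore validate the
algorithms, not instrument-specific performance.

## Numerical choices

- Rank decisions use SVD with tolerance 1e-9·σ_max·max(n,p); dropped
  columns prefer keeping earlier (first-entered) terms.
- F-statistics clip negative RSS differences (roundoff) at zero; a marker
  segregating in no family returns p = 1 with a flag.
- Permutation thresholds use the linear-interpolated empirical quantile;
  with 200 permutations at gwer 0.05 the realised false-positive rate is
  ≈5.2% by the order-statistic argument, well within the tested band.
- All randomness flows through numpy Generators seeded explicitly; the
  pipeline derives per-stage seeds from one master seed via SeedSequence,
  so reruns are byte-identical.

## Problem sizes used in the test suite

The statistical acceptance checks run at reduced but adequate sizes chosen
for precision per unit time: genome-wide error rate over 500 null datasets
(25 genotype sets × 20 phenotype draws) of 300 lines × 200 markers with
200 permutations each; QTL recovery over 100 seeds of the full 961 × 728
library with 120 permutations; heritability over a 3×3 component grid × 20
seeds at 961 lines. These sizes put the binomial/Monte-Carlo error of each
tallied rate well inside the asserted margins.

## Known limitations

- The simulator is neutral; it does not reproduce the excess
  heterozygosity or locus-specific donor enrichment of real selected NIL
  programs.
- Marker-based mapping only: no interval mapping between markers, no
  epistasis scan, no fine-mapping.
- Family labels are exchangeable in the generator — donor families differ
  only through the allele effects planted on them, not through donor-genome
  divergence.
- The unbalanced-data REML path inherits MixedLM's convergence behaviour;
  for heavily unbalanced or tiny datasets the method-of-moments
  cross-check is the more robust reference.
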