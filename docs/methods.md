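# Methods

This note documents the statistical models, the synthetic study conditions,
the numerical choices, and the limitations of `milletmap`.

## Data model

A panel is a set of named lines scored at multiallelic SSR loci; a call is an
unordered pair of amplicon sizes in bp, or missing. Diploid storage with
explicit heterozygotes is kept (rather than a haploid consensus) because the
AMOVA within-individual component and allele-copy frequency conventions need
it, even though the target panels are near-inbred. Allele identity is the
exact integer size — no binning; gel resolution is a wet-lab concern, not a
computational rule. Phenotypes are long-format records (line, location, year,
replicate, trait, value in ppm) over a three-location × two-year × three-
replicate trial; analysis operates on twelve line-level datasets per trait
(six environment means and six unweighted pooled means: per-location,
per-year and grand mean).

## Diversity statistics

Per locus, frequencies are counted over allele copies (two per non-missing
call). Nei gene diversity H = 1 − Σp², effective allele number n_e = 1/Σp²,
and PIC = 1 − Σp² − Σ_{i<j} 2p²ᵢp²ⱼ. Alleles under 5% frequency are flagged
rare but never filtered. The panel-level "allele deficit"
(mean n_a − mean n_e)/mean n_a summarizes how much of the allele count is
carried by low-frequency alleles.

## Admixture inference and K selection

The likelihood is the standard admixture mixture: each allele copy of line i
at locus l draws an ancestry k ~ q_i and then an allele a ~ p_kl. We fit by
EM, updating q and p from the same responsibilities (which guarantees
monotone log-likelihood ascent), with multiple random restarts
(Dirichlet(1/K) initial q; pooled frequencies perturbed by ×U(0.5, 1.5) for
initial p). Defaults: tol 1e-6 on the log-likelihood change, max_iter 2000,
5 restarts. K = 1 has the closed-form pooled-frequency solution.

A Bayesian MCMC sampler would give LnP(D) per run; here the maximized
log-likelihood of each restart plays that role in the Evanno statistic
ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)), defined for
interior K only, with the restart runs serving as the replicates. The spread
across restarts comes from multi-start variability rather than Monte Carlo
noise; empirically it behaves the same way — small sd and a sharp peak at
the true K, larger sd in the overfitting regime. sd = 0 is reported as +inf
with a warning. This trade (deterministic, seconds-scale, testable inference
for the sampler's posterior) is the package's main methodological
substitution.

Assignment uses the max-membership rule with an inclusive threshold of 0.6;
groups are lettered by descending size. Label switching in recovery tests is
resolved by exhaustive column permutation (K ≤ 8).

## Distances, trees, ordination, kinship

Nei (1972) standard distance between lines is computed on per-line
allele-frequency profiles (dosage/2), with −ln 0 capped at 10 by default.
Neighbor-joining uses scikit-bio (negative branches zeroed with the excess
moved to the sister edge); PCoA is classical Gower double-centering with
negative eigenvalues dropped (warned) and explained proportions over the
positive spectrum. Kinship is allele sharing: mean over loci of
Σ_a min(dosage_a, dosage_b)/2, in [0, 1], diagonal 1 for fully homozygous
lines, shifted past the most negative eigenvalue (+1e-6) if indefinite.

## AMOVA

Three levels over allele copies — among subpopulations, among individuals
within, within individuals — with the allele-mismatch distance. Sums of
squares use the count identity SS = (T² − Σm²)/(2T) per locus per group;
df = (g−1, n−g, n). Variance components come from the standard moment
equations (average copies per individual is 2; the among-group coefficient
is the usual unequal-size correction); negatives are clamped with a warning
and percentages recomputed. F_ST = Va/(Va+Vb+Vc). The permutation test
shuffles individuals among groups and compares the *unclamped* among-group
component: clamping the permuted statistic would pile null p-values at 1 and
destroy the uniformity a permutation p must have. The admixture group
participates as a group of its own (four groups on a three-subpopulation
panel).

## Phenotype statistics

Variance components come from the balanced two-way (genotype × environment,
environments = location-year cells) ANOVA expected mean squares:
σe² = MS_error, σGE² = (MS_GE − MS_error)/r, σG² = (MS_G − MS_GE)/(nr),
negatives clamped at 0. A one-way variant serves single environments. This
method-of-moments reading (genotypes effectively random for H²) is the
standard entry-mean heritability construction; incomplete-block (lattice)
adjustment is out of scope and replicate means are used instead. Pooled
datasets are unweighted means of their member environments; lines missing an
entire environment are excluded from pools that involve it (no imputation).

## LD

Multiallelic composite r² = Σᵢⱼ pᵢqⱼD²ᵢⱼ/(pᵢ(1−pᵢ)qⱼ(1−qⱼ)), with joint
copy frequencies estimated by pairing the allele copies of the two loci
within individuals (all four pairings; no phase needed). For complete panels
all C(L,2) pairs and their permutation p-values are computed by blocked
matrix products (one shared line permutation per replicate across pairs —
each pair's marginal null is exact); panels with missing calls fall back to
a per-pair loop on the lines observed at both loci. Pairs with a monomorphic
side are reported as r² = 0 with a flag.

## Association scans

Marker designs code allele dosage (0/1/2) per allele class; alleles with
fewer than `min_class_size` (default 3) carriers are merged into an "other"
class (folded into the reference if still rare); the largest class is the
dropped reference; missing calls are mean-imputed so GLM and MLM test
identical row sets. The GLM is OLS with the leading K−1 Q columns as
covariates; the marker p-value is the partial F-test and marker R² is
SS_marker/SS_total.

The MLM adds a polygenic random effect with covariance σu²·K. Variance
components are estimated once per dataset by REML on the marker-free null
model: rotate by the eigenvectors of K, profile out β and the scale, and
optimize the ratio δ = σe²/σu² on a log₁₀ grid over [−6, 6] refined by
bounded scalar minimization. Every marker is then tested on the whitened
data with those components fixed (P3D). Marker R² on the whitened scale is
taken against the whitened intercept-only model, which makes the definition
rotation-invariant and exactly equal to the GLM R² when σu² = 0. Exact
per-marker REML is deliberately not the default (desk-scale speed); the
`variance_ratio` argument forces a given λ = σu²/σe² when needed.

The significance threshold follows the marker-count convention
p < 1/n_markers (267 markers → 3.74 × 10⁻³, −log₁₀ = 2.43) rather than the
conventional α/n; the latter is a one-line caller-side change. QQ data use
expected quantiles (i − 0.5)/m; genomic inflation is the median χ²(1) ratio.
Within-subpopulation checks use one-way ANOVA of trait on genotype class
(distinct unordered allele pairs), dropping classes under 2 lines.

## Favorable alleles and crosses

a_i is the carrier mean minus the mean over lines scored at that marker (the
population-mean baseline keeps Σ n_i·a_i = 0 exact under missingness when
every line falls in one class). Heterozygotes contribute their full
phenotype to each carried class. Rare alleles have inflated apparent
effects, so cross planning filters with `min_carriers` (5 recommended on a
~130-line panel) and optionally keeps only the superior (largest-effect)
allele per marker × trait; plain mining (a_i > 0) applies no such filter.
Crosses are scored by the number of distinct favorable (trait, marker,
allele) combinations covered by either parent, with per-trait counts and the
distinct-marker count reported alongside (a marker favorable for both traits
counts once in the marker column); ties break lexicographically on parent
ids.

## Synthetic study conditions

Defaults emulate a biofortification association panel: 130 lines, 267 loci
with 2–5 alleles (ancestral frequencies symmetric Dirichlet(0.5), calibrated
so mean gene diversity lands in 0.25–0.45), three subpopulations under
Balding–Nichols drift F = 0.15 — the correlated-frequency model the
admixture likelihood assumes — admixture Dirichlet(0.2) (≈20–25% of lines
below the 0.6 assignment threshold), selfing rate 0.9 (≈3–4% residual
heterozygosity). Loci that realize fewer than two alleles are redrawn so the
panel is fully polymorphic; planted-QTL loci have the favorable allele's
ancestral frequency drawn in [0.20, 0.35] so carrier classes are common
enough to analyze.

Phenotypes: base means 58 (Fe) and 43 (Zn) ppm; variance components
σG² = 90/40, σGE² = 80/35, σe² = 90/40 ppm² (Fe/Zn), environment main
effects N(0, 16). These give entry-mean H² ≈ 0.83–0.90, the high-heritability
regime typical of grain micronutrient trials. Planted marker effects (three
per trait, 6–10 ppm per homozygous carrier, entering as favorable-copy
count/2 × effect so a homozygote shows the full effect — the lines are
near-inbred) each explain roughly 8–16% of line-mean variance. The polygenic
value is drawn with covariance σG² times the double-centered, unit-diagonal
kinship: raw allele-sharing kinship carries a large constant baseline shared
by all lines, and centering it is what makes the realized *between-line*
genetic variance equal σG², so that ANOVA recovery of the configured
components is a meaningful test. An option plants a complementary parent
pair (line_001/line_002 homozygous for disjoint halves of the favorable
alleles) as ground truth for cross-ranking recovery.

What the generator does **not** emulate: linkage (markers are independent;
LD arises from structure only, so LD-decay behavior is untestable here),
field spatial structure and incomplete blocks, genetic correlation between
Fe and Zn, assay error structure, and allele-size homoplasy. Passing
recovery tests therefore demonstrates correctness of the estimators under
the assumed generating model, not robustness to these real-data features.

## Problem sizes and reproducibility

Simulation-based checks use the default 130 × 267 panel; structure-recovery
sweeps run K = 1..6 with 5 restarts at max_iter 400 / tol 1e-5 (the
log-likelihood plateau relevant to ΔK is reached well before full
convergence), null-calibration uses 50 independent scans, and power/recovery
checks use 10–20 seeds — sizes chosen so the whole suite replays comfortably
on one CPU. Every random draw flows from a single seed through named
substreams (SeedSequence + CRC32 of the stage name); reruns are bit-identical.

## Known limitations

- The EM fit returns a point estimate; no posterior uncertainty on Q, and
  ΔK inherits the usual caveat that it cannot support K = 1 (interior only).
- P3D variance components are slightly anti-conservative relative to exact
  per-marker REML at strong single-marker effects.
- Composite LD r² on unphased heterozygotes can exceed gametic r²; with
  near-inbred panels the distinction is minor.
- The AMOVA df pattern assumes every individual contributes two copies at
  every locus; heavy locus-specific missingness biases SS slightly (copies
  are dropped from counts but df are not adjusted).
- Dataset pooling assumes near-balanced environments; badly unbalanced data
  warrant a mixed-model reanalysis instead of unweighted pooling.
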