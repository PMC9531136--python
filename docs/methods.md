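# Methods

## The measurement model

A TOMO-Seq sectioned-oocyte experiment yields raw counts `k_gj` for gene
`g` in sample `j`, where a sample is one axial section (A–E, animal pole
to vegetal pole) of one replicate oocyte at one ordered growth stage.
tomoloc models `k_gj` as negative binomial,

    k_gj ~ NB(mean = s_j · μ_gj,  variance = μ + α_g μ²),

with a per-sample size factor `s_j` capturing sequencing depth and a
per-gene dispersion `α_g` capturing biological replicate-to-replicate
variability. All inference is conditional on the five-section design;
there is no spatial model finer than the sections.

## Normalization

Size factors use the median-of-ratios construction: the reference for
each gene is its geometric mean across samples, and `s_j` is the median
ratio `k_gj / ref_g` over genes with nonzero counts in every sample
(an even number of eligible genes takes the mean of the two central
ratios). Localization is then expressed per oocyte as the percentage of
the gene's normalized transcripts in each section; stage-level profiles
are the unweighted mean of the per-oocyte percentages over replicates.
Oocytes in which a gene has zero total are excluded from that mean (a
0/0 percentage is undefined), flagged with a warning rather than imputed
as zeros. Each species is normalized independently; there is no joint
cross-species normalization.

**Known limitation — composition bias.** Median-of-ratios assumes that
the typical gene is unchanged between samples. When a large, directionally
consistent fraction of the transcriptome is localized (in simulations,
25 % of genes strongly vegetal and none animal), the section-E factors
absorb part of the localization signal (factors tilt ≈0.88 at A to ≈1.16
at E), which deflates vegetal percentages and makes genuinely uniform
genes appear weakly animal after normalization. In that regime the
false-discovery proportion of DLT calls rises to ≈0.18–0.23 even though
the test itself is exactly calibrated under oracle factors (type-I error
0.050). This is a property of the normalization, not of the GLM — the
reference median-of-ratios implementation produces factors identical to
ours on the same data — and it affects any analysis of strongly polarized
tissue with this normalization. Balanced animal/vegetal compositions, or
a majority of unlocalized genes, keep the factors clean; the simulator's
benchmark datasets therefore carry a realistic majority of uniform
background genes.

## DLT testing

Four nested design pairs answer the pipeline's questions (treatment
coding; position levels ordered A–E, stage levels in declared order,
first level as reference; interaction columns are products of main-effect
indicators; aliased columns are dropped with a warning):

| name | full | reduced | question |
|---|---|---|---|
| within_stage | ~replicate + position | ~replicate | localized at this stage? |
| profile_across_stages | ~Size + position + Size:position | ~Size + position | profile changes with stage? |
| magnitude_across_stages | ~Size + position | ~Size | per-section magnitude changes? |
| total_between_stages | ~Size | ~1 | total amount changes? |

The total test takes per-oocyte summed normalized counts, rounded to
integers, with offset 0 (rounding error is negligible at the totals
involved). Replicates are nested within stage and appear as a factor only
in the within-stage design; across stages they are treated as independent
samples, since replicate identities are not shared between stages.

Fits are log-link NB regressions with `log s_j` offset, by iteratively
reweighted least squares (convergence at max coefficient change < 1e-8,
at most 100 iterations; non-convergent genes are excluded from testing
with a warning). The likelihood-ratio statistic is `2(ll_full − ll_red)`
clipped at zero, with both fits sharing the gene's dispersion.

**Dispersion.** `α_g` is a single per-gene moment estimate with no
information sharing across genes: fit the Poisson (zero-dispersion)
limit under the full design, then solve

    Σ_j (k_j − μ̂_j)² / (μ̂_j + α μ̂_j²) = n − p

for `α` (Pearson statistic equated to its residual degrees of freedom),
clipped to [1e-8, 10]. The df correction matters: the uncorrected
residual-variance ratio underestimates `α` by roughly `(n−p)/n` — a
factor ≈0.5 at n = 15 samples and p = 7 parameters — which would inflate
the type-I error of the LRT several-fold.

**Reference distribution.** Because `α_g` is estimated from the same few
samples it calibrates, the asymptotic χ² reference is anti-conservative
at TOMO-Seq sample sizes (measured ≈0.14 at nominal 0.05 even with an
unbiased estimator). `detect_dlts` therefore refers `statistic/df` to an
F(df, n − p_full) distribution by default, the standard quasi-likelihood
small-sample correction; measured type-I error under the null is then
0.050 ± 0.005 at nominal 0.05. The plain χ² reference remains available
(`p_reference="chisq"`), and the `lrt()` primitive itself is the
χ² test. P-values are Benjamini–Hochberg adjusted across tested genes;
a DLT requires padj < 0.1 *and* more than 20 normalized transcripts per
oocyte (for cross-stage designs, in the best stage), so significance on
negligible material never counts.

Not implemented by design: dispersion-trend or empirical-Bayes shrinkage,
outlier replacement, and independent-filtering optimization of adjusted
p-values.

## Profile classes

A stage profile (pA..pE, summing to 100) is classified in fixed order:
extreme_animal if pA ≥ 60; extreme_vegetal if pE ≥ 60; animal if
pA+pB ≥ 60; vegetal if pD+pE ≥ 60; central if pB+pC+pD ≥ 70 and pC is
the unique maximum; otherwise undefined. First-match order resolves
overlaps deterministically (extremes win over pole pairs); the unique-
maximum condition keeps flat profiles out of "central". The numeric
thresholds (60/60/70) are package defaults chosen so that the simulator's
archetypes classify correctly with margin and uniform profiles fall to
undefined; they are configurable, and results on real data depend on
matching the thresholds used upstream. The rules are exactly mirror-
symmetric: reversing a profile swaps animal and vegetal labels and fixes
central/undefined.

## Temporal groups

Between the earliest (e) and latest (l) stage with profiles, each DLT is
assigned by rules on the pole-pair percentages (`veg = pD+pE`,
`an = pA+pB`) and classes, with fold ratios computed with a pseudocount
of one percentage point to tame near-zero denominators:

- **early_vegetal / early_animal** — pole class at both ends and pole
  fold < 1.5× (the gradient existed early and changed little). Early
  groups are exempt from the global filters below, since they change
  little by definition.
- **late_*_homogeneous** — undefined early class with the pole pair in
  [30, 45) (uniform is 40), pole class late.
- **late_*_predefined** — pole pair in [45, 60) early (a half-formed
  gradient), pole class late, pole fold ≥ 1.2×.
- **polar** — both pole pairs ≥ 35 and center ≤ 15 at the late stage.
- **other** — everything else, including any gene failing the filters.

The filters: at least one section's percentage must change ≥ 1.5× (2× is
the stricter alternative for very DLT-rich datasets) between the earliest
and latest stage, and the maximally changing section must move in the
same direction in every late-stage replicate (a single replicate passes
with a warning — reproducibility cannot be assessed). The [30,45)/[45,60)
homogeneous/predefined boundary and the 1.5×/1.2× early/late fold
discriminators are package defaults, configurable through
`TemporalThresholds`.

Rule-based assignment is the decision path. DIANA divisive clustering
(repeatedly split the cluster with the largest diameter by seeding a
splinter group from its most dissimilar member) of the concatenated
stage × section profile vectors, with k chosen by maximum mean silhouette,
is a verification path only: on simulated four-group data its clusters
agree with the rule assignment at adjusted Rand 1.0.

## Abundance dynamics

A gene is degraded (de novo synthesized) when the total test is
significant, the count threshold is met, and the latest/earliest total
ratio is ≤ 1/1.5 (≥ 1.5); otherwise stable. A zero earliest total gets a
one-count pseudocount. Spatial subgroups then describe the accompanying
profile change: animal-half drop ≥ 10 percentage points into a vegetal
class (animal degradation leaving a vegetal gradient), vegetal-half rise
≥ 10 points into a vegetal class (vegetal de novo), de novo into an
animal class, central drop ≥ 10 points with all other sections within
±5 (center degradation), or all sections within ±5 (uniform degradation /
synthesis). The 10- and 5-point margins are package defaults for rules
the source analyses describe qualitatively. Fold changes compare the
earliest and latest stages only, not adjacent pairs; no kinetic
synthesis/decay modeling is attempted.

## Conservation

Ortholog pairs are formed by case-insensitive exact gene-symbol matches
first (a multiply-mapping symbol takes the lexicographically first gene
with a warning), then through a supplied orthologous-unit table for genes
without a shared symbol; each gene joins at most one pair. Ortholog
*inference* (protein similarity) is out of scope — the map is an input.
A pair is conserved for a pooled set when both members carry a group in
that set: {early_vegetal}, {late_vegetal_homogeneous,
late_vegetal_predefined}, or all animal groups pooled as {animal};
requiring exact subgroup identity would be stricter than the pooled
early/late/animal comparison intended. Conserved degraded / de novo sets
intersect the abundance labels the same way. Z-score matrices standardize
each gene-and-stage row of section percentages with the population (n)
standard deviation; zero-variance rows map to zeros with a warning.

## The synthetic-data generator

The generator is first-class, tested code, and defines the study
conditions for all benchmarks. Each gene block has a localization
archetype (terminal fractions: extreme_animal (.70,.15,.08,.04,.03),
animal (.35,.30,.15,.12,.08), central (.10,.20,.40,.20,.10), vegetal and
extreme_vegetal their mirrors, polar (.35,.10,.05,.10,.40), uniform
(.2 ×5)), a temporal group and an abundance dynamics label. Late groups
interpolate fractions linearly (in stage index mapped to [0,1]) from
uniform to terminal, predefined groups from the midpoint of uniform and
terminal, early groups hold the terminal profile; degraded/de novo totals
multiply by 0.5/2 per stage step. Counts are NB draws with mean
`total(stage) · fraction(section) · library factor(sample)`; one
pseudo-random stream per dataset makes equal seeds bit-identical.

Defaults describe two ordered stages with three replicate oocytes,
per-gene totals of 8 000–30 000 expected transcripts per oocyte, library
factors in [0.75, 1.3], and dispersion α = 0.002. The low default
dispersion reflects deep libraries from size-matched staged oocytes and,
deliberately, puts the planted trajectories clear of the classification
boundaries so that recovery benchmarks measure the pipeline rather than
the noise floor; the calibration and power benchmarks override it to
α = 0.1 (a typical bulk biological-replicate dispersion) with totals of
1 000. What the generator does **not** emulate: gene–gene correlation,
within-section spatial structure, pigment/yolk/nucleus geometry,
sequence-level artifacts, and dispersion heterogeneity across genes —
so passing recovery tests demonstrates the pipeline's logic, not its
performance on any real library.

## Numerical and degenerate-input choices

- IRLS initializes at `μ = max(k, 0.5)` and solves the weighted least
  squares by LAPACK lstsq for rank safety; means are clipped to
  `exp(±30)`.
- Design-matrix rank is established by pivoted QR; aliased columns drop
  with a warning rather than erroring, so small unbalanced designs remain
  testable.
- All-zero genes are skipped before testing; all-zero samples make size
  factors undefined and raise a labeled error.
- DIANA on all-identical rows returns one cluster with a warning
  (silhouette undefined); silhouette ties prefer the smallest k.
- All output tables are UTF-8 TSV, Unix newlines, "NA" for missing, so
  reruns diff byte-for-byte; the run manifest records seed, thresholds,
  versions and warning counts.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: 200 random matrices
(≤10×6) for the normalization oracle; 2 000 genes for null calibration
and for planted-gradient power; 60 genes per archetype (plus 300 uniform)
for class recovery and 10 000 random profiles for the mirror invariant;
60 genes per temporal group on a 600-gene background for temporal
recovery; 50 genes per dynamics subgroup on a 400-gene background; 100
planted conserved pairs across two species; and an 11-table full-pipeline
determinism check.
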