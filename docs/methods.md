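# Methods

## The statistical model

The unit of inference is one cell of a grid: a case phenotype, a gene set and
a variant class. For each cell the per-sample burden score is the number of
set genes in which the sample carries at least one qualifying variant (QV) of
the class — gene-level binary indicators summed with equal weights in one
direction. Case-control status is modelled by logistic regression on the
burden score plus covariates:

    logit P(y_i = 1) = alpha + beta * s_i + gamma' x_i

with covariates sex (female = 1), the top ten principal components, the
exome-wide URV count and the exome-wide singleton (MAC = 1) count of the
sample. Both count covariates are computed from the variants passing the URV
filters of the *current* analysis, not supplied externally. The cell's p
value is the 1-df chi-square upper tail of the likelihood-ratio statistic
2(l_full − l_null), clipped at zero, where the null model drops only the
burden column. The reported effect is beta with a Wald 95% CI
(beta ± 1.959964·se). The LRT p and the Wald CI are a standard pairing;
profile-likelihood CIs are out of scope, and the CI construction is a
reporting caveat, not part of the test.

Under case-control (retrospective) sampling, the logistic slope on the score
is consistent while the intercept absorbs the sampling fractions; when gene
indicators are independent Bernoullis with a common per-gene odds ratio, the
regression of status on the summed score is *exactly* logistic-linear with
slope ln(OR), which is what makes the simulation recovery check sharp.

### Estimation

Maximum likelihood via Newton iterations (statsmodels `Logit`,
tol 1e-8 on the score/log-likelihood, 100 iterations cap); covariance is the
inverse observed information. Before fitting, constant non-intercept columns
are dropped with a logged warning (e.g. the sex column in a single-sex
contrast) and a rank check names collinear columns via pivoted QR. A fit is
flagged `converged = False` when the iteration cap is hit or any coefficient
exceeds 15 in absolute value (quasi-separation guard); there is no penalized
fallback — the cell is reported with its diagnostic flags. A burden score
that is constant across samples carries no information: the cell is flagged
`degenerate` and reported with log-odds 0, LRT 0, p 1, so degenerate cells
remain honest members of the grid.

### Multiplicity

All non-synonymous cells of a run — degenerate ones included — enter one
joint Benjamini–Hochberg step-up adjustment (statsmodels `multipletests`),
so the adjusted test count is a function of the grid dimensions alone: 92
sets × 3 phenotypes × 12 classes = 3,312. The synonymous class is computed
identically but excluded from adjustment; it is the negative-control track,
and its significance stars derive from the unadjusted p. Stars use strict
inequalities at 0.05 / 0.005 / 0.0005 / 0.00005; boundary values get the
weaker annotation.

## Qualifying variants and classes

URV thresholds (configurable in `UrvFilterConfig`): internal MAC ≤ 3 — MAC
sums allele copies, not carriers, and is recomputed within each analysis
cohort (one phenotype's cases plus all controls), so URV membership can
differ between analyses — absence from DiscovEHR, and gnomAD AF ≤ 2e-5
(inclusive). A missing reference frequency means absence and is treated
as 0.

Class predicates operate on one variant annotation row (one gene per row;
multi-gene annotations must be exploded upstream). Missing scores always
fail the predicate that needs them and are never imputed — constraint is not
invented for unscored variants. Damaging/benign missense default to the
concordance reading (PolyPhen-2 *and* SIFT agree); discordant or missing
predictions fall into neither class. An either-predictor rule is available
via `default_class_rules(damaging_requires_both=False)`. In-frame indels
enter only the "All functional" union, never missense-score classes, since
MPC/MTR/CCR are missense metrics. Chromosome names are normalised by
stripping a `chr` prefix; coordinates are 1-based VCF-style.

The class definitions imply strict nestings that the test suite asserts on
every simulated cohort: MPC 2 ⊆ MPC 1; MTR De Novo ⊆ MTR ClinVar;
CCR 80 ⊆ MPC 1 ∩ MTR ClinVar; paralog highly conserved ⊆ paralog conserved;
and paralog conserved/non-conserved partition the missense variants with an
observed para-Z.

## The synthetic-cohort generator

What it emulates: the singleton-dominated ultra-rare allele spectrum, score
distributions with clean positives and negatives for every class, the strong
sex imbalance of mixed-ancestry control reuse (defaults 53.6% female cases
vs 19.4% female controls), control sub-cohorts in configurable proportions
(default 1,100 : 2,789, mirroring a two-capture-kit control mix), Gaussian
principal-component noise, a configurable fraction of chromosome-X genes,
and per-(set, class) enrichments spiked on the carrier-probability logit of
case samples.

Carrier model: per sample, gene and disjoint *profile* an independent
Bernoulli draw. `baseline_qv_rate` is keyed by the 13 class names and means
the **realised** expected QV count per sample per class per 1,000 genes.
Because classes nest, realised rates are converted internally to disjoint
profile rates by subtraction (e.g. the MPC 1 profile rate is
rate[MPC 1] − rate[MPC 2] − rate[CCR 80]); configurations violating the
nesting are rejected. Defaults (per 1,000 genes): synonymous 3.0, benign
2.0, damaging 1.5, PTV 0.6, all-functional 2.4, MPC 1 1.5, MPC 2 0.5,
MTR ClinVar 1.5, MTR De Novo 0.5, CCR 80 0.4, paralog non-conserved 1.5,
conserved 1.2, highly conserved 0.4 — magnitudes chosen so that a
100-gene set yields on the order of 10²  carriers per class at n = 2,000 per
arm, enough for the asymptotic LRT to be trustworthy in every cell.

Spiking a class shifts the logit of every profile that realises into it, so
the spiked class's per-gene carrier odds ratio equals the configured value
exactly; a consequence is that classes nested *inside* a spiked class are
enriched too (spiking MPC 1 also enriches MPC 2 carriers). The truth table
records the configured entries and zeros elsewhere; recovery checks
therefore use leaf classes such as CCR 80, whose realisation has a single
profile. Sampling is stratified (case/control × spiked/unspiked genes) and
draws the number of carrier events binomially, then places them uniformly —
exactly equivalent to the independent Bernoulli model.

Carrier events become variant sites: most are private singletons; a
configurable fraction (default 10%) join shared sites of 2–3 alleles (still
ultra-rare); ~2% of private sites are homozygous; ~10% of events gain a
second site in the same gene so multi-QV-per-gene collapsing is exercised. A
small fraction of sites (default 2%) is planted with reference-population
alleles (gnomAD AF 1e-3 or DiscovEHR 1e-4) to exercise the frequency
filters, and ~10% get a gnomAD AF of 1e-5, below the threshold. Class-less
"filler" variants (default 2 per sample per 1,000 genes, including a few
MAC > 3 sites that the MAC filter removes) feed the exome-wide covariates
realistically. An optional sex-coupled carrier-rate shift
(`sex_effect_logit`, default off) makes tests of the sex adjustment
meaningful.

What it does **not** emulate: linkage disequilibrium, haplotypes, realistic
site-frequency spectra beyond the ultra-rare regime, read-level error,
annotation error, population substructure with real PC geometry, or
batch-correlated coverage differences. Passing tests therefore demonstrate
the statistical machinery's correctness and calibration under the stated
generative assumptions, not robustness to every artefact of real exome data.

Determinism: every stage draws from `SeedSequence(seed, spawn_key)` children
in a fixed order, so an identical configuration and seed reproduces
byte-identical output files.

## Secondary analyses

- **Chromosome-X exclusion**: genes are mapped to chromosomes from the
  variant table (conflicting mappings are fatal) and removed from variants,
  carriers and gene sets before rerunning the grid.
- **Group contrast**: any two disjoint sample groups are analysed with the
  identical machinery (internal MACs within their union). Swapping the
  labels negates the log-odds to numerical precision — asserted in tests.
- **Permutation subsampling**: repeated without-replacement draws of a
  configurable number of cases and controls rerun one cell; the summary
  reports the mean log-odds, the mean odds ratio *and* the
  exponentiated-mean (the "average odds" is ambiguous between the two, so
  both are emitted), 2.5th/97.5th centiles via linear interpolation between
  order statistics, and the mean raw p.
- **Leave-genes-out**: one cell before and after removing listed genes, for
  driver-gene sensitivity.

## Numerical and design choices

- Tolerances: Newton convergence 1e-8; the antisymmetry contract holds to
  1e-6; the 2×2 closed-form oracle agrees to 1e-6.
- TSV output: tab-separated UTF-8, header row, empty string for missing
  (never `.`). Data tables round-trip exactly (full float precision);
  result tables print 6 significant digits, with small p values in
  scientific notation.
- Gene symbols are matched case-insensitively; gene-set members absent from
  the data are counted and logged, never fatal.
- The exome-wide variant-count covariate counts URVs of the current
  analysis (configurable in intent; the URV reading keeps the covariate on
  the same footing as the outcome's variants).
- Problem sizes in the test suite — 2,000 + 2,000 samples, 1,000 genes, 20
  sets for calibration (1,200 null tests over five seeds; 2,400 in the
  acceptance script) and 100 replicates for recovery — were chosen to give
  binomial/Monte-Carlo intervals tight enough to detect miscalibration of a
  percentage point or an effect-size bias of ~0.02 on the log-odds scale.

## Known limitations

- No Firth or penalized regression: separated cells are flagged, not
  rescued. Real sparse cells (few carriers) may deserve exact or penalized
  methods.
- Wald CIs undercover for very sparse cells even when the LRT p is usable.
- BH-FDR assumes the usual positive-dependence conditions; grid cells are
  correlated through shared samples, overlapping classes and overlapping
  sets.
- The generator's per-gene effects within a spiked set are homogeneous;
  real gene sets mix driver and passenger genes (the leave-out analysis
  exists precisely because of this).
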