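# Methods

## The problem

Crohn's disease (CD) and ulcerative colitis (UC) are the two major
subtypes of inflammatory bowel disease (IBD). In a sizeable minority of
patients the clinical work-up cannot settle which subtype is present,
and misclassification carries real costs (subtype-specific therapies,
different complication profiles). `ibdprofiler` implements, end to end,
a molecular profiling pipeline that separates CD from UC *within* IBD
patients — a case-case design — using three factor families:

* a **polygenic risk score** (PRS) built by clumping + thresholding
  (P+T) from a case-case GWAS of CD (coded 1) versus UC (coded 0);
* **serum biomarkers**: ASCA-IgA, ASCA-IgG, ASCA-IgM, ANCA, anti-CBir1,
  anti-OmpC, anti-I2 titers;
* **tobacco smoking status** (Never / Quit / Current), the one
  environmental factor with firmly opposite subtype effects (current
  smoking: OR ≈ 1.76 for CD, ≈ 0.58 for UC).

Because the real ImmunoChip cohorts behind this design are
access-restricted, the package ships a first-class synthetic-cohort
generator that reproduces the statistical structure the analysis relies
on, records its own ground truth, and makes every downstream stage
testable.

## Variance explained

The headline metric is the Nagelkerke pseudo-R² of an alternative
logistic model over a population-structure baseline. With `l0` the
maximized log-likelihood of `subtype ~ intercept + PC1..PC10` and `l1`
that of the same model plus the factor blocks of interest,

    R²_CS  = 1 − exp(2(l0 − l1)/n)
    R²_Nag = R²_CS / (1 − exp(2 l0 / n))

*Marginal* variance explained adds one factor family to the PC
baseline; *conditional* variance explained adds it on top of all other
families. Both are computed by full maximum-likelihood refits (a tight
IRLS Newton solver shared across the package; quasi-separated fits fall
back to a ridge penalty of 1e-6 and are flagged `capped`). Uncertainty
comes from nonparametric bootstrap (percentile intervals) or repeated
2-fold cross-validation, matching which design each result uses: a
fixed train/test split for genetics-only results, CV for factor
families whose coefficients are refit in the evaluation cohort. In
cross-validation the factor coefficients fitted on the training fold
collapse to a single linear score that is evaluated on the test fold as
a one-column addition to the baseline; this is the standard PRS
evaluation convention and prevents optimism leakage.

## The genetic model

1. **QC** (pre-PCA): drop variants in the MHC (chr6:25–34 Mb, GRCh37),
   with MAF < 0.05, call rate < 0.99, or exact Hardy–Weinberg p < 1e-5
   (Levene–Haldane exact test over heterozygote counts; monomorphic
   variants return p = 1 by convention; tested in all samples).
2. **LD pruning**: sliding windows of 100 variants, step 5, pairwise
   dosage r² threshold 0.1, repeated three times. Within a window the
   member of the worst pair with the lower MAF is dropped (tie → later
   map position) — the drop rule is this package's own convention and
   the test oracle implements the same rule.
3. **PCA**: mean-centered, variance-standardized dosages (missing →
   variant mean), truncated SVD; scores are left singular vectors
   scaled by singular values; the largest-magnitude loading of each
   component is oriented positive.
4. **GWAS**: per-variant logistic regression `subtype ~ dosage + PC1..10`
   at MAF > 0.5% with Wald statistics; non-converged (quasi-separated)
   variants are emitted flagged with missing statistics. The CD-location
   scan (colonic = 1 vs small-bowel = 0) uses the same engine; the
   genome-wide SNP×smoking interaction scan uses a 2-df likelihood-ratio
   test of `g×Quit + g×Current` with Never as reference.
5. **Clumping**: greedy P+T. Survivors of the p cut-off are sorted by
   ascending p (ties: position, then id); the best unassigned variant
   indexes a clump and absorbs all unassigned variants on the same
   chromosome within 250 kb with in-sample dosage r² > 0.2. The MHC's
   long-range LD gets a 3-pass scheme: one pass at a 5 Mb radius and
   r² > 0.1, then two more passes *on the surviving index variants* at
   r² > 0.05 (composition is the only meaningful reading for a
   deterministic greedy rule; re-running on all variants is available
   behind a flag and is a no-op). Members accumulate across passes as a
   union attributed to each final index.
6. **Score**: `PRS_i = Σ_j weight_j · dosage_ij` over index variants
   with weight = the GWAS log-OR; swapped allele labels flip the
   dosage; missing dosages are mean-imputed at twice the scoring
   cohort's effect-allele frequency. The NOD2 region
   (chr16:50,693,588–50,733,081 ± 300 kb) can be overridden with an
   externally supplied fine-mapped variant/weight list replacing its
   P+T entries; gene-locus scores restrict the stats to a region ±
   300 kb flanks before clumping.

### Choice of p-value cut-off

The clump/threshold machinery accepts any cut-off; 0.1, 0.01 and 0.001
are the conventional grid. The pipeline default is **0.001**. At
desk-scale training sizes (thousands of samples) a liberal cut-off
admits hundreds of null clump indices whose weights are conditioned on
|z| exceeding the threshold (winner's curse); their summed variance
swamps the true score signal. At consortium scale the same null weights
are an order of magnitude smaller and a 0.1 cut-off is harmless — which
is why liberal thresholds are common practice at large n. The stringent
default keeps the expected null entry count near zero while retaining
all well-powered effects.

## Two-sample Mendelian randomization

Exposure: the case-case subtype GWAS. Outcomes: per-variant OLS of
rank-based inverse-normal transformed biomarker titers (Blom offsets,
`Φ⁻¹((rank − 3/8)/(n + 1/4))`, ties midranked, missing preserved).
Instruments: genome-wide-significant variants (p < 5e-8), clumped at
r² < 0.01 over 500 kb, with NOD2 (± 300 kb) and the MHC removed as a
pleiotropy precaution. Harmonization flips the outcome beta for
swapped allele labels and drops palindromic (A/T, C/G) variants, since
outcome allele frequencies are not assumed available. Estimators: the
Wald ratio (`β_Y/β_X`, first-order SE) for one instrument; fixed-effect
IVW (zero-intercept weighted regression, weights 1/se_Y², no residual
scaling) for two or more; MR-Egger (free intercept, exposure betas
oriented non-negative, multiplicative residual scaling bounded below by
1) for three or more, with the intercept test for directional
pleiotropy and Cochran's Q (df = n−1 for IVW, n−2 for Egger). The
biomarker panel applies a Bonferroni per-test threshold α/m (0.05/6 =
0.0083 for the seven-marker panel restricted to six outcomes with
usable instruments). The reverse direction (biomarker → subtype)
returns an empty instrument list when nothing reaches significance;
the caller decides how to report it.

## The synthetic cohort generator

The generator emulates the study's data-generating process, not
population-genetic history:

* **Genotypes.** Per haplotype and per LD block, a latent AR(1)
  Gaussian with lag-one correlation ρ is thresholded at each variant's
  MAF quantile; two haplotypes are summed into a dosage. Defaults:
  blocks of 5 variants at ρ = 0.92, MAF ~ Uniform(0.05, 0.5). Short
  dense blocks keep every intra-block pair above the 0.2 clump
  threshold, so a clump coincides with an LD block; long shallow blocks
  would instead leave "shoulder" variants straddling the threshold as
  duplicate score entries — a real P+T artifact worth studying, but not
  a useful default for parameter-recovery testing.
* **Causal architecture** (drawn once per `population_seed`, so cohorts
  differing only in `seed` are samples of one population): two large
  CD-risk effects in a NOD2-like block (log-OR 1.0, 0.7), three
  moderate mixed-sign effects in an MHC-like region, twelve
  "known-locus" effects (|log-OR| 0.4–0.55) on common (MAF ≥ 0.15–0.2)
  variants, and a sub-threshold polygenic tail (20 effects,
  N(0, 0.06)). Placing the large and medium tiers on common variants
  reflects how well-replicated association signals are ascertained, and
  makes them detectable at the default training size. All effects are
  rescaled so the latent genetic variance fraction
  var(G)/(var(G) + var(smoking) + π²/3) hits the configured target
  (default 0.2).
* **Subtype** is drawn from `logit P(CD) = α + s_i·G_i + γ(smoking)`
  with γ_Current = log(1.76/0.58), γ_Quit half that (the data only pin
  the Current contrast), smoking prevalences 0.56/0.22/0.22, the
  intercept solved for a 56% CD fraction, and s_i = 0.85 for the
  Jewish ancestry stratum (11.6% of samples) to emulate reduced
  cross-ancestry score portability by effect damping rather than
  separate allele frequencies.
* **Biomarkers** are Gaussian with subtype mean shifts sized so the
  joint serology separation is ≈ 1.3 SD (the ~0.8-AUC regime reported
  for serology panels), a loading on the standardized genetic liability
  for the ASCA/CBir1 markers (creating the genetics–serology overlap
  that drives conditional < marginal), and noise correlations *solved
  analytically* so the total correlations hit the configured targets
  (ASCA-IgG~ASCA-IgM R² = 0.52, I2~OmpC R² = 0.39) given the realized
  shared components; an infeasible target or a non-positive-definite
  noise matrix is an error.
* **CD location** (colonic vs small-bowel, CD samples only) follows a
  logistic model with a 24% baseline colonic fraction, smoking shifts
  (Quit +0.32, Current −0.42 on the logit — ex-smokers more colonic,
  current smokers less) and per-variant effects (default: the main
  NOD2-like allele pushes toward small-bowel disease).
* **Ground truth** recorded with each phenotype table: the realized
  latent variance fractions, the effect scale, and the Nagelkerke R²
  the *true* genetic score attains on that cohort (`y ~ G` vs
  intercept, fitted on the generated data) — the reference value for
  parameter-recovery tests. The generator also exposes its causal NOD2
  variants with their generating log-ORs as a stand-in fine-mapping
  resource for the score override.

What the generator does **not** emulate: recombination maps and
demography, genotyping artifacts, assay floor/ceiling effects in
titers, ancestry-specific allele frequencies, and real ImmunoChip
manifests. Tests passing on these cohorts show the pipeline's
statistics are implemented correctly and behave as designed under the
assumed generating process — not that the clinical performance numbers
transfer to real cohorts.

## Experiment designs and problem sizes

* **Parameter recovery**: train and test cohorts of 4,000 samples ×
  5,000 variants from one population at latent genetic R² = 0.2; the
  pipeline (GWAS → clump → NOD2 override → score) is fit on train and
  its marginal PRS R² on test is compared with the generator truth,
  averaged over three train/test seed pairs. P+T at this scale
  concentrates slightly below the true-score ceiling (selection misses
  the sub-threshold tail; clump indices are imperfect LD proxies), a
  systematic ~0.03–0.05 shortfall that shrinks with training size.
* **Misdiagnosis noise**: training labels are flipped at fraction f
  with a CD→UC:UC→CD ratio r (`n_flip = round(f·n)`, CD→UC flips =
  `round(n_flip·r/(1+r))`), the *pure P+T* pipeline is retrained from
  scratch, and R² on clean test labels is reported relative to the
  clean-trained value. The fine-map override is excluded here: an
  externally supplied component is immune to label noise by
  construction and would mask the information loss being measured.
  Flips shrink the labeled-group contrast (1 − 2f for symmetric flips;
  ≈ 0.15 at f = 0.5, r = 9), so the experiment uses a
  consortium-scale training cohort — 36,000 samples, the order of the
  real training consortium — over a 600-variant panel, with a
  2,000-sample test cohort. "20% flipped in an equal manner" is read as
  f = 0.2, r = 1. At large n, mild noise can *raise* retained R² by a
  few percent by pruning borderline tail entries (an implicit stricter
  threshold); the monotonicity check carries a 0.05 slack for this real
  effect.
* **Training size / case ratio**: subsampling a 4,000-sample training
  cohort (1,200 variants) to sizes {500, 1,000, 2,000, 4,000} over 10
  seeds; CD:UC compositions {50:50, 56:44, 64:36} at a fixed total,
  compared against two repeated-CV interval widths.
* **GWAS calibration**: 500 null variants at n = 2,000 (KS uniformity);
  a planted two-stratum confounder (frequency and prevalence both
  differ) corrected by 2 PCs; the null interaction scan over 5,000
  variants repeated 10 times on redrawn phenotypes.

These sizes are the package's chosen desk-scale study conditions; the
spirit of each experiment, not its original cohort, is what is
reproduced.

## Numerical choices

* Logistic fits: Newton/IRLS with step-halving, 25-iteration cap,
  ridge 1e-6 fallback flagged `capped`; likelihoods from the stable
  log1p(exp) form.
* Nagelkerke R² is clipped to [0, 1] and `l1` floored at `l0` (nested
  fits; tiny negative slack only ever arises from convergence noise).
* LD is composite (dosage-correlation) r², not haplotype EM — the
  standard choice for unphased data; pairwise-complete samples.
* Clump ties at equal p: ascending position, then id.
* AUC uses midranks; the Youden threshold resolves ties toward the
  lower threshold.
* Exact HWE p-values sum all outcomes with probability ≤ the observed
  one (with a 1+1e-12 relative guard against floating ties).
* All randomness flows through `numpy.random.Generator` seeded from
  explicit `SeedSequence([seed, stream])` pairs; outputs are
  bit-reproducible given seeds.

## Known limitations

* The copula LD model cannot produce the near-perfect proxy pairs
  (r² > 0.95) of dense real chips, so clump indices tag causal variants
  slightly lossily; parameter-recovery shortfalls of a few hundredths
  are expected and documented above.
* Variance-explained point values on synthetic cohorts are not
  comparable to any real-cohort numbers; only structural behavior
  (orderings, monotonicities, calibrations) is.
* The biomarker model is Gaussian on transformed scale; seropositivity
  dichotomization is available only by thresholding externally.
* HWE is tested in all samples jointly; no kinship/relatedness
  filtering; no X-chromosome dosage handling; no mixed-model
  association; no genotype imputation.
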