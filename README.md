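# ibdprofiler

Differentiating Crohn's disease (CD) from ulcerative colitis (UC) —
the two subtypes of inflammatory bowel disease (IBD) — from molecular
and environmental profiles: a clumping+thresholding polygenic risk
score with bespoke MHC and NOD2 handling, serum antibody biomarkers
(ASCA IgA/IgG/IgM, ANCA, anti-CBir1, anti-OmpC, anti-I2), and tobacco
smoking status, evaluated through a Nagelkerke pseudo-R² variance
framework with bootstrap/cross-validation uncertainty, misdiagnosis
label-noise simulations, and two-sample Mendelian randomization.

It is written for statistical geneticists and methodologists who want
a fully testable, self-contained implementation of this case-case
profiling design. The restricted clinical cohorts the design was
developed on are replaced by a first-class synthetic-cohort generator
with known ground truth, so every stage runs end to end out of the box.

## The model

Within IBD patients, the subtype is treated as a binary trait
(CD = 1, UC = 0). The genetic score is the standard P+T construction

    PRS_i = Σ_j log(OR_j) · G_ij

over clump index variants passing a p-value cut-off, where the log-OR
comes from a case-case logistic GWAS (`subtype ~ dosage + PC1..PC10`),
clumps are greedy (250 kb radius, in-sample dosage r² > 0.2), the MHC
uses a 3-pass scheme (5 Mb radius; r² > 0.1, then twice r² > 0.05 over
surviving indices), and the NOD2 locus P+T entries can be replaced by
an externally supplied fine-mapped variant/weight list.

Performance is measured as Nagelkerke pseudo-R² against a baseline of
the top ten principal components:

    R²_CS  = 1 − exp(2(ℓ₀ − ℓ₁)/n),   R²_Nag = R²_CS / (1 − exp(2ℓ₀/n))

computed marginally (one factor family over the baseline) or
conditionally (one family on top of the others). Causal direction
between subtype and biomarkers is probed by two-sample MR (Wald ratio /
fixed-effect IVW / MR-Egger with intercept and Cochran's Q) on
genome-wide-significant, LD-clumped instruments excluding NOD2 and the
MHC, against GWAS of rank-based inverse-normal transformed titers.

See `docs/methods.md` for the full methods note, including what the
synthetic cohorts do and do not emulate.

## Worked example

```python
from ibdprofiler.synthetic_cohort import make_fixture, nod2_finemap
from ibdprofiler.model_eval import (
    PrsPipeline, FactorSet, marginal_variance, conditional_variance,
)

# two independent cohorts from the same synthetic population
train_g, train_p, cfg = make_fixture("default", seed=1)   # 4,000 x 5,000
test_g, test_p, _ = make_fixture("default", seed=2)

# genetics: GWAS -> clump (+3-pass MHC) -> threshold -> NOD2 override
override = nod2_finemap(cfg, train_p.ground_truth["effect_scale"])
pipe = PrsPipeline(nod2_override=override).fit(train_g, train_p)

fs = FactorSet(test_p, prs=pipe.score(test_g))
print("genetics marginal R2 ", round(marginal_variance(fs, "prs").r2, 3))
print("generator truth      ", round(test_p.ground_truth["expected_prs_nagelkerke"], 3))
print("serology marginal R2 ", round(marginal_variance(fs, "biomarkers").r2, 3))
print("smoking marginal R2  ", round(marginal_variance(fs, "smoking").r2, 3))
print("full model R2        ",
      round(marginal_variance(fs, ["prs", "biomarkers", "smoking"]).r2, 3))
print("genetics conditional ",
      round(conditional_variance(fs, "prs", ["biomarkers", "smoking"]).r2, 3))
```

prints

```
genetics marginal R2  0.158
generator truth       0.186
serology marginal R2  0.468
smoking marginal R2   0.048
full model R2         0.501
genetics conditional  0.015
```

Read: on a cohort where the true genetic score could explain 0.186 of
the subtype variance, the trained P+T score recovers 0.158 (the
shortfall is the documented desk-scale selection/LD-proxy loss);
serology is the strongest single family; the full model beats every
single family; and the genetic contribution shrinks sharply when
conditioned on serology, because several biomarkers are generated
partly from the genetic liability.

The same stages are exposed as a thin CLI for file-based workflows —
`profiler simulate | validate | convert | qc | pca | gwas | clump |
score | evaluate | mr | noise-sim` — over tab-separated text formats
(a variant-major dosage TSV documented in `ibdprofiler.cohort_io`,
PLINK `.ped/.map` text, summary-stats TSV, PLINK-`--score`-style weight
files).

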