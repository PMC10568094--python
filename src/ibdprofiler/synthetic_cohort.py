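"""Synthetic IBD case-case cohorts with known ground truth.

The real training and validation cohorts for the CD-vs-UC profiling
problem (ImmunoChip-genotyped IBD case collections with serum biomarkers
and smoking history) are access-restricted, so every downstream stage is
exercised on generated cohorts that reproduce the statistical structure
the analysis relies on:

* a chip of ~10^3–10^5 biallelic variants in dense LD blocks (haplotype-
  level AR(1) Gaussian copula, thresholded at the minor-allele frequency);
* a CD(1)/UC(0) subtype label drawn from a logistic liability that sums a
  sparse set of causal log-odds-ratio effects — concentrated in NOD2-like
  and MHC-like regions plus a polygenic tail — and a smoking effect;
* a 3-level smoking variable (Never / Quit / Current) with opposite
  CD and UC odds ratios (defaults 1.76 and 0.58 for current smokers, so
  the case-case log-OR is log(1.76/0.58); Quit gets half that);
* seven serum biomarker titers with subtype mean shifts, optional loading
  on the genetic liability (creating genetics/serology overlap), and
  calibrated inter-marker correlations (defaults: ASCA-IgG ~ ASCA-IgM
  R^2 = 0.52, I2 ~ OmpC R^2 = 0.39);
* a colonic vs small-bowel disease-location label for CD samples with
  planted per-variant and smoking effects;
* a Jewish ancestry stratum whose genetic effects are scaled down
  (default 0.85) to emulate reduced cross-ancestry score portability.

The generator records its realized ground truth (latent variance
fractions and the pseudo-R^2 the *true* genetic score achieves on the
cohort) in ``PhenotypeTable.ground_truth`` so parameter-recovery tests
can compare pipeline estimates against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from ._logistic import fit_logistic
from .cohort_io import GenotypeMatrix, PhenotypeTable, VariantRecord

__all__ = [
    "BiomarkerSpec",
    "LocationSpec",
    "SimulationConfig",
    "default_config",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "make_fixture",
    "nod2_finemap",
]

LOGISTIC_VAR = math.pi ** 2 / 3.0  # residual variance of the logistic liability


@dataclass(frozen=True)
class BiomarkerSpec:
    """One serum biomarker: subtype mean shifts (in units of noise SD),
    noise SD, and a loading on the standardized genetic liability."""

    name: str
    shift_cd: float
    shift_uc: float
    noise_sd: float = 1.0
    liability_loading: float = 0.0


@dataclass(frozen=True)
class LocationSpec:
    """Colonic vs small-bowel CD location model (CD samples only)."""

    baseline_colonic_fraction: float = 0.24
    #: per-variant-index log-OR toward colonic location (centered dosage)
    variant_log_or: dict[int, float] = field(default_factory=dict)
    #: additive logit shifts by smoking level (Never is reference)
    smoking_log_or: dict[str, float] = field(
        default_factory=lambda: {"Quit": 0.32, "Current": -0.42}
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 4000
    n_variants: int = 5000
    ld_block_size: int = 5
    within_block_corr: float = 0.92
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: sparse causal architecture: (variant index, log-OR toward CD)
    causal_effects: tuple[tuple[int, float], ...] = ()
    #: label -> (start index, end index) half-open ranges, e.g. "MHC", "NOD2"
    region_map: dict[str, tuple[int, int]] = field(default_factory=dict)
    smoking_or_cd: float = 1.76
    smoking_or_uc: float = 0.58
    #: marginal P(Never), P(Quit), P(Current)
    smoking_prevalence: tuple[float, float, float] = (0.56, 0.22, 0.22)
    biomarker_spec: tuple[BiomarkerSpec, ...] = ()
    #: squared-correlation targets for marker pairs, e.g. {("ASCA-IgG","ASCA-IgM"): 0.52}
    biomarker_r2_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    location_spec: LocationSpec = field(default_factory=LocationSpec)
    jewish_fraction: float = 0.116
    jewish_effect_scale: float = 0.85
    #: overall CD fraction the liability intercept is solved for
    cd_fraction: float = 0.56
    #: if set, causal effects are rescaled so the latent-scale genetic
    #: variance fraction var(G) / (var(G) + var(smoking) + pi^2/3) hits this
    target_latent_r2: float | None = 0.2
    missing_rate: float = 0.0
    #: drives cohort sampling (haplotypes, phenotype draws); two configs
    #: differing only in ``seed`` are independent cohorts from one population
    seed: int = 0
    #: drives population-level structure (variant MAFs); shared between
    #: train and test cohorts of one study
    population_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.within_block_corr < 1):
            raise ValueError("within_block_corr must be in [0, 1)")
        if not (0 <= self.jewish_fraction <= 1):
            raise ValueError("jewish_fraction must be a probability")
        if not (0 < self.jewish_effect_scale <= 1):
            raise ValueError("jewish_effect_scale must be in (0, 1]")
        if abs(sum(self.smoking_prevalence) - 1.0) > 1e-9:
            raise ValueError("smoking_prevalence must sum to 1")
        for idx, _ in self.causal_effects:
            if not (0 <= idx < self.n_variants):
                raise ValueError(f"causal index {idx} out of range")
        for label, (a, b) in self.region_map.items():
            if not (0 <= a <= b <= self.n_variants):
                raise ValueError(f"region {label!r} indices out of range")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# default architecture
# ---------------------------------------------------------------------------

_DEFAULT_BIOMARKERS = (
    # CD-associated: ASCA (IgA/IgG/IgM), CBir1, OmpC, I2; UC-associated:
    # ANCA.  Shift sizes chosen so the joint serology separation is ~1.3
    # SD (the regime of a 0.8-ish serology AUC); CBir1 carries the
    # largest single contribution, and the ASCA/CBir1 markers load on the
    # genetic liability to create genetics/serology overlap.
    BiomarkerSpec("ASCA-IgA", 0.50, 0.0, 1.0, 0.35),
    BiomarkerSpec("ASCA-IgG", 0.55, 0.0, 1.0, 0.35),
    BiomarkerSpec("ASCA-IgM", 0.35, 0.0, 1.0, 0.20),
    BiomarkerSpec("ANCA", 0.0, 0.60, 1.0, 0.0),
    BiomarkerSpec("CBir1", 0.70, 0.0, 1.0, 0.30),
    BiomarkerSpec("OmpC", 0.30, 0.0, 1.0, 0.0),
    BiomarkerSpec("I2", 0.25, 0.0, 1.0, 0.0),
)

_DEFAULT_R2_TARGETS = {("ASCA-IgG", "ASCA-IgM"): 0.52, ("I2", "OmpC"): 0.39}

#: GRCh37 NOD2 gene body; the simulated NOD2-like block is laid down here
NOD2_REGION = ("16", 50_693_588, 50_733_081)
#: conventional extended MHC boundaries on GRCh37
MHC_REGION = ("6", 25_000_000, 34_000_000)


def default_config(
    n_samples: int = 4000,
    n_variants: int = 5000,
    seed: int = 0,
    population_seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Build the standard cohort configuration at a given size.

    A NOD2-like block (large CD-specific effects) and an MHC-like region
    (several moderate mixed-sign effects, long-range LD via a 5x block
    size) sit at the start of the map; a polygenic tail of small effects
    is spread over the remaining variants.  ``overrides`` are forwarded to
    :class:`SimulationConfig`.

    The causal architecture is drawn from ``population_seed`` so that
    configs differing only in ``seed`` describe independent cohorts from
    the same population (same causal variants, same MAFs).
    """
    block = int(overrides.pop("ld_block_size", 5))
    n_nod2 = block * max(1, 20 // block)
    n_mhc = min(300 // block * block, max(block, (n_variants // 10) // block * block))
    if n_nod2 + n_mhc > n_variants:
        n_nod2 = min(n_nod2, n_variants // 2)
        n_mhc = min(n_mhc, n_variants - n_nod2)
    region_map = {"NOD2": (0, n_nod2), "MHC": (n_nod2, n_nod2 + n_mhc)}

    rng = np.random.default_rng(np.random.SeedSequence([population_seed, 999]))
    # causal variants sit on common alleles (MAF >= 0.15 where available):
    # the large/medium tiers emulate well-powered, replicated association
    # signals, which are common-variant effects almost by construction
    maf_lo, maf_hi = overrides.get("maf_range", (0.05, 0.5))
    pop_rng = np.random.default_rng(np.random.SeedSequence([population_seed, 10]))
    maf = pop_rng.uniform(maf_lo, maf_hi, size=n_variants)
    common_cut = min(0.15, maf_hi)

    def common_in(lo: int, hi: int) -> np.ndarray:
        rng_idx = np.arange(lo, hi)
        c = rng_idx[maf[rng_idx] >= common_cut]
        return c if c.size else rng_idx

    causal: list[tuple[int, float]] = []
    # NOD2-like: two large CD-risk alleles (frameshift-like architecture)
    nod2_common = common_in(0, n_nod2)
    causal.append((int(nod2_common[0]), 1.0))
    causal.append((int(nod2_common[nod2_common.size // 2]), 0.7))
    # MHC-like: three moderate effects of mixed sign on common variants
    mhc_lo, mhc_hi = region_map["MHC"]
    mhc_common = common_in(mhc_lo, mhc_hi)
    for frac, b in ((0.05, 0.45), (0.5, -0.35), (0.92, 0.30)):
        causal.append((int(mhc_common[int(frac * (mhc_common.size - 1))]), b))
    # a tier of "known locus" effects (log-OR 0.4-0.55, mixed sign, on
    # MAF >= 0.2 variants) plus a small sub-threshold polygenic tail over
    # the rest of the chip
    other_lo = n_nod2 + n_mhc
    n_known = min(12, max(0, (n_variants - other_lo) // 60))
    n_tail = min(20, max(0, (n_variants - other_lo) // 60))
    rest = np.arange(other_lo, n_variants)
    known_pool = rest[maf[rest] >= min(0.2, maf_hi)]
    if known_pool.size < n_known:
        known_pool = rest
    if n_known + n_tail and rest.size >= n_known + n_tail:
        known_idx = np.sort(rng.choice(known_pool, size=n_known, replace=False))
        tail_pool = np.setdiff1d(rest, known_idx)
        tail_idx = np.sort(rng.choice(tail_pool, size=n_tail, replace=False))
        known_beta = rng.uniform(0.4, 0.55, size=n_known) * rng.choice(
            [-1.0, 1.0], size=n_known
        )
        tail_beta = rng.normal(0.0, 0.06, size=n_tail)
        causal.extend(zip(known_idx.tolist(), known_beta.tolist()))
        causal.extend(zip(tail_idx.tolist(), tail_beta.tolist()))

    loc_spec = overrides.pop(
        "location_spec",
        LocationSpec(
            baseline_colonic_fraction=0.24,
            variant_log_or={2: -0.5},  # NOD2-like risk allele pushes toward small bowel
        ),
    )
    return SimulationConfig(
        n_samples=n_samples,
        n_variants=n_variants,
        ld_block_size=block,
        causal_effects=overrides.pop("causal_effects", tuple(causal)),
        region_map=overrides.pop("region_map", region_map),
        biomarker_spec=overrides.pop("biomarker_spec", _DEFAULT_BIOMARKERS),
        biomarker_r2_targets=overrides.pop("biomarker_r2_targets", dict(_DEFAULT_R2_TARGETS)),
        location_spec=loc_spec,
        seed=seed,
        population_seed=population_seed,
        **overrides,
    )


def nod2_finemap(
    config: SimulationConfig, effect_scale: float = 1.0
):
    """The generator's fine-mapping analog for the NOD2-like region.

    Returns ``(GeneRegion, weights)`` suitable as a score-model override:
    the truly causal variants inside the NOD2 region with their (scaled)
    generating log-ORs, playing the role of an external fine-mapping
    resource.  ``effect_scale`` should be the ground-truth scale recorded
    by :func:`simulate_phenotypes` for the training cohort.
    """
    from .prs_builder import GeneRegion
    import pandas as pd

    if "NOD2" not in config.region_map:
        raise ValueError("config has no NOD2 region")
    lo, hi = config.region_map["NOD2"]
    rows = [
        {"id": f"var{i:06d}", "effect_allele": "A", "other_allele": "G",
         "weight": b * effect_scale}
        for i, b in config.causal_effects
        if lo <= i < hi
    ]
    region = GeneRegion("NOD2", NOD2_REGION[0], NOD2_REGION[1], NOD2_REGION[2])
    return region, pd.DataFrame(rows)


def _variant_map(config: SimulationConfig) -> list[VariantRecord]:
    """Lay variants onto chromosomes: special regions at their canonical
    coordinates, the rest in contiguous chunks across the autosomes."""
    n = config.n_variants
    chrom = np.empty(n, dtype=object)
    pos = np.zeros(n, dtype=np.int64)
    assigned = np.zeros(n, dtype=bool)
    for label, (a, b) in config.region_map.items():
        if label == "NOD2":
            c, lo, hi = NOD2_REGION
        elif label == "MHC":
            c, lo, hi = MHC_REGION
        else:
            continue
        k = b - a
        if k:
            step = max(1, (hi - lo) // max(k, 1))
            chrom[a:b] = c
            pos[a:b] = lo + step * np.arange(k)
            assigned[a:b] = True
    rest = np.flatnonzero(~assigned)
    if rest.size:
        autosomes = [str(c) for c in range(1, 23) if str(c) not in ("6", "16")]
        chunks = np.array_split(rest, len(autosomes))
        for c, idx in zip(autosomes, chunks):
            chrom[idx] = c
            pos[idx] = 1_000_000 + 10_000 * np.arange(idx.size)
    records = []
    alleles = ("A", "G")  # non-palindromic pair for every simulated variant
    for j in range(n):
        records.append(
            VariantRecord(f"var{j:06d}", str(chrom[j]), int(pos[j]), *alleles)
        )
    return records


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw an additive dosage matrix with block-AR(1) LD.

    Per haplotype and per LD block, a latent AR(1) Gaussian with lag-one
    correlation ``within_block_corr`` is thresholded at the normal
    quantile of each variant's MAF; the two haplotype indicators are
    summed to give the dosage.  Block boundaries break the correlation.
    Deterministic given ``config.seed``.
    """
    rng = _rng(config, 1)
    n, m = config.n_samples, config.n_variants
    lo, hi = config.maf_range
    pop_rng = np.random.default_rng(
        np.random.SeedSequence([config.population_seed, 10])
    )
    maf = pop_rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(maf)
    rho = config.within_block_corr
    dosage = np.zeros((n, m), dtype=float)
    innov_sd = math.sqrt(max(1.0 - rho * rho, 0.0))
    for _hap in range(2):
        z = np.empty((n, m))
        for start in range(0, m, config.ld_block_size):
            end = min(start + config.ld_block_size, m)
            block = rng.standard_normal((n, end - start))
            for j in range(1, end - start):
                block[:, j] = rho * block[:, j - 1] + innov_sd * block[:, j]
            z[:, start:end] = block
        dosage += (z < thresh).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = np.nan
    sample_ids = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosage, sample_ids, _variant_map(config))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _solve_intercept(eta: np.ndarray, target: float) -> float:
    f = lambda a: np.mean(1.0 / (1.0 + np.exp(-(a + eta)))) - target
    return optimize.brentq(f, -30.0, 30.0)


def _biomarker_noise_corr(
    config: SimulationConfig,
    shared: np.ndarray,
    names: list[str],
) -> np.ndarray:
    """Solve the noise correlation matrix so that total marker correlations
    hit the configured R^2 targets given the realized shared components."""
    specs = config.biomarker_spec
    k = len(specs)
    noise_sd = np.array([s.noise_sd for s in specs])
    shared_cov = np.cov(shared, rowvar=False) if k > 1 else np.atleast_2d(np.var(shared))
    total_sd = np.sqrt(np.diag(shared_cov) + noise_sd ** 2)
    corr = np.eye(k)
    index = {n: i for i, n in enumerate(names)}
    for (m1, m2), r2 in config.biomarker_r2_targets.items():
        if m1 not in index or m2 not in index:
            continue
        i, j = index[m1], index[m2]
        r_target = math.copysign(math.sqrt(r2), r2)
        cov_target = r_target * total_sd[i] * total_sd[j]
        rho = (cov_target - shared_cov[i, j]) / (noise_sd[i] * noise_sd[j])
        if not (-1 < rho < 1):
            raise ValueError(
                f"biomarker correlation target {m1}/{m2} infeasible (needs "
                f"noise correlation {rho:.3f})"
            )
        corr[i, j] = corr[j, i] = rho
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 1e-10:
        raise ValueError("biomarker noise correlation matrix not positive-definite")
    return corr


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> PhenotypeTable:
    """Draw subtype, smoking, biomarkers, location and ancestry stratum.

    Smoking and the ancestry stratum are assigned first; the subtype is
    drawn from ``logit P(CD) = alpha + s_i * sum_j beta_j g_ij + gamma(smoking)``
    where ``s_i`` is ``jewish_effect_scale`` for Jewish samples and 1
    otherwise, and ``alpha`` is solved so the expected CD fraction matches
    ``config.cd_fraction``.  Biomarkers are drawn conditional on subtype
    and (optionally) the genetic liability; CD location conditional on
    genotype and smoking.  Ground-truth latent quantities are recorded in
    ``PhenotypeTable.ground_truth``.
    """
    rng = _rng(config, 2)
    n = genotypes.n_samples
    for idx, _ in config.causal_effects:
        if idx >= genotypes.n_variants:
            raise ValueError(f"causal index {idx} not in genotype matrix")

    # -- smoking and ancestry stratum ---------------------------------------
    p_never, p_quit, p_current = config.smoking_prevalence
    smoking = rng.choice(
        np.array(["Never", "Quit", "Current"], dtype=object),
        size=n,
        p=[p_never, p_quit, p_current],
    )
    jewish = rng.random(n) < config.jewish_fraction

    # -- genetic liability ---------------------------------------------------
    if config.causal_effects:
        idx = np.array([i for i, _ in config.causal_effects], dtype=int)
        beta = np.array([b for _, b in config.causal_effects], dtype=float)
        g = genotypes.dosages[:, idx]
        g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
        g_centered = g - g.mean(axis=0)
        raw = g_centered @ beta
    else:
        beta = np.zeros(0)
        raw = np.zeros(n)

    gamma_current = math.log(config.smoking_or_cd / config.smoking_or_uc)
    gamma_quit = 0.5 * gamma_current  # Quit carries half the Current log-OR
    smoke_term = np.where(
        smoking == "Current", gamma_current, np.where(smoking == "Quit", gamma_quit, 0.0)
    )
    smoke_term = smoke_term - smoke_term.mean()
    var_smoke = float(np.var(smoke_term))

    scale = 1.0
    var_raw = float(np.var(raw))
    if config.target_latent_r2 is not None and var_raw > 0:
        t = config.target_latent_r2
        scale = math.sqrt(t * (var_smoke + LOGISTIC_VAR) / ((1.0 - t) * var_raw))
    genetic = scale * raw
    var_genetic = float(np.var(genetic))
    latent_r2 = var_genetic / (var_genetic + var_smoke + LOGISTIC_VAR)

    ancestry_scale = np.where(jewish, config.jewish_effect_scale, 1.0)
    eta = ancestry_scale * genetic + smoke_term
    alpha = _solve_intercept(eta, config.cd_fraction) if n else 0.0
    p_cd = 1.0 / (1.0 + np.exp(-(alpha + eta)))
    y = (rng.random(n) < p_cd).astype(np.int64)

    # -- ground truth: pseudo-R^2 achievable by the true genetic score ------
    gt: dict = {
        "latent_genetic_r2": latent_r2,
        "latent_smoking_var": var_smoke,
        "effect_scale": scale,
        "alpha": alpha,
    }
    if var_genetic > 0 and 0 < y.sum() < n:
        X1 = np.column_stack([np.ones(n), genetic])
        X0 = np.ones((n, 1))
        f1 = fit_logistic(X1, y)
        f0 = fit_logistic(X0, y)
        r2_cs = 1.0 - math.exp(2.0 * (f0.loglik - f1.loglik) / n)
        r2_max = 1.0 - math.exp(2.0 * f0.loglik / n)
        gt["expected_prs_nagelkerke"] = r2_cs / r2_max
    table = {
        "sample_id": genotypes.sample_ids,
        "subtype": y,
        "smoking": smoking,
        "ancestry_stratum": np.where(jewish, "jewish", "nonjewish"),
    }

    # -- serum biomarkers ----------------------------------------------------
    specs = config.biomarker_spec
    if specs:
        names = [s.name for s in specs]
        g_std = (
            genetic / math.sqrt(var_genetic) if var_genetic > 0 else np.zeros(n)
        )
        shifts = np.array([[s.shift_cd, s.shift_uc] for s in specs])
        load = np.array([s.liability_loading for s in specs])
        noise_sd = np.array([s.noise_sd for s in specs])
        shared = (
            np.outer(y, shifts[:, 0])
            + np.outer(1 - y, shifts[:, 1])
            + np.outer(g_std, load)
        )
        corr = _biomarker_noise_corr(config, shared, names)
        chol = np.linalg.cholesky(corr)
        eps = rng.standard_normal((n, len(specs))) @ chol.T
        values = shared + eps * noise_sd
        for i, name in enumerate(names):
            table[name] = values[:, i]

    # -- CD location ---------------------------------------------------------
    loc = np.array([None] * n, dtype=object)
    spec = config.location_spec
    logit_col = np.full(n, math.log(spec.baseline_colonic_fraction /
                                    (1 - spec.baseline_colonic_fraction)))
    for vi, b in spec.variant_log_or.items():
        d = genotypes.dosages[:, vi]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        logit_col += b * (d - d.mean())
    for level, shift in spec.smoking_log_or.items():
        logit_col += shift * (smoking == level)
    p_col = 1.0 / (1.0 + np.exp(-logit_col))
    cd = y == 1
    draw = rng.random(n)
    loc[cd & (draw < p_col)] = "colonic"
    loc[cd & (draw >= p_col)] = "small_bowel"
    table["cd_location"] = loc

    import pandas as pd

    return PhenotypeTable(pd.DataFrame(table), ground_truth=gt)


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, PhenotypeTable]:
    genotypes = simulate_genotypes(config)
    return genotypes, simulate_phenotypes(genotypes, config)


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

def make_fixture(
    name: str, seed: int = 0, with_pcs: int = 10
) -> tuple[GenotypeMatrix, PhenotypeTable, SimulationConfig]:
    """Seeded, versioned cohorts for tests and examples.

    ``tiny``     50 samples x 100 variants, seconds;
    ``default``  4,000 x 5,000, the standard study conditions;
    ``location`` a CD-only cohort with colonic/small-bowel labels and three
    planted location-associated loci (NOD2-like, MHC-like, one other).
    ``with_pcs`` attaches that many principal components (0 disables).
    """
    if name == "tiny":
        config = default_config(50, 100, seed=seed)
    elif name == "default":
        config = default_config(4000, 5000, seed=seed)
    elif name == "location":
        config = default_config(4000, 2000, seed=seed)
        mhc_lo, _ = config.region_map["MHC"]
        other = config.region_map["MHC"][1] + 200
        config = replace(
            config,
            location_spec=LocationSpec(
                baseline_colonic_fraction=0.30,
                variant_log_or={2: -0.7, mhc_lo + 5: 0.6, other: 0.65},
            ),
        )
    else:
        raise ValueError(f"unknown fixture name {name!r}")
    genotypes, phenotypes = simulate_cohort(config)
    if name == "location":
        keep = np.flatnonzero(phenotypes.subtype == 1)
        genotypes = genotypes.take_samples(keep)
        phenotypes = phenotypes.take(keep)
    if with_pcs:
        from .structure_qc import attach_pcs

        phenotypes = attach_pcs(genotypes, phenotypes, k=min(with_pcs,
                                genotypes.n_samples - 1, genotypes.n_variants))
    return genotypes, phenotypes, config
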