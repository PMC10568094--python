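"""Per-variant logistic association scans.

Three scans share one engine: the case-case CD-vs-UC GWAS, the colonic
vs small-bowel CD-location GWAS, and a genome-wide SNP x smoking
interaction scan on CD location.  Main scans report Wald statistics per
dosage (matching standard GWAS tooling); the interaction scan uses a
2-df likelihood-ratio test against the categorical smoking dummies.
Variants failing convergence (quasi-separation) are flagged and emitted
with missing statistics rather than dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._logistic import fit_logistic
from .cohort_io import GenotypeMatrix, PhenotypeTable, SummaryStats

__all__ = [
    "GwasConfig",
    "run_gwas",
    "run_interaction_scan",
    "genome_wide_hits",
    "smoking_dummies",
]


@dataclass(frozen=True)
class GwasConfig:
    maf_min: float = 0.005
    n_pcs: int = 10
    trait: str = "subtype"  # "subtype" (CD=1 vs UC=0) or "cd_location"
    gw_sig_threshold: float = 5e-8

    def __post_init__(self) -> None:
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if self.trait not in ("subtype", "cd_location"):
            raise ValueError(f"unknown trait {self.trait!r}")


def smoking_dummies(smoking: np.ndarray) -> np.ndarray:
    """Two indicator columns (Quit, Current); Never is the reference."""
    smoking = np.asarray(smoking, dtype=object)
    return np.column_stack(
        [(smoking == "Quit").astype(float), (smoking == "Current").astype(float)]
    )


def _trait_vector(phenotypes: PhenotypeTable, trait: str) -> np.ndarray:
    if trait == "subtype":
        return phenotypes.subtype.astype(float)
    loc = phenotypes.table["cd_location"]
    y = np.where(loc == "colonic", 1.0, np.where(loc == "small_bowel", 0.0, np.nan))
    return y


def _check_two_levels(y: np.ndarray) -> None:
    levels = np.unique(y[~np.isnan(y)])
    if levels.size < 2:
        raise ValueError("trait has a single level in the analysis sample")


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    config: GwasConfig = GwasConfig(),
) -> SummaryStats:
    """Per-variant ``trait ~ intercept + dosage + PC1..PCk`` by maximum
    likelihood, with Wald beta / SE / p per effect allele.

    Samples missing the trait are excluded globally; samples missing a
    dosage are excluded per variant.  MAF is computed on each variant's
    analysis subset and variants below ``maf_min`` are skipped entirely
    (not emitted).  Non-converged fits are emitted with ``converged=False``
    and missing statistics.
    """
    y_all = _trait_vector(phenotypes, config.trait)
    use = ~np.isnan(y_all)
    y = y_all[use]
    _check_two_levels(y)
    if y.size < 2 * (config.n_pcs + 2):
        raise ValueError("too few samples with non-missing trait")
    pcs = phenotypes.pcs(config.n_pcs)[use] if config.n_pcs else np.zeros((y.size, 0))
    covar = np.column_stack([np.ones(y.size), pcs])
    dos = genotypes.dosages[use]

    null_fit = fit_logistic(covar, y)
    k = covar.shape[1]
    rows = []
    n_cases = int(y.sum())
    n_controls = int(y.size - n_cases)
    for j in range(genotypes.n_variants):
        g = dos[:, j]
        ok = ~np.isnan(g)
        gj, yj = g[ok], y[ok]
        if gj.size == 0:
            continue
        freq = gj.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        if maf < config.maf_min:
            continue
        X = np.empty((gj.size, k + 1))
        X[:, :k] = covar[ok]
        X[:, k] = gj
        beta0 = np.append(null_fit.beta, 0.0) if ok.all() else None
        fit = fit_logistic(X, yj, beta0=beta0)
        rec = genotypes.variants.iloc[j]
        if fit.converged and not fit.capped:
            beta = fit.beta[k]
            se = fit.se[k]
            z = beta / se
            p = 2.0 * sps.norm.sf(abs(z))
            p = float(min(max(p, 5e-324), 1.0))
            rows.append((rec["id"], rec["chromosome"], rec["position_bp"],
                         rec["effect_allele"], rec["other_allele"],
                         beta, se, p, maf, n_cases, n_controls, True))
        else:
            rows.append((rec["id"], rec["chromosome"], rec["position_bp"],
                         rec["effect_allele"], rec["other_allele"],
                         np.nan, np.nan, np.nan, maf, n_cases, n_controls, False))
    if not rows:
        raise ValueError("no variants pass the MAF filter")
    df = pd.DataFrame(
        rows,
        columns=SummaryStats.COLUMNS + ["converged"],
    )
    return SummaryStats(df)


def run_interaction_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    config: GwasConfig = GwasConfig(trait="cd_location"),
) -> pd.DataFrame:
    """Genome-wide SNP x smoking interaction scan on CD location.

    Per variant, a 2-df likelihood-ratio test compares
    ``location ~ g + smoking + PCs`` against
    ``location ~ g + smoking + g x smoking + PCs`` where smoking enters as
    Quit/Current dummies (Never reference).  Returns a DataFrame with the
    LRT statistic and chi-square p-value per variant.
    """
    y_all = _trait_vector(phenotypes, "cd_location")
    use = ~np.isnan(y_all)
    y = y_all[use]
    _check_two_levels(y)
    pcs = phenotypes.pcs(config.n_pcs)[use] if config.n_pcs else np.zeros((y.size, 0))
    smoke = smoking_dummies(phenotypes.table["smoking"].to_numpy()[use])
    base = np.column_stack([np.ones(y.size), smoke, pcs])
    dos = genotypes.dosages[use]
    rows = []
    for j in range(genotypes.n_variants):
        g = dos[:, j]
        ok = ~np.isnan(g)
        gj, yj = g[ok], y[ok]
        if gj.size == 0:
            continue
        freq = gj.mean() / 2.0
        if min(freq, 1 - freq) < config.maf_min:
            continue
        B = base[ok]
        X0 = np.column_stack([B, gj])
        X1 = np.column_stack([B, gj, gj * B[:, 1], gj * B[:, 2]])
        f0 = fit_logistic(X0, yj)
        f1 = fit_logistic(X1, yj)
        rec = genotypes.variants.iloc[j]
        if f0.capped or f1.capped:
            rows.append((rec["id"], np.nan, np.nan, False))
            continue
        lrt = max(0.0, 2.0 * (f1.loglik - f0.loglik))
        p = float(sps.chi2.sf(lrt, df=2))
        rows.append((rec["id"], lrt, min(max(p, 5e-324), 1.0), True))
    return pd.DataFrame(rows, columns=["id", "lrt", "p_value", "converged"])


def genome_wide_hits(
    stats: SummaryStats, threshold: float = 5e-8, locus_merge_bp: int = 1_000_000
) -> list[list[str]]:
    """Genome-wide-significant variants grouped into loci.

    Hits with ``p < threshold`` on the same chromosome are merged into one
    locus when within ``locus_merge_bp`` of the previous hit.  Returns a
    list of loci, each a list of variant ids ordered by position.
    """
    df = stats.valid()
    hits = df[df["p_value"] < threshold].sort_values(
        ["chromosome", "position_bp"]
    )
    loci: list[list[str]] = []
    last_chrom, last_pos = None, None
    for _, row in hits.iterrows():
        if (
            row["chromosome"] != last_chrom
            or row["position_bp"] - last_pos > locus_merge_bp
        ):
            loci.append([])
        loci[-1].append(row["id"])
        last_chrom, last_pos = row["chromosome"], row["position_bp"]
    return loci
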