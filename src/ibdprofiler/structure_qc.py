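"""Variant QC, iterated LD pruning and principal components.

The population-structure covariates used throughout the pipeline come
from a strict pre-PCA filter (exclude the MHC, MAF >= 0.05, call rate
>= 0.99, exact Hardy-Weinberg p >= 1e-5) followed by three passes of
sliding-window LD pruning at r^2 = 0.1 (window 100 variants, step 5),
then an SVD of the standardized dosage matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds

from .cohort_io import GenotypeMatrix, PhenotypeTable

__all__ = [
    "QCConfig",
    "PruneConfig",
    "hwe_test",
    "variant_qc",
    "ld_prune",
    "compute_pcs",
    "attach_pcs",
    "dosage_r2",
]

#: conventional extended MHC boundaries on GRCh37
DEFAULT_MHC = ("6", 25_000_000, 34_000_000)


@dataclass(frozen=True)
class QCConfig:
    maf_min: float = 0.05
    call_rate_min: float = 0.99
    hwe_p_min: float = 1e-5
    exclude_regions: tuple[tuple[str, int, int], ...] = (DEFAULT_MHC,)

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.call_rate_min):
            if not (0 < v < 1):
                raise ValueError("QC thresholds must be in (0, 1)")
        if not (0 < self.hwe_p_min < 1):
            raise ValueError("hwe_p_min must be in (0, 1)")


@dataclass(frozen=True)
class PruneConfig:
    r2_threshold: float = 0.1
    window_variants: int = 100
    step_variants: int = 5
    passes: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must be in (0, 1)")
        if self.step_variants > self.window_variants:
            raise ValueError("step must be <= window")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_test(dosages: np.ndarray) -> float:
    """Exact Hardy-Weinberg equilibrium p-value for one variant.

    Dosages are rounded to {0, 1, 2}; missing values are dropped.  The
    test sums, over all heterozygote counts compatible with the observed
    allele counts, the probabilities no larger than that of the observed
    heterozygote count (the standard exact HWE formulation).  Monomorphic
    variants return 1 by convention.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no non-missing genotypes")
    d = np.rint(d).astype(int)
    if np.any((d < 0) | (d > 2)):
        raise ValueError("dosages must round into {0, 1, 2}")
    n_aa = int(np.sum(d == 2))
    n_ab = int(np.sum(d == 1))
    n_bb = int(np.sum(d == 0))
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab  # rare-allele count after folding below
    if n_a > n:  # fold so that "a" is the minor allele
        n_a = 2 * n - n_a
    if n_a == 0:
        return 1.0
    # log-probability of each possible heterozygote count under HWE,
    # conditional on allele counts (Levene-Haldane distribution)
    het_parity = n_a % 2
    hets = np.arange(het_parity, n_a + 1, 2)
    lg = math.lgamma
    logp = np.array(
        [
            lg(n + 1)
            - lg((n_a - h) // 2 + 1)
            - lg(h + 1)
            - lg((2 * n - n_a - h) // 2 + 1)
            + h * math.log(2.0)
            for h in hets
        ]
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = n_ab if n_ab <= n_a else None
    if obs is None or obs % 2 != het_parity:
        # observed genotypes inconsistent with folded allele count parity
        # cannot happen for integer dosages; defensive
        return 1.0
    p_obs = prob[(hets == obs).argmax()]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def variant_qc(
    genotypes: GenotypeMatrix, qc: QCConfig = QCConfig()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants failing region / MAF / call-rate / HWE criteria.

    Returns the filtered matrix and a removal log with one row per removed
    variant giving the *first* failing rule in the order region, maf,
    call_rate, hwe.
    """
    v = genotypes.variants
    maf = genotypes.maf()
    call = genotypes.call_rate()
    reasons: list[tuple[str, str]] = []
    keep = np.ones(genotypes.n_variants, dtype=bool)
    in_region = np.zeros(genotypes.n_variants, dtype=bool)
    for chrom, lo, hi in qc.exclude_regions:
        in_region |= (
            (v["chromosome"] == str(chrom))
            & (v["position_bp"] >= lo)
            & (v["position_bp"] <= hi)
        ).to_numpy()
    for j in range(genotypes.n_variants):
        vid = v["id"].iloc[j]
        if in_region[j]:
            reasons.append((vid, "region"))
        elif maf[j] < qc.maf_min:
            reasons.append((vid, "maf"))
        elif call[j] < qc.call_rate_min:
            reasons.append((vid, "call_rate"))
        elif hwe_test(genotypes.dosages[:, j]) < qc.hwe_p_min:
            reasons.append((vid, "hwe"))
        else:
            continue
        keep[j] = False
    if not keep.any():
        raise ValueError("empty matrix: all variants removed by QC")
    log = pd.DataFrame(reasons, columns=["id", "reason"])
    return genotypes.take_variants(np.flatnonzero(keep)), log


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors (composite
    LD on unphased data), over pairwise-complete samples."""
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        return 0.0
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return 0.0
    c = np.mean((a - a.mean()) * (b - b.mean()))
    return float(c * c / (va * vb))


def _prune_window(dos, maf, pos, window_idx, r2_threshold, dropped):
    """Greedily drop within one window: while any live pair exceeds the
    r^2 threshold, remove from the worst (highest-r^2) pair the member
    with lower MAF (tie -> later map position)."""
    live = [j for j in window_idx if not dropped[j]]
    if len(live) < 2:
        return
    k = len(live)
    sub = dos[:, live]
    col_mean = np.nanmean(sub, axis=0)
    filled = np.where(np.isnan(sub), col_mean, sub)
    sd = filled.std(axis=0)
    sd[sd == 0] = np.nan
    z = (filled - filled.mean(axis=0)) / sd
    r = (z.T @ z) / z.shape[0]
    r2 = np.square(np.nan_to_num(r))
    np.fill_diagonal(r2, 0.0)
    alive = np.ones(k, dtype=bool)
    while True:
        masked = np.where(np.outer(alive, alive), r2, 0.0)
        i, j = divmod(int(masked.argmax()), k)
        if masked[i, j] <= r2_threshold:
            break
        gi, gj = live[i], live[j]
        if maf[gi] < maf[gj]:
            victim = i
        elif maf[gj] < maf[gi]:
            victim = j
        else:
            victim = i if pos[gi] > pos[gj] else j
        alive[victim] = False
        dropped[live[victim]] = True


def ld_prune(
    genotypes: GenotypeMatrix, prune: PruneConfig = PruneConfig()
) -> list[str]:
    """Sliding-window greedy LD pruning; returns retained variant ids.

    Windows of ``window_variants`` surviving variants advance by
    ``step_variants``; the whole scan is repeated ``passes`` times on the
    surviving set.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need >= 2 samples for LD pruning")
    dos = genotypes.dosages
    maf = genotypes.maf()
    pos = genotypes.variants["position_bp"].to_numpy()
    surviving = list(range(genotypes.n_variants))
    for _ in range(prune.passes):
        dropped = {j: False for j in surviving}
        start = 0
        while start < len(surviving):
            window = surviving[start : start + prune.window_variants]
            _prune_window(dos, maf, pos, window, prune.r2_threshold, dropped)
            if start + prune.window_variants >= len(surviving):
                break
            start += prune.step_variants
        surviving = [j for j in surviving if not dropped[j]]
    ids = genotypes.variants["id"]
    return [ids.iloc[j] for j in surviving]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def compute_pcs(
    genotypes: GenotypeMatrix, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the standardized dosage matrix.

    Columns are mean-centered and variance-standardized (missing dosages
    imputed to the variant mean); scores are the left singular vectors
    scaled by their singular values, ordered by decreasing eigenvalue.
    Sign convention: the largest-magnitude variant loading of each
    component is positive.  Returns ``(scores (n x k), eigenvalues)``.
    """
    n, m = genotypes.n_samples, genotypes.n_variants
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n_samples, n_variants)={min(n, m)}")
    if k == 0:
        return np.zeros((n, 0)), np.zeros(0)
    X = genotypes.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    if k < min(n, m) - 1:
        u, s, vt = svds(X, k=k, v0=np.ones(min(n, m)))
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    else:
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(k):
        jmax = np.argmax(np.abs(vt[i]))
        if vt[i, jmax] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    eigenvalues = (s ** 2) / max(n - 1, 1)
    return scores, eigenvalues


def attach_pcs(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    k: int = 10,
    qc: QCConfig | None = None,
    prune: PruneConfig | None = None,
) -> PhenotypeTable:
    """Compute PCs (optionally after QC + pruning) and attach ``pc1..pck``
    columns to the phenotype table."""
    g = genotypes
    if qc is not None:
        g, _ = variant_qc(g, qc)
    if prune is not None:
        g = g.select_variants(ld_prune(g, prune))
    scores, _ = compute_pcs(g, k)
    table = phenotypes.table.copy()
    for i in range(k):
        table[f"pc{i + 1}"] = scores[:, i]
    return PhenotypeTable(table, phenotypes.ground_truth)
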