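"""Clumping + thresholding polygenic score construction and scoring.

The P+T score keeps, per LD clump, the most significant variant below a
p-value cut-off and sums weight x dosage over the retained index
variants, with two special cases:

* the MHC's long-range LD is handled by a 3-pass scheme — one clumping
  pass at a 5 Mb radius and r^2 > 0.1, then two more passes over the
  surviving index variants at r^2 > 0.05;
* the NOD2 locus P+T entries are replaced by an externally supplied
  fine-mapped variant/weight list (an override region).

LD is always "in-sample": dosage correlations computed from the supplied
training genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_io import GenotypeMatrix, ScoreModel, SummaryStats
from .structure_qc import dosage_r2

__all__ = [
    "ClumpConfig",
    "MhcClumpConfig",
    "Clump",
    "ClumpSet",
    "GeneRegion",
    "clump",
    "clump_mhc",
    "build_score_model",
    "score_samples",
    "locus_score_model",
]


@dataclass(frozen=True)
class ClumpConfig:
    radius_bp: int = 250_000
    r2_threshold: float = 0.2
    p_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.radius_bp <= 0:
            raise ValueError("radius_bp must be positive")
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must be in (0, 1)")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass(frozen=True)
class MhcClumpConfig:
    radius_bp: int = 5_000_000
    r2_schedule: tuple[float, ...] = (0.1, 0.05, 0.05)
    region: tuple[str, int, int] = ("6", 25_000_000, 34_000_000)
    p_threshold: float = 0.1
    #: if True, later passes re-run on all variants instead of composing
    #: over surviving indices (a no-op for deterministic greedy clumping)
    reclump_all: bool = False

    def __post_init__(self) -> None:
        if not self.r2_schedule:
            raise ValueError("r2_schedule must be non-empty")


@dataclass(frozen=True)
class Clump:
    index_id: str
    member_ids: tuple[str, ...]  # correlated neighbours, excluding the index
    index_p: float


@dataclass
class ClumpSet:
    clumps: list[Clump] = field(default_factory=list)

    def index_ids(self) -> list[str]:
        return [c.index_id for c in self.clumps]

    def __len__(self) -> int:
        return len(self.clumps)


@dataclass(frozen=True)
class GeneRegion:
    name: str
    chromosome: str
    start_bp: int
    end_bp: int
    flank_bp: int = 300_000

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.name}: start_bp > end_bp")

    def contains(self, chromosome: str, position_bp: int) -> bool:
        return (
            str(chromosome) == str(self.chromosome)
            and self.start_bp - self.flank_bp <= position_bp <= self.end_bp + self.flank_bp
        )


#: default NOD2 gene body (GRCh37), used with the standard 300 kb flank
NOD2_GENE = GeneRegion("NOD2", "16", 50_693_588, 50_733_081)


def _sorted_candidates(df: pd.DataFrame) -> pd.DataFrame:
    # ascending p, ties broken by ascending position then id
    return df.sort_values(
        ["p_value", "position_bp", "id"], kind="mergesort"
    ).reset_index(drop=True)


def clump(
    stats: SummaryStats,
    ld_genotypes: GenotypeMatrix,
    config: ClumpConfig = ClumpConfig(),
) -> ClumpSet:
    """Greedy clumping of summary statistics using in-sample LD.

    Variants with ``p > p_threshold`` are discarded first.  The survivor
    with the smallest p (ties: smallest position, then id) becomes an
    index; every unassigned survivor on the same chromosome within
    ``radius_bp`` and with dosage ``r^2 > r2_threshold`` against it joins
    its clump.  Repeats until all survivors are assigned.
    """
    df = stats.valid()
    df = df[df["p_value"] <= config.p_threshold]
    missing = [v for v in df["id"] if v not in ld_genotypes._id_index]
    if missing:
        raise KeyError(f"variants absent from LD genotypes: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    df = _sorted_candidates(df)
    n = len(df)
    assigned = np.zeros(n, dtype=bool)
    chrom = df["chromosome"].to_numpy()
    pos = df["position_bp"].to_numpy()
    ids = df["id"].to_numpy()
    pvals = df["p_value"].to_numpy()
    dos = ld_genotypes.dosages
    col = {v: ld_genotypes.variant_index(v) for v in ids}
    clumps: list[Clump] = []
    for i in range(n):
        if assigned[i]:
            continue
        assigned[i] = True
        members = []
        near = np.flatnonzero(
            ~assigned
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= config.radius_bp)
        )
        gi = dos[:, col[ids[i]]]
        for j in near:
            if dosage_r2(gi, dos[:, col[ids[j]]]) > config.r2_threshold:
                assigned[j] = True
                members.append(ids[j])
        clumps.append(Clump(ids[i], tuple(members), float(pvals[i])))
    return ClumpSet(clumps)


def clump_mhc(
    stats: SummaryStats,
    ld_genotypes: GenotypeMatrix,
    config: MhcClumpConfig = MhcClumpConfig(),
) -> ClumpSet:
    """Multi-pass clumping for the MHC's long-range LD.

    Pass 1 clumps all variants in ``config.region`` at
    ``r2_schedule[0]``; each later pass re-clumps only the surviving
    index variants at the next r^2 value.  Members attributed to an index
    accumulate across passes (union).
    """
    chrom, lo, hi = config.region
    region_stats = stats.in_region(chrom, lo, hi)
    base = ClumpConfig(
        radius_bp=config.radius_bp,
        r2_threshold=config.r2_schedule[0],
        p_threshold=config.p_threshold,
    )
    cs = clump(region_stats, ld_genotypes, base)
    members: dict[str, set[str]] = {
        c.index_id: set(c.member_ids) for c in cs.clumps
    }
    pvals = {c.index_id: c.index_p for c in cs.clumps}
    for r2 in config.r2_schedule[1:]:
        source = region_stats if config.reclump_all else stats.restrict(cs.index_ids())
        cs_next = clump(
            source, ld_genotypes, replace(base, r2_threshold=r2)
        )
        new_members: dict[str, set[str]] = {}
        for c in cs_next.clumps:
            acc = set(c.member_ids)
            acc |= members.get(c.index_id, set())
            for m in c.member_ids:
                acc |= members.get(m, set())
            new_members[c.index_id] = acc - {c.index_id}
            pvals[c.index_id] = c.index_p
        members = new_members
        cs = cs_next
    return ClumpSet(
        [
            Clump(c.index_id, tuple(sorted(members[c.index_id])), pvals[c.index_id])
            for c in cs.clumps
        ]
    )


def build_score_model(
    clumpsets: list[ClumpSet],
    stats: SummaryStats,
    p_threshold: float = 0.1,
    overrides: list[tuple[GeneRegion, pd.DataFrame]] | None = None,
    note: str = "",
) -> ScoreModel:
    """Assemble a score model from clump index variants.

    One entry per index variant with ``p <= p_threshold``; the weight is
    the association log-OR (beta) for the effect allele.  For each
    override ``(region, weights)`` all P+T entries inside region + flank
    are removed and replaced by the supplied fine-map table (columns
    ``id, effect_allele, weight`` and optionally ``other_allele,
    chromosome, position_bp``).
    """
    df = stats.valid().set_index("id")
    rows = []
    tags: dict[str, str] = {}
    seen: set[str] = set()
    for cs in clumpsets:
        for c in cs.clumps:
            if c.index_id in seen:
                continue
            if c.index_id not in df.index:
                raise KeyError(f"index variant {c.index_id!r} has no summary stats")
            rec = df.loc[c.index_id]
            if rec["p_value"] > p_threshold:
                continue
            seen.add(c.index_id)
            rows.append(
                {
                    "id": c.index_id,
                    "chromosome": rec["chromosome"],
                    "position_bp": int(rec["position_bp"]),
                    "effect_allele": rec["effect_allele"],
                    "other_allele": rec["other_allele"],
                    "weight": float(rec["beta"]),
                }
            )
    entries = pd.DataFrame(
        rows,
        columns=["id", "chromosome", "position_bp", "effect_allele",
                 "other_allele", "weight"],
    )
    for region, weights in overrides or []:
        if len(entries):
            inside = entries.apply(
                lambda r: region.contains(r["chromosome"], r["position_bp"]), axis=1
            )
            entries = entries[~inside.to_numpy()]
        w = weights.copy()
        if "other_allele" not in w.columns:
            w["other_allele"] = None
        if "chromosome" not in w.columns:
            w["chromosome"] = region.chromosome
        if "position_bp" not in w.columns:
            w["position_bp"] = region.start_bp
        w = w[[c for c in entries.columns if c in w.columns]]
        entries = (
            w.copy() if entries.empty
            else pd.concat([entries, w], ignore_index=True)
        )
        for vid in w["id"]:
            tags[vid] = region.name
    return ScoreModel(entries, region_tags=tags, p_threshold=p_threshold, note=note)


def score_samples(genotypes: GenotypeMatrix, model: ScoreModel) -> np.ndarray:
    """``score_i = sum_j weight_j * dosage_ij`` over model entries.

    Allele bookkeeping: if a model entry's effect/other alleles are
    swapped relative to the genotype map, the dosage is flipped
    (``2 - d``); any other mismatch is an error.  Missing dosages are
    mean-imputed as twice the effect-allele frequency of the scoring
    cohort.
    """
    scores = np.zeros(genotypes.n_samples)
    vmap = genotypes.variants.set_index("id")
    for row in model.entries.itertuples():
        try:
            j = genotypes.variant_index(row.id)
        except KeyError:
            raise KeyError(
                f"score-model variant {row.id!r} absent from genotype data"
            ) from None
        g_eff = vmap.loc[row.id, "effect_allele"]
        g_oth = vmap.loc[row.id, "other_allele"]
        d = genotypes.dosages[:, j]
        other = getattr(row, "other_allele", None)
        if row.effect_allele == g_eff and (other in (None, g_oth) or pd.isna(other)):
            pass
        elif row.effect_allele == g_oth and (other in (None, g_eff) or pd.isna(other)):
            d = 2.0 - d
        else:
            raise ValueError(
                f"allele mismatch for {row.id!r}: model {row.effect_allele}/"
                f"{other}, genotypes {g_eff}/{g_oth}"
            )
        mean = np.nanmean(d)
        d = np.where(np.isnan(d), mean, d)
        scores += row.weight * d
    return scores


def locus_score_model(
    stats: SummaryStats,
    ld_genotypes: GenotypeMatrix,
    region: GeneRegion,
    clump_config: ClumpConfig = ClumpConfig(),
    p_threshold: float | None = None,
) -> ScoreModel:
    """P+T model restricted to a gene region plus its flanks.

    The summary statistics are restricted to ``region`` extended by
    ``flank_bp`` up- and down-stream, then clumped, thresholded and
    assembled as usual.  An empty region yields an empty model.
    """
    sub = stats.in_region(
        region.chromosome,
        region.start_bp - region.flank_bp,
        region.end_bp + region.flank_bp,
    )
    p_thr = clump_config.p_threshold if p_threshold is None else p_threshold
    if len(sub) == 0:
        import warnings

        warnings.warn(f"region {region.name}: no variants", stacklevel=2)
        return ScoreModel(
            pd.DataFrame(columns=["id", "effect_allele", "weight"]),
            p_threshold=p_thr,
            note=f"locus model {region.name} (empty)",
        )
    cs = clump(sub, ld_genotypes, clump_config)
    return build_score_model(
        [cs], sub, p_threshold=p_thr, note=f"locus model {region.name}"
    )
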