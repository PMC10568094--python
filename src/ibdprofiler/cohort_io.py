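"""Core data containers and text-format readers/writers.

The pipeline passes four kinds of objects between stages: genotype dosage
matrices with a variant map, per-variant association summary statistics,
score models (variant -> log-OR weight), and per-sample phenotype tables
(IBD subtype, smoking, serum biomarkers, CD location, ancestry stratum,
principal components).  All on-disk formats are plain tab-separated text.

Conventions
-----------
* Coordinates are 1-based inclusive (PLINK ``.map`` convention); window
  arithmetic everywhere uses base-pair distance ``|pos_i - pos_index|``.
* Dosages count the *effect allele* and lie in ``[0, 2]``; missing values
  are ``NaN`` in memory and ``NA`` on disk.
* Summary statistics and score models always express ``beta`` / ``weight``
  for the stated effect allele.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "SummaryStats",
    "ScoreModel",
    "PhenotypeTable",
    "read_genotypes",
    "write_dosage_tsv",
    "read_summary_stats",
    "write_summary_stats",
    "read_score_model",
    "write_score_model",
    "read_phenotypes",
    "write_phenotypes",
]

_VALID_ALLELES = frozenset("ACGT")

SMOKING_LEVELS = ("Never", "Quit", "Current")
CD_LOCATIONS = ("colonic", "small_bowel")

VARIANT_COLUMNS = ["id", "chromosome", "position_bp", "effect_allele", "other_allele"]


class CohortIOError(ValueError):
    """Raised for malformed input files or invalid container contents."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant: identifier, position and allele labels."""

    id: str
    chromosome: str
    position_bp: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise CohortIOError(f"{self.id}: position_bp must be >= 1")
        for a in (self.effect_allele, self.other_allele):
            if a not in _VALID_ALLELES:
                raise CohortIOError(f"{self.id}: allele {a!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise CohortIOError(f"{self.id}: effect and other allele identical")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or C/G variants."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


def _variant_frame(variants: Iterable[VariantRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        df = variants.reset_index(drop=True).copy()
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise CohortIOError(f"variant table missing columns: {missing}")
    else:
        df = pd.DataFrame(
            [dataclasses.asdict(v) for v in variants], columns=VARIANT_COLUMNS
        )
    df["chromosome"] = df["chromosome"].astype(str)
    df["position_bp"] = df["position_bp"].astype(np.int64)
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise CohortIOError(f"duplicate variant id {dup!r}")
    return df


class GenotypeMatrix:
    """Samples x variants additive dosage matrix with its variant map.

    ``dosages[i, j]`` counts copies of ``variants.effect_allele[j]`` carried
    by sample ``i`` (real-valued in ``[0, 2]``; ``NaN`` = missing).  Column
    order of ``dosages`` matches row order of ``variants`` and is the single
    source of variant ordering for all downstream modules.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        sample_ids: Sequence[str],
        variants: Iterable[VariantRecord] | pd.DataFrame,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise CohortIOError("dosages must be a 2-D array")
        self.variants = _variant_frame(variants)
        self.sample_ids = np.asarray(list(sample_ids), dtype=object)
        if len(self.sample_ids) != dosages.shape[0]:
            raise CohortIOError("sample_ids length does not match dosage rows")
        if len(self.variants) != dosages.shape[1]:
            raise CohortIOError("variant map length does not match dosage columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortIOError("sample ids not unique")
        with np.errstate(invalid="ignore"):
            bad = (dosages < 0) | (dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortIOError(
                f"dosage out of range [0,2]: sample {self.sample_ids[i]!r}, "
                f"variant {self.variants['id'].iloc[j]!r} = {dosages[i, j]}"
            )
        self.dosages = dosages
        self._id_index: dict[str, int] = {
            vid: j for j, vid in enumerate(self.variants["id"])
        }

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._id_index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in genotype map") from None

    def variant_records(self) -> list[VariantRecord]:
        return [VariantRecord(**row) for row in self.variants.to_dict("records")]

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele frequency over non-missing samples."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency (folded effect-allele frequency)."""
        f = self.effect_allele_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    # -- subsetting ----------------------------------------------------------
    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index], self.sample_ids[index], self.variants
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.sample_ids,
            self.variants.iloc[index].reset_index(drop=True),
        )

    def select_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        return self.take_variants(np.array([self.variant_index(v) for v in ids]))


class SummaryStats:
    """Per-variant association results (the GWAS output, PRS/MR input).

    Wraps a DataFrame with columns ``id, chromosome, position_bp,
    effect_allele, other_allele, beta, se, p_value, maf, n_cases,
    n_controls`` and an optional boolean ``converged`` column.  Rows with
    ``converged == False`` carry ``NaN`` statistics (flagged-and-skipped
    fits) and are excluded by :meth:`valid`.
    """

    COLUMNS = VARIANT_COLUMNS + ["beta", "se", "p_value", "maf", "n_cases", "n_controls"]

    def __init__(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise CohortIOError(f"summary stats missing columns: {missing}")
        table = table.reset_index(drop=True).copy()
        if "converged" not in table.columns:
            table["converged"] = ~table["beta"].isna()
        ok = table["converged"].astype(bool)
        se = table.loc[ok, "se"]
        if (se <= 0).any():
            raise CohortIOError("se must be > 0")
        p = table.loc[ok, "p_value"]
        if ((p <= 0) | (p > 1)).any():
            raise CohortIOError("p_value outside (0, 1]")
        if table["id"].duplicated().any():
            raise CohortIOError("duplicate variant id in summary stats")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    def valid(self) -> pd.DataFrame:
        """Rows with converged, non-missing statistics."""
        return self.table[self.table["converged"].astype(bool)].reset_index(drop=True)

    def restrict(self, ids: Sequence[str]) -> "SummaryStats":
        keep = self.table["id"].isin(set(ids))
        return SummaryStats(self.table[keep])

    def in_region(
        self, chromosome: str, start_bp: int, end_bp: int, invert: bool = False
    ) -> "SummaryStats":
        m = (
            (self.table["chromosome"].astype(str) == str(chromosome))
            & (self.table["position_bp"] >= start_bp)
            & (self.table["position_bp"] <= end_bp)
        )
        return SummaryStats(self.table[~m if invert else m])


@dataclass
class ScoreModel:
    """A polygenic score: one weight (log odds ratio) per variant.

    ``entries`` columns: ``id, effect_allele, other_allele, weight`` plus
    optional ``chromosome, position_bp``.  ``region_tags`` labels entries
    belonging to special regions (e.g. ``"MHC"``, ``"NOD2"``).
    """

    entries: pd.DataFrame
    region_tags: dict[str, str] = field(default_factory=dict)
    p_threshold: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        need = ["id", "effect_allele", "weight"]
        missing = [c for c in need if c not in self.entries.columns]
        if missing:
            raise CohortIOError(f"score model missing columns: {missing}")
        self.entries = self.entries.reset_index(drop=True).copy()
        if self.entries["id"].duplicated().any():
            dup = self.entries.loc[self.entries["id"].duplicated(), "id"].iloc[0]
            raise CohortIOError(f"duplicate variant id {dup!r} in score model")
        w = np.asarray(self.entries["weight"], dtype=float)
        if not np.all(np.isfinite(w)):
            raise CohortIOError("score model weights must be finite")
        self.entries["weight"] = w

    def __len__(self) -> int:
        return len(self.entries)


class PhenotypeTable:
    """Per-sample phenotypes: subtype, smoking, biomarkers, location, PCs.

    ``subtype`` is 1 for Crohn's disease (CD) and 0 for ulcerative colitis
    (UC).  ``cd_location`` is non-missing iff the sample is CD.  Biomarker
    columns (ELISA titers, possibly missing) are any of
    :data:`BIOMARKER_NAMES`; principal components are ``pc1..pck``.
    """

    BIOMARKER_NAMES = ("ASCA-IgA", "ASCA-IgG", "ASCA-IgM", "ANCA", "CBir1", "OmpC", "I2")

    def __init__(self, table: pd.DataFrame, ground_truth: Mapping | None = None) -> None:
        table = table.reset_index(drop=True).copy()
        if "sample_id" not in table.columns or "subtype" not in table.columns:
            raise CohortIOError("phenotype table needs sample_id and subtype columns")
        sub = table["subtype"]
        if not sub.isin([0, 1]).all():
            raise CohortIOError("subtype must be binary (CD=1, UC=0)")
        table["subtype"] = sub.astype(np.int64)
        if "smoking" in table.columns:
            bad = ~table["smoking"].isin(SMOKING_LEVELS)
            if bad.any():
                raise CohortIOError(
                    f"smoking level {table.loc[bad, 'smoking'].iloc[0]!r} "
                    f"not in {SMOKING_LEVELS}"
                )
        if "cd_location" in table.columns:
            loc = table["cd_location"]
            uc = table["subtype"] == 0
            if loc[uc].notna().any():
                raise CohortIOError("cd_location must be missing for UC samples")
            if loc[~uc].isna().any():
                raise CohortIOError("cd_location missing for a CD sample")
            if not loc[~uc].isin(CD_LOCATIONS).all():
                raise CohortIOError(f"cd_location must be one of {CD_LOCATIONS}")
        self.table = table
        #: generator-side ground truth (latent variances etc.); empty for real data
        self.ground_truth: dict = dict(ground_truth or {})

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subtype(self) -> np.ndarray:
        return self.table["subtype"].to_numpy()

    def pc_columns(self, k: int | None = None) -> list[str]:
        cols = [c for c in self.table.columns if c.startswith("pc") and c[2:].isdigit()]
        cols.sort(key=lambda c: int(c[2:]))
        return cols if k is None else cols[:k]

    def pcs(self, k: int | None = None) -> np.ndarray:
        cols = self.pc_columns(k)
        if k is not None and len(cols) < k:
            raise CohortIOError(f"requested {k} PCs but table has {len(cols)}")
        return self.table[cols].to_numpy(dtype=float)

    def biomarker_columns(self) -> list[str]:
        return [c for c in self.BIOMARKER_NAMES if c in self.table.columns]

    def take(self, index: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(self.table.iloc[np.asarray(index)], self.ground_truth)


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``dosage_tsv`` or ``plink_text`` files.

    ``dosage_tsv`` is variant-major: one header row of sample ids after the
    five variant columns, one row per variant, dosages in ``[0, 2]`` with
    ``NA`` for missing.  ``plink_text`` names a ``.ped`` file (or prefix)
    with its companion ``.map``; the *minor* allele observed in the file is
    taken as the effect allele (ties broken alphabetically).
    """
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    if format == "plink_text":
        return _read_plink_text(path)
    raise CohortIOError(f"unknown genotype format {format!r}")


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in VARIANT_COLUMNS]
    if not sample_ids:
        raise CohortIOError(f"{path}: no sample columns")
    dosages = df[sample_ids].to_numpy(dtype=float).T  # samples x variants
    variants = _variant_frame(df[VARIANT_COLUMNS])
    for rec in variants.itertuples():
        VariantRecord(
            rec.id, rec.chromosome, rec.position_bp, rec.effect_allele, rec.other_allele
        )
    try:
        return GenotypeMatrix(dosages, sample_ids, variants)
    except CohortIOError as e:
        raise CohortIOError(f"{path}: {e}") from None


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.variants.copy()
    for i, sid in enumerate(genotypes.sample_ids):
        df[sid] = genotypes.dosages[i]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def _read_plink_text(path) -> GenotypeMatrix:
    path = str(path)
    prefix = path[:-4] if path.endswith((".ped", ".map")) else path
    map_rows = []
    with open(prefix + ".map") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise CohortIOError(f"{prefix}.map line {ln}: expected 4 fields")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_var = len(map_rows)
    sample_ids: list[str] = []
    allele_calls: list[list[tuple[str, str]]] = []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise CohortIOError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * n_var} fields, "
                    f"got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_calls.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_var)]
            )
    n_samp = len(sample_ids)
    dosages = np.full((n_samp, n_var), np.nan)
    records = []
    for j, (chrom, vid, pos) in enumerate(map_rows):
        seen: dict[str, int] = {}
        for i in range(n_samp):
            for a in allele_calls[i][j]:
                if a != "0":
                    if a not in _VALID_ALLELES:
                        raise CohortIOError(
                            f"{prefix}.ped variant {vid}: allele {a!r} not in A/C/G/T"
                        )
                    seen[a] = seen.get(a, 0) + 1
        if len(seen) > 2:
            raise CohortIOError(f"{prefix}.ped variant {vid}: more than 2 alleles")
        if len(seen) == 0:
            raise CohortIOError(f"{prefix}.ped variant {vid}: all genotypes missing")
        # minor allele = effect allele, ties broken alphabetically
        alleles = sorted(seen, key=lambda a: (seen[a], a))
        if len(alleles) == 1:
            other = next(a for a in "ACGT" if a != alleles[0])
            effect = alleles[0]
        else:
            effect, other = alleles[0], alleles[1]
        records.append(VariantRecord(vid, chrom, pos, effect, other))
        for i in range(n_samp):
            pair = allele_calls[i][j]
            if "0" not in pair:
                dosages[i, j] = sum(a == effect for a in pair)
    return GenotypeMatrix(dosages, sample_ids, records)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_STATS_HEADER = {
    "id": "id", "chr": "chromosome", "pos": "position_bp",
    "effect_allele": "effect_allele", "other_allele": "other_allele",
    "beta": "beta", "se": "se", "p": "p_value", "maf": "maf",
    "n_cases": "n_cases", "n_controls": "n_controls",
}


def read_summary_stats(path, or_column: bool = False) -> SummaryStats:
    """Read a summary-statistics TSV.

    With ``or_column=True`` the effect column is an odds ratio and is
    converted to ``beta = log(OR)`` on import.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chr": str, "chromosome": str})
    df = df.rename(columns=_STATS_HEADER)
    if or_column:
        if "or" not in {c.lower() for c in df.columns}:
            raise CohortIOError(f"{path}: or_column=True but no OR column")
        orcol = next(c for c in df.columns if c.lower() == "or")
        df["beta"] = np.log(df[orcol].astype(float))
    for col in ("n_cases", "n_controls"):
        if col not in df.columns:
            df[col] = 0
    if "maf" not in df.columns:
        df["maf"] = np.nan
    try:
        return SummaryStats(df)
    except CohortIOError as e:
        raise CohortIOError(f"{path}: {e}") from None


def write_summary_stats(stats: SummaryStats, path) -> None:
    df = stats.table.rename(
        columns={"chromosome": "chr", "position_bp": "pos", "p_value": "p"}
    )
    cols = ["id", "chr", "pos", "effect_allele", "other_allele",
            "beta", "se", "p", "maf", "n_cases", "n_controls", "converged"]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# score models
# ---------------------------------------------------------------------------

def write_score_model(model: ScoreModel, path) -> None:
    """Write a score model as TSV (spiritually PLINK ``--score`` input)."""
    df = model.entries.copy()
    df["region"] = [model.region_tags.get(v, "") for v in df["id"]]
    cols = [c for c in ("id", "chromosome", "position_bp", "effect_allele",
                        "other_allele", "weight", "region") if c in df.columns]
    header_note = model.note.replace("\n", " ")
    with open(path, "w") as fh:
        if model.p_threshold is not None or header_note:
            fh.write(f"# p_threshold={model.p_threshold}\tnote={header_note}\n")
        df[cols].to_csv(fh, sep="\t", index=False)


def read_score_model(path) -> ScoreModel:
    p_threshold = None
    note = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for fieldspec in first[1:].strip().split("\t"):
                key, _, val = fieldspec.partition("=")
                if key == "p_threshold" and val not in ("None", ""):
                    p_threshold = float(val)
                elif key == "note":
                    note = val
            df = pd.read_csv(fh, sep="\t", dtype={"chromosome": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"chromosome": str})
    if df["weight"].isna().any():
        bad = df.loc[df["weight"].isna(), "id"].iloc[0]
        raise CohortIOError(f"{path}: non-finite weight for {bad!r}")
    tags = {}
    if "region" in df.columns:
        tags = {
            r["id"]: r["region"]
            for _, r in df.iterrows()
            if isinstance(r["region"], str) and r["region"]
        }
        df = df.drop(columns=["region"])
    try:
        return ScoreModel(df, region_tags=tags, p_threshold=p_threshold, note=note)
    except CohortIOError as e:
        raise CohortIOError(f"{path}: {e}") from None


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(phenotypes: PhenotypeTable, path) -> None:
    phenotypes.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    return PhenotypeTable(df)
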