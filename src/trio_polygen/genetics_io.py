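"""Tabular I/O for the pipeline, with allele bookkeeping in one place.

All formats are tab-delimited text with a header row, 1-based inclusive
coordinates (PLINK convention):

* dosage:        ``ID CHR POS REF ALT <ind1> <ind2> ...`` (one row per variant,
  dosages count the ALT allele, real-valued in [0, 2] to admit imputed data);
* pedigree:      ``CHILD FATHER MOTHER LABEL``;
* summary stats: ``ID CHR POS A1 A2 BETA SE P`` (A1 is the effect allele;
  an ``OR`` column in place of ``BETA`` is log-transformed on load);
* weights:       ``TISSUE GENE ID REF ALT WEIGHT`` (sparse eQTL models,
  WEIGHT applies to the ALT allele).

Loaders canonicalise variant order (sorted by chromosome, position), apply
the MAF floor and the missing-dosage policy, and validate integrity
(biallelic single-nucleotide rows, unique ids, complete trios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("trio_polygen")

NUCLEOTIDES = frozenset("ACGT")

DOSAGE_META_COLUMNS = ["ID", "CHR", "POS", "REF", "ALT"]
SUMMARY_COLUMNS = ["ID", "CHR", "POS", "A1", "A2", "BETA", "SE", "P"]
PEDIGREE_COLUMNS = ["CHILD", "FATHER", "MOTHER", "LABEL"]
WEIGHT_COLUMNS = ["TISSUE", "GENE", "ID", "REF", "ALT", "WEIGHT"]


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


class IntegrityError(ValueError):
    """Inputs parse but violate a cross-record invariant."""


def _chrom_key(chrom: object) -> tuple[int, str]:
    """Sort key placing numeric chromosomes first, in numeric order."""
    s = str(chrom)
    try:
        return (0, f"{int(s):09d}")
    except ValueError:
        return (1, s)


def _canonical_variant_order(df: pd.DataFrame) -> pd.DataFrame:
    key = df["CHR"].map(_chrom_key)
    return (
        df.assign(_k=key)
        .sort_values(["_k", "POS"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


@dataclass
class DosageCohort:
    """Individuals x variants effect-allele (ALT) dosage matrix plus metadata.

    ``dosages[i, v]`` counts copies of ``variants.ALT[v]`` carried by
    ``individuals[i]``; real-valued in [0, 2] so imputed dosages are admitted.
    """

    individuals: list[str]
    variants: pd.DataFrame  # columns ID CHR POS REF ALT (+ optional extras)
    dosages: np.ndarray  # shape (n_individuals, n_variants), float

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise IntegrityError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise IntegrityError("duplicate individual ids")
        dup = self.variants["ID"].duplicated()
        if dup.any():
            raise IntegrityError(
                f"duplicate variant id(s): {sorted(self.variants.loc[dup, 'ID'])[:5]}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def individual_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {ind: i for i, ind in enumerate(self.individuals)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise IntegrityError(f"unknown individual id: {exc.args[0]}") from None

    def variant_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variants["ID"])}
        try:
            return np.array([lookup[v] for v in ids], dtype=int)
        except KeyError as exc:
            raise IntegrityError(f"unknown variant id: {exc.args[0]}") from None

    def allele_frequencies(self) -> np.ndarray:
        """Empirical ALT-allele frequencies over the cohort."""
        return self.dosages.mean(axis=0) / 2.0


@dataclass
class SummaryStats:
    """Per-variant discovery GWAS effects for one trait.

    ``BETA`` is the additive effect (log odds ratio for binary traits) of one
    copy of the effect allele ``A1``.
    """

    table: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SUMMARY_COLUMNS if c not in t.columns]
        if missing:
            raise ParseError(f"summary stats missing column(s) {missing}")
        if (t["SE"] <= 0).any():
            raise IntegrityError("summary stats contain non-positive SE")
        if ((t["P"] <= 0) | (t["P"] > 1)).any():
            raise IntegrityError("summary stats contain P outside (0, 1]")
        if (t["A1"] == t["A2"]).any():
            raise IntegrityError("summary stats contain A1 == A2 rows")
        self.table = _canonical_variant_order(t)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TrioSet:
    """Child -> (father, mother) mapping with diagnostic subgroup labels."""

    table: pd.DataFrame  # columns CHILD FATHER MOTHER LABEL

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PEDIGREE_COLUMNS if c not in t.columns]
        if missing:
            raise ParseError(f"pedigree missing column(s) {missing}")
        dup = t["CHILD"].duplicated()
        if dup.any():
            raise IntegrityError(
                f"individual(s) appear as child twice: {sorted(t.loc[dup, 'CHILD'])[:5]}"
            )
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def children(self) -> list[str]:
        return list(self.table["CHILD"])

    @property
    def labels(self) -> np.ndarray:
        return self.table["LABEL"].to_numpy()

    def validate_against(self, cohort: DosageCohort) -> None:
        """Every referenced individual must exist in the cohort (complete trios)."""
        known = set(cohort.individuals)
        for col in ("CHILD", "FATHER", "MOTHER"):
            absent = sorted(set(self.table[col]) - known)
            if absent:
                raise IntegrityError(f"trio {col.lower()} id(s) absent from cohort: {absent}")


@dataclass
class ExpressionWeightModel:
    """Sparse per-gene eQTL weights for one tissue; WEIGHT applies to ALT."""

    tissue: str
    table: pd.DataFrame  # columns GENE ID REF ALT WEIGHT

    def __post_init__(self) -> None:
        t = self.table
        for c in ("GENE", "ID", "REF", "ALT", "WEIGHT"):
            if c not in t.columns:
                raise ParseError(f"weight model missing column {c}")
        dup = t.duplicated(subset=["GENE", "ID"])
        if dup.any():
            raise IntegrityError(
                f"duplicate (gene, variant) pair(s) in tissue {self.tissue}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.table["GENE"]))


# ---------------------------------------------------------------------------
# dosage


def load_dosage(path: str | Path, maf_floor: float = 0.001) -> DosageCohort:
    """Load a dosage table, dropping variants below the MAF floor.

    Multi-allelic or non-single-nucleotide rows are rejected; missing dosages
    (empty or ``NA``) are mean-imputed to twice the empirical allele frequency
    of the variant, and both events are logged.
    """
    df = _read_table(path)
    missing = [c for c in DOSAGE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: dosage file missing column(s) {missing}")
    ind_cols = [c for c in df.columns if c not in DOSAGE_META_COLUMNS]
    if not ind_cols:
        raise ParseError(f"{path}: dosage file has no individual columns")

    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        ref, alt = str(row.REF), str(row.ALT)
        if "," in alt or "," in ref:
            raise ParseError(
                f"{path}:{lineno}: multi-allelic row for variant {row.ID!r} "
                f"(REF={ref!r}, ALT={alt!r}); only biallelic variants are supported"
            )
        if ref == alt:
            raise ParseError(f"{path}:{lineno}: REF == ALT for variant {row.ID!r}")

    dup = df["ID"].duplicated()
    if dup.any():
        raise IntegrityError(f"{path}: duplicated variant id(s) {sorted(df.loc[dup, 'ID'])[:5]}")

    df = _canonical_variant_order(df)
    mat = df[ind_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float).T
    if np.isnan(mat).any():
        n_missing = int(np.isnan(mat).sum())
        freqs = np.nanmean(mat, axis=0) / 2.0
        fill = np.where(np.isnan(freqs), 0.0, 2.0 * freqs)
        idx = np.where(np.isnan(mat))
        mat[idx] = fill[idx[1]]
        logger.info("load_dosage: mean-imputed %d missing dosage value(s)", n_missing)
    if mat.size and (mat.min() < 0 or mat.max() > 2):
        raise IntegrityError(f"{path}: dosages outside [0, 2]")

    freqs = mat.mean(axis=0) / 2.0
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = maf >= maf_floor
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("load_dosage: removed %d variant(s) below MAF floor %g", n_removed, maf_floor)
    return DosageCohort(
        individuals=ind_cols,
        variants=df.loc[keep, DOSAGE_META_COLUMNS].reset_index(drop=True),
        dosages=mat[:, keep],
    )


def write_dosage(cohort: DosageCohort, path: str | Path) -> None:
    mat = pd.DataFrame(cohort.dosages.T, columns=cohort.individuals)
    out = pd.concat([cohort.variants[DOSAGE_META_COLUMNS].reset_index(drop=True), mat],
                    axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summary statistics


def load_summary_stats(path: str | Path, trait: str = "") -> SummaryStats:
    """Load GWAS summary statistics; an OR column is log-transformed to BETA."""
    df = _read_table(path)
    if "OR" in df.columns and "BETA" not in df.columns:
        odds = pd.to_numeric(df["OR"])
        if (odds <= 0).any():
            raise IntegrityError(f"{path}: OR column contains non-positive values")
        df = df.assign(BETA=np.log(odds))
        logger.info("load_summary_stats: OR column log-transformed to BETA (%s)", path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: summary stats missing column(s) {missing}")
    df = df[SUMMARY_COLUMNS + [c for c in df.columns if c not in SUMMARY_COLUMNS]]
    for c in ("BETA", "SE", "P"):
        df[c] = pd.to_numeric(df[c])
    dup = df["ID"].duplicated()
    if dup.any():
        raise IntegrityError(f"{path}: duplicated variant id(s) in summary stats")
    return SummaryStats(table=df, trait=trait or Path(path).stem)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    stats.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigree


def load_trios(path: str | Path, cohort: DosageCohort | None = None) -> TrioSet:
    df = _read_table(path, dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: pedigree missing column(s) {missing}")
    trios = TrioSet(table=df[PEDIGREE_COLUMNS])
    if cohort is not None:
        trios.validate_against(cohort)
    return trios


def write_trios(trios: TrioSet, path: str | Path) -> None:
    trios.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression weights


def load_weights(path: str | Path) -> dict[str, ExpressionWeightModel]:
    """Load eQTL weight models, one :class:`ExpressionWeightModel` per tissue.

    An empty table (header only) yields an empty mapping; downstream
    prediction then returns zero genes.
    """
    df = _read_table(path)
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: weight table missing column(s) {missing}")
    df["WEIGHT"] = pd.to_numeric(df["WEIGHT"])
    models: dict[str, ExpressionWeightModel] = {}
    for tissue, sub in df.groupby("TISSUE", sort=True):
        models[str(tissue)] = ExpressionWeightModel(
            tissue=str(tissue),
            table=sub[["GENE", "ID", "REF", "ALT", "WEIGHT"]].reset_index(drop=True),
        )
    return models


def write_weights(models: Mapping[str, ExpressionWeightModel] | ExpressionWeightModel,
                  path: str | Path) -> None:
    if isinstance(models, ExpressionWeightModel):
        models = {models.tissue: models}
    parts = []
    for tissue in sorted(models):
        t = models[tissue].table.copy()
        t.insert(0, "TISSUE", tissue)
        parts.append(t)
    if parts:
        out = pd.concat(parts, ignore_index=True)
    else:
        out = pd.DataFrame(columns=WEIGHT_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------


def _read_table(path: str | Path, dtype=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=dtype)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    return df
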