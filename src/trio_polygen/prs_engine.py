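"""Clump-and-threshold polygenic scoring against a trio cohort.

The engine harmonizes discovery summary statistics to the cohort's counted
(ALT) allele — dropping indels and strand-ambiguous A/T, C/G pairs, flipping
reverse-strand matches, and negating allele-swapped effects — then thins
variants by greedy LD clumping on the cohort's own dosages (PLINK-style
``--clump-r2 / --clump-kb`` semantics) and accumulates, per individual, the
raw weighted sum of effect-allele dosages at each P-value threshold.

Scores are deliberately left unstandardized: the transmission statistics
downstream are invariant to any positive affine transform of a score column,
so the raw weighted sum is the canonical representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from trio_polygen.genetics_io import DosageCohort, SummaryStats

logger = logging.getLogger("trio_polygen")

DEFAULT_THRESHOLDS = (0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

FLAG_MATCH = "match"
FLAG_FLIPPED = "flipped_strand"
FLAG_SWAPPED = "swapped_alleles"
FLAG_AMBIGUOUS = "removed_ambiguous"
FLAG_MISMATCH = "removed_mismatch"


class HarmonizationError(ValueError):
    """No usable overlap between summary statistics and the cohort."""


@dataclass
class HarmonizedEffects:
    """Per-variant aligned effects plus provenance flags.

    ``table`` holds one row per summary-stat variant that overlaps the
    cohort, columns ``ID BETA P FLAG``; rows whose flag starts ``removed_``
    carry ``NaN`` beta and never enter scoring.
    """

    table: pd.DataFrame

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[~self.table["FLAG"].str.startswith("removed")]

    def flag_counts(self) -> dict[str, int]:
        return self.table["FLAG"].value_counts().to_dict()


@dataclass
class PRSProfile:
    """Individuals x thresholds polygenic score matrix for one trait."""

    individuals: list[str]
    thresholds: list[float]
    scores: np.ndarray  # (n_individuals, n_thresholds)
    n_variants_used: list[int]
    trait: str = ""

    def column(self, threshold: float) -> np.ndarray:
        return self.scores[:, self.thresholds.index(threshold)]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"IID": self.individuals})
        for j, t in enumerate(self.thresholds):
            out[f"P_{t:g}"] = self.scores[:, j]
        return out


def align_alleles(a1: str, a2: str, target_alt: str, target_ref: str
                  ) -> tuple[str, float]:
    """Classify one summary-stat allele pair against the cohort's pair.

    Returns ``(flag, sign)`` where the aligned beta is ``sign * beta``;
    removed variants get sign 0. A1 is the effect allele of the statistics,
    the target counts ALT. Strand-ambiguous pairs (A/T, C/G) are removed
    before any matching because their strand cannot be resolved; indels and
    non-ACGT codes are removed as mismatches.
    """
    alleles = (a1, a2, target_alt, target_ref)
    if any(len(x) != 1 or x not in "ACGT" for x in alleles):
        return FLAG_MISMATCH, 0.0
    if a2 == _COMPLEMENT[a1]:  # A/T or C/G
        return FLAG_AMBIGUOUS, 0.0
    if (a1, a2) == (target_alt, target_ref):
        return FLAG_MATCH, 1.0
    if (a1, a2) == (target_ref, target_alt):
        return FLAG_SWAPPED, -1.0
    ca1, ca2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
    if (ca1, ca2) == (target_alt, target_ref):
        return FLAG_FLIPPED, 1.0
    if (ca1, ca2) == (target_ref, target_alt):
        return FLAG_FLIPPED, -1.0
    return FLAG_MISMATCH, 0.0


def harmonize(stats: SummaryStats, cohort: DosageCohort) -> HarmonizedEffects:
    """Align summary-stat effects to the cohort's counted allele by variant id."""
    target = cohort.variants.set_index("ID")
    rows = []
    for row in stats.table.itertuples(index=False):
        if row.ID not in target.index:
            continue
        t = target.loc[row.ID]
        flag, sign = align_alleles(str(row.A1), str(row.A2), str(t["ALT"]), str(t["REF"]))
        beta = sign * row.BETA if sign else np.nan
        rows.append((row.ID, beta, row.P, flag))
    if not rows:
        raise HarmonizationError("no overlapping variants between summary stats and cohort")
    table = pd.DataFrame(rows, columns=["ID", "BETA", "P", "FLAG"])
    counts = table["FLAG"].value_counts().to_dict()
    logger.info("harmonize: %d overlapping variants, flags %s", len(table), counts)
    if table["FLAG"].str.startswith("removed").all():
        raise HarmonizationError("all overlapping variants removed during harmonization")
    return HarmonizedEffects(table=table)


def clump(effects: HarmonizedEffects, cohort: DosageCohort,
          r2_threshold: float = 0.1, window_kb: float = 500) -> list[str]:
    """Greedy LD clumping on the cohort's dosages.

    Repeatedly promote the remaining variant with the smallest P (ties broken
    by chromosome, then position) to index status and discard every remaining
    variant on the same chromosome within ``window_kb`` whose squared dosage
    correlation with the index reaches ``r2_threshold``. Returns the retained
    variant ids sorted by (chromosome, position). Zero-variance dosage
    columns are treated as r^2 = 0 with a warning.
    """
    kept_effects = effects.retained
    if kept_effects.empty:
        return []
    meta = cohort.variants.set_index("ID")
    df = kept_effects.merge(
        meta[["CHR", "POS"]], left_on="ID", right_index=True, how="inner"
    )
    df = df.sort_values(["P", "CHR", "POS"], kind="mergesort").reset_index(drop=True)

    col = cohort.variant_index(df["ID"].tolist())
    X = cohort.dosages[:, col]
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    zero_var = norms == 0
    if zero_var.any():
        logger.warning("clump: %d zero-variance variant(s), treated as r2=0",
                       int(zero_var.sum()))
        norms[zero_var] = 1.0

    chrom = df["CHR"].to_numpy()
    pos = df["POS"].to_numpy(dtype=float)
    window = window_kb * 1000.0
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        if near.any():
            j = np.flatnonzero(near)
            r = (Xc[:, j].T @ Xc[:, i]) / (norms[j] * norms[i])
            r[zero_var[j] | zero_var[i]] = 0.0
            alive[j[r**2 >= r2_threshold]] = False
    out = df.iloc[kept].sort_values(["CHR", "POS"], kind="mergesort")
    logger.info("clump: retained %d of %d variants (r2>=%g, window %g kb)",
                len(out), len(df), r2_threshold, window_kb)
    return out["ID"].tolist()


def score(effects: HarmonizedEffects, cohort: DosageCohort,
          thresholds=DEFAULT_THRESHOLDS, variant_ids: list[str] | None = None,
          trait: str = "") -> PRSProfile:
    """Raw weighted-sum PRS per individual at each P threshold.

    ``score(i, t) = sum over clumped variants v with P(v) < t of
    dosage(i, v) * aligned_beta(v)`` — strict inequality, matching the
    ``P < t`` notation of threshold scans.
    """
    table = effects.retained
    if variant_ids is not None:
        table = table[table["ID"].isin(set(variant_ids))]
    thresholds = sorted(float(t) for t in thresholds)
    n_ind = cohort.n_individuals
    scores = np.zeros((n_ind, len(thresholds)))
    n_used = []
    if len(table):
        col = cohort.variant_index(table["ID"].tolist())
        X = cohort.dosages[:, col]
        beta = table["BETA"].to_numpy()
        pvals = table["P"].to_numpy()
        for j, t in enumerate(thresholds):
            mask = pvals < t
            n_used.append(int(mask.sum()))
            if mask.any():
                scores[:, j] = X[:, mask] @ beta[mask]
            else:
                logger.warning("score: no variants below threshold %g", t)
    else:
        n_used = [0] * len(thresholds)
        logger.warning("score: empty variant set, all scores zero")
    return PRSProfile(individuals=list(cohort.individuals), thresholds=thresholds,
                      scores=scores, n_variants_used=n_used, trait=trait)


def clump_and_score(stats: SummaryStats, cohort: DosageCohort,
                    thresholds=DEFAULT_THRESHOLDS, r2_threshold: float = 0.1,
                    window_kb: float = 500) -> PRSProfile:
    """Convenience chain: harmonize -> clump -> score."""
    effects = harmonize(stats, cohort)
    kept = clump(effects, cohort, r2_threshold=r2_threshold, window_kb=window_kb)
    return score(effects, cohort, thresholds=thresholds, variant_ids=kept,
                 trait=stats.trait)
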