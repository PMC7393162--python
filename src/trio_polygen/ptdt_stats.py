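"""Polygenic transmission disequilibrium statistics for trio cohorts.

The pTDT deviation of a trio is the child's polygenic score minus the
mid-parent mean, standardized by the standard deviation of the mid-parent
score distribution over the analysis set:

    dev(trio) = (PRS_child - (PRS_father + PRS_mother) / 2) / SD(mid-parent)

Under Mendelian transmission with no ascertainment the deviations are
symmetric about zero, so a one-sample t-test of mean zero detects systematic
over-transmission. The module also provides the subgroup permutation null,
threshold selection by maximal whole-sample transmission, and the auxiliary
tests used around pTDT (two-sample, paired, Shapiro-Wilk, Spearman, BH-FDR).

Deviations are invariant under any positive affine transform of the PRS
column, so the unstandardized raw scores from the PRS engine are sufficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from trio_polygen.genetics_io import TrioSet
from trio_polygen.prs_engine import PRSProfile

logger = logging.getLogger("trio_polygen")


class DegenerateCohortError(ValueError):
    """The cohort cannot support the requested statistic."""


@dataclass
class PTDTResult:
    """One-sample transmission test for one (trait, subgroup) deviation set."""

    trait: str
    subgroup: str
    n: int
    mean: float
    ci_low: float
    ci_high: float
    t_stat: float
    p: float
    p_one_sided: float
    threshold: float | None = None
    permutation_p: float | None = None


@dataclass
class DeviationMatrix:
    """Trios x traits matrix of standardized pTDT deviations."""

    trio_ids: list[str]
    traits: list[str]
    values: np.ndarray  # (n_trios, n_traits)
    thresholds: dict[str, float]

    def column(self, trait: str) -> np.ndarray:
        return self.values[:, self.traits.index(trait)]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"CHILD": self.trio_ids})
        for j, t in enumerate(self.traits):
            out[t] = self.values[:, j]
        return out


def ptdt_deviations(prs: PRSProfile, trios: TrioSet, threshold: float) -> np.ndarray:
    """Standardized (child - mid-parent) deviations at one P threshold.

    The mid-parent SD uses the n-1 denominator over all trios passed in, so
    subgroup tests share the whole analysis set's scale.
    """
    if len(trios) < 2:
        raise DegenerateCohortError("need at least 2 trios for pTDT deviations")
    col = prs.column(threshold)
    lookup = {ind: i for i, ind in enumerate(prs.individuals)}
    t = trios.table
    child = col[[lookup[i] for i in t["CHILD"]]]
    father = col[[lookup[i] for i in t["FATHER"]]]
    mother = col[[lookup[i] for i in t["MOTHER"]]]
    midparent = (father + mother) / 2.0
    sd = midparent.std(ddof=1)
    if sd == 0:
        raise DegenerateCohortError("mid-parent scores are all identical (zero SD)")
    return (child - midparent) / sd


def ptdt_test(deviations: np.ndarray, trait: str = "", subgroup: str = "all",
              sided: str = "two", threshold: float | None = None) -> PTDTResult:
    """One-sample t-test of mean transmission deviation against zero.

    ``sided`` selects which p populates ``p`` ("two" or "one", one-sided
    toward over-transmission); both are always reported. A zero-variance
    deviation vector yields p = 1 by convention instead of NaN.
    """
    d = np.asarray(deviations, dtype=float)
    if d.size < 3:
        raise DegenerateCohortError("need at least 3 trios for the pTDT t-test")
    mean = float(d.mean())
    if d.std(ddof=1) == 0:
        logger.warning("ptdt_test: zero-variance deviations, p=1 by convention")
        return PTDTResult(trait=trait, subgroup=subgroup, n=d.size, mean=mean,
                          ci_low=mean, ci_high=mean, t_stat=0.0, p=1.0,
                          p_one_sided=1.0, threshold=threshold)
    res = sps.ttest_1samp(d, 0.0)
    ci = res.confidence_interval(0.95)
    p_two = float(res.pvalue)
    p_one = float(sps.t.sf(res.statistic, d.size - 1))
    return PTDTResult(
        trait=trait, subgroup=subgroup, n=int(d.size), mean=mean,
        ci_low=float(ci.low), ci_high=float(ci.high), t_stat=float(res.statistic),
        p=p_one if sided == "one" else p_two, p_one_sided=p_one,
        threshold=threshold,
    )


def select_threshold(thresholds, estimates) -> float:
    """Threshold with the highest whole-sample mean transmission estimate.

    Ties are broken toward the smaller threshold.
    """
    thresholds = [float(t) for t in thresholds]
    estimates = np.asarray(list(estimates), dtype=float)
    if len(thresholds) != len(estimates) or not thresholds:
        raise ValueError("thresholds and estimates must be equal-length and non-empty")
    order = np.lexsort((thresholds, -estimates))
    return thresholds[order[0]]


def build_deviation_matrix(profiles: dict[str, PRSProfile], trios: TrioSet,
                           thresholds: dict[str, float] | None = None,
                           selection_trios: TrioSet | None = None) -> DeviationMatrix:
    """Deviation matrix over traits, selecting each trait's threshold on the
    whole-sample estimate when not supplied.

    ``selection_trios`` (default: ``trios``) is the set on which the
    threshold scan is evaluated; deviations are then computed on ``trios``.
    """
    selection = selection_trios if selection_trios is not None else trios
    chosen: dict[str, float] = dict(thresholds or {})
    cols = []
    for trait, prof in profiles.items():
        if trait not in chosen:
            est = [float(ptdt_deviations(prof, selection, t).mean())
                   for t in prof.thresholds]
            chosen[trait] = select_threshold(prof.thresholds, est)
            logger.info("threshold selection: trait %s -> P < %g", trait, chosen[trait])
        cols.append(ptdt_deviations(prof, trios, chosen[trait]))
    return DeviationMatrix(
        trio_ids=trios.children, traits=list(profiles),
        values=np.column_stack(cols), thresholds=chosen,
    )


def permutation_test(deviations: np.ndarray, labels: np.ndarray, subgroup: str,
                     n_perm: int = 1000, seed: int | np.random.Generator = 0,
                     exact: bool = False) -> float:
    """One-sided permutation p for subgroup mean deviation.

    The subgroup's size is held fixed while labels are shuffled over trios;
    p = (1 + #{perm mean >= observed mean}) / (n_perm + 1), the add-one
    estimator, one-sided toward over-transmission. With ``exact=True`` every
    subgroup assignment is enumerated instead and
    p = #{assignments with mean >= observed} / C(n, k).
    """
    d = np.asarray(deviations, dtype=float)
    labels = np.asarray(labels)
    mask = labels == subgroup
    k = int(mask.sum())
    if k == 0 or k == d.size:
        raise DegenerateCohortError(
            f"subgroup {subgroup!r} must be a non-empty proper subset (size {k} of {d.size})"
        )
    observed = d[mask].mean()
    if exact:
        from itertools import combinations
        from math import comb

        hits = sum(1 for idx in combinations(range(d.size), k)
                   if d[list(idx)].mean() >= observed)
        return hits / comb(d.size, k)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # vectorised label shuffles: a random k-subset per row via argpartition
    keys = rng.random((n_perm, d.size))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    perm_means = d[idx].mean(axis=1)
    return float((1 + np.sum(perm_means >= observed)) / (n_perm + 1))


def paired_transmission_test(means_a, means_b) -> tuple[float, tuple[float, float]]:
    """Paired two-sided t-test of per-trait mean deviations between subgroups.

    Returns (p, 95% CI of the mean difference a - b). A constant difference
    vector is degenerate (zero variance) and raises.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise DegenerateCohortError("paired test needs >= 3 matched trait means")
    diff = a - b
    if diff.std(ddof=1) == 0:
        raise DegenerateCohortError("paired differences have zero variance")
    res = sps.ttest_rel(a, b)
    ci = res.confidence_interval(0.95)
    return float(res.pvalue), (float(ci.low), float(ci.high))


def compare_subgroups(deviations: np.ndarray, labels: np.ndarray,
                      group_a: str, group_b: str) -> float:
    """Two-sample (Welch) t-test p between two subgroups' deviations."""
    d = np.asarray(deviations, dtype=float)
    labels = np.asarray(labels)
    a, b = d[labels == group_a], d[labels == group_b]
    if a.size < 2 or b.size < 2:
        raise DegenerateCohortError("two-sample test needs >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 1.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def deviation_correlations(matrix: DeviationMatrix) -> pd.DataFrame:
    """Spearman rho matrix across trait deviation columns."""
    rho = sps.spearmanr(matrix.values).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-trait case
        r = float(sps.spearmanr(matrix.values[:, 0], matrix.values[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=matrix.traits, columns=matrix.traits)


def normality_check(deviations: np.ndarray) -> float:
    """Shapiro-Wilk p-value for the deviation vector."""
    d = np.asarray(deviations, dtype=float)
    if d.size < 3:
        raise DegenerateCohortError("Shapiro-Wilk needs n >= 3")
    return float(sps.shapiro(d).pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
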