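"""Genetically imputed expression: individual-level prediction, per-gene
association, summary-level gene Z-scores, and cross-profile correlation.

Individual-level prediction is the sparse linear model
``expr(i, g) = sum_v w(g, v) * dosage(i, v)`` with model alleles harmonized
to the cohort's counted allele (same rules as PRS harmonization). Per-gene
case/control association fits a logistic regression of subgroup status on
standardized predicted expression by IRLS.

The summary-level statistic reconstructs the same association from GWAS
summary statistics alone:

    Z(g) = sum_v w(g, v) * (sigma_v / sigma_g) * (beta_v / se_v)

with ``sigma_v`` the reference dosage SD of variant v and
``sigma_g^2 = w' Sigma w`` from the reference dosage covariance of the
gene's model variants. Correlating two gene-Z profiles over genes passing a
P cutoff in the second profile, across a ladder of cutoffs, yields the
threshold-stratified cross-disorder correlation grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

from trio_polygen.genetics_io import DosageCohort, ExpressionWeightModel, SummaryStats, TrioSet
from trio_polygen.prs_engine import align_alleles

logger = logging.getLogger("trio_polygen")

DEFAULT_XCAN_THRESHOLDS = (1.0, 0.5, 0.1, 0.05, 0.01, 0.001)


class AssociationError(ValueError):
    """The association design is degenerate."""


@dataclass
class PredictedExpression:
    """Individuals x genes matrix of predicted expression for one tissue.

    Genes with no harmonizable model variant in the cohort are absent
    (never zero-filled)."""

    individuals: list[str]
    genes: list[str]
    values: np.ndarray  # (n_individuals, n_genes)
    tissue: str
    n_variants_used: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"IID": self.individuals})
        for j, g in enumerate(self.genes):
            out[g] = self.values[:, j]
        return out


@dataclass
class GeneZProfile:
    """Per-gene association Z-scores, individual- or summary-level."""

    table: pd.DataFrame  # columns GENE Z P
    source: str  # "individual_level" | "summary_level"
    trait: str = ""
    tissue: str = ""
    excluded: dict[str, str] | None = None  # gene -> reason

    def z_series(self) -> pd.Series:
        return self.table.set_index("GENE")["Z"]


@dataclass
class CorrelationGrid:
    """Threshold-stratified Spearman correlation between two Z profiles."""

    table: pd.DataFrame  # columns trait tissue p_threshold n_genes rho p


def _harmonized_weights(model: ExpressionWeightModel, cohort: DosageCohort
                        ) -> pd.DataFrame:
    """Model rows aligned to the cohort (columns GENE, COL, WEIGHT)."""
    meta = cohort.variants.set_index("ID")
    col_lookup = {v: i for i, v in enumerate(cohort.variants["ID"])}
    rows = []
    dropped = 0
    for r in model.table.itertuples(index=False):
        if r.ID not in col_lookup:
            dropped += 1
            continue
        t = meta.loc[r.ID]
        flag, sign = align_alleles(str(r.ALT), str(r.REF), str(t["ALT"]), str(t["REF"]))
        if sign == 0.0:
            dropped += 1
            continue
        rows.append((r.GENE, col_lookup[r.ID], sign * r.WEIGHT))
    if dropped:
        logger.info("expression model %s: dropped %d unharmonizable entries",
                    model.tissue, dropped)
    return pd.DataFrame(rows, columns=["GENE", "COL", "WEIGHT"])


def predict_expression(cohort: DosageCohort, model: ExpressionWeightModel
                       ) -> PredictedExpression:
    """Weighted-dosage prediction of genetically regulated expression."""
    aligned = _harmonized_weights(model, cohort)
    genes: list[str] = []
    cols: list[np.ndarray] = []
    n_used: dict[str, int] = {}
    if aligned.empty:
        logger.warning("predict_expression: empty model for tissue %s", model.tissue)
    else:
        for gene, sub in aligned.groupby("GENE", sort=True):
            idx = sub["COL"].to_numpy()
            w = sub["WEIGHT"].to_numpy()
            genes.append(str(gene))
            cols.append(cohort.dosages[:, idx] @ w)
            n_used[str(gene)] = len(sub)
    values = (np.column_stack(cols) if cols
              else np.empty((cohort.n_individuals, 0)))
    return PredictedExpression(individuals=list(cohort.individuals), genes=genes,
                               values=values, tissue=model.tissue,
                               n_variants_used=n_used)


def _logistic_irls(x: np.ndarray, y: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-8, divergence: float = 15.0
                   ) -> tuple[float, float] | None:
    """Fit logit(P(y=1)) = b0 + b1*x by IRLS; return (b1, se1).

    Returns None on separation (slope diverging beyond ``divergence`` on a
    standardized predictor) or non-convergence."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            return None
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if np.abs(beta[1]) > divergence:
            return None
        if np.max(np.abs(step)) < tol:
            cov = np.linalg.inv(XtW @ X)
            return float(beta[1]), float(np.sqrt(cov[1, 1]))
    return None


def associate(expr: PredictedExpression, trios: TrioSet, subgroup: str = "AS",
              other: str = "Non_AS") -> GeneZProfile:
    """Per-gene logistic association of subgroup status (children only).

    Predicted expression is standardized over the analyzed children before
    the fit so Wald Z values are comparable across genes. Zero-variance or
    separating genes are excluded with a logged reason.
    """
    label_map = dict(zip(trios.table["CHILD"], trios.table["LABEL"]))
    keep = [i for i, ind in enumerate(expr.individuals)
            if label_map.get(ind) in (subgroup, other)]
    if not keep:
        raise AssociationError("no labeled children with predicted expression")
    inds = [expr.individuals[i] for i in keep]
    y = np.array([1.0 if label_map[i] == subgroup else 0.0 for i in inds])
    if y.min() == y.max():
        raise AssociationError("association needs both labels among children")
    X = expr.values[keep]

    rows = []
    excluded: dict[str, str] = {}
    for j, gene in enumerate(expr.genes):
        x = X[:, j]
        sd = x.std(ddof=0)
        if sd == 0:
            excluded[gene] = "zero variance"
            continue
        fit = _logistic_irls((x - x.mean()) / sd, y)
        if fit is None:
            excluded[gene] = "separation or non-convergence"
            continue
        slope, se = fit
        z = slope / se
        rows.append((gene, z, 2.0 * norm.sf(abs(z))))
    if excluded:
        logger.info("associate: excluded %d gene(s): %s", len(excluded),
                    dict(list(excluded.items())[:5]))
    return GeneZProfile(table=pd.DataFrame(rows, columns=["GENE", "Z", "P"]),
                        source="individual_level", tissue=expr.tissue,
                        trait=f"{subgroup}_vs_{other}", excluded=excluded)


def summary_zscore(stats: SummaryStats, model: ExpressionWeightModel,
                   reference: DosageCohort) -> GeneZProfile:
    """Summary-statistics-only gene Z using reference LD from dosages."""
    aligned = _harmonized_weights(model, reference)
    st = stats.table.set_index("ID")
    ref_meta = reference.variants["ID"]
    # aligned beta/se of cohort-oriented variants present in the stats
    zmap: dict[int, float] = {}
    for col, vid in enumerate(ref_meta):
        if vid not in st.index:
            continue
        r = st.loc[vid]
        flag, sign = align_alleles(str(r["A1"]), str(r["A2"]),
                                   str(reference.variants["ALT"].iloc[col]),
                                   str(reference.variants["REF"].iloc[col]))
        if sign == 0.0:
            continue
        zmap[col] = sign * float(r["BETA"]) / float(r["SE"])

    rows = []
    excluded: dict[str, str] = {}
    for gene, sub in aligned.groupby("GENE", sort=True):
        cols = sub["COL"].to_numpy()
        w = sub["WEIGHT"].to_numpy()
        have = np.array([c in zmap for c in cols])
        if not have.any():
            excluded[gene] = "no model variant in summary stats"
            continue
        cols, w = cols[have], w[have]
        D = reference.dosages[:, cols]
        sigma_v = D.std(axis=0, ddof=1)
        Sigma = np.cov(D, rowvar=False, ddof=1).reshape(len(cols), len(cols))
        sigma_g = float(np.sqrt(max(w @ Sigma @ w, 0.0)))
        if sigma_g == 0:
            excluded[gene] = "zero predicted-expression variance in reference"
            continue
        zv = np.array([zmap[c] for c in cols])
        z = float(np.sum(w * sigma_v / sigma_g * zv))
        rows.append((gene, z, 2.0 * norm.sf(abs(z))))
    if excluded:
        logger.info("summary_zscore: dropped %d gene(s)", len(excluded))
    return GeneZProfile(table=pd.DataFrame(rows, columns=["GENE", "Z", "P"]),
                        source="summary_level", trait=stats.trait,
                        tissue=model.tissue, excluded=excluded)


def threshold_correlation(profile_a: GeneZProfile, profile_b: GeneZProfile,
                          thresholds=DEFAULT_XCAN_THRESHOLDS,
                          min_genes: int = 10) -> CorrelationGrid:
    """Spearman correlation of Z profiles over genes passing each cutoff.

    At each threshold t the gene set is restricted to shared genes with
    ``profile_b``'s p < t; rows with fewer than ``min_genes`` genes report a
    missing rho with the reason recorded.
    """
    a = profile_a.table.set_index("GENE")
    b = profile_b.table.set_index("GENE")
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise AssociationError("gene sets of the two profiles are disjoint")
    rows = []
    for t in sorted(thresholds, reverse=True):
        genes = [g for g in shared if b.loc[g, "P"] < t]
        if len(genes) < min_genes:
            rows.append((profile_b.trait, profile_b.tissue, t, len(genes),
                         np.nan, np.nan, f"fewer than {min_genes} genes"))
            continue
        res = spearmanr(a.loc[genes, "Z"], b.loc[genes, "Z"])
        rows.append((profile_b.trait, profile_b.tissue, t, len(genes),
                     float(res.statistic), float(res.pvalue), ""))
    return CorrelationGrid(table=pd.DataFrame(
        rows, columns=["trait", "tissue", "p_threshold", "n_genes", "rho", "p", "note"]
    ))
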