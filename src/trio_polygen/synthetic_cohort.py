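"""Synthetic trio cohorts with known polygenic-transmission ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* **LD-blocked biallelic dosages** — haplotypes are produced by a first-order
  (Markov) allele-copying process within blocks, independent across blocks,
  so LD clumping is non-trivial but analytically tractable;
* **discovery GWAS summary statistics** — true effects follow a point-normal
  architecture with configurable cross-trait correlation at shared causal
  variants; observed effects add sampling noise with the standard
  ``SE = 1 / sqrt(2 f (1-f) N)`` for a standardized continuous discovery
  trait of size ``N``;
* **subgroup-restricted over-transmission** — children in an ascertained
  subgroup are accepted only if their liability (scaled true-effect score
  plus independent Gaussian environment) exceeds a population quantile,
  the classic liability-threshold construction under which risk alleles are
  over-transmitted to selected offspring;
* **sparse per-gene eQTL weight models** for multiple tissues with a
  configurable sharing fraction, and an optional "planted" tissue whose
  eQTLs are drawn from the causal variants of chosen traits so that
  cross-disorder expression correlation is concentrated there.

All randomness flows from one integer seed through a hierarchical
``numpy.random.SeedSequence``, split per stage, so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from trio_polygen.genetics_io import DosageCohort, SummaryStats, TrioSet

__all__ = [
    "AscertainmentSpec",
    "ConfigurationError",
    "SimulationConfig",
    "SimulationError",
    "SyntheticStudy",
    "TraitSpec",
    "VariantPanel",
    "sample_haplotypes",
    "simulate_panel",
    "simulate_study",
    "simulate_trait_effects",
    "simulate_trios",
    "simulate_weight_models",
]

_NON_AMBIGUOUS_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                        ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


class SimulationError(RuntimeError):
    """The simulation could not satisfy its constraints (e.g. retry cap)."""


@dataclass(frozen=True)
class TraitSpec:
    """One discovery trait: name, proportion of causal variants, the
    heritability-like fraction of liability variance explained by the
    simulated variants, and the discovery-GWAS sample size."""

    name: str
    prop_causal: float = 0.2
    h2: float = 0.5
    n_discovery: int = 100_000


@dataclass(frozen=True)
class AscertainmentSpec:
    """Children of `subgroup` are kept only if their liability for `trait`
    exceeds the population `quantile` (liability-threshold selection)."""

    subgroup: str
    trait: str
    quantile: float = 0.9


@dataclass
class SimulationConfig:
    """Full parameterisation of a synthetic trio study.

    Defaults mirror the target study design: 379 complete trios of which 39
    carry the AS label and 202 the Non_AS label (the remainder unlabeled),
    six psychiatric discovery traits plus a genetically unrelated negative
    control, and liability ascertainment of the AS subgroup on the three
    comorbid traits reported as over-transmitted.
    """

    n_trios: int = 379
    n_variants: int = 1000
    n_blocks: int = 100
    within_block_correlation: float = 0.8
    maf_floor: float = 0.001
    ambiguous_fraction: float = 0.05
    trait_specs: tuple[TraitSpec, ...] = (
        TraitSpec("ASD", 0.2, 0.12, 46_351),
        TraitSpec("SCZ", 0.2, 0.24, 105_318),
        TraitSpec("MDD", 0.2, 0.09, 480_359),
        TraitSpec("ADHD", 0.2, 0.22, 55_374),
        TraitSpec("ANX", 0.2, 0.10, 21_763),
        TraitSpec("OCD", 0.2, 0.28, 9_725),
        TraitSpec("BMI", 0.2, 0.20, 681_275),
    )
    cross_trait_correlation_matrix: np.ndarray | None = None  # identity if None
    subgroup_counts: Mapping[str, int] | None = None  # derived from n_trios if None
    ascertainment: tuple[AscertainmentSpec, ...] = (
        AscertainmentSpec("AS", "SCZ", 0.9),
        AscertainmentSpec("AS", "MDD", 0.9),
        AscertainmentSpec("AS", "ADHD", 0.9),
    )
    n_genes_per_tissue: int = 100
    eqtls_per_gene: int = 3
    tissues: tuple[str, ...] = ("frontal_cortex", "lung")
    tissue_sharing: float = 0.5
    planted_tissue: str | None = None
    planted_traits: tuple[str, ...] = ()
    retry_cap: int = 10_000
    reference_size: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.within_block_correlation < 1):
            raise ConfigurationError(
                f"within_block_correlation must be in [0, 1), got {self.within_block_correlation}"
            )
        if self.n_variants < self.n_blocks or self.n_blocks < 1:
            raise ConfigurationError("require n_variants >= n_blocks >= 1")
        if not self.trait_specs:
            raise ConfigurationError("trait_specs must be non-empty")
        names = [t.name for t in self.trait_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate trait names")
        for spec in self.ascertainment:
            if spec.trait not in names:
                raise ConfigurationError(f"ascertainment on unknown trait {spec.trait!r}")
            if not (0 < spec.quantile < 1):
                raise ConfigurationError("ascertainment quantiles must be in (0, 1)")
        C = self.cross_trait_correlation_matrix
        if C is not None:
            C = np.asarray(C, dtype=float)
            k = len(self.trait_specs)
            if C.shape != (k, k):
                raise ConfigurationError(f"correlation matrix must be {k}x{k}")
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise ConfigurationError("correlation matrix must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ConfigurationError("correlation matrix must be positive semi-definite")
            self.cross_trait_correlation_matrix = C
        if self.subgroup_counts is None:
            n_as = round(self.n_trios * 39 / 379)
            n_non = round(self.n_trios * 202 / 379)
            self.subgroup_counts = {
                "AS": n_as,
                "Non_AS": n_non,
                "unlabeled": self.n_trios - n_as - n_non,
            }
        self.subgroup_counts = {k: v for k, v in self.subgroup_counts.items() if v > 0}
        if sum(self.subgroup_counts.values()) != self.n_trios:
            raise ConfigurationError("subgroup_counts must sum to n_trios")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.trait_specs]


@dataclass
class VariantPanel:
    """Variant metadata with LD block assignment and population frequencies."""

    table: pd.DataFrame  # columns ID CHR POS REF ALT AF BLOCK
    within_block_correlation: float

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def block_indices(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.table["BLOCK"].to_numpy() == b)
                for b in np.unique(self.table["BLOCK"])]


@dataclass
class TraitEffects:
    """Ground-truth and observed (noisy) per-variant effects for one trait."""

    spec: TraitSpec
    true_beta: np.ndarray
    causal: np.ndarray  # boolean mask
    stats: SummaryStats


@dataclass
class SyntheticStudy:
    """All artifacts of one simulated study, ready for the analysis chain."""

    config: SimulationConfig
    panel: VariantPanel
    effects: dict[str, TraitEffects]
    cohort: DosageCohort
    trios: TrioSet
    weights: dict[str, "object"]  # tissue -> ExpressionWeightModel


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("panel", "effects", "trios", "weights")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# panel & haplotypes


def simulate_panel(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> VariantPanel:
    """Lay out ``n_variants`` across ``n_blocks`` LD blocks on one chromosome.

    Variants within a block are 1 kb apart and share an allele frequency;
    blocks are separated by 10 Mb so they never interact under any clumping
    window the pipeline uses.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["panel"]
    sizes = np.full(config.n_blocks, config.n_variants // config.n_blocks)
    sizes[: config.n_variants % config.n_blocks] += 1
    blocks = np.repeat(np.arange(config.n_blocks), sizes)

    pos = np.empty(config.n_variants, dtype=np.int64)
    cursor = 1
    for b, size in enumerate(sizes):
        start = cursor
        pos[blocks == b] = start + 1000 * np.arange(size)
        cursor = start + 1000 * size + 10_000_000

    lo = max(0.05, config.maf_floor)
    block_af = rng.uniform(lo, 0.5, size=config.n_blocks)
    af = block_af[blocks]

    amb = rng.random(config.n_variants) < config.ambiguous_fraction
    pair_idx = rng.integers(0, 8, size=config.n_variants)
    amb_idx = rng.integers(0, 4, size=config.n_variants)
    ref = np.empty(config.n_variants, dtype="<U1")
    alt = np.empty(config.n_variants, dtype="<U1")
    for i in range(config.n_variants):
        r, a = (_AMBIGUOUS_PAIRS[amb_idx[i]] if amb[i] else _NON_AMBIGUOUS_PAIRS[pair_idx[i]])
        ref[i], alt[i] = r, a

    table = pd.DataFrame(
        {
            "ID": [f"rs{i + 1:06d}" for i in range(config.n_variants)],
            "CHR": "1",
            "POS": pos,
            "REF": ref,
            "ALT": alt,
            "AF": af,
            "BLOCK": blocks,
        }
    )
    return VariantPanel(table=table, within_block_correlation=config.within_block_correlation)


def sample_haplotypes(panel: VariantPanel, n_haplotypes: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw haplotypes from the panel's blocked Markov copying process.

    Within a block the allele at each variant equals the previous variant's
    allele with probability ``within_block_correlation`` and is a fresh
    Bernoulli(AF) draw otherwise, giving first-order correlation equal to the
    copy probability; blocks are independent.
    """
    af = panel.table["AF"].to_numpy()
    blocks = panel.table["BLOCK"].to_numpy()
    rho = panel.within_block_correlation
    n_var = panel.n_variants
    out = np.empty((n_haplotypes, n_var), dtype=np.int8)
    fresh = (rng.random((n_haplotypes, n_var)) < af).astype(np.int8)
    if rho == 0:
        return fresh
    copy = rng.random((n_haplotypes, n_var)) < rho
    prev_block = -1
    for j in range(n_var):
        if blocks[j] != prev_block:
            out[:, j] = fresh[:, j]
            prev_block = blocks[j]
        else:
            out[:, j] = np.where(copy[:, j], out[:, j - 1], fresh[:, j])
    return out


# ---------------------------------------------------------------------------
# trait effects & summary statistics


def simulate_trait_effects(panel: VariantPanel, config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           ) -> dict[str, TraitEffects]:
    """Draw point-normal true effects and noisy discovery summary statistics.

    Causal sets are nested across traits through one shared uniform draw per
    variant, so traits with equal ``prop_causal`` share causal variants and
    the cross-trait correlation matrix acts at those shared positions. Per
    trait the non-zero effects are scaled so the variance of the true-effect
    score equals the trait's ``h2`` fraction (of unit total liability).
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["effects"]
    af = panel.table["AF"].to_numpy()
    n_var = panel.n_variants
    k = len(config.trait_specs)

    C = config.cross_trait_correlation_matrix
    if C is None:
        latent = rng.standard_normal((k, n_var))
    else:
        w, V = np.linalg.eigh(np.asarray(C, dtype=float))
        factor = V * np.sqrt(np.clip(w, 0.0, None))
        latent = factor @ rng.standard_normal((k, n_var))

    u = rng.random(n_var)  # shared -> nested causal sets
    var_weight = 2.0 * af * (1.0 - af)

    effects: dict[str, TraitEffects] = {}
    for t, spec in enumerate(config.trait_specs):
        causal = u < spec.prop_causal
        true_beta = np.zeros(n_var)
        if causal.any() and spec.h2 > 0:
            scale = np.sqrt(spec.h2 / float(var_weight[causal].sum()))
            true_beta[causal] = latent[t, causal] * scale
        se = 1.0 / np.sqrt(var_weight * spec.n_discovery)
        beta_hat = true_beta + rng.standard_normal(n_var) * se
        z = beta_hat / se
        pval = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
        stats = SummaryStats(
            table=pd.DataFrame(
                {
                    "ID": panel.table["ID"],
                    "CHR": panel.table["CHR"],
                    "POS": panel.table["POS"],
                    "A1": panel.table["ALT"],
                    "A2": panel.table["REF"],
                    "BETA": beta_hat,
                    "SE": se,
                    "P": pval,
                }
            ),
            trait=spec.name,
        )
        effects[spec.name] = TraitEffects(spec=spec, true_beta=true_beta,
                                          causal=causal, stats=stats)
    return effects


# ---------------------------------------------------------------------------
# trios


def _draw_trio_batch(panel: VariantPanel, n: int, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (father, mother, child) dosage arrays for n trios.

    Children inherit one uniformly chosen allele per parent per variant
    (Mendelian transmission, no recombination model beyond the per-variant
    choice)."""
    n_var = panel.n_variants
    hap = sample_haplotypes(panel, 4 * n, rng).reshape(n, 4, n_var)
    father_h, mother_h = hap[:, :2, :], hap[:, 2:, :]
    pick_f = rng.integers(0, 2, size=(n, 1, n_var))
    pick_m = rng.integers(0, 2, size=(n, 1, n_var))
    child = (np.take_along_axis(father_h, pick_f, axis=1)[:, 0, :]
             + np.take_along_axis(mother_h, pick_m, axis=1)[:, 0, :])
    return father_h.sum(axis=1), mother_h.sum(axis=1), child


def simulate_trios(panel: VariantPanel, effects: Mapping[str, TraitEffects],
                   config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[DosageCohort, TrioSet]:
    """Generate a trio cohort with liability-threshold child ascertainment.

    For each subgroup with an ascertainment rule, candidate trios are drawn
    and a trio is kept only if the child's liability exceeds the population
    quantile for *every* targeted trait; liability is
    ``sqrt(h2) * standardized true score + sqrt(1 - h2) * N(0, 1)``.
    Population score moments and liability thresholds come from a reference
    population generated alongside. Rejection sampling is batched; exceeding
    ``retry_cap`` expected draws per trio raises :class:`SimulationError`.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["trios"]
    true_mat = np.column_stack([effects[t].true_beta for t in effects])
    trait_order = list(effects)
    h2 = np.array([effects[t].spec.h2 for t in trait_order])

    by_group: dict[str, list[AscertainmentSpec]] = {}
    for spec in config.ascertainment:
        by_group.setdefault(spec.subgroup, []).append(spec)

    thresholds: dict[tuple[str, str], float] = {}
    mu = sd = None
    if config.ascertainment:
        # reference population for score standardization and liability thresholds
        ref_hap = sample_haplotypes(panel, 2 * config.reference_size, rng)
        ref_geno = ref_hap[::2] + ref_hap[1::2]
        ref_scores = ref_geno @ true_mat
        mu = ref_scores.mean(axis=0)
        sd = ref_scores.std(axis=0)
        sd[sd == 0] = 1.0
        ref_liab = (np.sqrt(h2) * (ref_scores - mu) / sd
                    + np.sqrt(1.0 - h2) * rng.standard_normal(ref_scores.shape))
        thresholds = {
            (s.subgroup, s.trait): np.quantile(ref_liab[:, trait_order.index(s.trait)],
                                               s.quantile)
            for s in config.ascertainment
        }

    fathers, mothers, children, labels = [], [], [], []
    for label, count in config.subgroup_counts.items():
        rules = by_group.get(label, [])
        if not rules:
            f, m, c = _draw_trio_batch(panel, count, rng)
            fathers.append(f); mothers.append(m); children.append(c)
            labels.extend([label] * count)
            continue
        accepted_f, accepted_m, accepted_c = [], [], []
        n_accepted = 0
        attempts = 0
        batch = max(4 * count, 64)
        while n_accepted < count:
            if attempts > config.retry_cap * count:
                raise SimulationError(
                    f"ascertainment retry cap exceeded at trio {n_accepted} "
                    f"of subgroup {label!r}"
                )
            f, m, c = _draw_trio_batch(panel, batch, rng)
            attempts += batch
            scores = (c @ true_mat - mu) / sd
            keep = np.ones(batch, dtype=bool)
            for spec_ in rules:
                t_idx = trait_order.index(spec_.trait)
                liab = (np.sqrt(h2[t_idx]) * scores[:, t_idx]
                        + np.sqrt(1.0 - h2[t_idx]) * rng.standard_normal(batch))
                keep &= liab > thresholds[(label, spec_.trait)]
            accepted_f.append(f[keep]); accepted_m.append(m[keep]); accepted_c.append(c[keep])
            n_accepted += int(keep.sum())
            rate = max(n_accepted / attempts, 1.0 / config.retry_cap)
            batch = int(min(max((count - n_accepted) / rate * 1.5, 64), 200_000))
        f = np.concatenate(accepted_f)[:count]
        m = np.concatenate(accepted_m)[:count]
        c = np.concatenate(accepted_c)[:count]
        fathers.append(f); mothers.append(m); children.append(c)
        labels.extend([label] * count)

    father_d = np.concatenate(fathers)
    mother_d = np.concatenate(mothers)
    child_d = np.concatenate(children)
    n = len(labels)
    child_ids = [f"C{i + 1:05d}" for i in range(n)]
    father_ids = [f"F{i + 1:05d}" for i in range(n)]
    mother_ids = [f"M{i + 1:05d}" for i in range(n)]

    cohort = DosageCohort(
        individuals=child_ids + father_ids + mother_ids,
        variants=panel.table[["ID", "CHR", "POS", "REF", "ALT"]].copy(),
        dosages=np.vstack([child_d, father_d, mother_d]).astype(float),
    )
    trios = TrioSet(
        table=pd.DataFrame(
            {"CHILD": child_ids, "FATHER": father_ids, "MOTHER": mother_ids, "LABEL": labels}
        )
    )
    return cohort, trios


# ---------------------------------------------------------------------------
# eQTL weight models


def simulate_weight_models(panel: VariantPanel, config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           effects: Mapping[str, TraitEffects] | None = None):
    """Build sparse per-tissue eQTL weight models.

    Each gene receives ``eqtls_per_gene`` distinct variants from one LD block
    with standard-normal weights. Tissues beyond the first share each gene's
    entries with probability ``tissue_sharing`` and otherwise redraw them.
    If ``planted_tissue``/``planted_traits`` are set (and true effects are
    supplied), that tissue's gene models are drawn from the causal variants
    of the planted traits, concentrating cross-disorder expression signal
    there.
    """
    from trio_polygen.genetics_io import ExpressionWeightModel

    rng = rng if rng is not None else _stage_rngs(config.seed)["weights"]
    if config.eqtls_per_gene < 1:
        raise ConfigurationError("eqtls_per_gene must be >= 1")
    block_idx = panel.block_indices()
    eligible = [b for b in block_idx if len(b) >= config.eqtls_per_gene]
    if not eligible:
        raise ConfigurationError(
            f"no LD block holds {config.eqtls_per_gene} variants for eQTL sampling"
        )
    planted_pool: np.ndarray | None = None
    if config.planted_tissue is not None and config.planted_traits and effects is not None:
        mask = np.zeros(panel.n_variants, dtype=bool)
        for t in config.planted_traits:
            mask |= effects[t].causal
        if mask.sum() >= config.eqtls_per_gene:
            planted_pool = np.flatnonzero(mask)

    ids = panel.table["ID"].to_numpy()
    ref = panel.table["REF"].to_numpy()
    alt = panel.table["ALT"].to_numpy()

    def draw_gene(gene: str, planted: bool) -> pd.DataFrame:
        if planted and planted_pool is not None:
            vs = rng.choice(planted_pool, size=config.eqtls_per_gene, replace=False)
        else:
            block = eligible[rng.integers(0, len(eligible))]
            vs = rng.choice(block, size=config.eqtls_per_gene, replace=False)
        return pd.DataFrame(
            {
                "GENE": gene,
                "ID": ids[vs],
                "REF": ref[vs],
                "ALT": alt[vs],
                "WEIGHT": rng.standard_normal(config.eqtls_per_gene),
            }
        )

    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes_per_tissue)]
    models: dict[str, ExpressionWeightModel] = {}
    base_tissue = config.tissues[0]
    base = {g: draw_gene(g, planted=base_tissue == config.planted_tissue) for g in genes}
    models[base_tissue] = ExpressionWeightModel(
        tissue=base_tissue, table=pd.concat(base.values(), ignore_index=True)
    )
    for tissue in config.tissues[1:]:
        parts = []
        for g in genes:
            if rng.random() < config.tissue_sharing:
                parts.append(base[g])
            else:
                parts.append(draw_gene(g, planted=tissue == config.planted_tissue))
        models[tissue] = ExpressionWeightModel(
            tissue=tissue, table=pd.concat(parts, ignore_index=True)
        )
    return models


# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator stage under one hierarchical seed."""
    rngs = _stage_rngs(config.seed)
    panel = simulate_panel(config, rngs["panel"])
    effects = simulate_trait_effects(panel, config, rngs["effects"])
    cohort, trios = simulate_trios(panel, effects, config, rngs["trios"])
    weights = simulate_weight_models(panel, config, rngs["weights"], effects=effects)
    return SyntheticStudy(config=config, panel=panel, effects=effects,
                          cohort=cohort, trios=trios, weights=weights)
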