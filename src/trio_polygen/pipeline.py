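"""End-to-end orchestration: simulate/load -> PRS -> pTDT -> cluster -> expression.

``run_all`` executes the full analysis chain under one validated
:class:`RunConfig`, writes every intermediate artifact as tab-delimited
text under the output directory, and emits a machine-readable JSON report.
The same seed and config always produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from trio_polygen import cluster_subtypes, expression_xcan, genetics_io, prs_engine, ptdt_stats
from trio_polygen.genetics_io import DosageCohort, TrioSet
from trio_polygen.synthetic_cohort import SimulationConfig, simulate_study

logger = logging.getLogger("trio_polygen")

REPORT_SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "simulation", "dosage_path", "pedigree_path", "stats_paths", "weights_path",
    "thresholds", "subgroup", "other_group", "control_traits", "n_permutations",
    "sided", "k_policy", "k_range_max", "xcan_thresholds", "min_genes",
    "run_expression", "out_dir", "seed",
}


class StageError(RuntimeError):
    """A pipeline stage failed; completed artifacts are kept on disk."""


@dataclass
class RunConfig:
    """Validated configuration for one full pipeline run."""

    simulation: SimulationConfig | None = None
    dosage_path: str | None = None
    pedigree_path: str | None = None
    stats_paths: Mapping[str, str] = field(default_factory=dict)
    weights_path: str | None = None
    thresholds: tuple[float, ...] = prs_engine.DEFAULT_THRESHOLDS
    subgroup: str = "AS"
    other_group: str = "Non_AS"
    control_traits: tuple[str, ...] = ("BMI",)
    n_permutations: int = 1000
    sided: str = "two"
    k_policy: str | int = "auto"
    k_range_max: int = 6
    xcan_thresholds: tuple[float, ...] = expression_xcan.DEFAULT_XCAN_THRESHOLDS
    min_genes: int = 10
    run_expression: bool = True
    out_dir: str = "trio_polygen_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and (self.dosage_path is None or self.pedigree_path is None
                                        or not self.stats_paths):
            raise ValueError("provide either a simulation config or input paths")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Build from a flat key/value YAML file; unknown keys are errors."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS - {"n_trios", "n_variants", "n_blocks",
                                            "within_block_correlation"}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        sim_keys = {k: raw.pop(k) for k in ("n_trios", "n_variants", "n_blocks",
                                            "within_block_correlation") if k in raw}
        if raw.pop("simulation", sim_keys or None) is not None or sim_keys:
            raw["simulation"] = SimulationConfig(seed=raw.get("seed", 0), **sim_keys)
        for key in ("thresholds", "xcan_thresholds", "control_traits"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = tuple(float(x) if key != "control_traits" else x
                                 for x in raw[key].split(","))
        return cls(**raw)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        study = simulate_study(sim)
        stats = {t: study.effects[t].stats for t in study.effects}
        return study.cohort, study.trios, stats, study.weights
    cohort = genetics_io.load_dosage(config.dosage_path)
    trios = genetics_io.load_trios(config.pedigree_path, cohort)
    stats = {t: genetics_io.load_summary_stats(p, trait=t)
             for t, p in config.stats_paths.items()}
    weights = genetics_io.load_weights(config.weights_path) if config.weights_path else {}
    return cohort, trios, stats, weights


def run_all(config: RunConfig, from_stage: str = "start") -> dict:
    """Execute the full study replica and return the report dictionary.

    ``from_stage="cluster"`` reuses the deviation matrix stored by a previous
    run in the same output directory (bit-exact resume); every other stage is
    recomputed deterministically from the seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_perm = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
    }

    stage = "inputs"
    try:
        cohort, trios, stats, weights = _load_inputs(config)
        report["stages"]["inputs"] = {
            "n_individuals": cohort.n_individuals,
            "n_variants": cohort.n_variants,
            "n_trios": len(trios),
            "traits": sorted(stats),
        }
        genetics_io.write_trios(trios, out / "trios.tsv")

        labeled_mask = np.isin(trios.labels, [config.subgroup, config.other_group])
        labeled = TrioSet(table=trios.table[labeled_mask].reset_index(drop=True))

        stage = "prs"
        profiles: dict[str, prs_engine.PRSProfile] = {}
        prs_meta = {}
        for trait in sorted(stats):
            prof = prs_engine.clump_and_score(stats[trait], cohort,
                                              thresholds=config.thresholds)
            profiles[trait] = prof
            prof.to_frame().to_csv(out / f"prs_{trait}.tsv", sep="\t", index=False)
            prs_meta[trait] = dict(zip([f"{t:g}" for t in prof.thresholds],
                                       prof.n_variants_used))
        report["stages"]["prs"] = {"n_variants_used": prs_meta}

        stage = "ptdt"
        if from_stage == "cluster" and (out / "deviations.tsv").exists():
            dev_df = pd.read_csv(out / "deviations.tsv", sep="\t")
            traits = [c for c in dev_df.columns if c != "CHILD"]
            dev = ptdt_stats.DeviationMatrix(
                trio_ids=list(dev_df["CHILD"]), traits=traits,
                values=dev_df[traits].to_numpy(),
                thresholds=json.loads((out / "thresholds.json").read_text()),
            )
        else:
            dev = ptdt_stats.build_deviation_matrix(profiles, trios)
            dev.to_frame().to_csv(out / "deviations.tsv", sep="\t", index=False)
            (out / "thresholds.json").write_text(json.dumps(_jsonable(dev.thresholds),
                                                            sort_keys=True))
        trio_labels = trios.labels
        ptdt_report = {}
        subgroup_means: dict[str, dict[str, float]] = {config.subgroup: {},
                                                       config.other_group: {}}
        for trait in dev.traits:
            col = dev.column(trait)
            per_trait = {"threshold": dev.thresholds[trait],
                         "all": dataclasses.asdict(
                             ptdt_stats.ptdt_test(col, trait, "all", config.sided,
                                                  dev.thresholds[trait]))}
            for group in (config.subgroup, config.other_group):
                mask = trio_labels == group
                if mask.sum() >= 3:
                    res = ptdt_stats.ptdt_test(col[mask], trait, group, config.sided,
                                               dev.thresholds[trait])
                    if group == config.subgroup:
                        lab_mask = np.isin(trio_labels, [config.subgroup,
                                                         config.other_group])
                        res.permutation_p = ptdt_stats.permutation_test(
                            col[lab_mask], trio_labels[lab_mask], group,
                            n_perm=config.n_permutations, seed=rng_perm)
                    per_trait[group] = dataclasses.asdict(res)
                    subgroup_means[group][trait] = float(col[mask].mean())
            ptdt_report[trait] = per_trait
        psych = [t for t in dev.traits if t not in config.control_traits]
        paired = None
        if (len(psych) >= 3
                and all(t in subgroup_means[config.subgroup] for t in psych)
                and all(t in subgroup_means[config.other_group] for t in psych)):
            p_paired, ci = ptdt_stats.paired_transmission_test(
                [subgroup_means[config.subgroup][t] for t in psych],
                [subgroup_means[config.other_group][t] for t in psych])
            paired = {"p": p_paired, "ci": list(ci), "traits": psych}
        report["stages"]["ptdt"] = {"results": ptdt_report, "paired_test": paired}

        stage = "cluster"
        cluster_report = None
        if len(labeled) >= 10 and psych:
            dev_labeled = ptdt_stats.DeviationMatrix(
                trio_ids=[i for i, m in zip(dev.trio_ids, labeled_mask) if m],
                traits=psych,
                values=dev.values[labeled_mask][:, [dev.traits.index(t) for t in psych]],
                thresholds={t: dev.thresholds[t] for t in psych},
            )
            if config.k_policy == "auto":
                k, k_table = cluster_subtypes.choose_k(
                    dev_labeled, range(2, min(config.k_range_max, len(labeled) - 1) + 1))
                k_table.to_csv(out / "cluster_k_indices.tsv", sep="\t", index=False)
            else:
                k, k_table = int(config.k_policy), None
            labels = cluster_subtypes.ward_cluster(dev_labeled, k)
            assignment = cluster_subtypes.silhouette_prune(dev_labeled, labels)
            assignment.to_frame().to_csv(out / "cluster_assignment.tsv", sep="\t",
                                         index=False)
            cluster_report = {
                "k": int(k),
                "sizes_before": assignment.cluster_sizes(retained_only=False),
                "sizes_after": assignment.cluster_sizes(retained_only=True),
            }
            if k == 2:
                enr = cluster_subtypes.enrichment_test(assignment, labeled,
                                                       subgroup=config.subgroup)
                cluster_report["enrichment"] = {
                    "table": enr.table.tolist(),
                    "odds_ratio": enr.odds_ratio,
                    "conditional_or": enr.conditional_or,
                    "ci": [enr.ci_low, enr.ci_high],
                    "p": enr.p,
                }
        report["stages"]["cluster"] = cluster_report

        stage = "expression"
        expr_report = None
        if config.run_expression and weights:
            grids = []
            assoc_profiles = {}
            children = TrioSet(table=labeled.table)
            for tissue in sorted(weights):
                expr = expression_xcan.predict_expression(cohort, weights[tissue])
                try:
                    assoc = expression_xcan.associate(expr, children,
                                                      subgroup=config.subgroup,
                                                      other=config.other_group)
                except expression_xcan.AssociationError:
                    continue
                assoc.table.to_csv(out / f"xcan_assoc_{tissue}.tsv", sep="\t",
                                   index=False)
                assoc_profiles[tissue] = assoc
                for trait in sorted(stats):
                    sz = expression_xcan.summary_zscore(stats[trait], weights[tissue],
                                                        cohort)
                    if sz.table.empty or assoc.table.empty:
                        continue
                    grid = expression_xcan.threshold_correlation(
                        assoc, sz, thresholds=config.xcan_thresholds,
                        min_genes=config.min_genes)
                    g = grid.table.copy()
                    g.insert(0, "assoc_tissue", tissue)
                    grids.append(g)
            if grids:
                grid_all = pd.concat(grids, ignore_index=True)
                grid_all.to_csv(out / "xcan_correlation_grid.tsv", sep="\t",
                                index=False)
                expr_report = {"grid": _jsonable(grid_all.to_dict(orient="records"))}
        report["stages"]["expression"] = expr_report
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_json = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    (out / "report.json").write_text(report_json)
    return report
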