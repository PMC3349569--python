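"""Pairwise inference/validation runs and core-module assembly.

Every cohort takes a turn as the inference cohort: pathway activities are
inferred on it, the top-ranked activities are projected onto each remaining
cohort, and consensus feature elimination on the projected activities (with
the validation cohort's labels) selects the reproducibly discriminative
subset. A pathway inferred from cohort D becomes a *core marker* when it is
selected against every validation partner of D; core markers pooled over all
inference cohorts, together with their member genes and per-cohort regulation
directions, constitute the core module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .activity import PathwayActivityModel, PathwayActivityTransformer
from .cfe import ConsensusMarkerSelector
from .dataset import ExpressionDataset, gene_stats, zscore_normalize
from .network import annotate_regulation
from .pathways import PathwayCollection

__all__ = [
    "PairwiseResult",
    "CoreModule",
    "run_pairwise_validation",
    "assemble_core_module",
    "common_markers",
    "run_all_pairs",
]


@dataclass
class PairwiseResult:
    """CFE outcome of one ordered inference -> validation run."""

    inference_cohort: str
    validation_cohort: str
    method: str
    selected: set[str]
    max_mean_auc: float
    frequencies: pd.Series
    models: dict[str, PathwayActivityModel]


@dataclass
class CoreModule:
    """Consistent pathway-activity markers and their constituent genes.

    ``markers`` maps a core pathway id to its provenance: which inference
    cohorts selected it (with the fitted model and the validation partners
    that confirmed it). ``core_genes`` maps each member gene to its
    per-cohort regulation direction and the overall up/down/contradictory
    call.
    """

    markers: dict[str, dict] = field(default_factory=dict)
    core_genes: dict[str, dict] = field(default_factory=dict)

    @property
    def pathway_ids(self) -> set[str]:
        return set(self.markers)

    @property
    def gene_set(self) -> set[str]:
        return set(self.core_genes)

    def marker_frame(self) -> pd.DataFrame:
        rows = []
        for pid, info in sorted(self.markers.items()):
            for cohort in sorted(info["models"]):
                model = info["models"][cohort]
                rows.append({
                    "pathway_id": pid,
                    "inference_cohort": cohort,
                    "validation_cohorts": ",".join(sorted(info["validated_in"][cohort])),
                    "member_genes": ",".join(model.member_genes),
                    "signs": ",".join(str(int(s)) for s in model.signs),
                    "max_mean_auc": info["max_mean_auc"].get(cohort, float("nan")),
                })
        return pd.DataFrame(rows, columns=["pathway_id", "inference_cohort",
                                           "validation_cohorts", "member_genes",
                                           "signs", "max_mean_auc"])

    def gene_frame(self) -> pd.DataFrame:
        rows = []
        for gene, info in sorted(self.core_genes.items()):
            rows.append({
                "gene": gene,
                "pathways": ",".join(sorted(info["pathways"])),
                "direction": info["direction"],
                "contradictory": info["direction"] == "contradictory",
                **{f"direction_{c}": d for c, d in sorted(info["per_cohort"].items())},
            })
        return pd.DataFrame(rows)


def run_pairwise_validation(
    inference: ExpressionDataset,
    validation: ExpressionDataset,
    pathways: PathwayCollection,
    method: str = "cmi",
    top_n: int = 100,
    classifier_kind: str = "lda",
    alpha: float = 0.05,
    max_k: int = 20,
    n_repeats: int = 100,
    n_splits: int = 100,
    n_folds: int = 5,
    seed: int | None = None,
) -> PairwiseResult:
    """Infer activities on one cohort, select reproducible ones on another.

    Models are inferred for every pathway on the inference cohort, the
    ``top_n`` by discriminative rank are projected onto the validation
    cohort, and repeated consensus feature elimination with the validation
    labels returns the selected pathway set and its maximal mean AUC.
    """
    transformer = PathwayActivityTransformer(
        pathways, method=method, alpha=alpha, max_k=max_k, top_n=top_n,
    ).fit(inference)
    am = transformer.transform(validation)
    if am.n_features == 0:
        raise ValueError(
            f"no activity model from {inference.name} is projectable onto "
            f"{validation.name}"
        )
    frame = pd.DataFrame(am.sample_major(), columns=am.feature_ids)
    sel = ConsensusMarkerSelector(
        classifier=classifier_kind, n_repeats=n_repeats, n_splits=n_splits,
        n_folds=n_folds, random_state=seed,
    ).fit(frame, am.labels)
    return PairwiseResult(
        inference_cohort=inference.name,
        validation_cohort=validation.name,
        method=method,
        selected=set(sel.selected_features_),
        max_mean_auc=sel.max_mean_auc_,
        frequencies=sel.feature_frequencies_,
        models={m.pathway_id: m for m in transformer.models_},
    )


def assemble_core_module(
    pair_results: list[PairwiseResult],
    cohort_tscores: dict[str, dict[str, float]],
) -> CoreModule:
    """Intersect pairwise selections into the core module.

    A pathway inferred from cohort D is a core marker iff it was selected in
    the run against *every* validation cohort other than D; markers are then
    pooled over all inference cohorts. ``cohort_tscores`` (cohort -> gene ->
    t) provides the per-cohort regulation direction of each member gene.
    """
    cohorts = sorted({r.inference_cohort for r in pair_results}
                     | {r.validation_cohort for r in pair_results})
    if len(cohorts) < 2:
        raise ValueError("core assembly needs at least 2 cohorts")
    by_pair = {(r.inference_cohort, r.validation_cohort): r for r in pair_results}
    for inf, val in permutations(cohorts, 2):
        if (inf, val) not in by_pair:
            raise ValueError(f"missing pairwise run {inf} -> {val}")

    core = CoreModule()
    for inf in cohorts:
        partners = [c for c in cohorts if c != inf]
        runs = [by_pair[(inf, v)] for v in partners]
        consistent = set.intersection(*(r.selected for r in runs))
        for pid in sorted(consistent):
            model = runs[0].models[pid]
            entry = core.markers.setdefault(
                pid, {"models": {}, "validated_in": {}, "max_mean_auc": {}})
            entry["models"][inf] = model
            entry["validated_in"][inf] = set(partners)
            entry["max_mean_auc"][inf] = float(
                np.mean([r.max_mean_auc for r in runs]))
            for gene in model.member_genes:
                ginfo = core.core_genes.setdefault(
                    gene, {"pathways": set(), "per_cohort": {}, "direction": None})
                ginfo["pathways"].add(pid)
    if not core.markers:
        warnings.warn("core module is empty", stacklevel=2)
    directions = annotate_regulation(core.gene_set, cohort_tscores)
    for gene, info in core.core_genes.items():
        info["direction"] = directions[gene]
        for cohort, ts in cohort_tscores.items():
            if gene in ts:
                t = ts[gene]
                info["per_cohort"][cohort] = ("up" if t > 0 else
                                              "down" if t < 0 else "none")
    return core


def common_markers(core_a: CoreModule, core_b: CoreModule) -> set[str]:
    """Genes shared by two core modules (e.g. built with different methods)."""
    return core_a.gene_set & core_b.gene_set


def run_all_pairs(
    cohorts: list[ExpressionDataset],
    pathways: PathwayCollection,
    seed: int | None = None,
    **kwargs,
) -> tuple[list[PairwiseResult], CoreModule]:
    """Run every ordered cohort pair and assemble the core module.

    Per-pair seeds derive deterministically from ``seed`` in the sorted pair
    order, so the whole run is reproducible and independent of the order the
    cohorts are supplied in.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    by_name = {c.name: c for c in sorted(cohorts, key=lambda c: c.name)}
    if len(by_name) != len(cohorts):
        raise ValueError("cohort names must be unique")
    pairs = list(permutations(sorted(by_name), 2))
    seeds = [
        int(child.generate_state(1)[0] % 2**31)
        for child in np.random.SeedSequence(seed).spawn(len(pairs))
    ]
    results = [
        run_pairwise_validation(by_name[inf], by_name[val], pathways,
                                seed=s, **kwargs)
        for (inf, val), s in zip(pairs, seeds)
    ]
    tscores: dict[str, dict[str, float]] = {}
    alpha = kwargs.get("alpha", 0.05)
    for name, ds in by_name.items():
        stats = gene_stats(zscore_normalize(ds), alpha=alpha)
        tscores[name] = {s.gene_id: s.tscore for s in stats}
    return results, assemble_core_module(results, tscores)
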