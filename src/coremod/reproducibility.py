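"""Cross-cohort reproducibility of ranked pathway activities.

A model inferred on one cohort is reproducible when its activity is similarly
discriminative on an independent cohort. For the top-N ranked activities the
Cscore is the mean product of each activity's t statistic on the inference
cohort and on the validation cohort:

    Cscore(N) = (1/N) * sum_{i<=N} t(P_I_i) * t(P_V_i)

Direction agreement is rewarded (both t's share a sign) and disagreement
penalized. The overall reproducibility of a method over a panel of cohorts is
the average Cscore over all ordered inference/validation pairs (six pairs for
three cohorts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .activity import PathwayActivityModel, PathwayActivityTransformer, project_activity
from .dataset import ExpressionDataset, t_statistics, zscore_normalize
from .pathways import PathwayCollection

__all__ = [
    "ReproducibilityResult",
    "cscore",
    "cscore_profile",
    "overall_reproducibility",
    "cscore_permutation_null",
]


@dataclass
class ReproducibilityResult:
    inference_cohort: str
    validation_cohort: str
    method: str
    n_values: list[int]
    cscores: list[float]

    def __post_init__(self) -> None:
        if len(self.n_values) != len(self.cscores):
            raise ValueError("one Cscore per N required")
        if any(n < 1 for n in self.n_values):
            raise ValueError("N must be >= 1")


def _validation_tscores(
    models: list[PathwayActivityModel], validation_ds: ExpressionDataset
) -> tuple[np.ndarray, np.ndarray, list[PathwayActivityModel]]:
    """Project models onto the validation cohort; returns (t_inf, t_val, kept)."""
    zds = zscore_normalize(validation_ds)
    acts, kept = [], []
    for m in models:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                acts.append(project_activity(m, zds))
            kept.append(m)
        except ValueError:
            warnings.warn(f"model {m.pathway_id} unprojectable onto "
                          f"{validation_ds.name}; excluded", stacklevel=2)
    if not kept:
        return np.empty(0), np.empty(0), []
    t_val, _ = t_statistics(np.vstack(acts), zds.labels)
    t_inf = np.array([m.inference_tscore for m in kept])
    return t_inf, t_val, kept


def cscore(
    inference_models: list[PathwayActivityModel],
    validation_ds: ExpressionDataset,
    n: int,
) -> float:
    """Cscore(N) of ranked inference models against a validation cohort.

    ``inference_models`` must already be ranked by discriminative power (see
    :func:`coremod.activity.rank_models`); ``n`` may not exceed their count.
    Models with no member gene in the validation cohort are excluded with a
    warning and the average taken over the survivors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(inference_models):
        raise ValueError(f"n={n} exceeds the {len(inference_models)} available models")
    t_inf, t_val, kept = _validation_tscores(inference_models[:n], validation_ds)
    if not kept:
        raise ValueError("no model could be projected onto the validation cohort")
    if len(kept) < n:
        warnings.warn(f"Cscore({n}) computed over {len(kept)} projectable models",
                      stacklevel=2)
    return float(np.mean(t_inf * t_val))


def cscore_profile(
    inference_models: list[PathwayActivityModel],
    validation_ds: ExpressionDataset,
    n_values: list[int],
    inference_cohort: str = "inference",
    method: str | None = None,
) -> ReproducibilityResult:
    """Cscore at several N, reusing a single projection pass."""
    n_max = max(n_values)
    if n_max > len(inference_models):
        raise ValueError("largest N exceeds the available models")
    t_inf, t_val, kept = _validation_tscores(inference_models[:n_max], validation_ds)
    prod = t_inf * t_val
    cs = [float(np.mean(prod[: min(n, len(prod))])) for n in n_values]
    return ReproducibilityResult(
        inference_cohort=inference_cohort,
        validation_cohort=validation_ds.name,
        method=method or (kept[0].method if kept else "?"),
        n_values=list(n_values),
        cscores=cs,
    )


def overall_reproducibility(
    cohorts: list[ExpressionDataset],
    pathways: PathwayCollection,
    method: str,
    n_grid: list[int],
    alpha: float = 0.05,
    max_k: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average Cscore over every ordered inference/validation cohort pair.

    Returns ``(pairs, overall)``: ``pairs`` has one row per (inference,
    validation, N); ``overall`` averages Cscore over all ordered pairs per N.
    LLR is rejected here -- its activities do not live in the expression
    z-score space the comparison assumes.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    if method.lower() == "llr":
        raise ValueError("LLR activities are not comparable in this protocol")
    names = [c.name for c in cohorts]
    if len(set(names)) != len(names):
        raise ValueError("cohort names must be unique")
    fitted = {
        c.name: PathwayActivityTransformer(
            pathways, method=method, alpha=alpha, max_k=max_k
        ).fit(c)
        for c in cohorts
    }
    rows = []
    for inf, val in permutations(cohorts, 2):
        models = fitted[inf.name].models_
        res = cscore_profile(models, val, n_grid, inference_cohort=inf.name,
                             method=method)
        for n, cs in zip(res.n_values, res.cscores):
            rows.append({"method": method, "inference": inf.name,
                         "validation": val.name, "N": n, "cscore": cs})
    pairs = pd.DataFrame(rows)
    overall = (pairs.groupby(["method", "N"], as_index=False)["cscore"]
               .mean().rename(columns={"cscore": "overall_cscore"}))
    return pairs, overall


def cscore_permutation_null(
    inference_models: list[PathwayActivityModel],
    validation_ds: ExpressionDataset,
    n: int,
    n_permutations: int = 200,
    seed: int | None = None,
) -> np.ndarray:
    """Cscore(N) under random relabelling of the validation cohort.

    Shuffling validation labels breaks any activity/phenotype association, so
    the resulting Cscores form a null distribution centred on zero. Returns
    one Cscore per permutation.
    """
    rng = np.random.default_rng(seed)
    zds = zscore_normalize(validation_ds)
    t_inf, _, kept = _validation_tscores(inference_models[:n], validation_ds)
    acts = np.vstack([project_activity(m, zds) for m in kept])
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        labels = rng.permutation(zds.labels)
        t_val, _ = t_statistics(acts, labels)
        out[b] = np.mean(t_inf * t_val)
    return out
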