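"""Pathway-activity inference and projection.

Core-module inference (CMI) summarizes a pathway by the prefix of its
differentially expressed genes -- ranked by descending absolute t-score --
whose sign-aligned average z-score is most discriminative between cases and
controls. Several comparator summaries are provided: the condition-responsive
gene (CORG) search restricted to one regulation direction, per-sample mean and
median of member z-scores, the first principal-component score, a per-gene
Gaussian log-likelihood ratio (LLR), and raw individual genes.

A model is *inferred* on one cohort and can then be *projected* onto any other
cohort that was z-normalized within itself, which is what the cross-cohort
reproducibility and validation machinery relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import ExpressionDataset, GeneStats, gene_stats, t_statistics, zscore_normalize
from .pathways import Pathway, PathwayCollection

__all__ = [
    "PathwayActivityModel",
    "ActivityMatrix",
    "PathwayActivityTransformer",
    "infer_cmi",
    "infer_corg",
    "infer_simple",
    "project_activity",
    "rank_models",
]

_SIGN_ALIGNED = {"cmi", "corg"}
_LLR_VAR_FLOOR = 1e-6


@dataclass
class PathwayActivityModel:
    """A frozen pathway-activity definition inferred on one cohort.

    ``member_genes`` and ``signs`` fix which z-score rows enter the activity
    and with which orientation; ``params`` carries method-specific extras
    (PCA loadings, LLR class-conditional Gaussians, the CMI divisor rule).
    ``inference_tscore`` is the two-sample t statistic of the activity vector
    on the cohort the model was inferred from.
    """

    pathway_id: str
    method: str
    member_genes: list[str]
    signs: np.ndarray
    inference_tscore: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=float)
        if len(self.member_genes) < 1:
            raise ValueError("model needs at least one member gene")
        if self.signs.shape != (len(self.member_genes),):
            raise ValueError("one sign per member gene required")
        if self.method == "cmi" and self.k > 20:
            raise ValueError("CMI marker size is capped at 20 genes")

    @property
    def k(self) -> int:
        return len(self.member_genes)

    def to_record(self) -> dict:
        rec = {
            "pathway_id": self.pathway_id,
            "method": self.method,
            "member_genes": list(self.member_genes),
            "signs": [int(s) if s in (-1.0, 1.0) else float(s) for s in self.signs],
            "k": self.k,
            "inference_tscore": float(self.inference_tscore),
        }
        for key, val in self.params.items():
            rec[key] = val.tolist() if isinstance(val, np.ndarray) else val
        return rec


@dataclass
class ActivityMatrix:
    """Pathway-activity features x samples for one cohort."""

    feature_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    source_models: list[PathwayActivityModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("activity matrix shape mismatch")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sample_major(self) -> np.ndarray:
        """Samples x features view for scikit-learn estimators."""
        return self.values.T


def _stats_lookup(stats: list[GeneStats]) -> dict[str, GeneStats]:
    return {s.gene_id: s for s in stats}


def _ordered_members(
    ds: ExpressionDataset, stats_by_gene: dict[str, GeneStats], pathway: Pathway,
    degs_only: bool,
) -> list[GeneStats]:
    """Pathway genes present in the cohort, ranked by descending |t|.

    Ties in |t| break on gene symbol so inference is order-independent.
    """
    present = [
        stats_by_gene[g]
        for g in pathway.gene_ids
        if g in stats_by_gene and g in ds.gene_index()
    ]
    if degs_only:
        present = [s for s in present if s.is_deg]
    return sorted(present, key=lambda s: (-abs(s.tscore), s.gene_id))


def _activity_tscores(acts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    t, _ = t_statistics(np.atleast_2d(acts), labels)
    return t


def infer_cmi(
    ds: ExpressionDataset,
    stats: list[GeneStats],
    pathway: Pathway,
    max_k: int = 20,
    denominator: str = "j",
) -> PathwayActivityModel | None:
    """Infer a core-module activity for one pathway.

    The pathway's DEGs are ranked by descending |t|; prefix activities
    ``P_j = (1/j) * sum_{i<=j} z(g_i) * sign(t_i)`` are evaluated for
    j = 1..min(#DEGs, max_k) and the prefix whose activity has the largest
    t statistic on the inference cohort is kept (ties favour the smallest j).
    Returns None when the pathway has no DEG in this cohort, the zero-activity
    boundary case. ``denominator`` may be "j" (plain average) or "sqrt"
    (divide by sqrt(j), the CORG normalization).

    ``ds`` must already be z-normalized and ``stats`` computed on it.
    """
    if denominator not in ("j", "sqrt"):
        raise ValueError("denominator must be 'j' or 'sqrt'")
    gi = ds.gene_index()
    members = _ordered_members(ds, _stats_lookup(stats), pathway, degs_only=True)
    if not members:
        if not (pathway.gene_ids & set(gi)):
            warnings.warn(f"{pathway.pathway_id}: no pathway gene present in cohort",
                          stacklevel=2)
        return None
    members = members[:max_k]
    signs = np.array([1.0 if s.tscore >= 0 else -1.0 for s in members])
    z = ds.values[[gi[s.gene_id] for s in members], :]
    csum = np.cumsum(z * signs[:, None], axis=0)
    js = np.arange(1, len(members) + 1, dtype=float)
    div = js if denominator == "j" else np.sqrt(js)
    prefixes = csum / div[:, None]
    tvals = _activity_tscores(prefixes, ds.labels)
    if np.max(tvals) > 0:
        k = int(np.argmax(tvals)) + 1  # argmax returns the first (smallest j) maximum
    else:  # degenerate: no prefix yields a positive t; fall back to |t|
        k = int(np.argmax(np.abs(tvals))) + 1
    return PathwayActivityModel(
        pathway_id=pathway.pathway_id,
        method="cmi",
        member_genes=[s.gene_id for s in members[:k]],
        signs=signs[:k],
        inference_tscore=float(tvals[k - 1]),
        params={"denominator": denominator},
    )


def infer_corg(
    ds: ExpressionDataset,
    stats: list[GeneStats],
    pathway: Pathway,
    max_k: int = 20,
) -> PathwayActivityModel | None:
    """Condition-responsive-gene search: one regulation direction only.

    All pathway genes present in the cohort are split into up- (t > 0) and
    down-regulated (t < 0) subsets, each ranked by descending |t|. Within a
    subset the member prefix grows greedily -- activity is the z-score sum
    divided by sqrt(j), negated for the down subset -- while the activity's
    t statistic improves, stopping at the first non-improving addition. The
    subset whose best activity has the larger |t| wins.
    """
    gi = ds.gene_index()
    ordered = _ordered_members(ds, _stats_lookup(stats), pathway, degs_only=False)
    best: tuple[float, list[str], float, float] | None = None  # |t|, genes, sign, t
    for sign, subset in (
        (1.0, [s for s in ordered if s.tscore > 0]),
        (-1.0, [s for s in ordered if s.tscore < 0]),
    ):
        if not subset:
            continue
        z = ds.values[[gi[s.gene_id] for s in subset[:max_k]], :]
        csum = np.cumsum(z, axis=0) * sign
        js = np.sqrt(np.arange(1, csum.shape[0] + 1, dtype=float))
        tvals = _activity_tscores(csum / js[:, None], ds.labels)
        j = 1
        while j < len(tvals) and tvals[j] > tvals[j - 1]:
            j += 1
        cand_t = float(tvals[j - 1])
        if best is None or abs(cand_t) > best[0]:
            best = (abs(cand_t), [s.gene_id for s in subset[:j]], sign, cand_t)
    if best is None:
        return None
    _, genes, sign, tval = best
    return PathwayActivityModel(
        pathway_id=pathway.pathway_id,
        method="corg",
        member_genes=genes,
        signs=np.full(len(genes), sign),
        inference_tscore=tval,
        params={"denominator": "sqrt"},
    )


def infer_simple(
    ds: ExpressionDataset,
    stats: list[GeneStats],
    pathway: Pathway,
    method: str,
) -> PathwayActivityModel | list[PathwayActivityModel] | None:
    """Comparator activity summaries: mean, median, pca, llr, or gene.

    ``gene`` returns one model per pathway gene present in the cohort (the
    no-inference baseline); the others return a single model over all pathway
    genes present. PCA activities are oriented so the inference t-score is
    non-negative. LLR fits per-gene class-conditional Gaussians with a
    variance floor.
    """
    method = method.lower()
    if method not in ("mean", "median", "pca", "llr", "gene"):
        raise ValueError(f"unknown method {method!r}")
    gi = ds.gene_index()
    genes = sorted(g for g in pathway.gene_ids if g in gi)
    if not genes:
        warnings.warn(f"{pathway.pathway_id}: no pathway gene present in cohort",
                      stacklevel=2)
        return None
    stats_by_gene = _stats_lookup(stats)
    z = ds.values[[gi[g] for g in genes], :]
    if method == "gene":
        return [
            PathwayActivityModel(
                pathway_id=f"{pathway.pathway_id}:{g}", method="gene",
                member_genes=[g], signs=np.array([1.0]),
                inference_tscore=stats_by_gene[g].tscore if g in stats_by_gene
                else float(_activity_tscores(z[i], ds.labels)[0]),
            )
            for i, g in enumerate(genes)
        ]
    params: dict = {}
    signs = np.ones(len(genes))
    if method == "mean":
        act = z.mean(axis=0)
    elif method == "median":
        act = np.median(z, axis=0)
    elif method == "pca":
        centered = z - z.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered.T, full_matrices=False)
        loadings = vt[0]
        act = loadings @ z
        t0 = float(_activity_tscores(act, ds.labels)[0])
        if t0 < 0:
            loadings, act = -loadings, -act
        params["loadings"] = loadings
    else:  # llr
        case, ctrl = z[:, ds.labels == 1], z[:, ds.labels == -1]
        mu_pos, mu_neg = case.mean(axis=1), ctrl.mean(axis=1)
        var_pos, var_neg = case.var(axis=1, ddof=1), ctrl.var(axis=1, ddof=1)
        if (var_pos < _LLR_VAR_FLOOR).any() or (var_neg < _LLR_VAR_FLOOR).any():
            warnings.warn(f"{pathway.pathway_id}: zero-variance class in LLR fit; "
                          f"variance floored at {_LLR_VAR_FLOOR}", stacklevel=2)
        params.update(
            mu_pos=mu_pos, mu_neg=mu_neg,
            var_pos=np.maximum(var_pos, _LLR_VAR_FLOOR),
            var_neg=np.maximum(var_neg, _LLR_VAR_FLOOR),
        )
        act = _llr_activity(z, params)
    t = float(_activity_tscores(act, ds.labels)[0])
    return PathwayActivityModel(
        pathway_id=pathway.pathway_id, method=method, member_genes=genes,
        signs=signs, inference_tscore=t, params=params,
    )


def _llr_activity(z: np.ndarray, params: dict, keep: np.ndarray | None = None) -> np.ndarray:
    idx = slice(None) if keep is None else keep
    mu_p, mu_n = params["mu_pos"][idx], params["mu_neg"][idx]
    v_p, v_n = params["var_pos"][idx], params["var_neg"][idx]
    ll_pos = -0.5 * (np.log(2 * np.pi * v_p)[:, None] + (z - mu_p[:, None]) ** 2 / v_p[:, None])
    ll_neg = -0.5 * (np.log(2 * np.pi * v_n)[:, None] + (z - mu_n[:, None]) ** 2 / v_n[:, None])
    return (ll_pos - ll_neg).sum(axis=0)


def project_activity(
    model: PathwayActivityModel, ds_target: ExpressionDataset
) -> np.ndarray:
    """Evaluate a frozen activity model on a (z-normalized) target cohort.

    Member genes missing from the target are dropped with a warning and the
    divisor (or loading/parameter vectors) adjusted to the survivors; if no
    member gene is present, a ValueError names the model.
    """
    gi = ds_target.gene_index()
    keep = np.array([g in gi for g in model.member_genes])
    if not keep.any():
        raise ValueError(
            f"model {model.pathway_id} ({model.method}): no member gene "
            f"present in cohort {ds_target.name}"
        )
    if not keep.all():
        missing = [g for g, k in zip(model.member_genes, keep) if not k]
        warnings.warn(
            f"model {model.pathway_id}: dropping members absent from "
            f"{ds_target.name}: {missing}", stacklevel=2,
        )
    genes = [g for g, k in zip(model.member_genes, keep) if k]
    z = ds_target.values[[gi[g] for g in genes], :]
    signs = model.signs[keep]
    m = len(genes)
    method = model.method
    if method in ("cmi", "corg"):
        div = float(m) if model.params.get("denominator", "j") == "j" else float(np.sqrt(m))
        return (z * signs[:, None]).sum(axis=0) / div
    if method == "mean":
        return z.mean(axis=0)
    if method == "median":
        return np.median(z, axis=0)
    if method == "pca":
        return np.asarray(model.params["loadings"])[keep] @ z
    if method == "llr":
        return _llr_activity(z, model.params, keep=keep)
    if method == "gene":
        return z[0]
    raise ValueError(f"unknown method {method!r}")


def rank_models(models: list[PathwayActivityModel]) -> list[PathwayActivityModel]:
    """Rank activity models by discriminative power on their inference cohort.

    Sign-aligned constructions (CMI, CORG) are ranked by descending signed
    t-score -- their activities are built to discriminate in the positive
    direction. Methods whose activity orientation is arbitrary relative to the
    phenotype (mean, median, gene; PCA is already oriented non-negative) rank
    by descending |t|, the sign being carried into any downstream product.
    """
    def key(m: PathwayActivityModel):
        t = m.inference_tscore
        score = t if m.method in _SIGN_ALIGNED else abs(t)
        return (-score, m.pathway_id)

    return sorted(models, key=key)


class PathwayActivityTransformer(BaseEstimator):
    """Infer pathway activities on one cohort and project them onto others.

    scikit-learn-style transformer over :class:`ExpressionDataset` objects:
    ``fit`` z-normalizes the inference cohort, computes per-gene t statistics,
    and infers one activity model per pathway with the configured method;
    ``transform`` z-normalizes the given cohort within itself and projects the
    fitted models onto it, returning an :class:`ActivityMatrix`.

    Parameters
    ----------
    pathways : PathwayCollection
        Gene sets to summarize.
    method : {"cmi", "corg", "mean", "median", "pca", "llr", "gene"}
    alpha : float
        DEG significance level for methods that use the DEG set.
    max_k : int
        Largest member count for the prefix searches (CMI/CORG).
    top_n : int or None
        If set, keep only the top-ranked ``top_n`` models after inference.
    denominator : {"j", "sqrt"}
        CMI prefix divisor convention.

    Attributes
    ----------
    models_ : list of PathwayActivityModel, ranked by discriminative power.
    stats_ : list of GeneStats on the inference cohort.
    inference_cohort_ : name of the cohort fitted on.
    """

    def __init__(self, pathways: PathwayCollection, method: str = "cmi",
                 alpha: float = 0.05, max_k: int = 20, top_n: int | None = None,
                 denominator: str = "j", equal_var: bool = True):
        self.pathways = pathways
        self.method = method
        self.alpha = alpha
        self.max_k = max_k
        self.top_n = top_n
        self.denominator = denominator
        self.equal_var = equal_var

    def fit(self, ds: ExpressionDataset, y=None) -> "PathwayActivityTransformer":
        zds = zscore_normalize(ds)
        stats = gene_stats(zds, alpha=self.alpha, equal_var=self.equal_var)
        method = self.method.lower()
        models: list[PathwayActivityModel] = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for pw in self.pathways:
                if method == "cmi":
                    got = infer_cmi(zds, stats, pw, max_k=self.max_k,
                                    denominator=self.denominator)
                elif method == "corg":
                    got = infer_corg(zds, stats, pw, max_k=self.max_k)
                else:
                    got = infer_simple(zds, stats, pw, method)
                if got is None:
                    continue
                models.extend(got if isinstance(got, list) else [got])
        models = rank_models(models)
        if self.top_n is not None:
            if len(models) < self.top_n:
                warnings.warn(
                    f"only {len(models)} inferable models (top_n={self.top_n}); "
                    "proceeding with all", stacklevel=2,
                )
            models = models[: self.top_n]
        self.models_ = models
        self.stats_ = stats
        self.inference_cohort_ = ds.name
        return self

    def transform(self, ds: ExpressionDataset) -> ActivityMatrix:
        if not hasattr(self, "models_"):
            raise RuntimeError("transformer is not fitted")
        zds = zscore_normalize(ds)
        rows, kept = [], []
        for m in self.models_:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rows.append(project_activity(m, zds))
                kept.append(m)
            except ValueError:
                warnings.warn(f"model {m.pathway_id} unprojectable onto "
                              f"{ds.name}; excluded", stacklevel=2)
        return ActivityMatrix(
            feature_ids=[m.pathway_id for m in kept],
            values=np.vstack(rows) if rows else np.empty((0, ds.n_samples)),
            labels=ds.labels,
            sample_ids=ds.sample_ids,
            source_models=kept,
        )

    def fit_transform(self, ds: ExpressionDataset, y=None) -> ActivityMatrix:
        return self.fit(ds).transform(ds)
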