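"""Labelled expression matrices for one cohort and per-gene differential statistics.

A cohort is a genes x samples real matrix with a binary phenotype per sample,
coded internally as -1 (control / good outcome) and +1 (case / poor outcome).
All downstream pathway-activity machinery operates on per-cohort z-scores, so
normalization and the two-sample t statistics live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "ExpressionDataset",
    "GeneStats",
    "read_expression",
    "zscore_normalize",
    "gene_stats",
    "t_statistics",
]


@dataclass
class ExpressionDataset:
    """One cohort: genes x samples expression values with binary labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene symbols, one per matrix row.
    sample_ids : list of str
        Unique sample identifiers, one per matrix column.
    values : ndarray of shape (n_genes, n_samples)
        Expression values in arbitrary units.
    labels : ndarray of shape (n_samples,)
        Phenotype per sample in {-1, +1}; +1 is the case class.
    name : str, optional
        Cohort identifier used in reports.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene identifiers: {sorted(dupes)}")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise ValueError(f"duplicate sample identifiers: {sorted(dupes)}")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be in {{-1, +1}}; found {sorted(bad)}")
        for cls in (-1, 1):
            if int(np.sum(self.labels == cls)) < 2:
                raise ValueError(f"need at least 2 samples of class {cls:+d}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneStats:
    """Two-sample t statistic for one gene (case vs control) and its DEG call."""

    gene_id: str
    tscore: float
    pvalue: float
    is_deg: bool
    alpha: float = 0.05


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression(
    path,
    labels_path=None,
    class_row: str = "CLASS",
    name: str | None = None,
    fold_case: bool = False,
) -> ExpressionDataset:
    """Read a cohort from a tab-separated matrix.

    The file's first column holds gene symbols and the header row holds sample
    identifiers. Labels come either from a row whose gene field equals
    ``class_row`` (values in {0,1} or {-1,+1}) or from a two-column side file
    ``labels_path`` of (sample_id, label). {0,1} codings are mapped to {-1,+1}.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    df.index = df.index.astype(str)
    labels: np.ndarray | None = None
    if class_row in df.index:
        labels = _coerce_labels(df.loc[class_row].to_numpy(), source=str(path))
        df = df.drop(index=class_row)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if labels_path is not None:
        side = pd.read_csv(labels_path, sep="\t", index_col=0, header=None, dtype=str)
        try:
            side = side.loc[df.columns]
        except KeyError as exc:
            raise ValueError(f"{labels_path}: missing labels for some samples") from exc
        labels = _coerce_labels(side.iloc[:, 0].to_numpy(), source=str(labels_path))
    if labels is None:
        raise ValueError(
            f"{path}: no '{class_row}' row found and no side label file given"
        )
    gene_ids = [g.upper() for g in df.index] if fold_case else list(df.index)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} at gene "
                    f"{gene_ids[i]!r}, sample {col!r}"
                ) from None
    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=list(df.columns),
        values=values,
        labels=labels,
        name=name or str(path),
    )


def _coerce_labels(raw: np.ndarray, source: str) -> np.ndarray:
    try:
        vals = np.asarray([int(float(v)) for v in raw])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{source}: non-numeric class label") from exc
    uniq = set(np.unique(vals))
    if uniq <= {0, 1}:
        vals = np.where(vals == 0, -1, 1)
    elif not uniq <= {-1, 1}:
        raise ValueError(f"{source}: labels must be coded 0/1 or -1/+1, got {sorted(uniq)}")
    for cls in (-1, 1):
        if int(np.sum(vals == cls)) < 2:
            raise ValueError(f"{source}: need at least 2 samples of each class")
    return vals


def zscore_normalize(ds: ExpressionDataset, ddof: int = 1) -> ExpressionDataset:
    """Return a copy with each gene row standardized to mean 0 and sd 1.

    Standardization is per cohort over all samples (both classes pooled).
    Zero-variance genes are set to all-zero rows with a warning so the gene
    universe stays aligned across cohorts.
    """
    mu = ds.values.mean(axis=1, keepdims=True)
    sd = ds.values.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel() | ~np.isfinite(sd).ravel()
    if flat.any():
        names = [ds.gene_ids[i] for i in np.nonzero(flat)[0][:10]]
        warnings.warn(
            f"{ds.name}: {int(flat.sum())} zero-variance gene(s) set to zero "
            f"(e.g. {names})",
            stacklevel=2,
        )
    sd = np.where(sd == 0, 1.0, sd)
    z = (ds.values - mu) / sd
    z[flat, :] = 0.0
    return replace(ds, values=z)


def t_statistics(
    values: np.ndarray, labels: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t statistics, case (+1) minus control (-1).

    Returns (t, p) arrays; two-tailed p-values. Rows with no variance in both
    groups get t = 0, p = 1.
    """
    case = values[:, labels == 1]
    ctrl = values[:, labels == -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = _sstats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    t = np.nan_to_num(np.asarray(res.statistic), nan=0.0)
    p = np.asarray(res.pvalue)
    p = np.where(np.isfinite(p), p, 1.0)
    return t, p


def gene_stats(
    ds: ExpressionDataset, alpha: float = 0.05, equal_var: bool = True
) -> list[GeneStats]:
    """Per-gene two-tailed two-sample t-test, case vs control.

    A gene is called differentially expressed (DEG) when its p-value is at or
    below ``alpha``. The t statistic is signed so that a positive value means
    higher mean expression in the case (+1) class. The pooled-variance test is
    the default; pass ``equal_var=False`` for Welch's test.
    """
    t, p = t_statistics(ds.values, ds.labels, equal_var=equal_var)
    return [
        GeneStats(gene_id=g, tscore=float(ti), pvalue=float(pi),
                  is_deg=bool(pi <= alpha), alpha=alpha)
        for g, ti, pi in zip(ds.gene_ids, t, p)
    ]
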