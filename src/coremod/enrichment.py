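"""Reference-gene-list enrichment of a marker signature.

Given a gene universe of size N containing M reference (e.g. known cancer)
genes, a signature of J genes with K reference genes among them is scored by
the hypergeometric tail probability P(X > K) of drawing more than K reference
genes in J draws without replacement, and by the plain enrichment rate K / J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom

__all__ = ["EnrichmentInput", "hypergeom_pvalue", "enrichment_rate", "read_gene_list"]


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts of a 2x2 enrichment setup: universe N, reference M, signature J, overlap K."""

    n_universe: int
    n_reference: int
    n_signature: int
    n_overlap: int

    def __post_init__(self) -> None:
        n, m, j, k = (self.n_universe, self.n_reference,
                      self.n_signature, self.n_overlap)
        if not (0 <= m <= n and 0 <= j <= n):
            raise ValueError("reference and signature sizes must lie within the universe")
        if not 0 <= k <= min(j, m):
            raise ValueError("overlap K must satisfy 0 <= K <= min(J, M)")


def hypergeom_pvalue(e: EnrichmentInput, inclusive: bool = False) -> float:
    """Tail probability of the reference-gene count in a random signature.

    Returns P(X > K) for X ~ Hypergeometric(N, M, J) — the strict inequality;
    ``inclusive=True`` gives the conventional P(X >= K). Numerically stable
    through scipy's survival function for universes up to ~1e5 genes.
    """
    k = e.n_overlap - 1 if inclusive else e.n_overlap
    return float(hypergeom.sf(k, e.n_universe, e.n_reference, e.n_signature))


def enrichment_rate(
    signature: set[str], reference: set[str], universe: set[str]
) -> tuple[float, EnrichmentInput]:
    """Fraction of signature genes that are reference genes, within a universe.

    Signature genes outside the universe are dropped with a warning. Returns
    the rate together with the counts needed for the hypergeometric p-value.
    """
    signature, reference, universe = set(signature), set(reference), set(universe)
    sig = signature & universe
    if len(sig) < len(signature):
        warnings.warn(
            f"{len(signature) - len(sig)} signature gene(s) outside the universe dropped",
            stacklevel=2,
        )
    if not sig:
        raise ValueError("no signature gene lies in the universe")
    ref = reference & universe
    overlap = sig & ref
    e = EnrichmentInput(
        n_universe=len(universe), n_reference=len(ref),
        n_signature=len(sig), n_overlap=len(overlap),
    )
    return len(overlap) / len(sig), e


def read_gene_list(path, fold_case: bool = False) -> set[str]:
    """Plain-text reference list: one gene symbol per line; blanks ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g:
                out.add(g.upper() if fold_case else g)
    return out
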