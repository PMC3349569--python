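"""Gene-set collections (GMT) and size/universe filtering.

Pathways are plain gene sets; topology is out of scope. Filtering restricts
each pathway to the gene universe shared by all cohorts under study and drops
sets that end up too small to be informative or too large ("bulky") to act as
a focused marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["Pathway", "PathwayCollection", "read_gmt", "filter_pathways"]


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"pathway {self.pathway_id!r} has no genes")

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class PathwayCollection:
    pathways: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway identifiers: {dupes}")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.gene_ids
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


def read_gmt(path, fold_case: bool = False) -> PathwayCollection:
    """Parse a tab-separated gene-set (GMT) file.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    genes within a line are collapsed. Malformed lines (fewer than three
    fields) and duplicate pathway names raise with the offending line number.
    """
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected name, "
                                 "description and at least one gene")
            name, desc = fields[0], fields[1]
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: no gene symbols")
            if fold_case:
                genes = [g.upper() for g in genes]
            pathways.append(Pathway(pathway_id=name, name=desc or name,
                                    gene_ids=frozenset(genes)))
    return PathwayCollection(pathways)


def filter_pathways(
    pc: PathwayCollection,
    shared_genes: set[str],
    min_size: int = 5,
    max_size: int = 200,
) -> tuple[PathwayCollection, pd.DataFrame]:
    """Restrict pathways to a shared gene universe and drop out-of-size sets.

    ``shared_genes`` should be the intersection of the gene universes of all
    cohorts in the study. Each pathway is intersected with it; the pathway is
    kept only when the surviving member count lies in [min_size, max_size].
    Returns the filtered collection and a per-pathway report of
    (pathway_id, original_size, filtered_size, kept).
    """
    if not shared_genes:
        raise ValueError("shared gene universe is empty")
    shared = set(shared_genes)
    kept: list[Pathway] = []
    rows = []
    for p in pc:
        genes = p.gene_ids & shared
        ok = min_size <= len(genes) <= max_size
        rows.append({"pathway_id": p.pathway_id, "original_size": p.size,
                     "filtered_size": len(genes), "kept": ok})
        if ok:
            kept.append(Pathway(p.pathway_id, p.name, frozenset(genes)))
    report = pd.DataFrame(rows, columns=["pathway_id", "original_size",
                                         "filtered_size", "kept"])
    return PathwayCollection(kept), report
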