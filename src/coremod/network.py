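"""Interaction-network exploration of a core module: hubs and driver genes.

The marker genes selected across cohorts are reassembled into the induced
subgraph of a gene-gene interaction network (e.g. a STRING export). Highly
connected "hub" genes that are also common marker genes are called the
module's driver genes; each gene is annotated with its regulation direction
across cohorts (up, down, or contradictory).
"""

from __future__ import annotations

import warnings

import networkx as nx

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "induced_subnetwork",
    "hub_genes",
    "driver_genes",
    "annotate_regulation",
    "functional_modules",
]


def read_edge_list(path, min_confidence: float = 0.0) -> nx.Graph:
    """Read an undirected gene-interaction TSV (gene_a, gene_b[, score]).

    Edges with a confidence score below ``min_confidence`` are dropped;
    self-loops are dropped with a warning; duplicate edges collapse (the
    larger score wins). Scores, when present, must lie in [0, 1].
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}: line {lineno}: expected 2 or 3 columns")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty gene symbol")
            score = None
            if len(fields) == 3:
                try:
                    score = float(fields[2])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric score {fields[2]!r}"
                    ) from None
                if not 0.0 <= score <= 1.0:
                    raise ValueError(f"{path}: line {lineno}: score outside [0, 1]")
            if a == b:
                warnings.warn(f"{path}: line {lineno}: self-loop {a} dropped",
                              stacklevel=2)
                continue
            if score is not None and score < min_confidence:
                continue
            if g.has_edge(a, b):
                old = g[a][b].get("weight")
                if score is not None and (old is None or score > old):
                    g[a][b]["weight"] = score
            else:
                g.add_edge(a, b, **({} if score is None else {"weight": score}))
    return g


def write_edge_list(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(net.edges(data=True)):
            w = data.get("weight")
            fh.write(f"{a}\t{b}" + ("" if w is None else f"\t{w}") + "\n")


def induced_subnetwork(net: nx.Graph, genes: set[str]) -> nx.Graph:
    """Subgraph on the given genes (isolated members kept as nodes)."""
    keep = set(genes) & set(net.nodes)
    return nx.Graph(net.subgraph(keep))


def hub_genes(net: nx.Graph, n_hubs: int = 20) -> list[str]:
    """Top-``n_hubs`` genes by degree (confidence-weighted when scores exist).

    Ties break by weighted degree, then lexicographically, so the ranking is
    stable under any input ordering.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(net.degree())
    wdeg = dict(net.degree(weight="weight"))
    ranked = sorted(net.nodes, key=lambda v: (-deg[v], -wdeg[v], v))
    return ranked[:n_hubs]


def driver_genes(hubs: list[str], common: set[str]) -> set[str]:
    """Hub genes that are also common marker genes."""
    return set(hubs) & set(common)


def annotate_regulation(
    genes: set[str], per_cohort_tscores: dict[str, dict[str, float]]
) -> dict[str, str]:
    """Regulation direction of each gene across cohorts.

    ``per_cohort_tscores`` maps cohort name -> {gene -> t-score}. A gene is
    "up" when t > 0 in every cohort where it was measured, "down" when t < 0
    in every one, otherwise "contradictory" (a zero t counts as no direction,
    hence contradictory).
    """
    out: dict[str, str] = {}
    for g in genes:
        ts = [c[g] for c in per_cohort_tscores.values() if g in c]
        if not ts:
            out[g] = "contradictory"
        elif all(t > 0 for t in ts):
            out[g] = "up"
        elif all(t < 0 for t in ts):
            out[g] = "down"
        else:
            out[g] = "contradictory"
    return out


def functional_modules(net: nx.Graph) -> dict[str, int]:
    """Heuristic module labels via greedy modularity communities.

    A convenience grouping for visualization only; singleton components get
    their own label. Falls back to connected components when the greedy
    search is not applicable (fewer than 2 edges).
    """
    if net.number_of_edges() < 2:
        comms = list(nx.connected_components(net))
    else:
        comms = list(nx.algorithms.community.greedy_modularity_communities(net))
    label: dict[str, int] = {}
    for i, comm in enumerate(sorted(comms, key=lambda c: (-len(c), sorted(c)))):
        for v in comm:
            label[v] = i
    return label
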