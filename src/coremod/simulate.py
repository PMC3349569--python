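"""Synthetic multi-cohort expression studies with driver/passenger structure.

The generator emulates the data-generating assumptions behind cross-cohort
core-module discovery: a small set of *driver* pathways whose member genes are
differentially expressed with a consistent direction in every cohort, plus
cohort-private *passenger* genes that are differentially expressed in exactly
one cohort, on top of i.i.d. noise. Driver genes are also wired as
high-degree nodes into a scale-free interaction network, so that the whole
pipeline -- inference, validation, core assembly, hub/driver extraction --
can be exercised against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .pathways import Pathway, PathwayCollection

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study", "write_study",
           "core_module_recovery"]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Effects are mean shifts applied to the case class, expressed in noise
    standard-deviation units. Driver pathways and their member shifts are
    shared (same genes, same directions) by every cohort; passenger genes are
    private to one cohort and disjoint across cohorts.
    """

    n_cohorts: int = 3
    n_genes: int = 1000
    samples_per_cohort: int = 100
    case_fraction: float = 0.5
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 20)
    n_driver_pathways: int = 5
    driver_effect: float = 0.8
    driver_member_count: int = 5
    n_passenger_degs_per_cohort: int = 25
    passenger_effect: float = 0.8
    noise_sd: float = 1.0
    noise: str = "gaussian"  # or "t" for heavier tails
    t_df: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cohorts, self.n_genes, self.samples_per_cohort,
               self.n_pathways) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid pathway_size_range")
        if self.n_driver_pathways > self.n_pathways:
            raise ValueError("more driver pathways than pathways")
        if self.driver_member_count > lo:
            raise ValueError("driver_member_count exceeds the smallest pathway size")
        if self.noise not in ("gaussian", "t"):
            raise ValueError("noise must be 'gaussian' or 't'")
        n_cases = round(self.samples_per_cohort * self.case_fraction)
        if n_cases < 2 or self.samples_per_cohort - n_cases < 2:
            raise ValueError("need at least 2 samples per class per cohort")


@dataclass
class SimulatedStudy:
    cohorts: list[ExpressionDataset]
    pathways: PathwayCollection
    network: nx.Graph
    driver_pathways: set[str]
    driver_genes: dict[str, int]  # gene -> shared shift sign
    passenger_genes: dict[str, dict[str, int]]  # cohort -> {gene -> sign}
    passenger_pathways: dict[str, set[str]]  # cohort -> pathways holding its passengers
    config: SimulationConfig = field(repr=False, default=None)

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "driver_pathway", "cohort": "", "pathway_id": p, "gene": "", "sign": 0}
            for p in sorted(self.driver_pathways)
        ]
        rows += [
            {"kind": "driver_gene", "cohort": "", "pathway_id": "", "gene": g, "sign": s}
            for g, s in sorted(self.driver_genes.items())
        ]
        for cohort in sorted(self.passenger_genes):
            rows += [
                {"kind": "passenger_gene", "cohort": cohort, "pathway_id": "",
                 "gene": g, "sign": s}
                for g, s in sorted(self.passenger_genes[cohort].items())
            ]
            rows += [
                {"kind": "passenger_pathway", "cohort": cohort, "pathway_id": p,
                 "gene": "", "sign": 0}
                for p in sorted(self.passenger_pathways[cohort])
            ]
        return pd.DataFrame(rows, columns=["kind", "cohort", "pathway_id", "gene", "sign"])


def _noise(rng: np.random.Generator, shape, cfg: SimulationConfig) -> np.ndarray:
    if cfg.noise == "gaussian":
        return rng.normal(0.0, cfg.noise_sd, size=shape)
    scale = cfg.noise_sd / np.sqrt(cfg.t_df / (cfg.t_df - 2))
    return rng.standard_t(cfg.t_df, size=shape) * scale


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate cohorts, pathways, network, and the ground-truth manifest.

    Driver pathways occupy a dedicated slice of the gene pool (mutually
    disjoint, no overlap with other pathways), so a "passenger-only" pathway
    is unambiguous: it contains a cohort's passenger genes and no driver
    gene. Passenger genes are sampled from non-driver pathway members,
    disjointly across cohorts. The interaction network is scale-free with
    extra edges attached to driver genes to make them hubs.
    """
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    pool = list(rng.permutation(genes))
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    if int(sizes[: cfg.n_driver_pathways].sum()) > cfg.n_genes:
        raise ValueError("not enough genes for disjoint driver pathways")

    pathways: list[Pathway] = []
    driver_pathways: set[str] = set()
    driver_genes: dict[str, int] = {}
    cursor = 0
    pw_width = max(3, len(str(cfg.n_pathways)))
    for i in range(cfg.n_driver_pathways):
        pid = f"PW{i + 1:0{pw_width}d}"
        members = pool[cursor: cursor + int(sizes[i])]
        cursor += int(sizes[i])
        pathways.append(Pathway(pid, f"driver pathway {pid}", frozenset(members)))
        driver_pathways.add(pid)
        picked = rng.choice(len(members), size=cfg.driver_member_count, replace=False)
        for idx in picked:
            driver_genes[members[idx]] = int(rng.choice([-1, 1]))
    rest = pool[cursor:]
    if len(rest) < hi:
        raise ValueError("gene pool too small for non-driver pathways")
    for i in range(cfg.n_driver_pathways, cfg.n_pathways):
        pid = f"PW{i + 1:0{pw_width}d}"
        members = rng.choice(len(rest), size=int(sizes[i]), replace=False)
        pathways.append(Pathway(pid, f"pathway {pid}",
                                frozenset(rest[j] for j in members)))
    pc = PathwayCollection(pathways)

    nondriver_universe = sorted(
        set().union(*(p.gene_ids for p in pathways[cfg.n_driver_pathways:]))
    ) if cfg.n_pathways > cfg.n_driver_pathways else []
    need = cfg.n_cohorts * cfg.n_passenger_degs_per_cohort
    if need > len(nondriver_universe):
        raise ValueError(
            f"cannot place {need} disjoint passenger genes in a non-driver "
            f"universe of {len(nondriver_universe)} genes"
        )
    shuffled = list(rng.permutation(nondriver_universe))

    gene_pos = {g: i for i, g in enumerate(genes)}
    n_cases = round(cfg.samples_per_cohort * cfg.case_fraction)
    labels = np.array([1] * n_cases + [-1] * (cfg.samples_per_cohort - n_cases))
    shift = cfg.driver_effect * cfg.noise_sd
    pshift = cfg.passenger_effect * cfg.noise_sd

    cohorts: list[ExpressionDataset] = []
    passenger_genes: dict[str, dict[str, int]] = {}
    passenger_pathways: dict[str, set[str]] = {}
    for c in range(cfg.n_cohorts):
        name = f"cohort{c + 1}"
        values = _noise(rng, (cfg.n_genes, cfg.samples_per_cohort), cfg)
        for g, s in driver_genes.items():
            values[gene_pos[g], labels == 1] += s * shift
        mine = shuffled[c * cfg.n_passenger_degs_per_cohort:
                        (c + 1) * cfg.n_passenger_degs_per_cohort]
        pg = {g: int(rng.choice([-1, 1])) for g in mine}
        for g, s in pg.items():
            values[gene_pos[g], labels == 1] += s * pshift
        passenger_genes[name] = pg
        passenger_pathways[name] = {
            p.pathway_id for p in pathways[cfg.n_driver_pathways:]
            if p.gene_ids & set(mine)
        }
        samples = [f"{name}_S{j + 1:04d}" for j in range(cfg.samples_per_cohort)]
        cohorts.append(ExpressionDataset(genes, samples, values, labels.copy(),
                                         name=name))

    network = _build_network(rng, pc, driver_genes)
    return SimulatedStudy(
        cohorts=cohorts, pathways=pc, network=network,
        driver_pathways=driver_pathways, driver_genes=driver_genes,
        passenger_genes=passenger_genes, passenger_pathways=passenger_pathways,
        config=cfg,
    )


def _build_network(rng: np.random.Generator, pc: PathwayCollection,
                   driver_genes: dict[str, int]) -> nx.Graph:
    """Scale-free backbone over pathway genes with driver genes as hubs."""
    nodes = sorted(pc.universe)
    base = nx.barabasi_albert_graph(len(nodes), m=2,
                                    seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(base, dict(enumerate(nodes)))
    max_base = max(d for _, d in g.degree)
    boost = max_base + 5
    pool = [v for v in nodes if v not in driver_genes]
    for gene in sorted(driver_genes):
        extra = rng.choice(len(pool), size=min(boost, len(pool)), replace=False)
        for j in extra:
            g.add_edge(gene, pool[j], weight=round(float(rng.uniform(0.7, 1.0)), 3))
    return g


def core_module_recovery(
    core_pathways: set[str], study: SimulatedStudy
) -> tuple[float, float]:
    """Sensitivity for driver pathways, specificity against passenger-only ones.

    Sensitivity is the fraction of planted driver pathways present in the
    recovered core; specificity is the fraction of pathways carrying only
    cohort-private passenger signal that were (correctly) excluded.
    """
    core = set(core_pathways)
    drivers = study.driver_pathways
    passenger_only = set().union(*study.passenger_pathways.values()) - drivers
    sens = len(core & drivers) / len(drivers) if drivers else float("nan")
    spec = (1.0 - len(core & passenger_only) / len(passenger_only)
            if passenger_only else float("nan"))
    return sens, spec


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write cohorts (TSV with a CLASS row), GMT, edge list, and truth TSV."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for ds in study.cohorts:
        p = out / f"{ds.name}.tsv"
        frame = ds.to_frame()
        with open(p, "w") as fh:
            fh.write("gene\t" + "\t".join(ds.sample_ids) + "\n")
            fh.write("CLASS\t" + "\t".join(str(int(l)) for l in ds.labels) + "\n")
            for g, row in zip(ds.gene_ids, frame.to_numpy()):
                fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
        paths[ds.name] = str(p)
    gmt = out / "pathways.gmt"
    with open(gmt, "w") as fh:
        for pw in study.pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.gene_ids)]) + "\n")
    paths["gmt"] = str(gmt)
    edges = out / "network.tsv"
    from .network import write_edge_list
    write_edge_list(study.network, edges)
    paths["network"] = str(edges)
    truth = out / "truth.tsv"
    study.truth_frame().to_csv(truth, sep="\t", index=False)
    paths["truth"] = str(truth)
    return paths
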