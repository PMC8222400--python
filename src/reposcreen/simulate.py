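"""Synthetic benchmark data with the structure the pipeline assumes.

Real inputs to this kind of screen — curated disease-gene databases, a
confidence-filtered interactome, drug–target tables, perturbation
signatures and a case/control expression cohort — are all external
downloads.  This module generates stand-ins with the planted statistical
structure the analysis is designed to detect, so every downstream stage
is testable end to end:

* a scale-free (preferential-attachment, m=2) or Erdős–Rényi network of
  synthetic gene symbols, reconnected into one component;
* a disease module grown by seeded neighborhood expansion, so disease
  genes interact (its induced subgraph is connected);
* "proximal" drugs whose targets sit in the module or its first
  neighbors, and "distal" drugs targeting nodes >= 3 hops from every
  disease gene;
* perturbation profiles in which hit drugs shift the disease genes
  toward one rank extreme by a fixed effect;
* a log-normal expression matrix with differentially expressed genes
  shifted in cases by a stated standardized effect size.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidParameterError
from .genesets import GeneSet, write_gmt
from .network import InteractionNetwork, write_edge_table
from .proximity import DrugTargetMap, write_drug_targets

__all__ = [
    "SyntheticScenario",
    "SyntheticData",
    "generate_network",
    "plant_disease_module",
    "generate_drug_targets",
    "generate_perturbation_profiles",
    "generate_expression",
    "write_profiles",
    "write_expression",
]


def _symbol(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_network(
    n_genes: int,
    network_model: str = "scale_free",
    seed: int = 0,
) -> InteractionNetwork:
    """Random interactome over synthetic symbols G0001..; one component.

    ``scale_free`` uses preferential attachment with m=2 edges per new
    node (heavy-tailed degrees, like real interactomes);
    ``erdos_renyi`` matches its expected edge count (p = 4/(n-1)).
    Disconnected components are reattached to the giant component by one
    edge each.
    """
    if n_genes < 10:
        raise InvalidParameterError(f"n_genes must be >= 10, got {n_genes}")
    if network_model == "scale_free":
        g = nx.barabasi_albert_graph(n_genes, m=2, seed=seed)
    elif network_model == "erdos_renyi":
        g = nx.gnp_random_graph(n_genes, p=4.0 / (n_genes - 1), seed=seed)
    else:
        raise InvalidParameterError(f"unknown network_model {network_model!r}")
    g.remove_edges_from(nx.selfloop_edges(g))
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    if len(components) > 1:
        rng = np.random.default_rng(seed)
        giant = sorted(components[0])
        for comp in components[1:]:
            a = sorted(comp)[rng.integers(len(comp))]
            b = giant[rng.integers(len(giant))]
            g.add_edge(a, b)
    g = nx.relabel_nodes(g, {i: _symbol(i) for i in g.nodes})
    return InteractionNetwork(g)


def plant_disease_module(
    network: InteractionNetwork, module_size: int, seed: int = 0
) -> GeneSet:
    """Grow a connected disease module by breadth-first expansion.

    Starting from a random seed node, neighbors are visited in random
    order until ``module_size`` genes are collected; because the set is
    grown along edges its induced subgraph has at least
    ``module_size - 1`` internal edges.
    """
    nodes = sorted(network.graph.nodes)
    if module_size > len(nodes):
        raise InvalidParameterError(
            f"module_size {module_size} exceeds node count {len(nodes)}"
        )
    if module_size < 1:
        raise InvalidParameterError("module_size must be >= 1")
    rng = np.random.default_rng(seed)
    start = nodes[rng.integers(len(nodes))]
    picked: list[str] = []
    seen = {start}
    frontier = [start]
    while frontier and len(picked) < module_size:
        node = frontier.pop(0)
        picked.append(node)
        neigh = sorted(set(network.graph[node]) - seen)
        rng.shuffle(neigh)
        seen.update(neigh)
        frontier.extend(neigh)
    while len(picked) < module_size:  # disconnected leftovers (rare)
        rest = sorted(set(nodes) - set(picked))
        picked.append(rest[rng.integers(len(rest))])
    genes = set(picked[:module_size])
    return GeneSet(
        name="synthetic_disease",
        genes=genes,
        provenance={g: {"planted_module"} for g in genes},
    )


def generate_drug_targets(
    network: InteractionNetwork,
    disease_set: Iterable[str],
    tier: str,
    targets_per_drug: int,
    n_drugs: int,
    seed: int = 0,
) -> DrugTargetMap:
    """Drug target sets at a controlled network distance from the module.

    ``proximal`` drugs draw targets from the disease set and its first
    neighbors; ``distal`` drugs from nodes at shortest-path distance
    >= 3 from every disease gene (falling back to the maximum-distance
    nodes if that pool is empty).
    """
    if tier not in ("proximal", "distal"):
        raise InvalidParameterError(f"tier must be proximal/distal, got {tier!r}")
    if targets_per_drug < 1:
        raise InvalidParameterError("targets_per_drug must be >= 1")
    if n_drugs < 0:
        raise InvalidParameterError("n_drugs must be >= 0")
    G = set(disease_set) & network.nodes
    dtm = DrugTargetMap()
    if n_drugs == 0:
        return dtm
    dist = network.multi_source_distances(G)
    if tier == "proximal":
        pool = set(G)
        for g in G:
            pool |= set(network.graph[g])
        pool = sorted(pool)
    else:
        pool = sorted(n for n, d in dist.items() if d >= 3)
        if not pool:
            finite = {n: d for n, d in dist.items() if np.isfinite(d) and d > 0}
            if finite:
                dmax = max(finite.values())
                pool = sorted(n for n, d in finite.items() if d == dmax)
    if len(pool) < targets_per_drug:
        raise GenerationError(
            f"tier '{tier}': eligible pool has {len(pool)} node(s), "
            f"need {targets_per_drug}"
        )
    rng = np.random.default_rng(seed)
    prefix = "PROX" if tier == "proximal" else "DIST"
    for i in range(n_drugs):
        targets = rng.choice(pool, size=targets_per_drug, replace=False)
        drug_id = f"{prefix}{i + 1:03d}"
        dtm.add(drug_id, f"{tier}_drug_{i + 1}", targets.tolist())
    return dtm


def generate_perturbation_profiles(
    gene_universe: Sequence[str],
    disease_set: Iterable[str],
    hit_drugs: Sequence[str],
    null_drugs: Sequence[str],
    effect: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes x drugs matrix of differential statistics.

    Every entry is standard normal; for hit drugs, the disease genes
    receive an added shift of magnitude ``effect`` whose sign is fixed
    per drug (drawn once), concentrating them at one rank extreme.
    """
    if effect < 0:
        raise InvalidParameterError("effect must be >= 0")
    universe = list(gene_universe)
    members = set(disease_set)
    if not members <= set(universe):
        raise InvalidParameterError("disease_set must be within gene_universe")
    rng = np.random.default_rng(seed)
    drugs = list(hit_drugs) + list(null_drugs)
    data = rng.standard_normal((len(universe), len(drugs)))
    mask = np.fromiter((g in members for g in universe), bool, count=len(universe))
    for j, drug in enumerate(drugs):
        if drug in set(hit_drugs):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[mask, j] += sign * effect
    return pd.DataFrame(data, index=universe, columns=drugs)


def generate_expression(
    gene_universe: Sequence[str],
    de_genes: Iterable[str],
    de_effect: float = 2.0,
    n_case: int = 20,
    n_control: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal expression matrix with planted case/control DE genes.

    Per-gene log2 values are Gaussian (baseline mean ~ N(8, 1), unit
    within-group sd); ``de_genes`` are shifted by ``de_effect`` standard
    deviations in cases.  Values are 2**log2, so the pipeline's log2
    step recovers Gaussian data.  Returns the matrix and a sample->group
    label Series aligned to its columns.
    """
    if n_case < 2 or n_control < 2:
        raise InvalidParameterError("n_case and n_control must be >= 2")
    if de_effect < 0:
        raise InvalidParameterError("de_effect must be >= 0")
    universe = list(gene_universe)
    de = set(de_genes)
    if not de <= set(universe):
        raise InvalidParameterError("de_genes must be within gene_universe")
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    baseline = rng.normal(8.0, 1.0, size=len(universe))[:, None]
    log2vals = baseline + rng.standard_normal((len(universe), n))
    mask = np.fromiter((g in de for g in universe), bool, count=len(universe))
    log2vals[mask, :n_case] += de_effect
    samples = [f"CASE{i + 1:03d}" for i in range(n_case)] + [
        f"CTRL{i + 1:03d}" for i in range(n_control)
    ]
    labels = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples, name="group"
    )
    return (
        pd.DataFrame(2.0 ** log2vals, index=universe, columns=samples),
        labels,
    )


# ---------------------------------------------------------------------------
# Scenario bundle


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study; generation is pure in (fields, seed).

    Defaults describe the benchmark conditions used throughout the test
    suite: a 1000-gene scale-free interactome with a 50-gene disease
    module, ten proximal and ten distal drugs with five targets each,
    and planted effects of two standard deviations in both the
    perturbation profiles and the expression cohort (20 cases vs 20
    controls).
    """

    n_genes: int = 1000
    network_model: str = "scale_free"
    module_size: int = 50
    n_drugs_proximal: int = 10
    n_drugs_distal: int = 10
    targets_per_drug: int = 5
    perturbation_effect: float = 2.0
    de_effect: float = 2.0
    n_case: int = 20
    n_control: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise InvalidParameterError("module_size must be <= n_genes")
        if min(self.n_drugs_proximal, self.n_drugs_distal) < 0:
            raise InvalidParameterError("drug counts must be >= 0")

    def generate(self) -> "SyntheticData":
        seed = self.seed
        network = generate_network(self.n_genes, self.network_model, seed)
        disease = plant_disease_module(network, self.module_size, seed + 1)
        prox = generate_drug_targets(
            network, disease.genes, "proximal", self.targets_per_drug,
            self.n_drugs_proximal, seed + 2,
        )
        dist = generate_drug_targets(
            network, disease.genes, "distal", self.targets_per_drug,
            self.n_drugs_distal, seed + 3,
        )
        drug_targets = DrugTargetMap()
        for entry in list(prox) + list(dist):
            drug_targets.add(entry.drug_id, entry.drug_name, entry.targets)
        universe = sorted(network.graph.nodes)
        profiles = generate_perturbation_profiles(
            universe,
            disease.genes,
            hit_drugs=sorted(prox.drugs),
            null_drugs=sorted(dist.drugs),
            effect=self.perturbation_effect,
            seed=seed + 4,
        )
        expression, labels = generate_expression(
            universe,
            disease.genes,
            de_effect=self.de_effect,
            n_case=self.n_case,
            n_control=self.n_control,
            seed=seed + 5,
        )
        return SyntheticData(
            scenario=self,
            network=network,
            disease=disease,
            drug_targets=drug_targets,
            proximal_drugs=sorted(prox.drugs),
            distal_drugs=sorted(dist.drugs),
            profiles=profiles,
            expression=expression,
            labels=labels,
        )


@dataclass
class SyntheticData:
    """One realised synthetic study, with writers for every input format."""

    scenario: SyntheticScenario
    network: InteractionNetwork
    disease: GeneSet
    drug_targets: DrugTargetMap
    proximal_drugs: list[str]
    distal_drugs: list[str]
    profiles: pd.DataFrame
    expression: pd.DataFrame
    labels: pd.Series
    paths: dict[str, Path] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all pipeline input files under ``out_dir``.

        The disease module is split into three overlapping pseudo-sources
        in the GMT so the merge/provenance stage is exercised; scored
        edges all carry combined_score 0.95 (above any sensible cutoff).
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genes = sorted(self.disease.genes)
        third = max(len(genes) // 3, 1)
        sources = {
            "sourceA": genes[: 2 * third],
            "sourceB": genes[third:],
            "sourceC": genes[::2],
        }
        paths = {
            "disease_sources": out / "disease_sources.gmt",
            "ppi_edges": out / "ppi_edges.tsv",
            "drug_targets": out / "drug_targets.tsv",
            "profiles": out / "profiles.tsv",
            "expression": out / "expression.tsv",
            "labels": out / "labels.tsv",
        }
        write_gmt(sources, paths["disease_sources"])
        with open(paths["ppi_edges"], "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for a, b in sorted(self.network.edges):
                fh.write(f"{a}\t{b}\t0.95\n")
        write_drug_targets(self.drug_targets, paths["drug_targets"])
        write_profiles(self.profiles, paths["profiles"])
        write_expression(self.expression, self.labels,
                         paths["expression"], paths["labels"])
        self.paths = paths
        return paths


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x drug TSV (index column ``gene``)."""
    profiles.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def write_expression(
    expression: pd.DataFrame,
    labels: pd.Series,
    expr_path: str | Path,
    labels_path: str | Path,
) -> None:
    expression.to_csv(expr_path, sep="\t", index_label="gene",
                      float_format="%.6g")
    with open(labels_path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in labels.items():
            fh.write(f"{sample}\t{group}\n")
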