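"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: random gene
networks with planted dense modules, two-condition spectral-count
tables with planted upregulation and decoy identifications, annotation
collections with exact designed overlaps, paired array-intensity
vectors with a set correlation, and a deterministic identification
table with a prescribed batch-presence tier structure.

All generators are pure functions of their parameters and seed, using
numpy's PCG64 generator (``numpy.random.default_rng``), so outputs are
reproducible across runs and platforms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSetCollection, IdentificationTable

DEFAULT_DISPERSION = 0.1   # mild overdispersion; 0 recovers exact Poisson


@dataclass
class SimTruth:
    """Ground truth of a simulation, for measuring recovery."""

    params: dict = field(default_factory=dict)
    module_members: set[str] = field(default_factory=set)
    up_proteins: set[str] = field(default_factory=set)
    up_genes: set[str] = field(default_factory=set)
    decoy_proteins: set[str] = field(default_factory=set)
    annotation_design: dict[str, tuple[int, int]] = field(default_factory=dict)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def gen_network(n: int, model: str = "erdos_renyi", param: float = 0.05,
                seed: int = 0) -> nx.Graph:
    """Random background gene network.

    ``model`` is "erdos_renyi" (param = edge probability) or
    "preferential_attachment" (param = integer number of edges each new
    node attaches, degree-proportionally, to existing nodes — the
    standard Barabasi-Albert rule).  Nodes are labelled G00000...
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if model == "erdos_renyi":
        if not (0 <= param <= 1):
            raise ValueError("edge probability must lie in [0, 1]")
        g = nx.gnp_random_graph(n, param, seed=int(seed))
    elif model == "preferential_attachment":
        m = int(param)
        if m < 1 or m >= n:
            raise ValueError("attachment edges must satisfy 1 <= m < n")
        g = nx.barabasi_albert_graph(n, m, seed=int(seed))
    else:
        raise ValueError(f"unknown model {model!r}")
    return nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})


def plant_module(net: nx.Graph, size: int, density: float, seed: int = 0,
                 ) -> tuple[nx.Graph, SimTruth]:
    """Plant a dense module: pick ``size`` nodes uniformly and add each
    absent within-pair edge independently with probability ``density``.

    Never removes edges; returns a copy plus the truth record.
    """
    if size > net.number_of_nodes():
        raise ValueError("module size exceeds network size")
    if not (0 <= density <= 1):
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    members = sorted(rng.choice(np.array(nodes), size=size, replace=False))
    g = net.copy()
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if not g.has_edge(a, b) and rng.random() < density:
                g.add_edge(a, b)
    truth = SimTruth(params={"size": size, "density": density, "seed": seed},
                     module_members=set(members))
    return g, truth


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
               shape: tuple[int, ...]) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws; dispersion 0 is Poisson.

    Var = mean + dispersion * mean², the standard ecological/RNA-seq
    parameterisation.
    """
    if dispersion == 0:
        return rng.poisson(np.broadcast_to(mean, shape))
    lam = rng.gamma(shape=1.0 / dispersion,
                    scale=np.broadcast_to(mean, shape) * dispersion)
    return rng.poisson(lam)


def gen_counts(n_proteins: int = 500, n_up: int = 50, rate_ratio: float = 8.0,
               batches: int = 3, mean_count: float = 10.0,
               dispersion: float = DEFAULT_DISPERSION, seed: int = 0,
               decoy_fraction: float = 0.05,
               conditions: tuple[str, str] = ("treated", "control"),
               ) -> tuple[IdentificationTable, SimTruth]:
    """Two-condition spectral-count table with planted upregulation.

    Control counts per batch are negative binomial with the given mean
    and dispersion; the first ``n_up`` proteins get mean x ``rate_ratio``
    in the treated condition.  True proteins draw identification FDRs
    below 0.01; a ``decoy_fraction`` of proteins draw FDRs above it (so
    the inclusion filter has nontrivial work).  Genes map 1:1 to
    proteins.  The truth lists up and decoy proteins.
    """
    if n_up > n_proteins:
        raise ValueError("n_up must not exceed n_proteins")
    if rate_ratio <= 0 or batches < 1 or dispersion < 0:
        raise ValueError("invalid generator parameters")
    rng = np.random.default_rng(seed)
    prot = np.array([f"P{i:05d}" for i in range(n_proteins)])
    gene = np.array([_gene_name(i) for i in range(n_proteins)])
    up_mask = np.zeros(n_proteins, dtype=bool)
    up_mask[:n_up] = True
    n_decoy = int(round(decoy_fraction * n_proteins))
    decoy_idx = rng.choice(n_proteins, size=n_decoy, replace=False)
    fdr = rng.uniform(0.0, 0.009, size=n_proteins)
    fdr[decoy_idx] = rng.uniform(0.011, 0.5, size=n_decoy)

    treated_mean = np.where(up_mask, mean_count * rate_ratio, mean_count)
    rows = []
    for cond, means in ((conditions[0], treated_mean),
                        (conditions[1], np.full(n_proteins, mean_count))):
        counts = _nb_counts(rng, means[:, None], dispersion,
                            (n_proteins, batches))
        for b in range(batches):
            rows.append(pd.DataFrame({
                "protein_id": prot, "gene_id": gene, "condition": cond,
                "batch": f"b{b + 1}", "spectral_count": counts[:, b],
                "fdr": fdr}))
    frame = pd.concat(rows, ignore_index=True)
    truth = SimTruth(
        params={"n_proteins": n_proteins, "n_up": n_up,
                "rate_ratio": rate_ratio, "batches": batches,
                "mean_count": mean_count, "dispersion": dispersion,
                "seed": seed, "decoy_fraction": decoy_fraction},
        up_proteins=set(prot[up_mask]), up_genes=set(gene[up_mask]),
        decoy_proteins=set(prot[decoy_idx]))
    return IdentificationTable(frame), truth


def gen_annotations(universe: set[str],
                    designs: dict[str, tuple[int, int]],
                    query: set[str], seed: int = 0,
                    ) -> tuple[GeneSetCollection, SimTruth]:
    """Annotation sets with exact designed overlap against a query set.

    Each design maps a set name to (K, k_target): the set gets exactly
    ``k_target`` members from ``query`` and K - k_target fillers from
    ``universe`` minus ``query``, so downstream enrichment counts are
    integer-exact by construction.
    """
    rng = np.random.default_rng(seed)
    query = set(query) & set(universe)
    outside = np.array(sorted(set(universe) - query))
    qarr = np.array(sorted(query))
    sets: dict[str, set[str]] = {}
    for name in sorted(designs):
        K, k = designs[name]
        if k > K:
            raise ValueError(f"{name}: k_target {k} exceeds K {K}")
        if k > len(qarr):
            raise ValueError(f"{name}: k_target {k} exceeds query size "
                             f"{len(qarr)}")
        if K - k > len(outside):
            raise ValueError(f"{name}: needs {K - k} fillers but only "
                             f"{len(outside)} genes lie outside the query")
        inside = rng.choice(qarr, size=k, replace=False) if k else []
        fillers = (rng.choice(outside, size=K - k, replace=False)
                   if K - k else [])
        sets[name] = set(inside) | set(fillers)
    truth = SimTruth(params={"seed": seed},
                     annotation_design=dict(designs))
    return GeneSetCollection(sets=sets), truth


def gen_paired_arrays(n: int = 90, target_r: float = 0.938, seed: int = 0,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Paired array-intensity vectors with population correlation
    ``target_r`` (bivariate normal construction); the default emulates
    a 90-protein cytokine-array comparison with r² near 0.88.
    """
    if not (-1 < target_r < 1):
        raise ValueError("|target_r| must be < 1")
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    y = target_r * x + np.sqrt(1.0 - target_r ** 2) * eps
    return x, y


def tiered_identification_table(
        exact_tier_proteins: tuple[int, int, int] = (602, 330, 591),
        exact_tier_genes: tuple[int, int, int] = (301, 154, 320),
        condition: str = "NBE",
        batches: tuple[str, ...] = ("b1", "b2", "b3"),
        ) -> IdentificationTable:
    """Deterministic synthetic table with a prescribed tier structure.

    ``exact_tier_proteins[t]`` proteins are present in exactly t+1
    batches (count 2 where present, 0 elsewhere, identification FDR
    0.001), and ``exact_tier_genes[t]`` genes have maximal protein tier
    exactly t+1.  The defaults reconstruct the printed NBE tier
    structure — cumulative protein tiers 1,523 / 921 / 591 and gene
    tiers 775 / 474 / 320 — as a stand-in for the study's unreleased
    supplementary protein lists (synthetic; no real identifiers).

    Leftover proteins of an exact tier (beyond one anchor protein per
    gene of that tier) are assigned round-robin to genes whose tier is
    at least as high, which leaves every gene's maximal tier unchanged.
    """
    n_tiers = len(batches)
    if len(exact_tier_proteins) != n_tiers or len(exact_tier_genes) != n_tiers:
        raise ValueError("need one protein and gene count per tier")
    for t in range(n_tiers):
        if exact_tier_genes[t] > exact_tier_proteins[t]:
            raise ValueError(f"tier {t + 1}: more genes than proteins")
    # genes, labelled by their exact tier
    genes_by_tier: dict[int, list[str]] = {}
    gi = 0
    for t in range(n_tiers):
        genes_by_tier[t] = [f"SYNGENE{gi + j:04d}"
                            for j in range(exact_tier_genes[t])]
        gi += exact_tier_genes[t]
    rows = []
    pi = 0

    def add_protein(gene: str, tier: int) -> None:
        nonlocal pi
        prot = f"SYNPROT{pi:04d}"
        pi += 1
        for b in range(n_tiers):
            rows.append((prot, gene, condition, batches[b],
                         2 if b <= tier else 0, 0.001))

    for t in range(n_tiers):
        # one anchor protein per gene of this exact tier
        for gene in genes_by_tier[t]:
            add_protein(gene, t)
        # leftovers go to genes with tier >= t (tier unchanged)
        leftover = exact_tier_proteins[t] - exact_tier_genes[t]
        hosts = [g for tt in range(t, n_tiers) for g in genes_by_tier[tt]]
        for j in range(leftover):
            add_protein(hosts[j % len(hosts)], t)
    frame = pd.DataFrame(rows, columns=["protein_id", "gene_id", "condition",
                                        "batch", "spectral_count", "fdr"])
    return IdentificationTable(frame)


def write_fixture_dir(out_dir: str | Path, seed: int = 0,
                      n_proteins: int = 500, n_up: int = 50,
                      rate_ratio: float = 8.0, batches: int = 3,
                      mean_count: float = 10.0,
                      dispersion: float = DEFAULT_DISPERSION,
                      network_nodes: int = 1000, edge_prob: float = 0.01,
                      module_density: float = 0.5) -> dict:
    """Write a complete synthetic fixture directory.

    Produces identifications.tsv, network.tsv, categories.gmt,
    vesicles.gmt and truth.json.  The planted network module is the set
    of truly upregulated genes, so the coherence stage has a positive
    control; the four category sets and a vesicle set are built with
    designed overlaps against the simulated proteome.
    """
    import json

    from .io import write_gmt, write_identification_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = gen_counts(n_proteins=n_proteins, n_up=n_up,
                              rate_ratio=rate_ratio, batches=batches,
                              mean_count=mean_count, dispersion=dispersion,
                              seed=seed)
    write_identification_table(table, out / "identifications.tsv")

    net = gen_network(max(network_nodes, n_proteins), "erdos_renyi",
                      edge_prob, seed=seed + 1)
    # plant the module exactly on the truly upregulated genes
    rng = np.random.default_rng(seed + 2)
    members = sorted(truth.up_genes)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if not net.has_edge(a, b) and rng.random() < module_density:
                net.add_edge(a, b)
    with open(out / "network.tsv", "w") as fh:
        for a, b in sorted(map(lambda e: tuple(sorted(e)), net.edges)):
            fh.write(f"{a}\t{b}\n")

    universe = {_gene_name(i) for i in range(max(network_nodes, n_proteins))}
    proteome_genes = {_gene_name(i) for i in range(n_proteins)}
    quarter = max(1, n_proteins // 10)
    designs = {name: (4 * quarter, quarter) for name in
               ("angiogenesis", "anti_inflammation", "neurogenesis",
                "apoptosis")}
    categories, cat_truth = gen_annotations(universe, designs,
                                            query=proteome_genes,
                                            seed=seed + 3)
    write_gmt(categories, out / "categories.gmt")
    # vesicle set covers ~80% of the proteome but only ~20% of the rest
    # of the universe, so observed coverage beats the random baseline
    k_ves = int(0.8 * n_proteins)
    fillers = int(0.2 * (len(universe) - n_proteins))
    vesicles, _ = gen_annotations(
        universe, {"vesicular": (k_ves + fillers, k_ves)},
        query=proteome_genes, seed=seed + 4)
    write_gmt(vesicles, out / "vesicles.gmt")

    truth_doc = {
        "params": truth.params,
        "up_proteins": sorted(truth.up_proteins),
        "up_genes": sorted(truth.up_genes),
        "decoy_proteins": sorted(truth.decoy_proteins),
        "module_members": members,
        "module_density": module_density,
        "annotation_design": {k: list(v) for k, v in
                              cat_truth.annotation_design.items()},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth_doc
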