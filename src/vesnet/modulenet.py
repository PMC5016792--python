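"""GO-category-filtered module ("therapeutic") network construction.

Filters a proteome's genes by four functional categories (angiogenesis,
anti-inflammation, neurogenesis, apoptosis), tests each category's
enrichment, projects the selection onto a gene network, labels
connected components, and annotates nodes with category membership,
upregulation and fold change.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSetCollection, normalize_gene
from .stats import EnrichmentResult, bh_fdr, hypergeometric_enrichment

DEFAULT_CATEGORIES = ("angiogenesis", "anti_inflammation",
                      "neurogenesis", "apoptosis")


class ConfigError(ValueError):
    pass


@dataclass
class TherapeuticNetwork:
    """Projected subnetwork of category-selected genes.

    Node attributes on ``graph``: one boolean flag per category, one
    fractional attribute per category (flags normalized to sum to 1
    over the node's true flags), ``upregulated`` flag, ``fold_change``
    (max |log2FC| over the gene's proteins; None when not upregulated),
    and ``component`` id.  Isolated selected genes are retained (their
    component has size 1) so "X of Y genes connected" stays computable.
    """

    graph: nx.Graph
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    component_sizes: dict[int, int] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def connected_genes(self) -> set[str]:
        """Genes in components of size >= 2 (i.e. with at least one link)."""
        return {v for v, d in self.graph.degree if d > 0}

    def largest_component(self) -> set[str]:
        if not self.component_sizes:
            return set()
        biggest = max(self.component_sizes, key=lambda c:
                      (self.component_sizes[c], -c))
        return {v for v, a in self.graph.nodes(data=True)
                if a["component"] == biggest}

    def summary(self) -> dict:
        return {"genes_selected": self.n_genes,
                "genes_connected": len(self.connected_genes()),
                "links": self.n_links,
                "largest_component_size": len(self.largest_component()),
                "n_components": len(self.component_sizes)}


def select_therapeutic_genes(proteome_genes: set[str],
                             categories: GeneSetCollection,
                             category_names: tuple[str, ...] = DEFAULT_CATEGORIES,
                             ) -> pd.DataFrame:
    """Proteome genes belonging to >= 1 configured category, with flags.

    Returns a DataFrame indexed by gene with one boolean column per
    category; genes in several categories carry several flags.  Flag
    values do not depend on the order of sets in the collection.
    """
    missing = [c for c in category_names if c not in categories]
    if missing:
        raise ConfigError(f"missing category set(s): {', '.join(missing)}")
    genes = sorted(normalize_gene(g) for g in proteome_genes)
    flags = pd.DataFrame(
        {c: [g in categories[c] for g in genes] for c in category_names},
        index=pd.Index(genes, name="gene_id"))
    selected = flags[flags.any(axis=1)]
    if selected.empty:
        import logging
        logging.getLogger("vesnet").warning(
            "no proteome gene belongs to any category")
    return selected


def enrich_categories(proteome_genes: set[str],
                      categories: GeneSetCollection,
                      background_n: int,
                      category_names: tuple[str, ...] = DEFAULT_CATEGORIES,
                      ) -> pd.DataFrame:
    """One hypergeometric enrichment per category, BH-adjusted.

    The background universe size ``background_n`` must be supplied
    explicitly (genome-wide vs annotated universes give very different
    p-values, and silently defaulting would hide that choice).
    """
    genes = {normalize_gene(g) for g in proteome_genes}
    n = len(genes)
    rows = []
    for name in category_names:
        if name not in categories:
            raise ConfigError(f"missing category set: {name}")
        cat = categories[name]
        res = hypergeometric_enrichment(k=len(genes & cat), n=n,
                                        K=len(cat), N=background_n)
        rows.append({"category": name, "k": res.k, "n": res.n, "K": res.K,
                     "N": res.N, "fold": res.fold, "p": res.p})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def project_onto_network(selection: pd.DataFrame, net: nx.Graph,
                         ) -> TherapeuticNetwork:
    """Induced subgraph of the gene network on the selected genes.

    Isolated selected genes (including those absent from the network)
    are kept as flagged singleton nodes; components are labelled in
    decreasing size order (ties broken lexicographically by smallest
    member).
    """
    category_names = tuple(selection.columns)
    g = nx.Graph()
    genes = list(selection.index)
    for gene in genes:
        flags = selection.loc[gene]
        n_flags = int(flags.sum())
        attrs = {c: bool(flags[c]) for c in category_names}
        attrs.update({f"frac_{c}": (float(flags[c]) / n_flags if n_flags
                                    else 0.0) for c in category_names})
        attrs["in_network"] = gene in net
        attrs["upregulated"] = False
        attrs["fold_change"] = None
        g.add_node(gene, **attrs)
    gene_set = set(genes)
    for gene in genes:
        if gene in net:
            for nb in net.adj[gene]:
                if nb in gene_set and not g.has_edge(gene, nb):
                    g.add_edge(gene, nb)
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (-len(c), min(c)))
    sizes = {}
    for cid, comp in enumerate(comps):
        sizes[cid] = len(comp)
        for v in comp:
            g.nodes[v]["component"] = cid
    return TherapeuticNetwork(graph=g, categories=category_names,
                              component_sizes=sizes)


def annotate_upregulation(net: TherapeuticNetwork, deps: pd.DataFrame,
                          ) -> TherapeuticNetwork:
    """Flag upregulated genes and attach fold changes.

    A node is flagged when its gene has >= 1 protein called "up"; the
    attached fold change is the maximum |log2FC| over the gene's up
    proteins.  Genes absent from the DEP table keep flag False and a
    null fold change.
    """
    up = deps[deps["direction"] == "up"]
    fc = up.assign(_abs=up["log2fc"].abs()).groupby("gene_id")["_abs"].max()
    for gene in net.graph.nodes:
        if gene in fc.index:
            net.graph.nodes[gene]["upregulated"] = True
            net.graph.nodes[gene]["fold_change"] = float(fc[gene])
    return net


def test_upregulated_enrichment(net: TherapeuticNetwork,
                                proteome_genes: set[str],
                                upregulated: set[str],
                                query: str = "connected",
                                ) -> EnrichmentResult:
    """Enrichment of the module network for upregulated genes.

    Hypergeometric test with query = the network's genes ("connected"
    genes by default; "all" selected or "largest" component via
    ``query``), category = the upregulated genes, background = the
    proteome gene set — both query and category are proteome-
    conditioned, so the proteome is the natural universe (configurable
    upstream by passing a different ``proteome_genes``).
    """
    if net.n_genes == 0:
        raise ValueError("empty therapeutic network")
    proteome = {normalize_gene(g) for g in proteome_genes}
    up = {normalize_gene(g) for g in upregulated}
    stray = up - proteome
    if stray:
        import logging
        logging.getLogger("vesnet").warning(
            "%d upregulated gene(s) outside the proteome universe; "
            "intersected away", len(stray))
        up &= proteome
    picker = {"connected": net.connected_genes,
              "all": lambda: set(net.graph.nodes),
              "largest": net.largest_component}
    if query not in picker:
        raise ValueError(f"unknown query policy {query!r}")
    qgenes = picker[query]() & proteome
    return hypergeometric_enrichment(k=len(qgenes & up), n=len(qgenes),
                                     K=len(up), N=len(proteome))


def node_table(net: TherapeuticNetwork) -> pd.DataFrame:
    """Per-node attribute table (sorted by gene id) for TSV export."""
    rows = []
    for gene in sorted(net.graph.nodes):
        attrs = dict(net.graph.nodes[gene])
        attrs["gene_id"] = gene
        rows.append(attrs)
    df = pd.DataFrame(rows)
    cols = ["gene_id"] + [c for c in df.columns if c != "gene_id"]
    return df[cols]
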