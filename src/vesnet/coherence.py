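"""Gene-set network coherence against random equal-size null sets.

Quantifies whether a gene set is more functionally connected in an
undirected gene network than random sets of the same size, using two
integer statistics — the within-group edge count and the number of
set pairs sharing at least one network neighbour — with an empirical
permutation null ("1,000 random gene sets of equal size"-style).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .io import normalize_gene
from .stats import empirical_p

STATISTICS = ("within_group_edges", "neighbour_overlap")

# fixed per-statistic substream offsets: adding a statistic never
# perturbs another statistic's null sample
_STAT_STREAM = {"within_group_edges": 0, "neighbour_overlap": 1,
                "neighbour_overlap_weighted": 2}


class DegenerateSetError(ValueError):
    """Fewer than two set members map into the network."""


@dataclass(frozen=True)
class CoherenceResult:
    statistic: str
    set_size: int                # genes of s present in the network
    observed: float
    null_mean: float
    null_sd: float
    m: int
    z: float
    p: float


def _mapped(net: nx.Graph, s: Iterable[str]) -> set[str]:
    nodes = {normalize_gene(g) for g in s}
    return nodes & set(net.nodes)


def within_group_edges(net: nx.Graph, s: Iterable[str]) -> int:
    """Number of network edges with both endpoints in ``s``.

    Genes absent from the network are ignored.  Bounded by C(|s'|, 2)
    with equality iff the mapped set induces a clique.
    """
    nodes = _mapped(net, s)
    total = sum(len(set(net.adj[v]) & nodes) for v in nodes)
    return total // 2


def neighbour_overlap(net: nx.Graph, s: Iterable[str]) -> int:
    """Number of unordered pairs in ``s`` sharing >= 1 network neighbour.

    A pair {i, j} counts when some third node w (w not in {i, j}) is
    adjacent to both i and j.  Monotone non-decreasing under adding a
    gene to the set.
    """
    nodes = sorted(_mapped(net, s))
    neigh = {v: set(net.adj[v]) for v in nodes}
    count = 0
    for i, a in enumerate(nodes):
        na = neigh[a]
        for b in nodes[i + 1:]:
            shared = na & neigh[b]
            shared.discard(a)
            shared.discard(b)
            if shared:
                count += 1
    return count


def neighbour_overlap_weighted(net: nx.Graph, s: Iterable[str]) -> float:
    """Weighted variant: sum of Jaccard indices of pair neighbourhoods."""
    nodes = sorted(_mapped(net, s))
    neigh = {v: set(net.adj[v]) for v in nodes}
    total = 0.0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            inter = neigh[a] & neigh[b]
            inter.discard(a)
            inter.discard(b)
            if inter:
                union = (neigh[a] | neigh[b]) - {a, b}
                total += len(inter) / len(union)
    return total


_STAT_FUNCS = {"within_group_edges": within_group_edges,
               "neighbour_overlap": neighbour_overlap,
               "neighbour_overlap_weighted": neighbour_overlap_weighted}


def sample_null_sets(net: nx.Graph, size: int, m: int,
                     universe: Iterable[str] | None = None,
                     seed: int = 0, degree_matched: bool = False,
                     reference: Iterable[str] | None = None,
                     ) -> list[set[str]]:
    """Draw ``m`` random gene sets of exactly ``size`` genes.

    The universe defaults to all network nodes; pass a user background
    (e.g. all detected genes) to calibrate against the assayed universe
    instead.  With ``degree_matched``, nodes are binned by degree decile
    and each draw matches the degree-decile profile of ``reference``
    (uniform sampling is the default, mirroring an equal-size uniform
    null).  Reproducible under ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    uni = sorted(set(net.nodes) if universe is None
                 else {normalize_gene(g) for g in universe})
    if size > len(uni):
        raise ValueError(f"set size {size} exceeds universe size {len(uni)}")
    rng = np.random.default_rng(seed)
    if not degree_matched:
        arr = np.array(uni)
        return [set(rng.choice(arr, size=size, replace=False))
                for _ in range(m)]
    # degree-matched: sample within degree-decile bins
    if reference is None:
        raise ValueError("degree_matched sampling needs a reference set")
    degrees = np.array([net.degree(v) if v in net else 0 for v in uni])
    edges = np.quantile(degrees, np.linspace(0, 1, 11))
    bins = np.clip(np.searchsorted(edges, degrees, side="right") - 1, 0, 9)
    by_bin = {b: np.array(uni)[bins == b] for b in range(10)}
    ref = sorted(_mapped(net, reference))
    ref_deg = np.array([net.degree(v) for v in ref])
    ref_bins = np.clip(np.searchsorted(edges, ref_deg, side="right") - 1, 0, 9)
    profile = np.bincount(ref_bins, minlength=10)
    out = []
    for _ in range(m):
        draw: set[str] = set()
        for b, need in enumerate(profile):
            if need == 0:
                continue
            pool = by_bin[b]
            take = min(int(need), len(pool))
            draw |= set(rng.choice(pool, size=take, replace=False))
        # top up from the whole universe if bins ran short
        if len(draw) < size:
            rest = np.array([u for u in uni if u not in draw])
            draw |= set(rng.choice(rest, size=size - len(draw), replace=False))
        out.append(draw)
    return out


def coherence_test(net: nx.Graph, s: Iterable[str],
                   statistic: str = "within_group_edges", m: int = 1000,
                   seed: int = 0, universe: Iterable[str] | None = None,
                   degree_matched: bool = False,
                   return_null: bool = False):
    """Empirical coherence test of a gene set against random equal-size sets.

    The observed statistic is compared with its distribution over ``m``
    random sets of the mapped size (genes missing from the network are
    dropped before sizing the null, so poor identifier mapping is never
    rewarded).  p is the add-one empirical upper-tail p-value; z uses
    the null mean and standard deviation (reported as 0 when the null is
    degenerate with observed equal to its mean).

    Each statistic draws its null from an independent substream of the
    master seed, so adding a statistic never changes another's null.
    """
    if statistic not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic {statistic!r}")
    mapped = _mapped(net, s)
    if len(mapped) < 2:
        raise DegenerateSetError(
            f"only {len(mapped)} gene(s) of the set map into the network; "
            "need >= 2")
    func = _STAT_FUNCS[statistic]
    observed = float(func(net, mapped))
    sub_seed = np.random.SeedSequence(
        entropy=seed, spawn_key=(_STAT_STREAM[statistic],))
    null_sets = sample_null_sets(net, size=len(mapped), m=m,
                                 universe=universe,
                                 seed=sub_seed,
                                 degree_matched=degree_matched,
                                 reference=mapped if degree_matched else None)
    null = np.array([func(net, ns) for ns in null_sets], dtype=float)
    sd = float(null.std(ddof=1)) if m > 1 else 0.0
    mean = float(null.mean())
    z = (observed - mean) / sd if sd > 0 else 0.0
    result = CoherenceResult(statistic=statistic, set_size=len(mapped),
                             observed=observed, null_mean=mean, null_sd=sd,
                             m=m, z=z,
                             p=empirical_p(observed, null, "greater"))
    if return_null:
        return result, null
    return result
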