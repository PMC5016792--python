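"""Per-condition proteome assembly from identification tables.

Applies the inclusion filter (spectral count >1 in at least one batch at
identification FDR <0.01), computes batch-presence tiers, collapses
proteins to genes, compares proteomes between conditions, and scores
vesicular-database coverage against random-sampling baselines.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IdentificationTable
from .stats import empirical_p

TIERS = ("ge1", "ge2", "all")


class TierError(ValueError):
    pass


def _check_tier(tier: str) -> None:
    if tier not in TIERS:
        raise TierError(f"unknown tier {tier!r}; expected one of {TIERS}")


@dataclass
class ProteomeSet:
    """One condition's assembled proteome.

    ``counts`` is a proteins x batches matrix of spectral counts (zeros
    for batches where a protein was not observed — absence and zero are
    not distinguished).  ``best_fdr`` is the minimum identification FDR
    per protein, ``gene_map`` protein -> gene.  Presence in a batch
    means spectral count >= 1 there; tiers classify proteins by how many
    batches they are present in (>=1, >=2, all).
    """

    condition: str
    counts: pd.DataFrame
    best_fdr: pd.Series
    gene_map: pd.Series

    @property
    def batches(self) -> list[str]:
        return list(self.counts.columns)

    def proteins(self, tier: str = "ge1") -> set[str]:
        _check_tier(tier)
        present = (self.counts >= 1).sum(axis=1)
        need = {"ge1": 1, "ge2": 2, "all": len(self.batches)}[tier]
        return set(self.counts.index[present >= need])

    def genes(self, tier: str = "ge1") -> set[str]:
        # a gene is in a tier iff at least one of its proteins is
        return {self.gene_map[p] for p in self.proteins(tier)}

    def tier_counts(self) -> dict[str, dict[str, int]]:
        return {tier: {"proteins": len(self.proteins(tier)),
                       "genes": len(self.genes(tier))}
                for tier in TIERS}


@dataclass(frozen=True)
class ProteomeComparison:
    tier: str
    level: str                    # "protein" or "gene"
    size_a: int
    size_b: int
    intersection: int
    union: int
    shared_fraction: float
    namespace_warning: bool


def filter_identifications(table: IdentificationTable, min_count: int = 2,
                           fdr_max: float = 0.01) -> IdentificationTable:
    """Apply the proteome inclusion filter.

    A protein is kept (within its condition) iff its maximum spectral
    count over batches is >= ``min_count`` and its best (minimum)
    identification FDR is < ``fdr_max``.  All batch rows of a kept
    protein are retained, including zero-count rows, so presence tiers
    remain computable.  Idempotent.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not (0 < fdr_max < 1):
        raise ValueError("fdr_max must lie in (0, 1)")
    df = table.frame
    agg = df.groupby(["condition", "protein_id"]).agg(
        max_count=("spectral_count", "max"), best_fdr=("fdr", "min"))
    keep = agg[(agg["max_count"] >= min_count) & (agg["best_fdr"] < fdr_max)]
    mask = df.set_index(["condition", "protein_id"]).index.isin(keep.index)
    return IdentificationTable(df[mask])


def assemble_proteome(table: IdentificationTable, condition: str,
                      ) -> ProteomeSet:
    """Build the per-condition proteome from an (already filtered) table.

    Proteins observed in only some batches get explicit zero counts for
    the missing batches.
    """
    if condition not in table.conditions:
        raise KeyError(f"condition {condition!r} not in table "
                       f"(has {sorted(table.conditions)})")
    sub = table.frame[table.frame["condition"] == condition]
    counts = sub.pivot_table(index="protein_id", columns="batch",
                             values="spectral_count", fill_value=0,
                             aggfunc="sum")
    counts = counts.sort_index().sort_index(axis=1).astype(int)
    best_fdr = sub.groupby("protein_id")["fdr"].min().reindex(counts.index)
    gene_map = sub.groupby("protein_id")["gene_id"].first().reindex(counts.index)
    return ProteomeSet(condition=condition, counts=counts,
                       best_fdr=best_fdr, gene_map=gene_map)


def compare_proteomes(a: ProteomeSet, b: ProteomeSet, tier: str = "ge1",
                      ) -> dict[str, ProteomeComparison]:
    """Exact set arithmetic between two proteomes at one tier.

    Returns protein-level and gene-level comparisons.  Zero overlap at
    both levels sets the namespace warning (reported, not fatal).
    Symmetric in its arguments.
    """
    _check_tier(tier)
    out = {}
    for level, getter in (("protein", lambda p: p.proteins(tier)),
                          ("gene", lambda p: p.genes(tier))):
        sa, sb = getter(a), getter(b)
        inter = len(sa & sb)
        union = len(sa | sb)
        out[level] = ProteomeComparison(
            tier=tier, level=level, size_a=len(sa), size_b=len(sb),
            intersection=inter, union=union,
            shared_fraction=inter / union if union else 0.0,
            namespace_warning=(inter == 0 and len(sa) > 0 and len(sb) > 0))
    return out


def genes_of(p: ProteomeSet, tier: str = "ge1") -> set[str]:
    """De-duplicated gene set of a proteome tier."""
    return p.genes(tier)


def vesicular_coverage(p: ProteomeSet, vesicle_set: set[str],
                       universe: set[str], n_samples: int = 10,
                       sample_size: int = 1000, seed: int = 0,
                       ) -> pd.DataFrame:
    """Vesicular-database coverage per tier with a random-sampling baseline.

    For each presence tier, the observed value is the fraction of the
    tier's genes annotated in the vesicular set.  The baseline draws
    ``n_samples`` random gene sets of ``sample_size`` from ``universe``
    and scores the same fraction; the empirical p uses the add-one rule.
    """
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe))
    if sample_size > len(uni):
        raise ValueError(f"sample_size {sample_size} exceeds universe "
                         f"size {len(uni)}")
    null = np.empty(n_samples)
    for i in range(n_samples):
        draw = rng.choice(uni, size=sample_size, replace=False)
        null[i] = len(set(draw) & vesicle_set) / sample_size
    rows = []
    for tier in TIERS:
        genes = p.genes(tier)
        obs = len(genes & vesicle_set) / len(genes) if genes else 0.0
        rows.append({"tier": tier, "n_genes": len(genes),
                     "coverage": obs,
                     "null_mean": float(null.mean()),
                     "null_sd": float(null.std(ddof=1)) if n_samples > 1 else 0.0,
                     "empirical_p": empirical_p(obs, null, "greater")})
    return pd.DataFrame(rows)
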