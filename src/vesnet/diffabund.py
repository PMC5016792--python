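"""Spectral-count differential abundance between two conditions.

Proteins are tested with a Poisson likelihood-ratio statistic using
per-batch size factors as exposures, with Benjamini-Hochberg control of
the false discovery rate.  A protein absent from one condition enters
with zero counts in all of that condition's batches — presence/absence
is the strongest differential signal, not a reason to drop the protein.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .assembly import ProteomeSet
from .stats import bh_fdr, poisson_lr_table

DEP_COLUMNS = ("protein_id", "gene_id", "log2fc", "lr", "p", "q", "direction")


class NamespaceError(ValueError):
    """Treated and control tables share no identifiers."""


class DegenerateBatchError(ValueError):
    pass


def normalize_counts(p: ProteomeSet) -> pd.Series:
    """Per-batch size factors: batch total spectral count / median total."""
    totals = p.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        batch = totals.index[totals == 0][0]
        raise DegenerateBatchError(f"batch {batch!r} of condition "
                                   f"{p.condition!r} has zero total count")
    return totals / totals.median()


def call_deps(treated: ProteomeSet, control: ProteomeSet,
              q_threshold: float = 0.01, pseudocount: float = 0.5,
              ) -> pd.DataFrame:
    """Call differentially abundant proteins (treated vs control).

    For every protein present in either proteome: LR statistic and p
    from the Poisson likelihood-ratio test with size factors as
    exposures; q by BH; log2 fold change of normalized mean rates with
    pseudocount ``pseudocount`` on both sides.  Direction is "up" iff
    q <= threshold and log2fc > 0, "down" iff q <= threshold and
    log2fc < 0, else "ns".  Rows sorted by q, then descending |log2fc|,
    then protein id.
    """
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must lie in (0, 1)")
    shared_proteins = set(treated.counts.index) & set(control.counts.index)
    shared_genes = set(treated.gene_map.values) & set(control.gene_map.values)
    if not shared_proteins and not shared_genes:
        raise NamespaceError(
            "treated and control proteomes share no protein or gene "
            "identifiers; check identifier namespaces")

    proteins = sorted(set(treated.counts.index) | set(control.counts.index))
    ct = treated.counts.reindex(proteins, fill_value=0).to_numpy(float)
    cc = control.counts.reindex(proteins, fill_value=0).to_numpy(float)
    st = normalize_counts(treated).to_numpy()
    sc = normalize_counts(control).to_numpy()

    lr, p = poisson_lr_table(ct, st, cc, sc)
    q = bh_fdr(p)
    rate_t = ct.sum(axis=1) / st.sum()
    rate_c = cc.sum(axis=1) / sc.sum()
    log2fc = np.log2((rate_t + pseudocount) / (rate_c + pseudocount))

    gene = treated.gene_map.reindex(proteins).fillna(
        control.gene_map.reindex(proteins))
    direction = np.where(q > q_threshold, "ns",
                         np.where(log2fc > 0, "up",
                                  np.where(log2fc < 0, "down", "ns")))
    df = pd.DataFrame({"protein_id": proteins, "gene_id": gene.to_numpy(),
                       "log2fc": log2fc, "lr": lr, "p": p, "q": q,
                       "direction": direction})
    df["_abs"] = df["log2fc"].abs()
    df = (df.sort_values(["q", "_abs", "protein_id"],
                         ascending=[True, False, True])
            .drop(columns="_abs").reset_index(drop=True))
    return df


def upregulated_genes(records: pd.DataFrame) -> set[str]:
    """Genes with at least one protein called up; de-duplicated."""
    up = records[records["direction"] == "up"]
    return set(up["gene_id"])
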