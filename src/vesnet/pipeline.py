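"""Chained pipeline: assemble -> enrich -> diffabund -> coherence -> modulenet.

Each stage writes TSV/JSON artefacts into the output directory; a
manifest records the seed, null-sample count, thresholds and input
digests so every results directory is traceable to its inputs.
Identical config + seed gives byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import assembly, coherence, diffabund, modulenet
from .io import (PipelineConfig, export_graphml, read_gmt,
                 read_identification_table, read_network_edgelist,
                 write_gene_list, write_manifest)

log = logging.getLogger("vesnet")


class StageError(RuntimeError):
    """A pipeline stage failed; partial results are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sanitize(obj):
    # strict JSON has no NaN; unset quantities become null
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and obj != obj:
        return None
    return obj


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_sanitize(obj), fh, indent=2, sort_keys=True, default=str,
                  allow_nan=False)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages in order; returns the results directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(config, out)

    state: dict = {}
    for stage in config.stages:
        log.info("stage %s: starting", stage)
        try:
            _STAGES[stage](config, out, state)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            log.error("stage %s failed: %s", stage, exc)
            raise StageError(stage, exc) from exc
        log.info("stage %s: done", stage)
    return out


def _stage_assemble(config: PipelineConfig, out: Path, state: dict) -> None:
    table = read_identification_table(config.identifications)
    filtered = assembly.filter_identifications(
        table, min_count=config.min_spectral_count,
        fdr_max=config.inclusion_fdr)
    log.info("inclusion filter: %d -> %d rows", len(table), len(filtered))
    summary = {}
    for cond in (config.treated_condition, config.control_condition):
        if cond not in filtered.conditions:
            continue
        prot = assembly.assemble_proteome(filtered, cond)
        state[f"proteome:{cond}"] = prot
        summary[cond] = prot.tier_counts()
        rows = []
        for tier in assembly.TIERS:
            for pid in sorted(prot.proteins(tier)):
                rows.append({"tier": tier, "protein_id": pid,
                             "gene_id": prot.gene_map[pid]})
        pd.DataFrame(rows).to_csv(out / f"tiers_{cond}.tsv", sep="\t",
                                  index=False)
    if len(summary) == 2:
        comp = assembly.compare_proteomes(
            state[f"proteome:{config.treated_condition}"],
            state[f"proteome:{config.control_condition}"], tier="ge1")
        summary["comparison_ge1"] = {lvl: asdict(c) for lvl, c in comp.items()}
    _json_dump(summary, out / "assemble_summary.json")
    state["assemble_summary"] = summary


def _treated(config: PipelineConfig, state: dict) -> assembly.ProteomeSet:
    key = f"proteome:{config.treated_condition}"
    if key not in state:
        raise ValueError("assemble stage must run before this stage")
    return state[key]


def _stage_enrich(config: PipelineConfig, out: Path, state: dict) -> None:
    if config.vesicle_gmt is None:
        log.info("enrich: no vesicle_gmt configured; skipping coverage")
        return
    vesicles = read_gmt(config.vesicle_gmt)
    vset = set().union(*vesicles.sets.values()) if len(vesicles) else set()
    prot = _treated(config, state)
    universe = set(prot.genes("ge1"))
    if config.network is not None:
        universe |= set(read_network_edgelist(config.network).nodes)
    # baseline draws of up to 1,000 genes, capped at half the universe so
    # the baseline never degenerates to the whole universe
    sample_size = min(1000, max(10, len(universe) // 2))
    cov = assembly.vesicular_coverage(prot, vset, universe,
                                      n_samples=config.null_samples,
                                      sample_size=sample_size,
                                      seed=config.seed)
    cov.to_csv(out / "vesicular_coverage.tsv", sep="\t", index=False)


def _stage_diffabund(config: PipelineConfig, out: Path, state: dict) -> None:
    treated = _treated(config, state)
    control = state.get(f"proteome:{config.control_condition}")
    if control is None:
        raise ValueError(f"condition {config.control_condition!r} missing; "
                         "cannot test differential abundance")
    deps = diffabund.call_deps(treated, control,
                               q_threshold=config.dep_q_threshold,
                               pseudocount=config.pseudocount)
    deps.to_csv(out / "deps.tsv", sep="\t", index=False)
    up = diffabund.upregulated_genes(deps)
    write_gene_list(up, out / "upregulated_genes.txt")
    state["deps"] = deps
    state["up_genes"] = up
    log.info("diffabund: %d proteins tested, %d up genes", len(deps), len(up))


def _stage_coherence(config: PipelineConfig, out: Path, state: dict) -> None:
    net = read_network_edgelist(config.network)
    up = state.get("up_genes")
    if up is None:
        raise ValueError("diffabund stage must run before coherence")
    universe = (None if config.background_universe == "network_nodes"
                else _treated(config, state).genes("ge1"))
    rows = []
    for stat in coherence.STATISTICS:
        res = coherence.coherence_test(net, up, statistic=stat,
                                       m=config.null_samples,
                                       seed=config.seed, universe=universe)
        row = asdict(res)
        row["null_universe"] = config.background_universe
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "coherence.tsv", sep="\t", index=False)
    state["coherence"] = rows


def _stage_modulenet(config: PipelineConfig, out: Path, state: dict) -> None:
    prot = _treated(config, state)
    genes = prot.genes("ge1")
    categories = read_gmt(config.categories_gmt)
    net = read_network_edgelist(config.network)
    n_bg = config.enrichment_background
    if n_bg is None:
        # declared policy: union of network nodes, proteome genes and
        # category members (recorded in the summary)
        bg = set(net.nodes) | genes
        for s in categories.sets.values():
            bg |= s
        n_bg = len(bg)
    names = tuple(sorted(categories.sets))
    report = modulenet.enrich_categories(genes, categories, n_bg,
                                         category_names=names)
    report.to_csv(out / "category_enrichment.tsv", sep="\t", index=False)
    selection = modulenet.select_therapeutic_genes(genes, categories,
                                                   category_names=names)
    tnet = modulenet.project_onto_network(selection, net)
    if "deps" in state:
        tnet = modulenet.annotate_upregulation(tnet, state["deps"])
    modulenet.node_table(tnet).to_csv(out / "module_nodes.tsv", sep="\t",
                                      index=False)
    export_graphml(tnet, out / "module_network.graphml")
    summary = tnet.summary()
    summary["enrichment_background_n"] = n_bg
    if state.get("up_genes"):
        up = state["up_genes"] & genes
        if up and tnet.n_genes and tnet.connected_genes():
            res = modulenet.test_upregulated_enrichment(tnet, genes, up)
            summary["upregulated_enrichment"] = asdict(res)
            summary["upregulated_enrichment_query"] = "connected"
    _json_dump(summary, out / "modulenet_summary.json")
    state["modulenet_summary"] = summary


_STAGES = {
    "assemble": _stage_assemble,
    "enrich": _stage_enrich,
    "diffabund": _stage_diffabund,
    "coherence": _stage_coherence,
    "modulenet": _stage_modulenet,
}
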