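"""Readers and writers for the on-disk formats.

Tab-separated identification tables, 2/3-column network edge lists,
GMT gene sets, GraphML export of annotated networks, and the structured
pipeline configuration.  All parse errors carry a line number; nothing
is dropped silently except logged self-loops and duplicate edges.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

log = logging.getLogger("vesnet")

IDENT_COLUMNS = ("protein_id", "gene_id", "condition", "batch",
                 "spectral_count", "fdr")


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ParseError(ValueError):
    """A line could not be parsed; the message names the line number."""


class IntegrityError(ValueError):
    """Input violates a table invariant (duplicates, inconsistent maps)."""


def normalize_gene(g: str) -> str:
    """The single identifier-normalization rule: strip and uppercase.

    Network, GMT and identification-table gene symbols come from sources
    with inconsistent casing; a single declared rule keeps set arithmetic
    well defined.
    """
    return g.strip().upper()


# ---------------------------------------------------------------------------
# identification tables

@dataclass(frozen=True)
class IdentificationRecord:
    protein_id: str
    gene_id: str
    condition: str
    batch: str
    spectral_count: int
    fdr: float


class IdentificationTable:
    """Validated per-batch protein identification observations.

    Wraps a DataFrame with columns protein_id, gene_id, condition,
    batch, spectral_count, fdr.  Invariants enforced on construction:
    (protein_id, batch) unique within a condition; integer counts >= 0;
    fdr in [0, 1]; one gene per protein.
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.loc[:, list(IDENT_COLUMNS)].copy()
        df["gene_id"] = df["gene_id"].map(normalize_gene)
        for col in ("protein_id", "gene_id"):
            if (df[col].astype(str).str.len() == 0).any():
                raise IntegrityError(f"empty {col} in table")
        if (df["spectral_count"] < 0).any():
            raise IntegrityError("negative spectral_count")
        if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
            raise IntegrityError("fdr outside [0, 1]")
        dup = df.duplicated(["condition", "protein_id", "batch"])
        if dup.any():
            i = df.index[dup][0]
            raise IntegrityError(
                f"duplicate (protein, batch) within condition: "
                f"{df.loc[i, 'protein_id']}/{df.loc[i, 'batch']}"
                f"/{df.loc[i, 'condition']}")
        genes_per_protein = df.groupby("protein_id")["gene_id"].nunique()
        bad = genes_per_protein[genes_per_protein > 1]
        if len(bad):
            raise IntegrityError(
                f"protein {bad.index[0]} maps to {bad.iloc[0]} genes; "
                "one gene per protein required")
        self.frame = df.reset_index(drop=True)

    @property
    def conditions(self) -> set[str]:
        return set(self.frame["condition"].unique())

    def batches(self, condition: str) -> list[str]:
        sub = self.frame[self.frame["condition"] == condition]
        return sorted(sub["batch"].unique())

    @property
    def records(self) -> list[IdentificationRecord]:
        return [IdentificationRecord(*row) for row in
                self.frame.itertuples(index=False, name=None)]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return (isinstance(other, IdentificationTable)
                and self.frame.equals(other.frame))


def read_identification_table(path: str | Path,
                              schema: Mapping[str, str] | None = None,
                              ) -> IdentificationTable:
    """Read a tab-separated identification table.

    ``schema`` optionally maps the canonical column names to the names
    used in the file's header.  Counts must parse as integers; the
    offending line number (header = line 1) is reported otherwise.
    """
    path = Path(path)
    rename = {v: k for k, v in (schema or {}).items()}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns=rename)
    missing = [c for c in IDENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    counts = pd.to_numeric(df["spectral_count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round())
    if bad.any():
        lineno = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}:{lineno}: spectral_count "
                         f"{df.loc[df.index[bad][0], 'spectral_count']!r} "
                         "is not an integer")
    df["spectral_count"] = counts.astype(int)
    fdr = pd.to_numeric(df["fdr"], errors="coerce")
    if fdr.isna().any():
        lineno = int(df.index[fdr.isna()][0]) + 2
        raise ParseError(f"{path}:{lineno}: fdr is not a number")
    df["fdr"] = fdr
    return IdentificationTable(df)


def write_identification_table(table: IdentificationTable,
                               path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# networks

def read_network_edgelist(path: str | Path, directed_policy: str = "ignore",
                          ) -> nx.Graph:
    """Read a 2- or 3-column tab/whitespace-separated edge list.

    Returns an undirected simple graph over normalized gene identifiers.
    Self-loops are dropped and duplicate edges collapsed, with counts
    logged.  A third column (edge weight) is parsed but unused: the
    coherence analysis is purely topological.
    """
    path = Path(path)
    g = nx.Graph()
    self_loops = duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 fields, "
                                 f"got {len(fields)}")
            a, b = normalize_gene(fields[0]), normalize_gene(fields[1])
            if a == b:
                self_loops += 1
                continue
            if g.has_edge(a, b):
                duplicates += 1
                continue
            g.add_edge(a, b)
    if self_loops or duplicates:
        log.info("read_network_edgelist(%s): dropped %d self-loops, "
                 "%d duplicate edges", path, self_loops, duplicates)
    return g


# ---------------------------------------------------------------------------
# gene sets (GMT)

@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set category tags."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.sets:
            if not name:
                raise IntegrityError("empty gene-set name")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return sorted(self.sets)


def read_gmt(path: str | Path, empty_sets: str = "warn") -> GeneSetCollection:
    """Read a standard GMT file (name, description, members...).

    Members are de-duplicated and case-normalized.  ``empty_sets`` is
    "warn" (keep the empty set, log a warning) or "error".
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 "
                                 f"tab-separated fields, got {len(fields)}")
            name, desc, *members = fields
            if name in sets:
                raise IntegrityError(f"{path}:{lineno}: duplicate set name "
                                     f"{name!r}")
            genes = {normalize_gene(m) for m in members if m.strip()}
            if not genes:
                if empty_sets == "error":
                    raise ParseError(f"{path}:{lineno}: set {name!r} has no "
                                     "members")
                log.warning("%s:%d: set %r has no members", path, lineno, name)
            sets[name] = genes
            descs[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descs)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {normalize_gene(line) for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# GraphML export

_NULL = "NA"  # explicit null marker for nullable node attributes


def export_graphml(net, path: str | Path) -> None:
    """Write a :class:`~vesnet.modulenet.TherapeuticNetwork` as GraphML.

    Nodes and edges are emitted in sorted order so identical networks
    always produce identical files.  Nullable attributes (fold change)
    are written as the explicit marker "NA".
    """
    g = nx.Graph()
    # a GraphML key holds one type; attributes that can be null are
    # therefore written as strings throughout, with the keys recorded so
    # import can restore numeric types
    nullable = sorted({k for _, attrs in net.graph.nodes(data=True)
                       for k, v in attrs.items() if v is None})
    for node in sorted(net.graph.nodes):
        attrs = dict(net.graph.nodes[node])
        for key in nullable:
            val = attrs.get(key)
            attrs[key] = _NULL if val is None else repr(val)
        g.add_node(node, **attrs)
    for a, b in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges)):
        g.add_edge(a, b)
    g.graph["nullable_keys"] = " ".join(nullable)
    nx.write_graphml(g, str(path), named_key_ids=True)


def import_graphml(path: str | Path) -> nx.Graph:
    """Re-read a GraphML export, mapping the "NA" marker back to None."""
    g = nx.read_graphml(str(path))
    nullable = set(g.graph.get("nullable_keys", "").split())
    for _, attrs in g.nodes(data=True):
        for key in nullable & set(attrs):
            val = attrs[key]
            if val == _NULL:
                attrs[key] = None
            else:
                try:
                    attrs[key] = float(val)
                except ValueError:
                    pass
    return g


# ---------------------------------------------------------------------------
# configuration + manifest

@dataclass
class PipelineConfig:
    """Flat configuration for the chained pipeline run."""

    identifications: str | None = None
    network: str | None = None
    categories_gmt: str | None = None
    vesicle_gmt: str | None = None
    treated_condition: str = "treated"
    control_condition: str = "control"
    out_dir: str = "results"
    seed: int = 0
    null_samples: int = 1000          # M random sets for the empirical null
    min_spectral_count: int = 2       # strict reading of ">1 spectral count"
    inclusion_fdr: float = 0.01       # identification FDR gate
    dep_q_threshold: float = 0.01     # DEP call threshold on BH q
    pseudocount: float = 0.5
    background_universe: str = "network_nodes"   # or "proteome"
    enrichment_background: int | None = None     # N for category enrichment
    stages: tuple[str, ...] = ("assemble", "enrich", "diffabund",
                               "coherence", "modulenet")

    def validate(self) -> None:
        if self.null_samples < 1:
            raise ValueError("null_samples (M) must be >= 1")
        for name in ("inclusion_fdr", "dep_q_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_spectral_count < 1:
            raise ValueError("min_spectral_count must be >= 1")
        if self.identifications is None:
            raise ValueError("missing input: identifications")
        needs_network = {"coherence", "modulenet"} & set(self.stages)
        if needs_network and self.network is None:
            raise ValueError("missing input: network (required by "
                             f"{', '.join(sorted(needs_network))})")
        if "modulenet" in self.stages and self.categories_gmt is None:
            raise ValueError("missing input: categories_gmt (required by "
                             "modulenet)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: PipelineConfig, out_dir: Path,
                   extra: dict | None = None) -> None:
    inputs = {}
    for key in ("identifications", "network", "categories_gmt", "vesicle_gmt"):
        p = getattr(config, key)
        if p is not None and Path(p).exists():
            inputs[key] = {"path": str(p), "sha256": file_digest(p)}
    manifest = {
        "seed": config.seed,
        "null_samples": config.null_samples,
        "min_spectral_count": config.min_spectral_count,
        "inclusion_fdr": config.inclusion_fdr,
        "dep_q_threshold": config.dep_q_threshold,
        "pseudocount": config.pseudocount,
        "background_universe": config.background_universe,
        "stages": list(config.stages),
        "inputs": inputs,
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
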