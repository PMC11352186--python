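"""Readers and writers for tabular datasets, knowledge graphs and networks.

TSV and CSV are auto-detected by extension (``.csv`` -> comma, anything
else -> tab).  Missing intensities are empty cells or ``NA``.
"""

from __future__ import annotations

import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    ConsensusNetwork,
    KnowledgeGraph,
    MatchedDesign,
    OmicsDataset,
    ValidationError,
)

_NA_VALUES = ["", "NA"]


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_omics_table(
    path: str | Path,
    feature_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> OmicsDataset:
    """Read an intensity table plus its two metadata tables.

    The intensity table has feature ids in the first column and sample ids
    in the header.  Metadata are joined by id; all dataset invariants are
    checked on construction.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(path))[1:]
    seen: set[str] = set()
    dup = sorted({h for h in header if h in seen or seen.add(h)})
    if dup:
        raise ValidationError(f"duplicate sample id(s) in header of {path}: {dup}")
    raw = pd.read_csv(
        path, sep=_sep(path), index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    if raw.index.duplicated().any():
        dup = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValidationError(f"duplicate feature id(s) in {path}: {dup}")

    fm = pd.read_csv(
        feature_meta_path,
        sep=_sep(feature_meta_path),
        na_values=_NA_VALUES,
        keep_default_na=False,
        dtype={"feature_id": str, "layer": str, "consolidation_key": str},
    )
    sm = pd.read_csv(
        sample_meta_path,
        sep=_sep(sample_meta_path),
        na_values=_NA_VALUES,
        keep_default_na=False,
        dtype={"sample_id": str, "role": str, "group": str, "pair_id": str},
    )
    fm["consolidation_key"] = fm["consolidation_key"].fillna("")
    sm["pair_id"] = sm["pair_id"].fillna("")
    sm["group"] = sm["group"].replace({np.nan: "none"})
    if fm["is_internal_standard"].dtype == object:
        fm["is_internal_standard"] = (
            fm["is_internal_standard"].astype(str).str.lower().isin(["true", "1", "yes"])
        )
    fm["is_internal_standard"] = fm["is_internal_standard"].astype(bool)
    if not np.all(sm["injection_order"] == sm["injection_order"].astype(int)):
        bad = list(sm.loc[sm["injection_order"] != sm["injection_order"].astype(int), "sample_id"])
        raise ValidationError(f"non-integer injection order for sample(s) {bad}")
    sm["injection_order"] = sm["injection_order"].astype(int)

    unknown = set(sm["sample_id"]) - set(map(str, raw.columns))
    if unknown:
        raise ValidationError(f"sample metadata references unknown sample id(s): {sorted(unknown)}")
    unknown_f = set(fm["feature_id"]) - set(map(str, raw.index))
    if unknown_f:
        raise ValidationError(f"feature metadata references unknown feature id(s): {sorted(unknown_f)}")

    # order the matrix by the metadata tables
    mat = raw.loc[fm["feature_id"], sm["sample_id"]].to_numpy(dtype=float)
    return OmicsDataset(intensities=mat, feature_meta=fm, sample_meta=sm)


def write_omics_table(ds: OmicsDataset, path: str | Path,
                      feature_meta_path: str | Path, sample_meta_path: str | Path) -> None:
    """Write a dataset back out as intensity + metadata tables (inverse of
    :func:`read_omics_table`)."""
    df = pd.DataFrame(ds.intensities, index=ds.feature_ids, columns=ds.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep=_sep(path), na_rep="NA", float_format="%.12g")
    ds.feature_meta.to_csv(feature_meta_path, sep=_sep(feature_meta_path), index=False)
    ds.sample_meta.to_csv(sample_meta_path, sep=_sep(sample_meta_path), index=False)


def read_design(path: str | Path) -> MatchedDesign:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    return MatchedDesign(zip(df["case_sample_id"], df["control_sample_id"]))


def write_design(design: MatchedDesign, path: str | Path) -> None:
    pd.DataFrame(design.pairs, columns=["case_sample_id", "control_sample_id"]).to_csv(
        path, sep=_sep(path), index=False
    )


def read_knowledge_graph(path: str | Path) -> KnowledgeGraph:
    """Read a knowledge-graph edge list (columns: idA, idB, source)."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    kg = KnowledgeGraph()
    src = df["source"] if "source" in df.columns else [""] * len(df)
    for a, b, s in zip(df.iloc[:, 0], df.iloc[:, 1], src):
        kg.add(a, b, s)
    return kg


def write_knowledge_graph(kg: KnowledgeGraph, path: str | Path) -> None:
    rows = [(a, b, s) for (a, b), s in sorted(kg.edges.items())]
    pd.DataFrame(rows, columns=["idA", "idB", "source"]).to_csv(path, sep=_sep(path), index=False)


# ---------------------------------------------------------------------------
# consensus-network serialization


def _to_nx(network: ConsensusNetwork) -> nx.Graph:
    g = nx.Graph()
    for node, layer in network.nodes.items():
        g.add_node(node, layer=layer)
    for (a, b), (raw, mod) in network.edges.items():
        g.add_edge(a, b, strength_raw=float(raw), strength_modified=float(mod))
    g.graph["threshold"] = float(network.threshold)
    return g


def write_network(network: ConsensusNetwork, path: str | Path, format: str = "graphml") -> None:
    """Serialize a consensus network.

    ``graphml`` carries node attribute ``layer`` and edge attributes
    ``strength_raw``/``strength_modified``; ``sif`` uses the interaction
    label ``assoc``; ``tsv`` is one edge per row.
    """
    path = Path(path)
    if path.parent and not path.parent.exists():
        raise IOError(f"unwritable path: {path}")
    if format == "graphml":
        nx.write_graphml(_to_nx(network), path)
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(network.edges):
                fh.write(f"{a}\tassoc\t{b}\n")
    elif format == "tsv":
        rows = [
            (a, b, raw, mod)
            for (a, b), (raw, mod) in sorted(network.edges.items())
        ]
        pd.DataFrame(
            rows, columns=["idA", "idB", "strength_raw", "strength_modified"]
        ).to_csv(path, sep="\t", index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path: str | Path) -> ConsensusNetwork:
    """Read back a GraphML file written by :func:`write_network`."""
    g = nx.read_graphml(path)
    nodes = {n: d.get("layer", "") for n, d in g.nodes(data=True)}
    edges = {
        KnowledgeGraph.canonical(a, b): (
            float(d["strength_raw"]),
            float(d["strength_modified"]),
        )
        for a, b, d in g.edges(data=True)
    }
    return ConsensusNetwork(
        nodes=nodes, edges=edges, threshold=float(g.graph.get("threshold", 0.0))
    )


def ensure_dir(path: str | Path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
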