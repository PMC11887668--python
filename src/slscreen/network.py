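"""Protein-interaction corroboration of screen hits and ortholog mapping.

Genetic screens carry false positives from reagent off-target effects and
assay noise.  Because genes with related functions tend to share synthetic
lethal partners, a hit that physically interacts with at least one other hit
is more trustworthy than an isolated one.  This module filters a hit list
against an undirected protein-protein interaction network (e.g. a STRING
physical-subnetwork export), restricts survivors to genes with clear human
orthologs, and groups the retained genes into functional components.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = [
    "load_edge_list",
    "filter_hits_by_network",
    "load_ortholog_map",
    "filter_by_orthologs",
    "group_hits",
]


def load_edge_list(
    path,
    min_score: float | None = None,
    channels: Iterable[str] | None = None,
    sep: str | None = None,
) -> nx.Graph:
    """Load an undirected interaction network from a two-column edge list.

    The first two columns are gene identifiers; optional ``score`` (in
    [0, 1]) and ``channel`` columns support filtering to, e.g., the physical
    subnetwork above a combined-score cutoff.  Self-loops are dropped with a
    warning; duplicate edges are merged keeping the maximum score.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty:
        raise ValueError("empty edge list")
    df.columns = [c.strip().lower() for c in df.columns]
    a_col, b_col = df.columns[:2]
    if channels is not None:
        if "channel" not in df.columns:
            raise ValueError("channel filter requested but no 'channel' column")
        df = df[df["channel"].isin(set(channels))]
    if min_score is not None:
        if "score" not in df.columns:
            raise ValueError("min_score requested but no 'score' column")
        df = df[df["score"] >= min_score]
    loops = df[a_col].astype(str) == df[b_col].astype(str)
    if loops.any():
        warnings.warn(f"dropping {int(loops.sum())} self-loop edge(s)", stacklevel=2)
        df = df[~loops]
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        score = float(getattr(row, "score", 1.0)) if "score" in df.columns else 1.0
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b].get("score", 1.0), score)
        else:
            graph.add_edge(a, b, score=score)
    return graph


def filter_hits_by_network(hits: Iterable[str], network: nx.Graph) -> set[str]:
    """Retain hits with a physical interaction to at least one *other* hit.

    The criterion is evaluated against the original hit list in a single
    pass, so retention of one gene never depends on whether its partner
    itself survives (it always does, by symmetry).
    """
    hit_set = set(hits)
    return {
        h
        for h in hit_set
        if h in network and any(nbr in hit_set and nbr != h for nbr in network.neighbors(h))
    }


def load_ortholog_map(path, sep: str | None = None) -> pd.DataFrame:
    """Load a many-to-many ortholog table (source_gene, target_gene, confidence).

    Duplicate (source, target) pairs collapse to their maximum confidence.
    A missing confidence column defaults to 1.0.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    src, tgt = df.columns[:2]
    out = df.rename(columns={src: "source_gene", tgt: "target_gene"})
    if "confidence" not in out.columns:
        conf_cols = [c for c in out.columns if c in ("score", "weight")]
        out["confidence"] = out[conf_cols[0]] if conf_cols else 1.0
    if (out["confidence"] < 0).any():
        raise ValueError("negative ortholog confidence")
    out = (
        out.groupby(["source_gene", "target_gene"], as_index=False)["confidence"].max()
    )
    return out


def filter_by_orthologs(
    genes: Iterable[str],
    ortholog_map: pd.DataFrame,
    min_confidence: float = 0.0,
) -> pd.DataFrame:
    """Keep genes with at least one ortholog at ``confidence >= min_confidence``.

    Returns one row per retained (source_gene, target_gene) mapping — one
    screened gene may expand to several human genes.
    """
    gene_set = set(map(str, genes))
    m = ortholog_map
    kept = m[
        m["source_gene"].astype(str).isin(gene_set) & (m["confidence"] >= min_confidence)
    ]
    return kept.sort_values(["source_gene", "target_gene"]).reset_index(drop=True)


def group_hits(retained: Iterable[str], network: nx.Graph) -> list[list[str]]:
    """Partition retained genes into connected components of their induced subgraph.

    Genes absent from the network form singleton groups.  Groups are listed
    deterministically, ordered by their lexically smallest member; members
    within a group are sorted.
    """
    retained = set(map(str, retained))
    sub = network.subgraph(retained & set(network.nodes))
    components = [sorted(comp) for comp in nx.connected_components(sub)]
    components += [[g] for g in retained - set(network.nodes)]
    return sorted(components, key=lambda comp: comp[0])
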