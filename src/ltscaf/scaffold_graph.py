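"""Scaffolding graph: link-count-thresholded contig graph and its components.

Contigs are vertices; an edge joins two contigs when enough links connect
them.  Thresholding suppresses edges created by chimeric reads and repeats.
Connected components are the candidate scaffold sets processed downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model_io import ScaffoldGraph, canonical_pair

log = logging.getLogger(__name__)


def pair_link_counts(paired: pd.DataFrame, tgs: pd.DataFrame) -> pd.DataFrame:
    """Tally links per canonical contig pair: columns i, j, a, b.

    ``a`` counts links with relative orientation +1, ``b`` those with -1.
    """
    frames = []
    for df in (paired, tgs):
        if len(df):
            frames.append(df[["i", "j", "d"]])
    if not frames:
        return pd.DataFrame(columns=["i", "j", "a", "b"])
    links = pd.concat(frames, ignore_index=True)
    grouped = links.groupby(["i", "j"])["d"]
    a = grouped.apply(lambda s: int((s == 1).sum()))
    b = grouped.apply(lambda s: int((s == -1).sum()))
    out = pd.DataFrame({"a": a, "b": b}).reset_index()
    return out


def default_threshold(link_counts, floor: int = 2) -> int:
    """Default edge threshold: the 10% quantile of non-zero per-pair counts.

    Lower-interpolation quantile on the sorted counts, floored at ``floor``
    so a single chimeric read can never create an edge.  Users tuning by
    hand are advised to pick between 0.25x and 0.5x the read coverage
    instead.
    """
    counts = np.asarray(link_counts, dtype=float)
    counts = counts[counts > 0]
    if not len(counts):
        raise ValueError("no linking evidence: cannot derive a threshold")
    q = int(np.quantile(counts, 0.1, method="lower"))
    return max(q, floor)


def build_graph(paired: pd.DataFrame, tgs: pd.DataFrame, vertices,
                threshold: int | None = None) -> ScaffoldGraph:
    """Build the thresholded scaffolding graph over ``vertices``.

    An edge (i, j) is retained iff its total link count ``a+b >= threshold``
    (inclusive).  When ``threshold`` is None the default quantile rule is
    applied to the observed per-pair counts.
    """
    counts = pair_link_counts(paired, tgs)
    if threshold is None:
        threshold = default_threshold((counts["a"] + counts["b"]).to_numpy()
                                      if len(counts) else [])
    edges = {}
    for row in counts.itertuples(index=False):
        if row.a + row.b >= threshold:
            edges[canonical_pair(row.i, row.j)] = (int(row.a), int(row.b))
    log.info("scaffold graph: %d vertices, %d/%d edges at threshold %d",
             len(vertices), len(edges), len(counts), threshold)
    return ScaffoldGraph(vertices=set(vertices), edges=edges,
                         threshold=int(threshold))


def write_edge_list(graph: ScaffoldGraph, path) -> None:
    """Dump the graph as a tab-separated edge list (i, j, a, b)."""
    with open(path, "w") as fh:
        fh.write("i\tj\ta\tb\n")
        for (i, j), (a, b) in sorted(graph.edges.items(),
                                     key=lambda kv: (str(kv[0][0]),
                                                     str(kv[0][1]))):
            fh.write(f"{i}\t{j}\t{a}\t{b}\n")


def restrict_links(links: pd.DataFrame, graph: ScaffoldGraph) -> pd.DataFrame:
    """Discard links whose contig pair lost its edge to the threshold."""
    if not len(links):
        return links
    keep = [canonical_pair(i, j) in graph.edges
            for i, j in zip(links["i"], links["j"])]
    return links[np.asarray(keep)].reset_index(drop=True)


def connected_components(graph: ScaffoldGraph) -> list:
    """Partition vertices into connected components (iterative DFS).

    Singleton contigs come through as single-member components.  The result
    is deterministic: components ordered by their smallest member, members
    sorted.
    """
    adjacency: dict = {v: [] for v in graph.vertices}
    for (i, j) in graph.edges:
        adjacency[i].append(j)
        adjacency[j].append(i)
    seen: set = set()
    components = []
    for start in sorted(graph.vertices, key=str):
        if start in seen:
            continue
        stack = [start]
        comp = []
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in sorted(adjacency[v], key=str, reverse=True):
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        components.append(sorted(comp, key=str))
    components.sort(key=lambda c: str(c[0]))
    return components
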