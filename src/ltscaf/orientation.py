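"""Contig orientation by minimising an Ising-type energy over link evidence.

Each contig carries a spin ``D_i`` in {+1, -1} (forward/reverse along the
scaffold axis).  Every link votes for the relative orientation of its two
contigs; the votes are pooled into couplings ``J_ij = (a_ij - b_ij)/2``
where ``a``/``b`` count the +1/-1 votes, and the assignment minimises

    H(D) = - sum_edges J_ij * D_i * D_j .

(The energy is summed once per unordered edge; summing over ordered pairs
merely doubles H and leaves the minimiser unchanged.)  Finding the ground
state is NP-complete, so a deterministic heuristic is used: initialisation
along a maximum-|J| spanning forest, then greedy best-improvement single
spin flips until a local minimum certificate holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import ScaffoldGraph, canonical_pair

log = logging.getLogger(__name__)


@dataclass
class OrientationProblem:
    vertices: list
    couplings: dict  # canonical (i, j) -> J_ij
    counts: dict = field(default_factory=dict)  # canonical (i, j) -> (a, b)


def couplings(graph: ScaffoldGraph, component) -> OrientationProblem:
    """Extract the coupling constants J_ij = (a_ij - b_ij)/2 for a component."""
    comp = set(component)
    J = {}
    counts = {}
    for (i, j), (a, b) in graph.edges.items():
        if i in comp and j in comp:
            J[(i, j)] = (a - b) / 2.0
            counts[(i, j)] = (a, b)
    return OrientationProblem(vertices=sorted(comp, key=str), couplings=J,
                              counts=counts)


def energy(problem: OrientationProblem, D: dict) -> float:
    """H(D) = -sum over unordered edges of J_ij D_i D_j."""
    return -sum(J * D[i] * D[j] for (i, j), J in problem.couplings.items())


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[ry] = rx
        return True


def orient(problem: OrientationProblem, seed: int = 0,
           n_restarts: int = 20) -> dict:
    """Assign orientations minimising H by spanning-tree init + local flips.

    Initialisation visits edges in decreasing |J| (Kruskal maximum-|J|
    spanning forest); each newly attached vertex takes the spin that makes
    its tree edge happy (``D_child = sign(J) * D_parent``).  Refinement
    repeatedly flips the single vertex whose flip decreases H the most
    (ties to the smallest vertex id) until no flip helps.  Because greedy
    descent can stall in a local minimum on frustrated instances, the
    search is repeated from ``n_restarts`` seeded random initialisations
    and the lowest-energy assignment wins (ties to the tree-initialised
    run).  The result is renormalised so the smallest vertex id carries +1
    and is deterministic for a given seed.
    """
    verts = problem.vertices
    if not verts:
        return {}
    index = {v: k for k, v in enumerate(verts)}
    m = len(verts)
    # adjacency with couplings; zero couplings carry no information
    nbrs: list = [[] for _ in range(m)]
    tree_edges = []
    uf = _UnionFind(range(m))
    edges = sorted(problem.couplings.items(),
                   key=lambda kv: (-abs(kv[1]), str(kv[0])))
    for (i, j), J in edges:
        a, b = index[i], index[j]
        if J != 0:
            nbrs[a].append((b, J))
            nbrs[b].append((a, J))
            if uf.union(a, b):
                tree_edges.append((a, b, J))
    # propagate spins over the spanning forest
    D = np.zeros(m, dtype=np.int8)
    tree_adj: list = [[] for _ in range(m)]
    for a, b, J in tree_edges:
        tree_adj[a].append((b, J))
        tree_adj[b].append((a, J))
    for root in range(m):
        if D[root]:
            continue
        D[root] = 1
        stack = [root]
        while stack:
            v = stack.pop()
            for u, J in tree_adj[v]:
                if not D[u]:
                    D[u] = D[v] * (1 if J > 0 else -1)
                    stack.append(u)
    def refine(D):
        # greedy best-improvement single flips; flipping v changes H by
        # delta_v = 2 * sum_u J_vu D_v D_u
        D = D.copy()
        field_ = np.zeros(m)
        for v in range(m):
            field_[v] = sum(J * D[u] for u, J in nbrs[v])
        while True:
            delta = 2.0 * D * field_
            best = int(np.argmin(delta))
            if delta[best] >= -1e-12:
                break
            D[best] = -D[best]
            for u, J in nbrs[best]:
                field_[u] += 2 * J * D[best]
            field_[best] = sum(J * D[u] for u, J in nbrs[best])
        return D

    def H_of(D):
        return -sum(J * D[index[i]] * D[index[j]]
                    for (i, j), J in problem.couplings.items())

    best_D = refine(D)
    best_H = H_of(best_D)
    rng = np.random.default_rng(seed)
    for _ in range(max(n_restarts, 0)):
        cand = refine(rng.choice(np.array([-1, 1], dtype=np.int8), size=m))
        h = H_of(cand)
        if h < best_H - 1e-9:
            best_D, best_H = cand, h
    D = best_D
    if D[0] < 0:  # anchor (smallest id) fixed to +1; H is flip-invariant
        D = -D
    return {v: int(D[index[v]]) for v in verts}


def orientation_supported(links: pd.DataFrame, D: dict) -> pd.DataFrame:
    """Keep links consistent with the assignment: ``d == D_i * D_j``.

    Links touching contigs outside ``D`` are dropped too (they belong to
    other components).
    """
    if not len(links):
        return links
    di = links["i"].map(D)
    dj = links["j"].map(D)
    keep = (links["d"] == di * dj).fillna(False)
    return links[keep].reset_index(drop=True)


def exhaustive_minimum(problem: OrientationProblem) -> float:
    """Exact ground-state energy by enumeration (test oracle; m <= ~20)."""
    verts = problem.vertices
    m = len(verts)
    if m > 24:
        raise ValueError("exhaustive enumeration is limited to small problems")
    index = {v: k for k, v in enumerate(verts)}
    Jmat = np.zeros((m, m))
    for (i, j), J in problem.couplings.items():
        Jmat[index[i], index[j]] = J
        Jmat[index[j], index[i]] = J
    n = 1 << (m - 1) if m > 1 else 1
    bits = ((np.arange(n)[:, None] >> np.arange(m)) & 1)
    S = 1 - 2 * bits.astype(np.float64)  # first spin always +1
    energies = -0.5 * np.einsum("ki,ij,kj->k", S, Jmat, S)
    return float(energies.min())
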