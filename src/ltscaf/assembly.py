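"""Untangling layouts into super-contigs, pipeline iteration, polish, assess.

A position estimate places contigs on a shared axis but allows arbitrary
overlap; untangling walks the contigs in position order and breaks the
layout into *super-contigs* — linear placements with adjacent overlaps no
larger than a tolerance — resolving branches toward the most-linked
neighbour.  The whole pipeline (graph -> orient -> cluster -> regress ->
untangle) is iterated with super-contigs replacing contigs, links remapped
into the new frames each round, until no more merges happen or the
iteration budget ``k`` is spent.  Finally, overlapping adjacent contigs
whose junction sequences locally align are spliced together, and existing
scaffolds can be assessed by plugging their positions into the regression
model and inspecting residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import link_clustering as lc
from . import orientation as ori
from . import scaffold_graph as sg
from .model_io import (Gap, LayoutEstimate, Placement, SuperContig,
                       canonical_pair, revcomp)

log = logging.getLogger(__name__)

DEFAULT_OVERLAP_TOLERANCE = 200


@dataclass
class ScaffoldConfig:
    """Tunable pipeline parameters (defaults per the method)."""

    threshold: int | None = None          # None -> 10% quantile rule
    max_error: float = 100.0              # trimming bound, +50 per round
    iterations: int = 3                   # outer rounds k
    overlap_tolerance: int = DEFAULT_OVERLAP_TOLERANCE
    kernel: str = "gaussian"
    bandwidth_factor: float = 0.5          # KDE bandwidth / insert SD
    merge_distance_factor: float = 2.0
    saddle_ratio: float = 0.6
    min_cluster_size: int = 1
    multi_mode: bool = True               # False: single-median baseline
    confidence_level: float = 0.95
    min_identity: float = 0.95            # polish merge identity gate
    max_overlap_check: int = 2000         # polish: largest overlap attempted


def untangle(layout: LayoutEstimate, lengths: dict,
             overlap_tolerance: int = DEFAULT_OVERLAP_TOLERANCE) -> list:
    """Split one positioned component into linear chains.

    Contigs are walked in position order.  When the next contig overlaps
    the current chain end by more than ``overlap_tolerance`` a branch
    exists: among the consecutive run of such conflicting contigs, the one
    with the most supporting links (trimmed-in observations) to the chain's
    last contig continues the chain — ties broken toward the smaller
    estimated overlap — and every other branch member seeds its own chain.

    Returns a list of chains, each a list of ``(contig, start)`` with
    starts shifted so every chain begins at 0.
    """
    beta = layout.beta
    order = sorted(beta.index, key=lambda v: (beta[v], str(v)))
    support: dict = {}
    for r in layout.selected_observations.itertuples(index=False):
        key = canonical_pair(r.i, r.j)
        support[key] = support.get(key, 0) + int(getattr(r, "n", 1))
    chains = []
    current = [order[0]]
    current_end = beta[order[0]] + lengths[order[0]]
    k = 1
    while k < len(order):
        nxt = order[k]
        overlap = current_end - beta[nxt]
        if overlap <= overlap_tolerance:
            current.append(nxt)
            current_end = max(current_end, beta[nxt] + lengths[nxt])
            k += 1
            continue
        # consecutive run of contigs all conflicting with the chain end
        branch = [nxt]
        k += 1
        while k < len(order) and current_end - beta[order[k]] > overlap_tolerance:
            branch.append(order[k])
            k += 1
        last = current[-1]
        def rank(v):
            sup = support.get(canonical_pair(last, v), 0)
            return (-sup, current_end - beta[v], str(v))
        branch.sort(key=rank)
        winner = branch[0]
        for loser in branch[1:]:
            chains.append([loser])
        current.append(winner)
        current_end = max(current_end, beta[winner] + lengths[winner])
    chains.append(current)
    out = []
    for chain in chains:
        base = min(beta[v] for v in chain)
        out.append([(v, float(beta[v] - base)) for v in
                    sorted(chain, key=lambda v: (beta[v], str(v)))])
    # deterministic order: by first contig id
    out.sort(key=lambda ch: str(ch[0][0]))
    return out


# ---------------------------------------------------------------------------
# iterated pipeline
# ---------------------------------------------------------------------------

@dataclass
class _Unit:
    """A current scaffolding unit: placements of original contigs."""

    id: str
    placements: list
    gaps: list
    length: int


def _contig_to_unit_map(units: dict) -> dict:
    """contig -> (unit id, offset, orientation, contig length, unit length)."""
    mapping = {}
    for uid, unit in units.items():
        for p in unit.placements:
            mapping[p.contig] = (uid, p.start, p.orientation, p.length,
                                 unit.length)
    return mapping


def _remap_paired(paired: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    if not len(paired):
        return paired
    rows = {c: [] for c in paired.columns}
    for r in paired.itertuples(index=False):
        ui, oi, di, li, Li = mapping[r.i]
        uj, oj, dj, lj, Lj = mapping[r.j]
        if ui == uj:
            continue
        s_i = oi + (r.s_i if di > 0 else li - r.s_i)
        s_j = oj + (r.s_j if dj > 0 else lj - r.s_j)
        st_i, st_j = r.strand_i * di, r.strand_j * dj
        if str(ui) > str(uj):
            ui, uj, s_i, s_j, st_i, st_j = uj, ui, s_j, s_i, st_j, st_i
        rows["read_id"].append(r.read_id)
        rows["i"].append(ui)
        rows["j"].append(uj)
        rows["d"].append(-st_i * st_j)
        rows["s_i"].append(s_i)
        rows["s_j"].append(s_j)
        rows["strand_i"].append(st_i)
        rows["strand_j"].append(st_j)
        rows["lib"].append(r.lib)
    return pd.DataFrame(rows)


def _remap_tgs(tgs: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    if not len(tgs):
        return tgs
    rows = {c: [] for c in tgs.columns}
    for r in tgs.itertuples(index=False):
        ui, oi, di, li, Li = mapping[r.i]
        uj, oj, dj, lj, Lj = mapping[r.j]
        if ui == uj:
            continue
        cs_i = oi + (r.cs_i if di > 0 else li - r.cs_i - r.al_i)
        cs_j = oj + (r.cs_j if dj > 0 else lj - r.cs_j - r.al_j)
        st_i, st_j = r.strand_i * di, r.strand_j * dj
        qs_i, qs_j, al_i, al_j = r.qs_i, r.qs_j, r.al_i, r.al_j
        if str(ui) > str(uj):
            ui, uj = uj, ui
            cs_i, cs_j = cs_j, cs_i
            st_i, st_j = st_j, st_i
            qs_i, qs_j = qs_j, qs_i
            al_i, al_j = al_j, al_i
        rows["read_id"].append(r.read_id)
        rows["i"].append(ui)
        rows["j"].append(uj)
        rows["d"].append(st_i * st_j)
        rows["qs_i"].append(qs_i)
        rows["qs_j"].append(qs_j)
        rows["cs_i"].append(cs_i)
        rows["cs_j"].append(cs_j)
        rows["al_i"].append(al_i)
        rows["al_j"].append(al_j)
        rows["strand_i"].append(st_i)
        rows["strand_j"].append(st_j)
        rows["read_len"].append(r.read_len)
        rows["lib"].append(r.lib)
    return pd.DataFrame(rows)


def _unit_lengths(units: dict) -> dict:
    return {uid: u.length for uid, u in units.items()}


def _merge_units(chain: list, units: dict, D: dict, results,
                 new_id: str) -> _Unit:
    """Flatten a chain of positioned units into one new unit."""
    from .regression import ContigPositionResults  # local import, no cycle
    placements = []
    gaps = []
    base = min(start for _u, start in chain)
    prev = None
    cov = results.cov_params() if results is not None and \
        isinstance(results, ContigPositionResults) else None
    support: dict = {}
    if results is not None:
        sel = results.model.observations[results.selected]
        for r in sel.itertuples(index=False):
            key = canonical_pair(r.i, r.j)
            support[key] = support.get(key, 0) + 1
    for uid, start in chain:
        unit = units[uid]
        d = D.get(uid, 1)
        offset = start - base
        if d > 0:
            ps = [Placement(p.contig, p.orientation, int(round(offset + p.start)),
                            p.length, p.trim) for p in unit.placements]
            gs = list(unit.gaps)
        else:
            ps = [Placement(p.contig, -p.orientation,
                            int(round(offset + unit.length - p.end - p.trim)),
                            p.length, p.trim) for p in unit.placements]
            gs = list(reversed(unit.gaps))
        ps.sort(key=lambda p: (p.start, p.contig))
        if prev is not None:
            prev_uid, prev_start = prev
            gap_est = start - (prev_start + units[prev_uid].length)
            se = 0.0
            if cov is not None:
                anchor = results.model.anchor
                var = 0.0
                if prev_uid != anchor:
                    var += cov.loc[prev_uid, prev_uid]
                if uid != anchor:
                    var += cov.loc[uid, uid]
                if prev_uid != anchor and uid != anchor:
                    var -= 2.0 * cov.loc[prev_uid, uid]
                se = float(np.sqrt(max(var, 0.0)))
            gaps.append(Gap(size=float(gap_est),
                            ci_low=gap_est - 1.96 * se,
                            ci_high=gap_est + 1.96 * se,
                            n_clusters=support.get(
                                canonical_pair(prev_uid, uid), 0)))
        placements.extend(ps)
        gaps.extend(gs)
        prev = (uid, start)
    placements.sort(key=lambda p: (p.start, p.contig))
    length = max(p.start + p.length for p in placements)
    return _Unit(id=new_id, placements=placements, gaps=_reindex_gaps(
        placements, gaps), length=int(length))


def _reindex_gaps(placements: list, gaps: list) -> list:
    """Match the gap list to adjacent placements after re-sorting.

    Chains are built left-to-right, so gap order normally survives; this
    guards the bookkeeping invariant (one gap per adjacent pair).
    """
    need = max(len(placements) - 1, 0)
    if len(gaps) == need:
        return gaps
    out = list(gaps)[:need]
    while len(out) < need:
        out.append(Gap(size=1.0, ci_low=float("nan"), ci_high=float("nan")))
    return out


def scaffold_round(units: dict, paired: pd.DataFrame, tgs: pd.DataFrame,
                   libraries: dict, insert_models: dict,
                   config: ScaffoldConfig, max_error: float,
                   round_index: int = 0) -> dict:
    """One pass of graph -> orient -> cluster -> regress -> untangle.

    ``paired``/``tgs`` must already be expressed in the frame of ``units``.
    Returns the new unit dictionary.
    """
    lengths = _unit_lengths(units)
    vertices = list(units)
    try:
        graph = sg.build_graph(paired, tgs, vertices, config.threshold)
    except ValueError:
        log.info("round %d: no linking evidence; all units pass through",
                 round_index)
        return dict(units)
    paired = sg.restrict_links(paired, graph)
    tgs = sg.restrict_links(tgs, graph)
    tasks = sg.connected_components(graph)
    new_units: dict = {}
    serial = 0

    def new_id():
        nonlocal serial
        serial += 1
        return f"u{round_index}_{serial:05d}"

    while tasks:
        comp = tasks.pop(0)
        if len(comp) == 1:
            uid = comp[0]
            new_units[new_id()] = units[uid]
            continue
        comp_set = set(comp)
        p_sub = paired[paired["i"].isin(comp_set) &
                       paired["j"].isin(comp_set)] if len(paired) else paired
        t_sub = tgs[tgs["i"].isin(comp_set) &
                    tgs["j"].isin(comp_set)] if len(tgs) else tgs
        sub_graph = sg.build_graph(p_sub, t_sub, comp, threshold=1) \
            if (len(p_sub) or len(t_sub)) else None
        if sub_graph is None:
            for uid in comp:
                new_units[new_id()] = units[uid]
            continue
        problem = ori.couplings(sub_graph, comp)
        D = ori.orient(problem)
        p_ok = ori.orientation_supported(p_sub, D)
        t_ok = ori.orientation_supported(t_sub, D)
        p_F = lc.compute_paired_distances(p_ok, D, lengths, insert_models,
                                          libraries)
        t_F = lc.compute_tgs_distances(t_ok, D, lengths)
        obs = lc.build_observations(
            p_F, t_F, insert_models, libraries,
            multi_mode=config.multi_mode,
            min_cluster_size=config.min_cluster_size,
            kernel=config.kernel,
            merge_distance_factor=config.merge_distance_factor,
            saddle_ratio=config.saddle_ratio,
            bandwidth_factor=config.bandwidth_factor)
        if not len(obs):
            for uid in comp:
                new_units[new_id()] = units[uid]
            continue
        from .regression import ContigPositionModel
        model = ContigPositionModel(obs, lengths, component=comp)
        res = model.fit(max_error=max_error)
        if res.split is not None:
            log.info("round %d: component of %d split into %d parts",
                     round_index, len(comp), len(res.split))
            for part in res.split:
                tasks.append(part)
            continue
        layout = LayoutEstimate(
            component=comp, D=D, beta=res.params,
            selected_observations=model.observations[res.selected],
            residuals=res.resid, gap_ci=res.gap_confidence(
                config.confidence_level))
        chains = untangle(layout, lengths, config.overlap_tolerance)
        for chain in chains:
            if len(chain) == 1:
                uid = chain[0][0]
                new_units[new_id()] = units[uid]
            else:
                nid = new_id()
                new_units[nid] = _merge_units(chain, units, D, res, nid)
                new_units[nid].id = nid
    return new_units


def iterate_scaffolding(contigs: dict, paired: pd.DataFrame,
                        tgs: pd.DataFrame, libraries: dict,
                        insert_models: dict,
                        config: ScaffoldConfig | None = None) -> list:
    """Run ``config.iterations`` scaffolding rounds and emit super-contigs.

    Each round rebuilds the graph over the current units with the original
    links remapped into unit frames, and relaxes the trimming bound by 50 bp.
    Stops early when a round merges nothing.
    """
    config = config or ScaffoldConfig()
    from .regression import maxerror_schedule
    units = {cid: _Unit(id=cid,
                        placements=[Placement(cid, 1, 0, c.length)],
                        gaps=[], length=c.length)
             for cid, c in contigs.items()}
    for t in range(config.iterations):
        mapping = _contig_to_unit_map(units)
        p_t = _remap_paired(paired, mapping)
        g_t = _remap_tgs(tgs, mapping)
        n_before = len(units)
        units = scaffold_round(units, p_t, g_t, libraries, insert_models,
                               config, maxerror_schedule(config.max_error, t),
                               round_index=t)
        log.info("round %d: %d -> %d units", t, n_before, len(units))
        if len(units) == n_before:
            log.info("no merges in round %d; stopping early", t)
            break
    supercontigs = []
    ordered = sorted(units.values(), key=lambda u: (-u.length, u.id))
    for k, unit in enumerate(ordered, 1):
        supercontigs.append(SuperContig(
            id=f"scaffold_{k:05d}", placements=unit.placements,
            gaps=_reindex_gaps(unit.placements, unit.gaps)))
    return supercontigs


# ---------------------------------------------------------------------------
# polish
# ---------------------------------------------------------------------------

def _best_overlap(left_seq: str, right_seq: str, estimate: int, pad: int):
    """Scan overlap widths near the estimate; return (width, identity)."""
    best = (0, -1.0)
    lo = max(1, estimate - pad)
    hi = min(estimate + pad, len(left_seq), len(right_seq))
    for w in range(lo, hi + 1):
        a = np.frombuffer(left_seq[-w:].encode(), dtype="S1")
        b = np.frombuffer(right_seq[:w].encode(), dtype="S1")
        ident = float((a == b).mean())
        if ident > best[1]:
            best = (w, ident)
    return best


def polish(supercontigs: list, contigs: dict, min_identity: float = 0.95,
           max_overlap_check: int = 2000, pad: int = 50) -> list:
    """Merge adjacent contigs whose estimated overlap is confirmed in sequence.

    For every junction with a negative estimated gap (an overlap up to
    ``max_overlap_check`` bp) the two flanking sequences are compared over
    widths within ``pad`` bp of the estimate; if the best width reaches
    ``min_identity`` the right contig's leading bases are spliced off and
    the junction marked merged, otherwise a 1 bp gap remains.  Positive
    gaps are untouched.  Super-contig sequences are rendered as a side
    effect.
    """
    from .model_io import render_sequence
    out = []
    for sc in supercontigs:
        placements = [Placement(p.contig, p.orientation, p.start, p.length,
                                p.trim) for p in sc.placements]
        gaps = [Gap(g.size, g.ci_low, g.ci_high, g.n_clusters, g.merged)
                for g in sc.gaps]
        for idx, g in enumerate(gaps):
            est_overlap = int(round(-g.size))
            if g.merged or est_overlap <= 0 or est_overlap > max_overlap_check:
                continue
            pl, pr = placements[idx], placements[idx + 1]
            left = contigs[pl.contig].sequence
            right = contigs[pr.contig].sequence
            if left is None or right is None:
                continue
            if pl.orientation < 0:
                left = revcomp(left)
            if pr.orientation < 0:
                right = revcomp(right)
            left = left[pl.trim:]
            w, ident = _best_overlap(left, right[pr.trim:], est_overlap, pad)
            if w > 0 and ident >= min_identity:
                pr.trim += w
                g.size = -w
                g.merged = True
            else:
                g.size = 1
        merged_sc = SuperContig(id=sc.id, placements=placements, gaps=gaps)
        merged_sc.sequence = render_sequence(merged_sc, contigs)
        out.append(merged_sc)
    return out


# ---------------------------------------------------------------------------
# scaffold assessment
# ---------------------------------------------------------------------------

def assess(scaffold: SuperContig, paired: pd.DataFrame, tgs: pd.DataFrame,
           libraries: dict, insert_models: dict,
           max_error: float = 100.0, config: ScaffoldConfig | None = None):
    """Residual-based check of an existing scaffold.

    The scaffold's own placements define positions and orientations; all
    compressed link observations are evaluated against them.  Observations
    with |residual| > ``max_error`` are flagged as outliers, and if their
    removal disconnects the link graph over the scaffold's contigs, each
    break between adjacent contigs is reported as a suspicious junction.

    Returns ``(outliers, junctions)``: a DataFrame of flagged observations
    with residuals, and a list of ``(left_contig, right_contig)`` pairs.
    """
    config = config or ScaffoldConfig()
    members = {p.contig for p in scaffold.placements}
    D = {p.contig: p.orientation for p in scaffold.placements}
    beta = {p.contig: float(p.start) for p in scaffold.placements}
    lengths = {p.contig: p.length for p in scaffold.placements}
    p_sub = paired[paired["i"].isin(members) & paired["j"].isin(members)] \
        if len(paired) else paired
    t_sub = tgs[tgs["i"].isin(members) & tgs["j"].isin(members)] \
        if len(tgs) else tgs
    p_ok = ori.orientation_supported(p_sub, D)
    t_ok = ori.orientation_supported(t_sub, D)
    p_F = lc.compute_paired_distances(p_ok, D, lengths, insert_models,
                                      libraries)
    t_F = lc.compute_tgs_distances(t_ok, D, lengths)
    obs = lc.build_observations(p_F, t_F, insert_models, libraries,
                                multi_mode=config.multi_mode,
                                kernel=config.kernel,
                                merge_distance_factor=config.merge_distance_factor,
                                saddle_ratio=config.saddle_ratio)
    if not len(obs):
        return obs.assign(resid=pd.Series(dtype=float)), []
    resid = (obs["j"].map(beta) - obs["i"].map(beta)) - obs["Y"]
    obs = obs.assign(resid=resid)
    flagged = np.abs(resid.to_numpy()) > max_error
    outliers = obs[flagged].reset_index(drop=True)
    # connectivity over the scaffold's contigs using unflagged observations
    from .regression import _components_over_rows
    good = obs[~flagged]
    comps = _components_over_rows(sorted(members, key=str),
                                  zip(good["i"], good["j"]))
    junctions = []
    if len(comps) > 1:
        comp_of = {}
        for ci, comp in enumerate(comps):
            for v in comp:
                comp_of[v] = ci
        ordered = sorted(scaffold.placements, key=lambda p: p.start)
        for a, b in zip(ordered[:-1], ordered[1:]):
            if comp_of[a.contig] != comp_of[b.contig]:
                junctions.append((a.contig, b.contig))
    return outliers, junctions
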