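"""Alignment filtering and per-library insert-model re-estimation.

Three filters run before scaffolding: ambiguous (multi-mapped) reads are
removed entirely, links touching abnormally high-coverage regions are
dropped, and paired links mapping too far from the contig edge (beyond
``mu + 3*sigma``) are discarded.  Insert means/SDs are re-estimated from
read pairs mapping within single long contigs (> 10 kb), robustly via
median/MAD so chimeric pairs cannot inflate them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import COVERAGE_BIN, Library

log = logging.getLogger(__name__)

#: contigs shorter than this contribute no insert observations
MIN_LONG_CONTIG = 10_000
#: below this many pairs the nominal insert model is kept
MIN_PAIRS = 100
#: consistency factor making MAD unbiased for a normal SD
MAD_SCALE = 1.4826


@dataclass
class InsertModel:
    library_id: str
    mu: float
    sigma: float
    n_pairs_used: int
    from_nominal: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("insert sigma must be > 0")


def nominal_model(lib: Library) -> InsertModel:
    return InsertModel(lib.id, float(lib.insert_mean), float(lib.insert_sd),
                       0, from_nominal=True)


def estimate_insert(insert_obs: pd.DataFrame, contig_lengths: dict,
                    nominal: Library | InsertModel,
                    min_contig_length: int = MIN_LONG_CONTIG,
                    min_pairs: int = MIN_PAIRS) -> InsertModel:
    """Re-estimate one library's insert model from same-contig pairs.

    Only pairs on contigs longer than ``min_contig_length`` are used so the
    observed spans are not truncated by contig ends.  The location/scale are
    the median and 1.4826*MAD.  With fewer than ``min_pairs`` observations
    the nominal model is returned with a warning.
    """
    if isinstance(nominal, Library):
        nominal = nominal_model(nominal)
    lib_id = nominal.library_id
    obs = insert_obs[insert_obs["lib"] == lib_id] if len(insert_obs) else insert_obs
    if len(obs):
        long_enough = obs["contig"].map(
            lambda c: contig_lengths.get(c, 0) > min_contig_length)
        values = obs.loc[long_enough, "insert"].to_numpy(dtype=float)
    else:
        values = np.empty(0)
    if len(values) < min_pairs:
        log.warning("library %s: only %d usable pairs (< %d); keeping nominal "
                    "insert model", lib_id, len(values), min_pairs)
        return InsertModel(lib_id, nominal.mu, nominal.sigma, len(values),
                           from_nominal=True)
    mu = float(np.median(values))
    mad = float(np.median(np.abs(values - mu)))
    sigma = MAD_SCALE * mad
    if sigma <= 0:
        sigma = nominal.sigma
    return InsertModel(lib_id, mu, sigma, len(values))


def estimate_all_inserts(insert_obs: pd.DataFrame, contig_lengths: dict,
                         libraries: dict, **kw) -> dict:
    return {lid: estimate_insert(insert_obs, contig_lengths, lib, **kw)
            for lid, lib in libraries.items() if lib.kind != "TGS"}


def drop_ambiguous(links: pd.DataFrame, id_column: str = "read_id") -> pd.DataFrame:
    """Remove every link from reads that appear more than once.

    A read id occurring in several link rows means the read (or its mate)
    was placed at multiple loci; all of its evidence is discarded.
    """
    if not len(links):
        return links
    counts = links[id_column].value_counts()
    keep = links[id_column].map(counts) == 1
    dropped = int((~keep).sum())
    if dropped:
        log.info("drop_ambiguous: removed %d link rows from multi-mapped reads",
                 dropped)
    return links[keep].reset_index(drop=True)


def mark_high_coverage(coverage: dict, window: int = COVERAGE_BIN,
                       factor: float = 2.0, mad_z: float = 3.0) -> dict:
    """Find per-contig intervals of abnormally high read coverage.

    The cutoff is ``max(factor * median, median + mad_z * 1.4826*MAD)`` over
    all windowed coverage values in the assembly; maximal runs of windows
    above it are returned as ``{contig: [(start, end), ...]}`` in bp.  These
    flag collapsed repeats whose links would be unreliable.
    """
    if not coverage:
        return {}
    allv = np.concatenate([t for t in coverage.values() if len(t)])
    if not len(allv):
        return {}
    med = float(np.median(allv))
    mad_sd = MAD_SCALE * float(np.median(np.abs(allv - med)))
    cutoff = max(factor * med, med + mad_z * mad_sd)
    masks: dict = {}
    for cid, track in coverage.items():
        above = track > cutoff
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8),
                                                       [0]))))
        intervals = [(int(s) * window, int(e) * window)
                     for s, e in zip(edges[::2], edges[1::2])]
        masks[cid] = intervals
    return masks


def apply_coverage_mask(paired: pd.DataFrame, masks: dict) -> pd.DataFrame:
    """Drop paired links whose outer end on either contig falls in a mask."""
    if not len(paired) or not masks:
        return paired

    def inside(contig, pos):
        for s, e in masks.get(contig, ()):
            if s <= pos < e:
                return True
        return False

    bad = paired.apply(lambda r: inside(r["i"], r["s_i"]) or
                       inside(r["j"], r["s_j"]), axis=1)
    if bad.any():
        log.info("coverage mask: removed %d links", int(bad.sum()))
    return paired[~bad].reset_index(drop=True)


def _edge_distances(paired: pd.DataFrame, contig_lengths: dict,
                    libraries: dict) -> tuple:
    """Distance of each read's outer end from its contig's relevant edge.

    The relevant edge is the one the mate extends past: for inward (PE)
    geometry a forward read's mate lies downstream, so the distance is to
    the contig's 3' edge; a reverse read's is to the 5' edge.  Outward raw
    MP geometry mirrors the rule.  The measure is orientation-invariant, so
    it can run before contigs are oriented.
    """
    len_i = paired["i"].map(contig_lengths).to_numpy(dtype=float)
    len_j = paired["j"].map(contig_lengths).to_numpy(dtype=float)
    pe_geom = paired["lib"].map(lambda l: libraries[l].pe_geometry).to_numpy()
    s_i = paired["s_i"].to_numpy(dtype=float)
    s_j = paired["s_j"].to_numpy(dtype=float)
    fwd_i = paired["strand_i"].to_numpy() > 0
    fwd_j = paired["strand_j"].to_numpy() > 0
    # mate lies toward the 3' edge when (forward XOR outward-geometry)
    toward_3p_i = np.where(pe_geom, fwd_i, ~fwd_i)
    toward_3p_j = np.where(pe_geom, fwd_j, ~fwd_j)
    d_i = np.where(toward_3p_i, len_i - s_i, s_i)
    d_j = np.where(toward_3p_j, len_j - s_j, s_j)
    return d_i, d_j


def edge_filter(paired: pd.DataFrame, insert_models: dict,
                contig_lengths: dict, libraries: dict,
                z: float = 3.0) -> pd.DataFrame:
    """Keep paired links whose reads map within ``mu + z*sigma`` of the edge.

    A mate can only land on the neighbouring contig when its anchor read is
    within roughly one insert of the contig boundary; anything farther is a
    chimera or mismap.  The bound is inclusive.  TGS links are untouched by
    this filter.
    """
    if not len(paired):
        return paired
    d_i, d_j = _edge_distances(paired, contig_lengths, libraries)
    bound = paired["lib"].map(
        lambda l: insert_models[l].mu + z * insert_models[l].sigma
    ).to_numpy(dtype=float)
    keep = (d_i <= bound) & (d_j <= bound)
    removed = int((~keep).sum())
    if removed:
        log.info("edge filter: removed %d links beyond mu+%gsigma",
                 removed, z)
    return paired[keep].reset_index(drop=True)
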