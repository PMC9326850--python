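"""Linking distances and their multi-modal clustering into regression rows.

Every orientation-supported link measures the difference between its two
contigs' start coordinates on the scaffold axis.  For a paired read with
outer-end mapping coordinates ``s_i``/``s_j`` and library insert mean
``mu_b``:

    F_ijr = mu_b + s_ir - s_jr        when contig i is upstream,
    F_ijr = -(mu_b - s_ir + s_jr)     when contig j is upstream;

for a long read spanning both contigs:

    F_ijr = qs_jr - qs_ir + cs_ir - cs_jr .

With canonical pair order (i < j) every F observes ``beta_j - beta_i``.

Per contig pair and per library, the distances are usually unimodal — but
repeats and contaminated libraries produce extra modes.  A Gaussian kernel
density with bandwidth ``sigma_b / 2`` is scanned for well-separated peaks;
each link joins its nearest peak, and each cluster is compressed to its
median.  By the central limit theorem for the sample median, the cluster
median errs like N(0, pi*sigma_b^2 / (2 n)), so the observation receives
weight ``n / sigma_b^2`` (the sample variance replaces ``sigma_b^2`` once
the cluster holds more than 6 links).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from sklearn.neighbors import KernelDensity

from .model_io import CompressedObservation, Library
from .preprocess import MAD_SCALE, InsertModel

log = logging.getLogger(__name__)

#: sample variance replaces sigma_b^2 for clusters larger than this
SAMPLE_VAR_MIN = 6
#: floor for the TGS pseudo-bandwidth sigma (bp)
TGS_SIGMA_FLOOR = 50.0

OBS_COLUMNS = ["i", "j", "lib", "Y", "n", "w"]


def median_sd(sigma: float, n: int) -> float:
    """Asymptotic SD of the median of n draws from N(mu, sigma^2)."""
    return math.sqrt(math.pi / (2.0 * n)) * sigma

def residual_bound(sigma: float, n: int, z: float = 2.0) -> float:
    """Residual bound z * sqrt(pi/(2n)) * sigma for a compressed observation.

    With the typical insert SD 500 and cluster size 150 this evaluates to
    about 102.33 bp, motivating the default trimming threshold of 100 bp.
    """
    return z * median_sd(sigma, n)


def paired_distance(mu: float, s_i: float, s_j: float,
                    i_upstream: bool) -> float:
    """Linking distance of one paired read (scalar form)."""
    if i_upstream:
        return mu + s_i - s_j
    return -(mu - s_i + s_j)


def tgs_distance(qs_i: float, qs_j: float, cs_i: float, cs_j: float) -> float:
    """Linking distance of one long read (scalar form)."""
    return qs_j - qs_i + cs_i - cs_j


def compute_paired_distances(paired: pd.DataFrame, D: dict,
                             contig_lengths: dict, insert_models: dict,
                             libraries: dict) -> pd.DataFrame:
    """Vectorised F for orientation-supported paired links.

    Coordinates are first mapped into the oriented frame (contigs with
    ``D = -1`` are mirrored: ``s' = len - s``, strand flipped); the upstream
    side is then identified from the oriented strand under the library's
    pair geometry, and F is signed so it observes ``beta_j - beta_i`` for
    the canonical (i < j) pair.
    """
    if not len(paired):
        out = paired.copy()
        out["F"] = pd.Series(dtype=float)
        return out
    di = paired["i"].map(D).to_numpy(dtype=float)
    dj = paired["j"].map(D).to_numpy(dtype=float)
    len_i = paired["i"].map(contig_lengths).to_numpy(dtype=float)
    len_j = paired["j"].map(contig_lengths).to_numpy(dtype=float)
    s_i = np.where(di > 0, paired["s_i"], len_i - paired["s_i"])
    s_j = np.where(dj > 0, paired["s_j"], len_j - paired["s_j"])
    str_i = paired["strand_i"].to_numpy() * di
    str_j = paired["strand_j"].to_numpy() * dj
    mu = paired["lib"].map(lambda l: insert_models[l].mu).to_numpy(dtype=float)
    pe_geom = paired["lib"].map(lambda l: libraries[l].pe_geometry).to_numpy()
    # inward geometry: the forward read's mate lies downstream; outward: reverse
    i_upstream = np.where(pe_geom, str_i > 0, str_i < 0)
    out = paired.copy()
    out["F"] = np.where(i_upstream, mu + s_i - s_j, -(mu - s_i + s_j))
    if not np.all(str_i * str_j < 0):
        log.warning("paired links with equal oriented strands slipped through "
                    "orientation support; their F values are unreliable")
    return out


def compute_tgs_distances(tgs: pd.DataFrame, D: dict,
                          contig_lengths: dict) -> pd.DataFrame:
    """Vectorised F for orientation-supported TGS links.

    Contig alignment starts are mirrored for reversed contigs
    (``cs' = len - cs - al``); when the read aligns in reverse on both
    (oriented) contigs its coordinates are rewritten in the read's
    reverse-complement frame so the co-linearity formula applies.
    """
    if not len(tgs):
        out = tgs.copy()
        out["F"] = pd.Series(dtype=float)
        return out
    di = tgs["i"].map(D).to_numpy(dtype=float)
    dj = tgs["j"].map(D).to_numpy(dtype=float)
    len_i = tgs["i"].map(contig_lengths).to_numpy(dtype=float)
    len_j = tgs["j"].map(contig_lengths).to_numpy(dtype=float)
    cs_i = np.where(di > 0, tgs["cs_i"], len_i - tgs["cs_i"] - tgs["al_i"])
    cs_j = np.where(dj > 0, tgs["cs_j"], len_j - tgs["cs_j"] - tgs["al_j"])
    str_i = tgs["strand_i"].to_numpy() * di
    rl = tgs["read_len"].to_numpy(dtype=float)
    reverse = str_i < 0  # both strands equal after orientation support
    qs_i = np.where(reverse, rl - tgs["qs_i"] - tgs["al_i"], tgs["qs_i"])
    qs_j = np.where(reverse, rl - tgs["qs_j"] - tgs["al_j"], tgs["qs_j"])
    out = tgs.copy()
    out["F"] = qs_j - qs_i + cs_i - cs_j
    return out


def cluster_pair(distances, sigma: float, kernel: str = "gaussian",
                 merge_distance_factor: float = 2.0,
                 saddle_ratio: float = 0.6,
                 grid_step_factor: float = 0.05,
                 pad_factor: float = 3.0,
                 bandwidth_factor: float = 0.5) -> list:
    """Cluster one (contig pair, library)'s linking distances by their KDE.

    A kernel density (bandwidth ``sigma * bandwidth_factor``, default half
    the insert SD) is evaluated on a grid of step ``sigma *
    grid_step_factor`` padded ``pad_factor * sigma`` beyond the data range.  Local maxima are peak candidates; peaks closer than
    ``merge_distance_factor * sigma`` or whose connecting saddle exceeds
    ``saddle_ratio`` of the lower peak are merged (they are not "well
    separated").  Each distance joins its nearest surviving peak.

    Returns a list of index arrays into ``distances``, ordered by peak
    position.
    """
    x = np.asarray(distances, dtype=float)
    if not len(x):
        return []
    if x.max() - x.min() < 1e-9 or len(x) == 1:
        return [np.arange(len(x))]
    lo, hi = x.min() - pad_factor * sigma, x.max() + pad_factor * sigma
    step = max(sigma * grid_step_factor, 1e-6)
    grid = np.arange(lo, hi + step, step)
    kde = KernelDensity(bandwidth=sigma * bandwidth_factor, kernel=kernel)
    kde.fit(x[:, None])
    dens = np.exp(kde.score_samples(grid[:, None]))
    peak_idx = argrelextrema(dens, np.greater_equal, order=1)[0]
    # collapse plateaus and drop flat zero regions
    peaks = []
    for p in peak_idx:
        if dens[p] <= 0:
            continue
        if peaks and p - peaks[-1] == 1 and dens[p] == dens[peaks[-1]]:
            continue
        peaks.append(int(p))
    if not peaks:
        peaks = [int(np.argmax(dens))]
    # iteratively merge peaks that are not well separated
    while len(peaks) > 1:
        merged = False
        for k in range(len(peaks) - 1):
            p, q = peaks[k], peaks[k + 1]
            saddle = dens[p:q + 1].min()
            lower = min(dens[p], dens[q])
            if (grid[q] - grid[p] < merge_distance_factor * sigma
                    or saddle > saddle_ratio * lower):
                peaks.pop(k if dens[p] < dens[q] else k + 1)
                merged = True
                break
        if not merged:
            break
    centres = grid[peaks]
    assignment = np.argmin(np.abs(x[:, None] - centres[None, :]), axis=1)
    return [np.flatnonzero(assignment == k) for k in range(len(centres))
            if np.any(assignment == k)]


def compress(member_distances, sigma: float) -> tuple:
    """Compress one cluster to (median, n, weight).

    The weight is ``n / variance`` with the variance basis being the
    library's ``sigma^2``, replaced by the cluster's sample variance when
    the cluster holds more than ``SAMPLE_VAR_MIN`` links.
    """
    x = np.asarray(member_distances, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("cannot compress an empty cluster")
    y = float(np.median(x))
    if n > SAMPLE_VAR_MIN:
        var = float(np.var(x, ddof=1))
        if var <= 0:
            var = sigma ** 2
    else:
        var = sigma ** 2
    return y, n, n / var


def _pair_sigma(lib: Library, model: InsertModel | None,
                distances: np.ndarray) -> float:
    """Clustering scale: the library sigma, or a robust MAD-based pseudo-sigma
    (floored) for TGS libraries which carry no insert model."""
    if lib.kind != "TGS" and model is not None:
        return model.sigma
    med = np.median(distances)
    mad_sd = MAD_SCALE * float(np.median(np.abs(distances - med)))
    return max(mad_sd, TGS_SIGMA_FLOOR)


def build_observations(paired_F: pd.DataFrame, tgs_F: pd.DataFrame,
                       insert_models: dict, libraries: dict,
                       multi_mode: bool = True,
                       min_cluster_size: int = 1,
                       kernel: str = "gaussian",
                       merge_distance_factor: float = 2.0,
                       saddle_ratio: float = 0.6,
                       bandwidth_factor: float = 0.5) -> pd.DataFrame:
    """Cluster and compress all links into the observation table.

    One row per (contig pair, library, mode): columns ``i, j, lib, Y, n, w``.
    ``multi_mode=False`` is the single-median baseline used for contrast in
    the test-suite: every pair/library collapses to one observation
    regardless of modality.
    """
    frames = [df for df in (paired_F, tgs_F) if len(df)]
    rows = []
    for df in frames:
        for (i, j, lib_id), group in df.groupby(["i", "j", "lib"], sort=True):
            x = group["F"].to_numpy(dtype=float)
            lib = libraries[lib_id]
            sigma = _pair_sigma(lib, insert_models.get(lib_id), x)
            if multi_mode:
                clusters = cluster_pair(
                    x, sigma, kernel=kernel,
                    merge_distance_factor=merge_distance_factor,
                    saddle_ratio=saddle_ratio,
                    bandwidth_factor=bandwidth_factor)
            else:
                clusters = [np.arange(len(x))]
            for members in clusters:
                if len(members) < min_cluster_size:
                    continue
                y, n, w = compress(x[members], sigma)
                rows.append((i, j, lib_id, y, n, w))
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return obs.sort_values(["i", "j", "lib", "Y"]).reset_index(drop=True)


def write_cluster_tsv(obs: pd.DataFrame, path) -> None:
    """Dump the observation table (one row per cluster) for inspection."""
    cols = [c for c in ("i", "j", "lib", "Y", "n", "w") if c in obs.columns]
    obs[cols].to_csv(path, sep="\t", index=False)


def to_compressed_observations(obs: pd.DataFrame) -> list:
    """Observation table rows as :class:`CompressedObservation` records."""
    return [CompressedObservation(i=r.i, j=r.j, library_id=r.lib, Y=r.Y,
                                  n=int(r.n), w=r.w)
            for r in obs.itertuples(index=False)]
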