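"""Planted-truth simulator for genomes, contig sets and alignment-level links.

The generator emulates the statistical structure the scaffolder assumes:
normal insert sizes per library, inward (PE) and outward (MP) pair
geometries, long reads spanning several contigs, short-insert contamination
of mate-pair libraries (a bimodal insert distribution), and the mis-mapping
of reads whose true locus sits in an unassembled tandem-repeat copy onto a
surviving homologous copy — the mechanism that creates dominant false link
clusters offset by one repeat unit.

Links are emitted directly at the alignment level (the scaffolder consumes
alignments; base-level errors only matter through the external mapper) with
a truth table sufficient to score every pipeline stage.  All outputs are
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import (INSERT_COLUMNS, PAIRED_COLUMNS, TGS_COLUMNS, Contig,
                       Library, empty_insert_obs, empty_paired_links,
                       empty_tgs_links, revcomp)

TRUTH_COLUMNS = ["contig", "start", "end", "orient"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_genome(length: int, repeats=None, seed: int = 0) -> str:
    """Uniform-random genome with optional exact tandem-repeat blocks.

    ``repeats`` is a list of ``(unit_length, copies, position)``; each block
    replaces ``unit_length * copies`` bp at ``position`` with identical
    copies of one random unit.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    for unit_length, copies, position in (repeats or []):
        if position + unit_length * copies > length:
            raise ValueError("repeat block does not fit inside the genome")
        unit = rng.choice(_BASES, size=unit_length)
        block = np.tile(unit, copies)
        seq[position:position + len(block)] = block
    return seq.tobytes().decode()


def fragment(genome: str, intervals) -> tuple:
    """Cut contigs out of a genome at explicit intervals.

    ``intervals``: list of ``(id, start, end, orient)``; the contig sequence
    is ``genome[start:end]``, reverse-complemented when ``orient == -1``
    (emulating arbitrary assembly strand).  Regions covered by no interval
    are unassembled (dropped).  Returns ``(contigs, truth)`` where truth is
    a DataFrame with columns contig/start/end/orient.
    """
    contigs: dict = {}
    rows = []
    for cid, start, end, orient in intervals:
        if not (0 <= start < end <= len(genome)):
            raise ValueError(f"interval {cid!r} outside the genome")
        if cid in contigs:
            raise ValueError(f"duplicate contig id {cid!r}")
        seq = genome[start:end]
        if orient == -1:
            seq = revcomp(seq)
        contigs[cid] = Contig(id=cid, length=end - start, sequence=seq)
        rows.append((cid, start, end, orient))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS).sort_values("start") \
        .reset_index(drop=True)
    if (truth["start"].to_numpy()[1:] < truth["end"].to_numpy()[:-1]).any():
        raise ValueError("contig intervals overlap")
    return contigs, truth


def fragment_evenly(genome: str, n_contigs: int, gap_length: int = 500,
                    rc_ids=(), prefix: str = "c") -> tuple:
    """Cut a genome into equal contigs separated by fixed unassembled gaps."""
    L = len(genome)
    span = (L - (n_contigs - 1) * gap_length) // n_contigs
    if span < 1:
        raise ValueError("gaps larger than the genome")
    width = len(str(n_contigs))
    intervals = []
    for k in range(n_contigs):
        start = k * (span + gap_length)
        cid = f"{prefix}{k + 1:0{width}d}"
        intervals.append((cid, start, start + span,
                          -1 if cid in set(rc_ids) else 1))
    return fragment(genome, intervals)


def _truth_arrays(truth: pd.DataFrame):
    t = truth.sort_values("start")
    return (t["start"].to_numpy(np.int64), t["end"].to_numpy(np.int64),
            t["contig"].to_numpy(), t["orient"].to_numpy(np.int64))


def _locate(starts, ends, a, b):
    """Index of the contig fully containing [a, b), else -1 (vectorised)."""
    idx = np.searchsorted(starts, a, side="right") - 1
    idx_c = np.clip(idx, 0, len(starts) - 1)
    ok = (idx >= 0) & (a >= starts[idx_c]) & (b <= ends[idx_c])
    return np.where(ok, idx_c, -1)


def _relocate(a, b, starts, ends, repeats, rng, rate):
    """Mis-map a read from a dropped repeat copy onto a surviving homolog.

    Returns the shift to apply (0 when the read stays unmapped).  Candidate
    shifts are whole repeat units within the same block; the nearest
    surviving copy wins (ties toward the downstream copy).
    """
    if not repeats or rate <= 0:
        return 0
    for unit, copies, position in repeats:
        block_end = position + unit * copies
        if position <= a and b <= block_end:
            if rng.random() >= rate:
                return 0
            candidates = []
            for k in range(-(copies - 1), copies):
                if k == 0:
                    continue
                na, nb = a + k * unit, b + k * unit
                if na < position or nb > block_end:
                    continue
                if _locate(starts, ends, np.array([na]), np.array([nb]))[0] >= 0:
                    candidates.append((abs(k), -np.sign(k), k * unit))
            if candidates:
                return min(candidates)[2]
            return 0
    return 0


def simulate_paired_links(genome_length: int, truth: pd.DataFrame,
                          library: Library, coverage: float,
                          contamination_fraction: float = 0.0,
                          contaminant_mean: float = 300.0,
                          contaminant_sd: float = 30.0,
                          mismap_rate: float = 0.0,
                          repeats=None, seed: int = 0) -> tuple:
    """Simulate one paired library against a fragmented genome.

    Fragments start uniformly; inserts are N(mu, sd^2) truncated at twice
    the read length, with ``contamination_fraction`` of pairs drawn from the
    short contaminant distribution instead.  Each read maps to the contig
    fully containing its locus.  Reads falling in a dropped tandem-repeat
    copy are, with probability ``mismap_rate``, relocated one-or-more repeat
    units onto a surviving homologous copy; otherwise the pair is discarded.

    Returns ``(paired_links, insert_obs)``.
    """
    if coverage <= 0:
        return empty_paired_links(), empty_insert_obs()
    rng = np.random.default_rng(seed)
    rl = int(library.read_length or 100)
    mu, sd = float(library.insert_mean), float(library.insert_sd)
    n = int(round(coverage * genome_length / (2.0 * rl)))
    ins = rng.normal(mu, sd, size=n)
    if contamination_fraction > 0:
        contaminated = rng.random(n) < contamination_fraction
        ins[contaminated] = rng.normal(contaminant_mean, contaminant_sd,
                                       size=int(contaminated.sum()))
    ins = np.maximum(np.rint(ins).astype(np.int64), 2 * rl)
    ins = np.minimum(ins, genome_length)
    s = np.floor(rng.random(n) * (genome_length - ins + 1)).astype(np.int64)

    starts, ends, cids, orients = _truth_arrays(truth)
    # read intervals: left [s, s+rl), right [s+ins-rl, s+ins)
    a1, b1 = s, s + rl
    a2, b2 = s + ins - rl, s + ins
    idx1 = _locate(starts, ends, a1, b1)
    idx2 = _locate(starts, ends, a2, b2)
    shift1 = np.zeros(n, dtype=np.int64)
    shift2 = np.zeros(n, dtype=np.int64)
    if repeats and mismap_rate > 0:
        for k in np.flatnonzero(idx1 < 0):
            shift1[k] = _relocate(a1[k], b1[k], starts, ends, repeats, rng,
                                  mismap_rate)
        for k in np.flatnonzero(idx2 < 0):
            shift2[k] = _relocate(a2[k], b2[k], starts, ends, repeats, rng,
                                  mismap_rate)
        moved1 = shift1 != 0
        moved2 = shift2 != 0
        idx1[moved1] = _locate(starts, ends, a1[moved1] + shift1[moved1],
                               b1[moved1] + shift1[moved1])
        idx2[moved2] = _locate(starts, ends, a2[moved2] + shift2[moved2],
                               b2[moved2] + shift2[moved2])
    mapped = (idx1 >= 0) & (idx2 >= 0)

    # observed genome-frame outer ends (mis-mapped reads report shifted loci)
    outer1 = s + shift1
    outer2 = s + ins + shift2
    if library.pe_geometry:
        g1, g2 = 1, -1  # inward: left mate forward, right mate reverse
    else:
        g1, g2 = -1, 1  # outward (raw MP)

    same = mapped & (idx1 == idx2)
    insert_rows = pd.DataFrame({
        "contig": cids[idx1[same]],
        "insert": (outer2[same] - outer1[same]),
        "lib": library.id,
    }) if same.any() else empty_insert_obs()

    link = mapped & (idx1 != idx2)
    if not link.any():
        return empty_paired_links(), insert_rows
    k = np.flatnonzero(link)
    c1, c2 = cids[idx1[k]], cids[idx2[k]]
    o1 = np.where(orients[idx1[k]] > 0, outer1[k] - starts[idx1[k]],
                  ends[idx1[k]] - outer1[k])
    o2 = np.where(orients[idx2[k]] > 0, outer2[k] - starts[idx2[k]],
                  ends[idx2[k]] - outer2[k])
    s1 = g1 * orients[idx1[k]]
    s2 = g2 * orients[idx2[k]]
    swap = c1.astype(str) > c2.astype(str)
    i = np.where(swap, c2, c1)
    j = np.where(swap, c1, c2)
    s_i = np.where(swap, o2, o1)
    s_j = np.where(swap, o1, o2)
    str_i = np.where(swap, s2, s1)
    str_j = np.where(swap, s1, s2)
    paired = pd.DataFrame({
        "read_id": [f"{library.id}_{x}" for x in k],
        "i": i, "j": j, "d": -str_i * str_j,
        "s_i": s_i, "s_j": s_j, "strand_i": str_i, "strand_j": str_j,
        "lib": library.id,
    })[PAIRED_COLUMNS]
    return paired, insert_rows


def simulate_tgs_links(genome_length: int, truth: pd.DataFrame,
                       library: Library, coverage: float,
                       read_length_mean: float = 8000.0,
                       read_length_sd: float | None = None,
                       min_aln: int = 500, seed: int = 0) -> pd.DataFrame:
    """Simulate error-free long reads and emit a TGS link per bridged pair.

    Read spans are uniform on the genome; every pair of contigs a read
    overlaps by at least ``min_aln`` bp yields one link carrying the
    alignment start coordinates on the read and on each contig.
    """
    if coverage <= 0:
        return empty_tgs_links()
    rng = np.random.default_rng(seed)
    n = int(round(coverage * genome_length / read_length_mean))
    sd = read_length_sd if read_length_sd is not None else read_length_mean / 10
    lengths = np.maximum(np.rint(rng.normal(read_length_mean, sd, n)),
                         2 * min_aln).astype(np.int64)
    lengths = np.minimum(lengths, genome_length)
    starts_r = np.floor(rng.random(n) * (genome_length - lengths + 1)) \
        .astype(np.int64)
    cst, cen, cids, orients = _truth_arrays(truth)
    rows = []
    for r in range(n):
        rs, re = int(starts_r[r]), int(starts_r[r] + lengths[r])
        hits = []
        for t in range(len(cst)):
            lo, hi = max(rs, int(cst[t])), min(re, int(cen[t]))
            if hi - lo >= min_aln:
                qs = lo - rs
                al = hi - lo
                if orients[t] > 0:
                    cs, strand = lo - int(cst[t]), 1
                else:
                    cs, strand = int(cen[t]) - hi, -1
                hits.append((str(cids[t]), qs, cs, al, strand))
            if cst[t] > re:
                break
        for x in range(len(hits)):
            for y in range(x + 1, len(hits)):
                hi_, hj_ = hits[x], hits[y]
                if hi_[0] > hj_[0]:
                    hi_, hj_ = hj_, hi_
                rows.append((f"{library.id}_{r}", hi_[0], hj_[0],
                             hi_[4] * hj_[4], hi_[1], hj_[1], hi_[2], hj_[2],
                             hi_[3], hj_[3], hi_[4], hj_[4],
                             int(lengths[r]), library.id))
    return pd.DataFrame(rows, columns=TGS_COLUMNS) if rows else empty_tgs_links()


# ---------------------------------------------------------------------------
# scenario bundles
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    """Everything a test needs to run and score the pipeline."""

    genome: str
    contigs: dict
    truth: pd.DataFrame
    libraries: dict
    paired: pd.DataFrame
    tgs: pd.DataFrame
    insert_obs: pd.DataFrame
    repeats: list = field(default_factory=list)

    def true_positions(self) -> pd.Series:
        """True start coordinate of each contig on the genome axis."""
        t = self.truth.sort_values("start")
        return pd.Series(t["start"].to_numpy(dtype=float),
                         index=t["contig"], name="true_start")

    def true_gaps(self) -> pd.DataFrame:
        """True gap between genome-adjacent contigs."""
        t = self.truth.sort_values("start").reset_index(drop=True)
        rows = []
        for k in range(len(t) - 1):
            rows.append((t.loc[k, "contig"], t.loc[k + 1, "contig"],
                         int(t.loc[k + 1, "start"] - t.loc[k, "end"])))
        return pd.DataFrame(rows, columns=["left", "right", "gap"])


def chain_scenario(seed: int = 0, length: int = 200_000, n_contigs: int = 40,
                   gap_length: int = 500, rc_alternate: bool = True,
                   pe_coverage: float = 30.0, mp_coverage: float = 30.0,
                   contamination_fraction: float = 0.0) -> SimBundle:
    """A chain genome cut into equal contigs, with one PE and one MP library.

    The short-insert PE library (300 +/- 30 bp) supplies coverage and
    insert-model evidence; the MP library (3000 +/- 300 bp) spans the
    unassembled gaps and carries the ordering signal.  Every other contig
    is reverse-complemented so the orientation stage is exercised.
    """
    genome = make_genome(length, seed=seed)
    width = len(str(n_contigs))
    rc_ids = [f"c{k + 1:0{width}d}" for k in range(n_contigs) if k % 2] \
        if rc_alternate else []
    contigs, truth = fragment_evenly(genome, n_contigs, gap_length,
                                     rc_ids=rc_ids)
    libraries = {
        "pe1": Library("pe1", "PE", 300, 30, read_length=100),
        "mp1": Library("mp1", "MP", 3000, 300, read_length=100),
    }
    p1, i1 = simulate_paired_links(length, truth, libraries["pe1"],
                                   pe_coverage, seed=seed + 1)
    p2, i2 = simulate_paired_links(
        length, truth, libraries["mp1"], mp_coverage,
        contamination_fraction=contamination_fraction, seed=seed + 2)
    paired = pd.concat([p1, p2], ignore_index=True)
    inserts = pd.concat([i1, i2], ignore_index=True)
    return SimBundle(genome, contigs, truth, libraries, paired,
                     empty_tgs_links(), inserts)


def contamination_scenario(seed: int = 0, length: int = 60_000,
                           n_contigs: int = 12,
                           contamination_fraction: float = 0.4) -> SimBundle:
    """A chain with short (50 bp) gaps and a PE-contaminated MP library.

    40% of the mate-pair inserts are drawn from the short-insert
    contaminant (300 +/- 30 bp).  Because the gaps are short, contaminant
    pairs can physically span junctions; their linking distances — computed
    under the nominal 3000 bp insert — form a false mode about +2700 bp
    above the true one, which the trimming regression must reject.
    """
    genome = make_genome(length, seed=seed)
    contigs, truth = fragment_evenly(genome, n_contigs, gap_length=50)
    libraries = {
        "mp1": Library("mp1", "MP", 3000, 300, read_length=100),
    }
    paired, inserts = simulate_paired_links(
        length, truth, libraries["mp1"], coverage=30.0,
        contamination_fraction=contamination_fraction, seed=seed + 1)
    return SimBundle(genome, contigs, truth, libraries, paired,
                     empty_tgs_links(), inserts)


def tandem_repeat_scenario(seed: int = 0, coverage: float = 40.0,
                           mismap_rate: float = 1.0) -> SimBundle:
    """Three contigs around a 4-copy tandem repeat (unit 600 bp).

    Three of the four copies are unassembled; reads from the missing copies
    mis-map onto the surviving copy at the start of the middle contig,
    producing false link clusters offset by whole repeat units that
    outnumber the true cluster between the middle and right contigs.  A
    longer-insert library bridges the outer contigs and supplies the global
    evidence that lets the trimming regression discard the false modes.
    """
    unit, copies, position = 600, 4, 10_000
    length = 30_000
    genome = make_genome(length, repeats=[(unit, copies, position)], seed=seed)
    intervals = [
        ("c12", 0, 10_000, 1),        # ends at the repeat block
        ("c13", 11_800, 12_600, 1),   # surviving copy 4 + 200 bp unique
        ("c14", 12_800, 30_000, 1),
    ]
    contigs, truth = fragment(genome, intervals)
    libraries = {
        "mp1": Library("mp1", "MP", 3000, 150, read_length=100),
        "mp2": Library("mp2", "MP", 6000, 200, read_length=100),
    }
    repeats = [(unit, copies, position)]
    p1, i1 = simulate_paired_links(length, truth, libraries["mp1"], coverage,
                                   mismap_rate=mismap_rate, repeats=repeats,
                                   seed=seed + 1)
    p2, i2 = simulate_paired_links(length, truth, libraries["mp2"], coverage,
                                   mismap_rate=mismap_rate, repeats=repeats,
                                   seed=seed + 2)
    paired = pd.concat([p1, p2], ignore_index=True)
    inserts = pd.concat([i1, i2], ignore_index=True)
    return SimBundle(genome, contigs, truth, libraries, paired,
                     empty_tgs_links(), inserts, repeats=repeats)
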