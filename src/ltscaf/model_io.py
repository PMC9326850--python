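"""Domain types shared by every scaffolding stage, plus format readers/writers.

Internally every coordinate is 0-based, half-open.  SAM's 1-based positions are
converted by pysam on read; AGP's 1-based inclusive coordinates are converted on
write and back-converted on read.

Link tables
-----------
Links are carried in bulk as :class:`pandas.DataFrame` tables (one row per
linking read) so downstream stages can vectorise.  Two schemas exist:

paired links (``PAIRED_COLUMNS``):
    ``read_id, i, j, d, s_i, s_j, strand_i, strand_j, lib``
    where ``i < j`` (canonical pair order), ``d`` is the relative orientation
    in {+1, -1}, ``s_*`` the outer-end mapping coordinate on each contig (the
    distance from the contig start to the outer end of the mapped read, in the
    contig's own FASTA frame) and ``strand_*`` the read strand (+1 forward) on
    the contig's FASTA frame.

TGS links (``TGS_COLUMNS``):
    ``read_id, i, j, d, qs_i, qs_j, cs_i, cs_j, al_i, al_j, strand_i,
    strand_j, read_len, lib``
    with ``qs_*`` alignment starts on the long read (original read frame),
    ``cs_*`` alignment starts on the contigs, ``al_*`` aligned lengths.

The relative orientation is ``d = -strand_i*strand_j`` for paired reads (both
inward PE and outward MP geometries put the two reads on opposite strands when
the contigs agree) and ``d = strand_i*strand_j`` for a co-linear long read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

PAIRED_COLUMNS = ["read_id", "i", "j", "d", "s_i", "s_j", "strand_i", "strand_j", "lib"]
TGS_COLUMNS = [
    "read_id", "i", "j", "d", "qs_i", "qs_j", "cs_i", "cs_j",
    "al_i", "al_j", "strand_i", "strand_j", "read_len", "lib",
]
INSERT_COLUMNS = ["contig", "insert", "lib"]

#: coverage-track bin width in bp
COVERAGE_BIN = 200


def empty_paired_links() -> pd.DataFrame:
    return pd.DataFrame(columns=PAIRED_COLUMNS)


def empty_tgs_links() -> pd.DataFrame:
    return pd.DataFrame(columns=TGS_COLUMNS)


def empty_insert_obs() -> pd.DataFrame:
    return pd.DataFrame(columns=INSERT_COLUMNS)


@dataclass
class Library:
    """Per-library insert model.

    ``kind`` is one of ``PE`` (short-insert, inward-facing pairs), ``MP``
    (long-insert, outward-facing pairs) or ``TGS`` (long reads).  PE/MP carry a
    nominal insert mean/SD in bp; TGS libraries carry no insert model.
    ``already_flipped`` marks MP libraries whose mates were flipped to PE
    geometry by the alignment pipeline.
    """

    id: str
    kind: str
    insert_mean: float | None = None
    insert_sd: float | None = None
    read_length: int | None = None
    already_flipped: bool = False
    path: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("PE", "MP", "TGS"):
            raise ValueError(f"library {self.id!r}: unknown kind {self.kind!r}")
        if self.kind in ("PE", "MP"):
            if not self.insert_mean or self.insert_mean <= 0:
                raise ValueError(f"library {self.id!r}: insert_mean must be > 0")
            if not self.insert_sd or self.insert_sd <= 0:
                raise ValueError(f"library {self.id!r}: insert_sd must be > 0")

    @property
    def pe_geometry(self) -> bool:
        """True when mates face inward (PE, or MP flipped by the aligner)."""
        return self.kind == "PE" or (self.kind == "MP" and self.already_flipped)


@dataclass
class Contig:
    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"contig {self.id!r}: sequence/length mismatch")


@dataclass
class Link:
    """One read's evidence joining two contigs (record form of a table row)."""

    read_id: str
    i: str
    j: str
    d: int
    library_id: str
    s_i: float | None = None
    s_j: float | None = None
    qs_i: float | None = None
    qs_j: float | None = None
    cs_i: float | None = None
    cs_j: float | None = None
    F: float | None = None

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("a link must join two distinct contigs")
        if self.d not in (+1, -1):
            raise ValueError("relative orientation d must be +1 or -1")
        paired = self.s_i is not None or self.s_j is not None
        tgs = self.qs_i is not None or self.qs_j is not None
        if paired == tgs:
            raise ValueError("exactly one of the paired / TGS coordinate sets "
                             "must be populated")


@dataclass
class ScaffoldGraph:
    """Contig graph with link-count-thresholded edges.

    ``edges`` maps the canonical unordered pair ``(i, j)`` (``i < j``) to the
    tally ``(a, b)`` of links with relative orientation +1 / -1.
    """

    vertices: set
    edges: dict
    threshold: int

    def neighbours(self, v) -> list:
        out = []
        for (i, j) in self.edges:
            if i == v:
                out.append(j)
            elif j == v:
                out.append(i)
        return out


@dataclass
class CompressedObservation:
    """One cluster's regression row: observed ``beta_j - beta_i``."""

    i: str
    j: str
    library_id: str
    Y: float
    n: int
    w: float
    member_distances: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class Placement:
    contig: str
    orientation: int
    start: int
    length: int
    #: leading bases of the oriented contig clipped by an overlap merge
    trim: int = 0

    @property
    def end(self) -> int:
        return self.start + self.length - self.trim


@dataclass
class Gap:
    size: float
    ci_low: float
    ci_high: float
    n_clusters: int = 0
    #: True when the junction was spliced by the overlap-merge polish
    merged: bool = False


@dataclass
class LayoutEstimate:
    """Per-component orientation and position estimate."""

    component: list
    D: dict
    beta: "pd.Series"
    selected_observations: "pd.DataFrame"
    residuals: "np.ndarray"
    gap_ci: "pd.DataFrame"


@dataclass
class SuperContig:
    """Linear placement of oriented contigs separated by estimated gaps."""

    id: str
    placements: list
    gaps: list
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.placements = sorted(self.placements, key=lambda p: (p.start, p.contig))
        if len(self.gaps) != max(len(self.placements) - 1, 0):
            raise ValueError("need exactly one gap record per adjacent pair")

    @property
    def length(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        total = sum(p.length - p.trim for p in self.placements)
        total += sum(max(int(g.size), 1) for g in self.gaps if not g.merged)
        return total


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_library_config(path) -> dict:
    """Parse a YAML library config into ``{id: Library}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "libraries" not in doc:
        raise ValueError(f"{path}: no 'libraries' section")
    libs = {}
    for entry in doc["libraries"]:
        lib = Library(
            id=str(entry["id"]),
            kind=str(entry["kind"]).upper(),
            insert_mean=entry.get("insert_mean"),
            insert_sd=entry.get("insert_sd"),
            read_length=entry.get("read_length"),
            already_flipped=bool(entry.get("already_flipped", False)),
            path=entry.get("path"),
        )
        if lib.id in libs:
            raise ValueError(f"duplicate library id {lib.id!r}")
        libs[lib.id] = lib
    return libs


def read_contigs(path) -> dict:
    """Read a contig FASTA into an ordered ``{id: Contig}`` mapping.

    Ids are the first whitespace-delimited header token; sequences are
    upper-cased.  Duplicate ids or an empty file are hard errors.
    """
    contigs: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        cid = rec.id
        if cid in contigs:
            raise ValueError(f"duplicate contig id {cid!r} in {path}")
        seq = str(rec.seq).upper()
        contigs[cid] = Contig(id=cid, length=len(seq), sequence=seq)
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return contigs


@dataclass
class AlignmentData:
    """Bundle returned by :func:`read_alignments`."""

    paired_links: pd.DataFrame
    tgs_links: pd.DataFrame
    insert_obs: pd.DataFrame
    coverage: dict
    counters: dict = field(default_factory=dict)


def _new_coverage(contigs: dict) -> dict:
    return {cid: np.zeros(max(1, -(-c.length // COVERAGE_BIN)))
            for cid, c in contigs.items()}


def _add_coverage(coverage: dict, contig: str, start: int, end: int) -> None:
    track = coverage.get(contig)
    if track is None:
        return
    lo, hi = int(start) // COVERAGE_BIN, max(int(start) // COVERAGE_BIN + 1,
                                             -(-int(end) // COVERAGE_BIN))
    track[lo:min(hi, len(track))] += 1.0


def _outer_end(lib: Library, start: int, end: int, forward: bool) -> int:
    """Outer-end coordinate of a mapped read in its contig's FASTA frame.

    For inward geometry the fragment extends away from the read's 5' end, so
    a forward read's outer end is its leftmost coordinate and a reverse
    read's is its rightmost.  Outward (raw MP) geometry is the mirror image.
    """
    if lib.pe_geometry:
        return start if forward else end
    return end if forward else start


def canonical_pair(i, j):
    return (i, j) if str(i) < str(j) else (j, i)


def read_alignments(path, libraries: dict, contigs: dict,
                    library_id: str | None = None,
                    min_tgs_aln: int = 500) -> AlignmentData:
    """Read one library's alignments (SAM/BAM or PAF) into link tables.

    Paired records mapping to two distinct contigs become paired links;
    proper pairs on one contig are routed to insert-size estimation.  Long
    reads with local alignments on two contigs (each at least
    ``min_tgs_aln`` bp) become TGS links.  A per-contig coverage track (bin
    width ``COVERAGE_BIN``) is accumulated for the high-coverage filter.
    """
    path = Path(path)
    if library_id is None:
        candidates = [lid for lid, l in libraries.items() if l.path and
                      Path(l.path).name == path.name]
        if len(candidates) != 1:
            raise ValueError(f"cannot infer library for {path}; pass library_id")
        library_id = candidates[0]
    if library_id not in libraries:
        raise ValueError(f"unknown library id {library_id!r}")
    lib = libraries[library_id]

    if path.suffix.lower() == ".paf":
        return _read_paf(path, lib, contigs, min_tgs_aln)
    if lib.kind == "TGS":
        return _read_sam_tgs(path, lib, contigs, min_tgs_aln)
    return _read_sam_paired(path, lib, contigs)


def _read_sam_paired(path, lib: Library, contigs: dict) -> AlignmentData:
    coverage = _new_coverage(contigs)
    counters = {"records": 0, "unmapped_mate": 0, "multimapped": 0,
                "paired_links": 0, "insert_obs": 0}
    # first pass: collect primary alignments per (qname, mate-index)
    reads: dict = {}
    ambiguous: set = set()
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            counters["records"] += 1
            if rec.reference_name not in contigs:
                raise ValueError(f"alignment references unknown contig "
                                 f"{rec.reference_name!r}")
            _add_coverage(coverage, rec.reference_name,
                          rec.reference_start, rec.reference_end)
            if rec.is_secondary or rec.is_supplementary:
                ambiguous.add(rec.query_name)
                continue
            if rec.mate_is_unmapped or not rec.is_paired:
                counters["unmapped_mate"] += 1
                continue
            key = (rec.query_name, 2 if rec.is_read2 else 1)
            if key in reads:
                ambiguous.add(rec.query_name)
                continue
            reads[key] = (rec.reference_name, rec.reference_start,
                          rec.reference_end, not rec.is_reverse)

    paired_rows, insert_rows = [], []
    qnames = {q for (q, _m) in reads}
    for qname in sorted(qnames):
        if qname in ambiguous:
            counters["multimapped"] += 1
            continue
        r1, r2 = reads.get((qname, 1)), reads.get((qname, 2))
        if r1 is None or r2 is None:
            counters["unmapped_mate"] += 1
            continue
        (c1, st1, en1, fw1), (c2, st2, en2, fw2) = r1, r2
        if c1 == c2:
            span = max(en1, en2) - min(st1, st2)
            insert_rows.append((c1, span, lib.id))
            counters["insert_obs"] += 1
            continue
        o1 = _outer_end(lib, st1, en1, fw1)
        o2 = _outer_end(lib, st2, en2, fw2)
        s1, s2 = (1 if fw1 else -1), (1 if fw2 else -1)
        if str(c1) < str(c2):
            i, j, s_i, s_j, str_i, str_j = c1, c2, o1, o2, s1, s2
        else:
            i, j, s_i, s_j, str_i, str_j = c2, c1, o2, o1, s2, s1
        paired_rows.append((qname, i, j, -str_i * str_j, s_i, s_j,
                            str_i, str_j, lib.id))
        counters["paired_links"] += 1

    paired = pd.DataFrame(paired_rows, columns=PAIRED_COLUMNS) \
        if paired_rows else empty_paired_links()
    inserts = pd.DataFrame(insert_rows, columns=INSERT_COLUMNS) \
        if insert_rows else empty_insert_obs()
    if counters["unmapped_mate"] or counters["multimapped"]:
        log.info("%s: skipped %d unmatched and %d multi-mapped reads",
                 path, counters["unmapped_mate"], counters["multimapped"])
    return AlignmentData(paired, empty_tgs_links(), inserts, coverage, counters)


def _tgs_links_from_alignments(alns: dict, lib: Library, min_tgs_aln: int):
    """Pair up per-read local alignments into TGS link rows.

    ``alns``: read_id -> list of (contig, qs, cs, al, strand, read_len) in the
    original read frame.  A pair of contigs yields a link only when the read
    has exactly one qualifying alignment on each.
    """
    rows = []
    for rid in sorted(alns):
        per_contig: dict = {}
        for a in alns[rid]:
            if a[3] >= min_tgs_aln:
                per_contig.setdefault(a[0], []).append(a)
        usable = sorted(c for c, lst in per_contig.items() if len(lst) == 1)
        for x in range(len(usable)):
            for y in range(x + 1, len(usable)):
                ci, cj = usable[x], usable[y]
                (_, qsi, csi, ali, si, rl) = per_contig[ci][0]
                (_, qsj, csj, alj, sj, _) = per_contig[cj][0]
                rows.append((rid, ci, cj, si * sj, qsi, qsj, csi, csj,
                             ali, alj, si, sj, rl, lib.id))
    return pd.DataFrame(rows, columns=TGS_COLUMNS) if rows else empty_tgs_links()


def _read_paf(path, lib: Library, contigs: dict, min_tgs_aln: int) -> AlignmentData:
    coverage = _new_coverage(contigs)
    alns: dict = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            qname, qlen, qst, qen = f[0], int(f[1]), int(f[2]), int(f[3])
            strand, tname, tst = f[4], f[5], int(f[7])
            ten = int(f[8])
            tags = {t.split(":")[0]: t for t in f[12:]}
            if "tp" in tags and not tags["tp"].endswith(":P"):
                continue
            if tname not in contigs:
                raise ValueError(f"PAF references unknown contig {tname!r}")
            _add_coverage(coverage, tname, tst, ten)
            n += 1
            al = qen - qst
            alns.setdefault(qname, []).append(
                (tname, qst, tst, al, 1 if strand == "+" else -1, qlen))
    tgs = _tgs_links_from_alignments(alns, lib, min_tgs_aln)
    return AlignmentData(empty_paired_links(), tgs, empty_insert_obs(),
                         coverage, {"records": n, "tgs_links": len(tgs)})


def _read_sam_tgs(path, lib: Library, contigs: dict, min_tgs_aln: int) -> AlignmentData:
    """SAM long-read alignments: primary and supplementary records are the
    read's local alignments (secondaries are ignored)."""
    coverage = _new_coverage(contigs)
    alns: dict = {}
    n = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.reference_name not in contigs:
                raise ValueError(f"alignment references unknown contig "
                                 f"{rec.reference_name!r}")
            _add_coverage(coverage, rec.reference_name,
                          rec.reference_start, rec.reference_end)
            n += 1
            rl = rec.infer_read_length() or rec.query_length
            qst = rec.query_alignment_start
            qen = rec.query_alignment_end
            if rec.is_reverse:
                # stored coords are in the reverse-complement frame
                qst, qen = rl - qen, rl - qst
            alns.setdefault(rec.query_name, []).append(
                (rec.reference_name, qst, rec.reference_start, qen - qst,
                 -1 if rec.is_reverse else 1, rl))
    tgs = _tgs_links_from_alignments(alns, lib, min_tgs_aln)
    return AlignmentData(empty_paired_links(), tgs, empty_insert_obs(),
                         coverage, {"records": n, "tgs_links": len(tgs)})


# ---------------------------------------------------------------------------
# simulator link TSV dialect
# ---------------------------------------------------------------------------

def write_links_tsv(path, paired: pd.DataFrame, tgs: pd.DataFrame,
                    insert_obs: pd.DataFrame | None = None) -> None:
    """Write link tables as one TSV with a ``kind`` discriminator column."""
    frames = []
    if len(paired):
        p = paired.copy()
        p.insert(0, "kind", "paired")
        frames.append(p)
    if len(tgs):
        t = tgs.copy()
        t.insert(0, "kind", "tgs")
        frames.append(t)
    if insert_obs is not None and len(insert_obs):
        o = insert_obs.copy()
        o.insert(0, "kind", "insert")
        frames.append(o)
    merged = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["kind"])
    merged.to_csv(path, sep="\t", index=False)


def read_links_tsv(path):
    """Read the TSV link dialect back into (paired, tgs, insert_obs)."""
    df = pd.read_csv(path, sep="\t")
    if not len(df):
        return empty_paired_links(), empty_tgs_links(), empty_insert_obs()
    paired = df[df["kind"] == "paired"][[c for c in PAIRED_COLUMNS
                                         if c in df.columns]].reset_index(drop=True)
    tgs = df[df["kind"] == "tgs"][[c for c in TGS_COLUMNS
                                   if c in df.columns]].reset_index(drop=True)
    ins = df[df["kind"] == "insert"][[c for c in INSERT_COLUMNS
                                      if c in df.columns]].reset_index(drop=True)
    for frame, ints in ((paired, ["d", "s_i", "s_j", "strand_i", "strand_j"]),
                        (tgs, ["d", "qs_i", "qs_j", "cs_i", "cs_j", "al_i",
                               "al_j", "strand_i", "strand_j", "read_len"]),
                        (ins, ["insert"])):
        for c in ints:
            if c in frame.columns:
                frame[c] = frame[c].astype(np.int64)
    if not len(paired):
        paired = empty_paired_links()
    if not len(tgs):
        tgs = empty_tgs_links()
    if not len(ins):
        ins = empty_insert_obs()
    return paired, tgs, ins


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def render_sequence(sc: SuperContig, contigs: dict) -> str:
    """Render a super-contig's sequence with gaps as N runs (floor 1 bp).

    Junctions flagged ``merged`` contribute no Ns; the right contig's
    ``trim`` leading bases (already spliced into the left one) are skipped.
    """
    parts = []
    for idx, p in enumerate(sc.placements):
        seq = contigs[p.contig].sequence
        if seq is None:
            raise ValueError(f"contig {p.contig!r} has no sequence")
        oriented = seq if p.orientation > 0 else revcomp(seq)
        parts.append(oriented[p.trim:])
        if idx < len(sc.gaps) and not sc.gaps[idx].merged:
            parts.append("N" * max(int(sc.gaps[idx].size), 1))
    return "".join(parts)


def write_scaffolds(supercontigs: Sequence[SuperContig], contigs: dict,
                    fasta_path, agp_path, gap_report_path) -> None:
    """Write scaffold FASTA, AGP v2.1 and a TSV gap report."""
    if not supercontigs:
        log.warning("no scaffolds to write; emitting empty files")
    records = []
    agp_lines = []
    gap_lines = ["\t".join(["scaffold", "left_contig", "right_contig",
                            "gap_estimate", "ci_low", "ci_high", "n_clusters"])]
    for sc in supercontigs:
        seq = sc.sequence if sc.sequence is not None else \
            render_sequence(sc, contigs)
        records.append(SeqRecord(Seq(seq), id=sc.id, description=""))
        pos, part = 0, 0
        for idx, p in enumerate(sc.placements):
            part += 1
            span = p.length - p.trim
            comp_lo, comp_hi = (p.trim + 1, p.length) if p.orientation > 0 \
                else (1, p.length - p.trim)
            agp_lines.append("\t".join(map(str, [
                sc.id, pos + 1, pos + span, part, "W", p.contig,
                comp_lo, comp_hi, "+" if p.orientation > 0 else "-"])))
            pos += span
            if idx < len(sc.gaps):
                g = sc.gaps[idx]
                right = sc.placements[idx + 1].contig
                if not g.merged:
                    size = max(int(g.size), 1)
                    agp_lines.append("\t".join(map(str, [
                        sc.id, pos + 1, pos + size, part + 1, "N", size,
                        "scaffold", "yes", "paired-ends"])))
                    part += 1
                    pos += size
                gap_lines.append("\t".join(map(str, [
                    sc.id, p.contig, right, int(g.size),
                    round(g.ci_low, 1), round(g.ci_high, 1), g.n_clusters])))
    SeqIO.write(records, str(fasta_path), "fasta")
    Path(agp_path).write_text("##agp-version\t2.1\n" +
                              "".join(l + "\n" for l in agp_lines))
    Path(gap_report_path).write_text("".join(l + "\n" for l in gap_lines))


def read_agp(path, contigs: dict | None = None) -> list:
    """Read an AGP v2.1 file back into SuperContig skeletons (no sequence)."""
    placements: dict = {}
    gaps: dict = {}
    order: list = []
    last_type: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{lineno}: malformed AGP row")
            sid, start = f[0], int(f[1]) - 1
            if sid not in placements:
                placements[sid] = []
                gaps[sid] = []
                order.append(sid)
                last_type[sid] = None
            if f[4] == "W":
                cid = f[5]
                if contigs is not None and cid not in contigs:
                    raise ValueError(f"{path}:{lineno}: unknown contig {cid!r}")
                trim = int(f[6]) - 1
                if last_type[sid] == "W":
                    # two abutting contigs: a merged (spliced) junction
                    gaps[sid].append(Gap(size=0, ci_low=float("nan"),
                                         ci_high=float("nan"), merged=True))
                placements[sid].append(Placement(
                    contig=cid, orientation=1 if f[8] == "+" else -1,
                    start=start, length=int(f[7]), trim=trim))
                last_type[sid] = "W"
            elif f[4] in ("N", "U"):
                gaps[sid].append(Gap(size=int(f[5]), ci_low=float("nan"),
                                     ci_high=float("nan")))
                last_type[sid] = f[4]
            else:
                raise ValueError(f"{path}:{lineno}: unsupported AGP component "
                                 f"type {f[4]!r}")
    out = []
    for sid in order:
        # trailing gaps would be malformed; require alternation
        if len(gaps[sid]) != len(placements[sid]) - 1:
            raise ValueError(f"{path}: scaffold {sid!r} has "
                             f"{len(gaps[sid])} gaps for "
                             f"{len(placements[sid])} contigs")
        out.append(SuperContig(id=sid, placements=placements[sid],
                               gaps=gaps[sid]))
    return out
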