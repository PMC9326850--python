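# Methods

This note records the statistical model behind `ltscaf`, the defaults and
why they hold, what the bundled simulator does and does not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer
from the code.

## Model and assumptions

A draft assembly is a set of contigs cut from an unknown genome. A
*link* is a read whose alignments touch two contigs: a PE/MP pair with one
mate on each, or a long read with a local alignment on each. The model
assumes:

- library inserts are approximately normal, N(μ_b, σ_b²), per library *b*;
- a link's relative-orientation vote is wrong only through mismapping,
  with the same error probability for every link of a pair — under which
  minimising the Ising energy H(D) = −Σ J_ij D_i D_j with
  J_ij = (a_ij − b_ij)/2 is the natural pooled-vote rule;
- conditional on its cluster, a linking distance is an unbiased
  observation of β_j − β_i with variance σ_b², so the cluster median errs
  like N(0, πσ_b²/(2n)) by the central limit theorem for sample medians;
- mistaken alignments are a minority overall, but may dominate
  *individual* contig pairs (repeat-induced modes); they appear as
  separate, internally consistent clusters rather than diffuse noise.

The last assumption is what the multi-mode clustering plus trimmed
regression is for: a single-median compression irreversibly commits to the
locally dominant mode, whereas retaining every mode as its own weighted
row lets the globally consistent subset win.

## Pipeline stages and parameters

**Preprocessing.** Multi-mapped reads are removed entirely (both mates).
Insert models are re-estimated per library from pairs mapping within
single contigs longer than 10 kb, as median and 1.4826·MAD — robust
location/scale, because chimeric pairs make the tails heavy; below 100
usable pairs the nominal config values are kept with a warning. Paired
links whose outer mapping coordinate lies further than μ_b + 3σ_b from the
relevant contig edge (the edge the mate extends past) are discarded —
inclusive bound, reading "beyond" as strict. Regions whose 200 bp windowed
coverage exceeds max(2 × assembly median, median + 3·MAD-SD) are masked
and links touching them dropped; this flags collapsed repeats. The exact
published rule for "high-coverage area" is not available, so this stand-in
is isolated in one function (`preprocess.mark_high_coverage`).

**Graph.** An edge needs at least *threshold* links (inclusive). The
default threshold is the lower-interpolation 10% quantile of the non-zero
per-pair link counts, floored at 2 so a single chimeric read can never
create an edge; users scaffolding high-coverage data are advised to set it
to 0.25–0.5× coverage instead. Components come from an iterative DFS.

**Orientation.** Ground-state search is NP-complete, so the search is
heuristic: Kruskal maximum-|J| spanning forest, each new vertex taking the
spin its tree edge prefers; then greedy best-improvement single flips
(ties to the smallest contig id) until no flip lowers H; repeated from 20
seeded random initialisations, keeping the best. Deterministic for a given
seed, and the result always carries a local-minimum certificate. Zero
couplings are excluded from the tree. Only links with d_ijr = D_i·D_j
survive to the distance stage; reversed contigs have coordinates mirrored
(s → len − s) and strands flipped before any distance is computed.

**Clustering.** Per pair and library, a kernel density (Gaussian by
default; tophat and epanechnikov supported and covered by tests) with
bandwidth σ_b/2 is evaluated on a grid of step σ_b/20 padded 3σ_b beyond
the data. Local maxima are candidate modes; two adjacent peaks merge when
they are closer than 2σ_b *or* the saddle between them exceeds 60% of the
lower peak — our operationalisation of "well separated", both knobs
config-exposed. Each distance joins its nearest surviving peak. Clusters
compress to their median with weight n/σ_b², the sample variance replacing
σ_b² when n > 6. TGS libraries carry no insert model; their clustering
scale is the pair's own 1.4826·MAD of distances, floored at 50 bp.

**Regression.** The anchor contig (smallest id) is fixed at β = 0 by
eliminating its column, so X'WX is the weighted graph Laplacian over the
remaining contigs — solved sparsely (conjugate gradients above 50 000
contigs; deterministic to 1e−6 bp). Trimming keeps the (n − t) rows with
the smallest *raw* absolute residuals in bp — MaxError is a bp quantity,
so residuals must be too — re-selected from the full row set each
iteration (a removed row can re-enter), with concentration steps iterated
to a fixed point at each size. MaxError defaults to 100 bp, the rounded
2-SD bound 2·√(π/(2·150))·500 ≈ 102.33 of a typical compressed
observation, and grows by 50 bp per outer pipeline round because later
rounds have smaller clusters. If the kept rows disconnect the component,
the parts re-enter at the orientation stage; a component whose rows are
exhausted dissolves into singletons with a warning.

**Gap confidence intervals.** Cov(β̂) = s²(X'WX)⁻¹ over the selected rows,
with s² the weighted residual mean square and a Student-t quantile at the
residual degrees of freedom (|I*| − free parameters). With zero degrees of
freedom the model-based covariance is used and flagged: weights are
n/σ_b² while the true error variance is (π/2)·σ_b²/n, so the model-based
scale is π/2 — this makes a single 150-link, σ = 500 cluster report
2·SE ≈ 102.33 bp, consistent with the residual-bound derivation. Whether
the published procedure uses residual or model variance is not stated; we
default to residual variance and flag the fallback in the report.

**Untangling and iteration.** Contigs are walked in position order; when
the next contig overlaps the chain end by more than 200 bp (default
tolerance) a branch exists, resolved toward the contig with the most
trimmed-in supporting links to the chain end (ties toward the smaller
estimated overlap); losers seed their own super-contigs. Only trimmed-in
observations vote, since outlier links should not decide topology. The
whole pipeline iterates k = 3 times by default, remapping original link
coordinates into super-contig frames each round (reflection for reversed
placements, then translation) and stopping early when a round merges
nothing. Gap records keep the round in which their junction was formed.

**Polish.** Junctions with a negative estimated gap (up to 2 kb) are
checked in sequence: overlap widths within 50 bp of the estimate are
scored by exact base identity, and the best width merges the junction when
identity ≥ 0.95, splicing the right contig's leading bases; otherwise a
1 bp gap remains. Merged junctions appear in AGP as abutting W rows with
the right component's start coordinate advanced.

**Assessment.** An existing scaffold's placements define β and D; all
compressed observations are recomputed against them, rows with |residual|
above MaxError are flagged, and if removing the flagged rows disconnects
the link graph the break is reported as a suspicious junction between the
adjacent contigs spanning it.

## The simulator

`ltscaf.simulate` generates what the method consumes — alignment-level
links with planted truth — rather than FASTQ, because base-level errors
reach the scaffolder only through the external mapper, which is out of
scope. It emulates: uniform fragment placement; normal inserts truncated
at twice the read length; inward (PE) and outward (MP) pair geometries on
either contig strand; long reads bridging several contigs; short-insert
contamination of MP libraries (bimodal inserts, default contaminant
300 ± 30 bp); and the mis-mapping of reads whose true locus lies in an
unassembled tandem-repeat copy onto the nearest surviving homologous copy,
which manufactures false link clusters offset by whole repeat units.

Study conditions fixed by the scenarios: the chain scenario is a 200 kb
genome in 40 contigs with 500 bp unassembled gaps, alternating contig
strands, a 300 ± 30 bp PE library and a 3000 ± 300 bp MP library at 30×
each. The tandem-repeat scenario plants a 4-copy 600 bp repeat with three
copies unassembled, a short middle contig holding the surviving copy, and
two MP libraries (3000 ± 150, 6000 ± 200 at 40×) with mis-mapping on;
the false clusters between the middle and right contigs then outnumber
the true one, which defeats single-median compression but not the trimmed
regression. The contamination scenario uses 50 bp gaps so the 40%
short-insert contaminant can physically span junctions.

What the simulator does **not** emulate — so what passing tests do not
show: sequencing errors and mapping-quality effects; chimeric reads beyond
insert contamination; PCR duplicates; non-uniform (GC-dependent) coverage;
repeat families longer or more diverged than the planted tandem blocks.
Results on real libraries depend on the upstream mapper handling these.

## Known limitations

- **Spanning-sample insert bias.** Fragments observed to span a junction
  are a size-biased sample of the insert distribution
  (E[insert | spans] ≈ μ_b + σ_b²/(μ_b − gap − 2·read length)), while
  linking distances use the nominal μ_b. Gap estimates therefore carry a
  deterministic negative bias of roughly σ_b²/μ_b (≈ 30–40 bp for a
  3000 ± 300 library); the linking-distance formula has no correction for
  it, and the gap RMSE observed in the planted chain (≈ 45 bp) is mostly
  this bias, not noise. Libraries whose insert barely exceeds the gap are
  affected most, which is why short-insert PE contributes calibration
  rather than spanning evidence.
- **Trimming is greedy.** The trimmed estimator tolerates gross outliers
  that are a minority on every graph cut (30% per pair with margin). If
  mutually consistent false clusters form the weighted majority across a
  cut, the shifted solution genuinely minimises the trimmed-sum objective
  and no trimming scheme can recover the truth from links alone.
- **No repeat multiplicity.** Each contig is placed exactly once;
  collapsed repeats that should appear at several loci are handled only by
  the high-coverage mask, not by multiplicity inference.
- **Penalty/threshold duality.** The trimmed-sum objective's per-row
  removal penalty corresponds to a residual threshold of √(1/w) bp, which
  matches MaxError only at the typical cluster scale; the implementation
  follows the MaxError stopping rule throughout.
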