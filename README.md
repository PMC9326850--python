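# ltscaf — robust-regression genome scaffolding

`ltscaf` orders, orients and spaces the contigs of a draft genome assembly
from linking reads — paired-end (PE) and mate-pair (MP) short-read
libraries, or long (TGS) reads whose local alignments bridge two contigs.
It is aimed at assembly practitioners who already have read-to-contig
alignments (SAM/BAM for pairs, SAM or PAF for long reads) and want
scaffolds whose gap sizes come with honest confidence intervals, and whose
construction is robust to the mistaken alignments that repeats inevitably
produce.

## The model

Each contig *i* carries an orientation spin *D<sub>i</sub>* ∈ {+1, −1} and
a start coordinate *β<sub>i</sub>* on the scaffold axis. Scaffolding splits
into two estimation problems:

**Orientation.** Every linking read votes on the relative orientation
*d<sub>ijr</sub>* ∈ {+1, −1} of its two contigs. Votes are pooled into
couplings *J<sub>ij</sub>* = (*a<sub>ij</sub>* − *b<sub>ij</sub>*)/2 (the
+1 votes minus the −1 votes, halved) and the assignment minimises the
Ising-type energy

> H(D) = − Σ<sub>(i,j)</sub> J<sub>ij</sub> D<sub>i</sub> D<sub>j</sub>,

searched heuristically (maximum-|J| spanning-tree initialisation, greedy
single-spin flips, seeded restarts).

**Position.** Each orientation-supported link measures
*β<sub>j</sub>* − *β<sub>i</sub>* through its linking distance
*F<sub>ijr</sub>* = *μ<sub>b</sub>* + *s<sub>ir</sub>* − *s<sub>jr</sub>*
(paired, library insert mean *μ<sub>b</sub>*) or
*qs<sub>jr</sub>* − *qs<sub>ir</sub>* + *cs<sub>ir</sub>* − *cs<sub>jr</sub>*
(long read). Per contig pair and library, the distances are clustered by a
kernel density with bandwidth *σ<sub>b</sub>*/2; every well-separated mode
becomes one *compressed observation* — its median *Y<sub>ijk</sub>* with
weight *n<sub>ijk</sub>*/σ<sub>b</sub>², because the median of an
*n*-link cluster errs like N(0, πσ<sub>b</sub>²/(2*n*)). Pooling all
clusters gives a sparse linear model **Y** = **X**β + ε (design rows −1/+1,
anchor contig fixed at 0), estimated by **weighted least trimmed squares**:
refit, keep the rows with the smallest residuals (one fewer per round,
re-selected from all rows each time), stop when every kept residual is
below `MaxError` (default 100 bp, derived from 2·√(π/(2·150))·500 ≈ 102.33
for a typical cluster). Mistaken link clusters — repeat-induced modes
offset by a repeat unit, contaminated-insert modes — are trimmed away
instead of corrupting the layout. Gap estimates inherit standard errors
from the weighted normal equations.

The graph → orient → cluster → regress → untangle pipeline is iterated
(default *k* = 3) with super-contigs replacing contigs, then overlapping
adjacent contigs are merged by local alignment.

## Worked example

The regression core follows the Model/Results convention. Six link
clusters over four contigs, where the pair (c1, c2) kept two contradictory
modes (the second one 600 bp too long — a repeat-unit shift):

```python
import pandas as pd
from ltscaf import ContigPositionModel

obs = pd.DataFrame({
    "i": ["c1", "c1", "c2", "c2", "c3", "c1"],
    "j": ["c2", "c2", "c3", "c3", "c4", "c3"],
    "Y": [5480.0, 6080.0, 5230.0, 5235.0, 5510.0, 10705.0],
    "w": [140/250**2, 60/250**2, 120/250**2, 80/250**2, 150/250**2, 90/250**2],
    "n": [140, 60, 120, 80, 150, 90],
})
lengths = {"c1": 5000, "c2": 5200, "c3": 5100, "c4": 4800}
res = ContigPositionModel(obs, lengths).fit(max_error=100.0)
print(res.summary())
```

prints

```
Contig position estimates (weighted least trimmed squares)
============================================================
contigs: 4   observations: 6   selected: 5   iterations: 2
max_error: 100 bp   residual scale^2: 0.026 (dof 2)
------------------------------------------------------------
contig               beta (bp)
c1                         0.0
c2                      5477.8
c3                     10708.3
c4                     16218.3
------------------------------------------------------------
gap                         estimate                    ci
c1 .. c2                       477.8        [465.5, 490.2]
c2 .. c3                        30.5          [19.5, 41.5]
c3 .. c4                       410.0        [395.7, 424.3]
```

The positions are the trimmed weighted-least-squares estimate with c1
anchored at 0; each gap row is `β_right − β_left − length(left)` with a
95% confidence interval from the estimated covariance. `res.removed`
shows what the trimming discarded — here exactly the false 6080 bp mode,
with residual −602 bp:

```
 i  j      Y  n       resid
c1 c2 6080.0 60 -602.150171
```

The full pipeline runs from the shell:

```bash
ltscaf simulate --scenario chain --seed 5 --out-dir sim   # planted fixture
ltscaf scaffold sim/contigs.fasta sim/config.yaml --out-prefix out
ltscaf assess out.agp sim/config.yaml --contigs sim/contigs.fasta
```

writing `out.fasta` (scaffolds, gaps as N runs), `out.agp` (AGP v2.1) and
`out.gaps.tsv` (per-gap estimate, confidence interval and supporting
cluster count). `assess` re-checks any existing AGP scaffold set against
the link residuals and reports outlier clusters and suspicious junctions.

## Layout

| module | contents |
| --- | --- |
| `ltscaf.model_io` | domain types; FASTA/SAM/PAF readers, AGP + gap-report writers |
| `ltscaf.preprocess` | ambiguity/coverage/edge filters, insert re-estimation |
| `ltscaf.scaffold_graph` | link-count-thresholded contig graph, components |
| `ltscaf.orientation` | couplings, energy, heuristic ground-state search |
| `ltscaf.link_clustering` | linking distances, KDE mode clustering, compression |
| `ltscaf.regression` | `ContigPositionModel` / `ContigPositionResults` (WLTS) |
| `ltscaf.assembly` | untangling, pipeline iteration, polish, assessment |
| `ltscaf.simulate` | planted-truth genome/link generator and scenarios |
| `ltscaf.cli` | `ltscaf scaffold / assess / simulate` |

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.
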