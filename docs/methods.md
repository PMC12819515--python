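# Methods

This note documents the models, conventions and numerical choices behind
`secrc`, and what the synthetic study does and does not establish.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention); 1-based inputs
are not supported, since every consumed format (BED3/6, narrowPeak,
broadPeak, bedGraph, BEDPE) is BED-family. Chromosome names pass through
verbatim — a `chr1` vs `1` mismatch between inputs surfaces as zero
overlap plus a logged warning, never as a silent rename, because silent
renaming hides data errors. Strand is carried but ignored by interval
arithmetic: H3K27ac coverage and chromatin loops are unstranded.
Parsers are dialect-strict (exact column counts) and report the line
number of any malformed record.

## Super-enhancer calling

The procedure follows the ROSE geometry. Peaks with a gap ≤ the stitch
distance merge into stitched regions; the default of 12,500 bp is the
ROSE default, as is the optional ±2,500 bp TSS exclusion (off by
default — appropriate for tumor panels without a curated TSS set; a flag
enables it). Net signal is Σ(treatment coverage) − Σ(input coverage)
over the region, floored at 0: negative enrichment after input
subtraction is noise. Signal tracks are piecewise-constant bedGraphs;
region sums are exact (value × covered length).

The SE cutoff is computed on the ascending rank-vs-signal curve with
both axes min-max scaled to [0, 1]. The discrete slope uses a central
difference (one-sided at the ends); the first rank where the slope
exceeds 1 sets the cutoff signal, and regions **strictly above** it are
super-enhancers — ties at the cutoff stay typical enhancers. A flat
curve never crosses slope 1 and yields zero SEs (the degenerate case is
defined, not an error). Per sample, intensities are normalized by the
maximum net signal and only the top 500 SEs are retained, applied after
calling and before consensus building.

"Overlapping by at least 50%" for cross-sample merging is interpreted as
≥ 50% of the **smaller** region, merged transitively; a stricter
reciprocal mode (≥ 50% of both) is exposed as an option. The consensus
region is the union span of its group; each matrix cell holds the
sample's normalized intensity of its best-overlapping SE, and 0 (not NA)
where a sample contributes no SE, so the PCA operates on a complete
matrix. PCA is mean-centered; component signs are fixed so the
largest-magnitude loading is positive, making scores deterministic.

## Microsatellite model

The agnostic scan enumerates rotational equivalence classes of repeat
units: 66 classes of 4-mers (≥ 4 tandem copies) and 20 classes of 3-mers
(≥ 5 copies). Homopolymers are excluded — an AAAA×4 run is a poly-A
tract, not a period-4 microsatellite. Rotations are collapsed because
GGAA, GAAG, AAGG and AGGA describe the same physical tract; the
lexicographically minimal rotation is the class representative, and each
class records its reverse-complement partner.

A hit is a **maximal run**: a 7-copy run is one hit with `n_repeats = 7`,
never four overlapping hits, matching the "consecutive copies" reading.
Runs are found as maximal period-k tracts (positions where
`seq[i] == seq[i+k]`), implemented as a vectorized self-offset equality
scan; ambiguous bases (N) break tracts — conservative, avoiding phantom
repeats across assembly gaps. For units whose primitive period is
smaller than k (e.g. CGCG), the reported run end is the maximal
whole-unit coverage over the primitive-period offsets, which makes the
output exactly equal to the union of per-rotation maximal regex matches
(the independent oracle used in the tests).

GGAA detection defaults to rotation + reverse-complement mode
(GGAA/TTCC), since ETS elements occur on both strands of a reference
scan; a literal mode (tandem GGAA only) is available. "Number of mSats"
counts runs, not total unit copies, and the size-normalized density is
hits × 1000 / region length (hits per kb) — the standard densitometric
choice.

The SE-vs-enhancer comparison is a two-sided paired Wilcoxon signed-rank
test on per-sample mean densities, pairs matched by sample and zero
differences dropped before ranking (Wilcoxon's original treatment).
Fewer than 5 usable pairs is an error at the library level; the pipeline
degrades gracefully (reports the test as unavailable) for small cohorts.

## CRC inference

Activity: a gene is active in a sample when its log2 expression is ≥ 1
(configurable) — a round threshold on the log2 scale separating the
expressed mode from background in typical expression matrices. Each SE
is annotated to the closest active gene by TSS-to-interval distance
(0 if contained), ties broken by smaller coordinate then symbol, so
annotation is deterministic.

Motif scanning uses log-odds PWMs from JASPAR-format counts with
pseudocount 1.0 and a uniform background, scored on both strands; a hit
requires ≥ 85% of the maximal attainable score (configurable), a common
operating point for CRC mapping. Scanning runs over SE **constituent
peaks**, not the full stitched span, because stitched gaps are mostly
unbound sequence. A TF may carry several motif matrices; an edge exists
if any matrix hits (robust to motif-database versioning), weighted by
total hit count.

A CRC clique is a maximal TF set in which every member has a self-edge
(auto-regulation) and every ordered pair is connected — the
"interconnected auto-regulatory loops" definition. Equivalently:
maximal cliques of the undirected graph of bidirectional pairs among
self-looped nodes, enumerated exactly (networkx Bron–Kerbosch). Clique
score is the mean over members of total inbound motif support from
within the clique — a deterministic, documented ranking; ordering is by
score, then size, then lexicographic TF set. The top 10 cliques per
sample are retained to avoid overly stringent calls, and a TF is a CRC
member of a sample when it appears in any of them. A driver with
out-edges only (no self-edge, no in-edges) can never satisfy the clique
predicate — this is the graph-theoretic form of the hegemonic
configuration, and it is what the pipeline's driver report measures.

Specificity: candidate MTFs are CRC members in ≥ 50% of case samples
and < 30% of controls. (Presence below 30% of controls is the same rule
as absence in more than 70%.)

## Promoter–enhancer chains

Loop ends merge into anchors by single-linkage ≥ 1 bp overlap. An
anchor is a promoter when within ±2,500 bp of a TSS (standard HiChIP
anchor annotation), else an enhancer when overlapping an H3K27ac peak,
else "other". Chains traverse promoter and enhancer anchors only —
"other" anchors are not part of a cis-regulatory chain. Promoter
anchors are traversable intermediate steps (promoter–promoter loops are
real contacts; excluding them would require evidence the analysis does
not have). Hop counting is 1-based on edges: a directly looped element
is at hop 1, and the default cap of five interactions bounds the BFS.
The reported path is one shortest witness with smaller-coordinate
anchors visited first, so results are deterministic. The loop support
threshold defaults to 1 (all loops), configurable.

## MTF selection

The three evidence lines are integrated with a 2-of-3 rule:

1. **mSat in SE** — ≥ 1 flagged fusion-TF mSat peak in the TF's
   associated SE in at least half of the samples where the TF has an SE
   (samples without an SE for the TF are excluded from the denominator;
   no evaluable sample yields False).
2. **Case-specific expression** — case median ≥ control 95th percentile
   (+ configurable margin, default 0). The criterion is deliberately a
   simple order-statistic rule; with margin 0 it has a small per-gene
   false-positive rate under identical distributions, which is why the
   pipeline applies it only to the specificity-filtered candidates.
3. **Dependency** — membership in the case-lineage gene list with a
   negative dependency T-statistic. The dependency table is consumed
   precomputed (gene, lineage, gene_effect, t_statistic, adj_p); no
   re-estimation of screen scores is attempted.

Selection requires ≥ 2 criteria; output order is selected-first then
alphabetical. Colocalization over the top-100 consensus SEs counts, per
SE, the number of TF peak sets with ≥ 1 overlapping peak and reports the
histogram and the all-bound fraction.

## The synthetic study

The generator emulates the statistical structure the analysis assumes —
not real genomes. Two 1-Mb chromosomes of i.i.d. uniform sequence are
partitioned into a case SE territory (20 loci of 4 constituent peaks
each), a disjoint control SE territory, a scattered typical-enhancer
zone (peaks on an 18-kb grid so they never stitch together), and a decoy
loop zone. Planted features, all recorded in a JSON truth manifest:

* GGAA runs (4–12 copies) at ~1.0/kb inside case SE loci vs 0.1/kb
  background everywhere else (10× enrichment); flanking bases are
  mutated to break periodicity so every planted run is maximal exactly
  as recorded. A minority of background runs use random 4-mer and 3-mer
  classes so the agnostic scan sees variety.
* A 3-TF circuit: each ordered pair (self included) has the source TF's
  12-bp consensus planted in a constituent of the target's SE. Other
  TFs hold SEs without planted motifs, so they appear as network nodes
  without self-edges — exercising the clique-exclusion rule.
* A driver TF whose motif is a GGAA repeat, bound (via ETS peaks) at
  planted mSats in case samples only; its own locus carries no SE,
  mirroring the absence of SEs at fusion-partner loci. It receives no
  motif planting, is the most negative dependency, and is case-specific
  in expression.
* Loops forming chains from six TF promoters to mSat anchors at hops
  1–6; the hop-6 chain verifies the depth cap. Decoy loops connect
  unannotated anchors.
* Expression: case-specific genes at log2 ≈ 8 in cases vs 0.3 in
  controls, other genes 4–6 everywhere, Gaussian noise sd 0.5.
  Dependency: driver T = −12; circuit TFs ≈ −3; five SE-associated and
  five non-SE non-TF genes mildly negative; 20 positives; one row in a
  second lineage so lineage filtering is non-trivial.

Peak heights are lognormal with SE constituents ~10× typical-enhancer
height; the signal model is piecewise-constant coverage rather than
read-level simulation, because SE calling consumes coverage — simulating
reads would add nothing testable. Boundary jitter (sd 50 bp) varies
peaks between samples. Generation is deterministic: one seed sequence
per stage, byte-identical outputs for a fixed config.

What passing on this generator shows: every algorithmic stage recovers
a planted truth through the full file-format round trip, and the
statistics are calibrated (the paired test attains the exact 2/1024
two-sided p at n = 10 concordant pairs; its type-I error under the
equal-density null is near nominal). What it does not show: robustness
to real-genome base composition, repeat families and mappability
artifacts, to peak-caller idiosyncrasies, or to biological confounding
between entities — conclusions about real cohorts still require the
real data.

The power and type-I studies use a lighter per-region simulation
(sequences with Poisson-planted GGAA runs at the class rate: 10 samples,
10 SEs of 2 kb and 50 enhancers of 1 kb per sample, background 0.3
runs/kb, 10× in SEs for the power arm). The "null" arm plants **equal**
density in SEs and enhancers rather than nothing: a truly unplanted
uniform sequence yields almost no hits at all, leaving all paired
differences zero and the test undefined; the equal-density null is the
exchangeable hypothesis the test actually addresses. Problem sizes (100
power / 500 null simulations) give the rejection-rate estimates ~±2–3%
precision.

## Known limitations

* SE scoring consumes bedGraph coverage only (no bigWig input).
* The expression-specificity rule is a fixed order-statistic comparison,
  not a cross-dataset meta-analysis.
* Chain traversal treats loops as unweighted beyond the support
  threshold; contact significance modelling is out of scope.
* The clique score is a documented local convention; other CRC tools
  rank by related but not identical quantities.
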