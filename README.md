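# secrc — super-enhancers, GGAA microsatellites and core regulatory circuitry

`secrc` is an analysis pipeline for a question that comes up in
fusion-driven sarcomas such as Ewing sarcoma: does the tumor's identity
rest on a classical **core regulatory circuitry (CRC)** — a set of master
transcription factors (MTFs) that bind their own and each other's
super-enhancers, forming interconnected auto-regulatory loops — or is it
dominated by a single **hegemonic** driver (an EWSR1::ETS-type fusion
oncoprotein) that regulates the candidate MTFs without receiving any
reciprocal regulation?

The package implements every computational stage of that analysis as a
tested library, with an orchestrating CLI and a synthetic-data generator
that plants a known ground truth so each stage can be verified without
any external downloads.

## What it computes

* **Super-enhancer calling (ROSE geometry).** H3K27ac peaks within a
  stitching distance (default 12.5 kb) are merged; each stitched region
  is scored by input-subtracted signal; regions are ranked and both axes
  of the rank/signal curve are scaled to [0, 1]; the super-enhancer
  cutoff is the first rank where the discrete slope exceeds 1. Signals
  are normalized by the per-sample maximum, the top 500 SEs retained,
  and SEs overlapping ≥ 50% across samples merged into a consensus
  matrix summarized by PCA.
* **Agnostic microsatellite scan.** All tandem-repeat classes of 4-mers
  (≥ 4 copies) and 3-mers (≥ 5 copies) up to rotation, homopolymers
  excluded — 66 + 20 classes. GGAA microsatellites (≥ 4 consecutive
  GGAA, the binding substrate of ETS fusion oncoproteins) are the
  special case. Per-region densities (hits/kb) are compared between SEs
  and typical enhancers with a paired Wilcoxon signed-rank test across
  samples.
* **CRC inference.** Per sample, SEs are assigned to the closest active
  gene; a directed graph over SE-assigned TFs has an edge *i → j* when
  TF *i*'s JASPAR motif hits TF *j*'s SE constituents (log-odds PWM scan,
  both strands, ≥ 85% of the maximal score). CRC cliques are maximal TF
  sets where every member has a self-edge and every ordered pair is
  connected; the top 10 per sample are kept. The specificity filter
  keeps TFs present in ≥ 50% of case samples and < 30% of controls.
* **Promoter–enhancer chains.** Loop anchors are merged, labelled
  promoter/enhancer/other, and flagged when overlapping a fusion-TF peak
  containing a GGAA run; a BFS from each TF promoter reports the hop
  index of the first mSat-bound anchor within five interactions.
* **MTF selection (2-of-3 rule).** A candidate is selected when it meets
  at least two of: mSat peaks in its SE (majority of evaluable samples),
  case-specific expression, and a negative CRISPR-dependency
  T-statistic in the case lineage.

A node with out-edges to the whole circuit but no self-edge and no
in-edges — the hegemonic configuration — is excluded from every clique
by definition; the pipeline surfaces it instead as the top dependency
outside the CRC.

## Worked example

Generate the default synthetic study (seed 42) and run the full
analysis:

```sh
secrc simulate --out results/dataset
secrc run-all --dataset results/dataset --out results/run
```

or equivalently step through the numbered drivers:

```sh
python analysis/01_simulate_study.py
python analysis/02_superenhancer_landscape.py
python analysis/03_microsatellite_enrichment.py
python analysis/04_core_regulatory_circuitry.py
python analysis/05_promoter_enhancer_chains.py
python analysis/06_mtf_selection.py
```

which prints:

```
super-enhancers per sample: min=20 max=20
40 consensus SE regions; PC1 explains 97.0% of variance
PC1 separates case from control: True
mean mSat density per kb: SE=0.787 enhancer=0.154
paired Wilcoxon (n=10): p=1.95e-03
regions with >= 1 mSat: SEs 100.0% vs enhancers 14.5%
samples with >= 1 CRC clique: 10 case, 0 control
specificity-filtered MTF candidates: ['TF01', 'TF02', 'TF03']
hops in case01: {'TF01': 1, 'TF02': 2, 'TF03': 3, 'TF04': 4, 'TF05': 5}
selected MTFs (>= 2 of 3 criteria): ['TF01', 'TF02', 'TF03']
top dependency: TF12 (in CRC: False) — the planted driver regulates the
circuit without being part of it
```

Reading the output: each case sample recovers exactly its 20 planted
super-enhancers; case and control samples separate cleanly on PC1 of the
consensus-SE intensity matrix; GGAA microsatellite density is ~5× higher
in SEs than in typical enhancers and the paired Wilcoxon p-value
(1.95 × 10⁻³ = 2/1024) is the exact two-sided minimum for 10 concordant
pairs; the planted 3-TF circuit — and nothing else — survives the
specificity filter and the 2-of-3 selection; the planted chain hop
distances (1–5) are recovered while the hop-6 chain is invisible at the
depth cap; and the driver TF12 tops the dependency table while staying
outside every clique.

## Layout

```
src/secrc/          the library (io, motifs, superenhancers,
                    microsatellites, circuitry, chains, selection,
                    tables, simulate, pipeline, cli)
analysis/           numbered narrative drivers over the library
scripts/acceptance.py   from-scratch recomputation of all quantities
tests/              pytest suite incl. oracle-based acceptance checks
docs/methods.md     model, parameters, generator and design notes
```
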