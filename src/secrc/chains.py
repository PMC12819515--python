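"""Promoter-enhancer chain traversal over chromatin-loop anchor graphs.

HiChIP loops are turned into an undirected anchor graph: overlapping loop
ends are merged into anchors (single linkage, >= 1 bp), each anchor is
labelled promoter (within a window of a TSS), enhancer (overlapping an
H3K27ac peak) or other, and marked as mSat-bound when it overlaps a
fusion-TF peak that contains a GGAA microsatellite. A cis-regulatory
chain starts at a TF's promoter anchor and walks promoter-enhancer and
enhancer-enhancer interactions; the quantity of interest is the hop index
(1-based on edges) of the first mSat-bound anchor, capped by default at
five interactions. Anchors labelled "other" are not traversable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .io import GenomicRegion, Loop, RegionSet
from .circuitry import GeneModel

DEFAULT_PROMOTER_WINDOW = 2_500
DEFAULT_MAX_DEPTH = 5


@dataclass(frozen=True)
class Anchor:
    region: GenomicRegion
    label: str  # promoter | enhancer | other
    genes: tuple[str, ...] = ()
    msat_bound: bool = False

    def __post_init__(self) -> None:
        if self.label not in ("promoter", "enhancer", "other"):
            raise ValueError(f"invalid anchor label {self.label!r}")
        if (self.label == "promoter") != bool(self.genes):
            raise ValueError("label is promoter iff genes are non-empty")


@dataclass
class AnchorGraph:
    anchors: list[Anchor]
    graph: nx.Graph  # nodes: anchor indices; edge attr "support"

    def promoter_anchor(self, tf: str) -> int | None:
        """Index of the TF's promoter anchor (smallest coordinate wins)."""
        candidates = [
            i for i, a in enumerate(self.anchors)
            if a.label == "promoter" and tf in a.genes
        ]
        if not candidates:
            return None
        return min(candidates, key=lambda i: self.anchors[i].region.sort_key())


@dataclass
class Chain:
    """A shortest witness path from a TF promoter to an mSat-bound anchor."""

    tf: str
    path: list[Anchor]
    first_msat_hop: int | None  # 1-based edge count, None if unreached


def _merge_intervals(regions: list[GenomicRegion]) -> list[list[int]]:
    """Single-linkage (>= 1 bp overlap) grouping of regions; returns index groups."""
    order = sorted(range(len(regions)), key=lambda i: regions[i].sort_key())
    groups: list[list[int]] = []
    current: list[int] = []
    current_end = -1
    current_chrom = None
    for i in order:
        r = regions[i]
        if current and r.chrom == current_chrom and r.start < current_end:
            current.append(i)
            current_end = max(current_end, r.end)
        else:
            if current:
                groups.append(current)
            current = [i]
            current_chrom = r.chrom
            current_end = r.end
    if current:
        groups.append(current)
    return groups


def _overlaps_any(region: GenomicRegion, others: Sequence[GenomicRegion]) -> bool:
    return any(region.overlaps(o) for o in others)


def build_anchor_graph(
    loops: Sequence[Loop],
    genes: Sequence[GeneModel],
    h3k27ac_peaks: RegionSet | None = None,
    ets_msat_peaks: RegionSet | None = None,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    min_support: float = 1.0,
) -> AnchorGraph:
    """Merge loop ends into labelled anchors and connect them by loops.

    A loop contributes an edge when its support count reaches
    ``min_support`` (default 1: all loops). Promoter labelling uses a
    +/- ``promoter_window`` bp window around each TSS.
    """
    kept = [lp for lp in loops if lp.count >= min_support]
    ends: list[GenomicRegion] = []
    for lp in kept:
        ends.append(lp.anchor_a)
        ends.append(lp.anchor_b)
    groups = _merge_intervals(ends)
    end_to_anchor: dict[int, int] = {}
    anchors: list[Anchor] = []
    peak_list = list(h3k27ac_peaks) if h3k27ac_peaks is not None else []
    msat_list = list(ets_msat_peaks) if ets_msat_peaks is not None else []
    for anchor_idx, group in enumerate(groups):
        members = [ends[i] for i in group]
        span = GenomicRegion(
            members[0].chrom,
            min(r.start for r in members),
            max(r.end for r in members),
        )
        hit_genes = tuple(sorted(
            g.gene for g in genes
            if g.tss.chrom == span.chrom
            and span.start < g.tss.start + promoter_window + 1
            and g.tss.start - promoter_window < span.end
        ))
        if hit_genes:
            label = "promoter"
        elif _overlaps_any(span, peak_list):
            label = "enhancer"
        else:
            label = "other"
        anchors.append(Anchor(
            span, label, hit_genes,
            msat_bound=_overlaps_any(span, msat_list),
        ))
        for i in group:
            end_to_anchor[i] = anchor_idx
    graph = nx.Graph()
    graph.add_nodes_from(range(len(anchors)))
    for k, lp in enumerate(kept):
        a = end_to_anchor[2 * k]
        b = end_to_anchor[2 * k + 1]
        if a == b:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["support"] += lp.count
        else:
            graph.add_edge(a, b, support=lp.count)
    return AnchorGraph(anchors, graph)


def chain_search(anchor_graph: AnchorGraph, tf: str,
                 max_depth: int = DEFAULT_MAX_DEPTH) -> Chain:
    """BFS from the TF promoter for the nearest mSat-bound anchor.

    Traversal only passes through promoter or enhancer anchors. The hop
    index is 1-based on edges (a directly looped mSat element is hop 1).
    The witness path is one shortest path, with ties broken by visiting
    smaller genomic coordinates first. Raises when the TF has no promoter
    anchor.
    """
    start = anchor_graph.promoter_anchor(tf)
    if start is None:
        raise ValueError(f"no promoter anchor for TF {tf!r}")
    anchors = anchor_graph.anchors
    graph = anchor_graph.graph
    parent: dict[int, int | None] = {start: None}
    frontier = [start]
    depth = 0
    while frontier and depth < max_depth:
        depth += 1
        next_frontier: list[int] = []
        for node in frontier:
            neighbors = sorted(
                graph.neighbors(node),
                key=lambda i: anchors[i].region.sort_key(),
            )
            for nb in neighbors:
                if nb in parent:
                    continue
                if anchors[nb].label == "other":
                    continue
                parent[nb] = node
                if anchors[nb].msat_bound:
                    path_idx = [nb]
                    while parent[path_idx[-1]] is not None:
                        path_idx.append(parent[path_idx[-1]])
                    path_idx.reverse()
                    return Chain(tf, [anchors[i] for i in path_idx], depth)
                next_frontier.append(nb)
        frontier = next_frontier
    return Chain(tf, [anchors[start]], None)


def chain_table(anchor_graph: AnchorGraph,
                tfs: Sequence[str],
                max_depth: int = DEFAULT_MAX_DEPTH) -> dict[str, int | None]:
    """First mSat hop per TF; None when unreached or no promoter anchor."""
    out: dict[str, int | None] = {}
    for tf in tfs:
        try:
            out[tf] = chain_search(anchor_graph, tf, max_depth).first_msat_hop
        except ValueError:
            out[tf] = None
    return out
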