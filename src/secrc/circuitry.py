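"""Core regulatory circuitry (CRC) inference and cross-entity specificity.

A CRC is a set of master transcription factors (MTFs) that collectively
regulate their own expression through interconnected auto-regulatory
loops: each member's motif occurs in its own super-enhancer (a self-edge)
and in every other member's super-enhancer (bidirectional pairwise
edges). Per sample, super-enhancers are assigned to their closest active
gene, a directed motif-support network is built over SE-assigned active
TFs, and CRC cliques are the maximal fully interconnected auto-regulatory
sets. The top 10 cliques per sample are retained to avoid overly
stringent calls, and candidates are filtered for entity specificity:
present in at least 50% of case samples and under 30% of controls.

A driver that regulates every MTF without reciprocal regulation — out-
edges to all, no in-edges, no self-edge (the "hegemonic" configuration) —
is excluded from every clique by definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import GenomicRegion
from .motifs import MotifMatrix, pwm_scan
from .tables import ExpressionTable

logger = logging.getLogger(__name__)

DEFAULT_ACTIVITY_THRESHOLD = 1.0  # log2 expression units
DEFAULT_SCORE_FRACTION = 0.85
DEFAULT_TOP_K = 10
DEFAULT_CASE_MIN = 0.5
DEFAULT_CONTROL_MAX = 0.3


@dataclass(frozen=True)
class GeneModel:
    """A gene with a 1-bp TSS and a transcription-factor flag."""

    gene: str
    tss: GenomicRegion
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.tss.length != 1:
            raise ValueError(f"TSS of {self.gene} must be a 1-bp region")


@dataclass(frozen=True)
class SEAssignment:
    """A super-enhancer assigned to its closest active gene."""

    se_region: GenomicRegion
    assigned_gene: str
    distance: int  # bp from SE boundary to TSS, 0 if contained


@dataclass
class TFNetwork:
    """Directed motif-support graph over one sample's SE-assigned TFs."""

    sample_id: str
    graph: nx.DiGraph  # edge i -> j: motif of i hits SE constituents of j

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_weight(self, i: str, j: str) -> float:
        if self.graph.has_edge(i, j):
            return float(self.graph[i][j]["weight"])
        return 0.0


@dataclass(frozen=True)
class CRCClique:
    """A fully interconnected auto-regulatory TF set with its rank."""

    tf_set: tuple[str, ...]
    score: float
    rank: int


@dataclass(frozen=True)
class SpecificityResult:
    tf: str
    case_fraction: float
    control_fraction: float
    is_candidate: bool


def active_genes(expr: ExpressionTable, sample: str,
                 threshold: float = DEFAULT_ACTIVITY_THRESHOLD) -> set[str]:
    """Genes whose log2 expression reaches ``threshold`` in ``sample``."""
    if sample not in expr.values.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = expr.values[sample]
    return set(col.index[col >= threshold])


def assign_se_to_gene(se: GenomicRegion,
                      genes: Sequence[GeneModel]) -> SEAssignment | None:
    """Closest-active-gene annotation of a super-enhancer.

    Distance is from the SE interval to the TSS (0 when the TSS lies
    inside the SE). Ties break by smaller genomic coordinate, then by
    gene symbol. Returns None (logged) when no gene shares the
    chromosome.
    """
    best: tuple[int, int, str] | None = None
    best_gene: GeneModel | None = None
    for gm in genes:
        if gm.tss.chrom != se.chrom:
            continue
        pos = gm.tss.start
        if se.start <= pos < se.end:
            dist = 0
        elif pos < se.start:
            dist = se.start - pos
        else:
            dist = pos - (se.end - 1)
        key = (dist, pos, gm.gene)
        if best is None or key < best:
            best, best_gene = key, gm
    if best_gene is None:
        logger.warning("no active gene on %s for SE %s; left unassigned",
                       se.chrom, se)
        return None
    return SEAssignment(se, best_gene.gene, best[0])


def build_tf_network(
    sample_id: str,
    tf_constituents: Mapping[str, Sequence[GenomicRegion]],
    genome: Mapping[str, object],
    motifs_by_tf: Mapping[str, Sequence[MotifMatrix]],
    score_fraction: float = DEFAULT_SCORE_FRACTION,
) -> TFNetwork:
    """Directed network: edge i -> j iff TF i's motif hits TF j's SE.

    ``tf_constituents`` maps each SE-assigned active TF to the constituent
    peaks of its super-enhancer; scanning runs over constituents rather
    than the full stitched span. A TF may carry several motif matrices —
    an edge exists if any of them hits; the weight is the total hit
    count. TFs without any motif are excluded from the node set (logged).
    """
    from .microsatellites import fetch_sequence

    tfs = []
    for tf in sorted(tf_constituents):
        if not motifs_by_tf.get(tf):
            logger.warning("TF %s has no motif matrix; excluded from network", tf)
            continue
        tfs.append(tf)
    graph = nx.DiGraph()
    graph.add_nodes_from(tfs)
    target_seqs = {
        tf: [fetch_sequence(genome, r) for r in tf_constituents[tf]]
        for tf in tfs
    }
    for source in tfs:
        for target in tfs:
            n_hits = 0
            for motif in motifs_by_tf[source]:
                for seq in target_seqs[target]:
                    n_hits += len(pwm_scan(seq, motif, score_fraction))
            if n_hits > 0:
                graph.add_edge(source, target, weight=n_hits)
    return TFNetwork(sample_id, graph)


def find_crc_cliques(net: TFNetwork, top_k: int = DEFAULT_TOP_K) -> list[CRCClique]:
    """Maximal fully interconnected auto-regulatory TF sets, top-k by score.

    Only TFs with a self-edge (auto-regulation) qualify; within a clique
    every ordered pair must be connected, i.e. maximal cliques of the
    undirected graph whose edges are the bidirectional pairs among
    self-looped nodes. Scored by the mean, over members, of total inbound
    motif support from within the clique; ordered by score, then size,
    then lexicographic tf set, deterministically.
    """
    autoreg = [n for n in net.graph.nodes if net.graph.has_edge(n, n)]
    undirected = nx.Graph()
    undirected.add_nodes_from(autoreg)
    for i in autoreg:
        for j in autoreg:
            if i < j and net.graph.has_edge(i, j) and net.graph.has_edge(j, i):
                undirected.add_edge(i, j)
    cliques = []
    for members in nx.find_cliques(undirected):
        tf_set = tuple(sorted(members))
        inbound = [
            sum(net.edge_weight(i, j) for i in tf_set) for j in tf_set
        ]
        score = sum(inbound) / len(tf_set)
        cliques.append((score, len(tf_set), tf_set))
    cliques.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [
        CRCClique(tf_set, score, rank)
        for rank, (score, _, tf_set) in enumerate(cliques[:top_k], start=1)
    ]


def validate_clique(net: TFNetwork, clique: CRCClique) -> bool:
    """Re-check the full-interconnection + auto-regulation predicate."""
    return all(
        net.graph.has_edge(i, j) for i in clique.tf_set for j in clique.tf_set
    )


def crc_membership(
    cliques_by_sample: Mapping[str, Sequence[CRCClique]],
) -> pd.DataFrame:
    """TF x sample boolean matrix: member of any top-k clique in the sample."""
    samples = sorted(cliques_by_sample)
    tfs = sorted({
        tf for cliques in cliques_by_sample.values()
        for c in cliques for tf in c.tf_set
    })
    matrix = pd.DataFrame(False, index=tfs, columns=samples)
    for sample, cliques in cliques_by_sample.items():
        for clique in cliques:
            for tf in clique.tf_set:
                matrix.loc[tf, sample] = True
    return matrix


def specificity_filter(
    membership: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    case_min: float = DEFAULT_CASE_MIN,
    control_max: float = DEFAULT_CONTROL_MAX,
) -> list[SpecificityResult]:
    """Candidate MTFs: CRC members in >= ``case_min`` of cases and
    < ``control_max`` of controls.

    Samples absent from the membership matrix count as absences (a sample
    in which the TF was in no clique).
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids or not control_ids:
        raise ValueError("case and control groups must be non-empty")
    if set(case_ids) & set(control_ids):
        raise ValueError(
            f"overlapping groups: {sorted(set(case_ids) & set(control_ids))}"
        )
    results = []
    for tf in membership.index:
        row = membership.loc[tf]
        case_frac = sum(bool(row.get(s, False)) for s in case_ids) / len(case_ids)
        ctrl_frac = sum(bool(row.get(s, False)) for s in control_ids) / len(control_ids)
        results.append(SpecificityResult(
            tf, case_frac, ctrl_frac,
            is_candidate=case_frac >= case_min and ctrl_frac < control_max,
        ))
    return results
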