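"""CRC inference: assignment, motif scanning, clique enumeration, specificity."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from secrc.circuitry import (
    CRCClique,
    GeneModel,
    TFNetwork,
    active_genes,
    assign_se_to_gene,
    build_tf_network,
    crc_membership,
    find_crc_cliques,
    specificity_filter,
    validate_clique,
)
from secrc.io import GenomicRegion
from secrc.motifs import MotifMatrix, pwm_scan
from secrc.tables import ExpressionTable


def _tss(chrom, pos):
    return GenomicRegion(chrom, pos, pos + 1)


def _expr(data, columns):
    return ExpressionTable(pd.DataFrame(data, columns=columns))


class TestActiveGenes:
    def setup_method(self):
        self.expr = ExpressionTable(pd.DataFrame(
            {"s1": [5.0, 0.2, 3.0], "s2": [0.0, 0.0, 0.0]},
            index=["A", "B", "C"]))

    def test_threshold_minus_inf_keeps_all(self):
        assert active_genes(self.expr, "s1", float("-inf")) == {"A", "B", "C"}

    def test_threshold_above_max_is_empty(self):
        assert active_genes(self.expr, "s1", 99.0) == set()

    def test_bimodal_threshold_splits_at_antimode(self):
        assert active_genes(self.expr, "s1", 1.0) == {"A", "C"}

    def test_unknown_sample_errors(self):
        with pytest.raises(KeyError):
            active_genes(self.expr, "nope", 1.0)


class TestAssignment:
    def test_tss_inside_se_wins_with_distance_zero(self):
        se = GenomicRegion("chr1", 1000, 5000)
        genes = [GeneModel("IN", _tss("chr1", 2000)),
                 GeneModel("OUT", _tss("chr1", 5100))]
        a = assign_se_to_gene(se, genes)
        assert a.assigned_gene == "IN" and a.distance == 0

    def test_nearer_tss_wins(self):
        se = GenomicRegion("chr1", 10_000, 12_000)
        genes = [GeneModel("NEAR", _tss("chr1", 13_000)),
                 GeneModel("FAR", _tss("chr1", 17_000))]
        assert assign_se_to_gene(se, genes).assigned_gene == "NEAR"

    def test_no_gene_on_chromosome_returns_none(self):
        se = GenomicRegion("chr9", 0, 100)
        assert assign_se_to_gene(se, [GeneModel("A", _tss("chr1", 5))]) is None

    def test_matches_exhaustive_distance_scan(self):
        rng = np.random.default_rng(47)
        for _ in range(100):
            se_start = int(rng.integers(0, 90_000))
            se = GenomicRegion("chr1", se_start, se_start + int(rng.integers(500, 8000)))
            genes = [
                GeneModel(f"G{i}", _tss("chr1", int(rng.integers(0, 100_000))))
                for i in range(int(rng.integers(1, 15)))
            ]
            a = assign_se_to_gene(se, genes)

            def dist(g):
                p = g.tss.start
                if se.start <= p < se.end:
                    return 0
                return se.start - p if p < se.start else p - (se.end - 1)

            best = min(genes, key=lambda g: (dist(g), g.tss.start, g.gene))
            assert a.assigned_gene == best.gene
            assert a.distance == dist(best)


def _consensus_motif(consensus):
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 20.0
    return MotifMatrix("M1", "TF", counts)


def _naive_log_odds_scores(sequence, motif):
    """Position-by-position pure-Python scorer (independent route)."""
    import math

    counts = motif.counts
    L = motif.length
    bg = list(motif.background)
    lo = [[math.log2(((counts[r][j] + motif.pseudocount * bg[r])
                      / (sum(counts[r2][j] for r2 in range(4)) + motif.pseudocount))
                     / bg[r])
           for j in range(L)] for r in range(4)]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i:i + L]
        if any(b not in idx for b in window):
            out.append(float("-inf"))
            continue
        out.append(sum(lo[idx[b]][j] for j, b in enumerate(window)))
    return out


class TestPwmScan:
    def test_consensus_hits_itself_maximally(self):
        motif = _consensus_motif("ACGTAC")
        hits = pwm_scan("ACGTAC", motif, 1.0)
        assert len(hits) == 1
        assert hits[0].position == 0 and hits[0].strand == "+"
        assert hits[0].score == pytest.approx(motif.max_score())

    def test_reverse_complement_hits_minus_strand(self):
        motif = _consensus_motif("AACGTT"[:6])
        from secrc.microsatellites import reverse_complement
        rc = reverse_complement("AACGTT")
        hits = pwm_scan(rc, motif, 1.0)
        assert any(h.strand == "-" for h in hits)

    def test_sequence_shorter_than_motif_yields_nothing(self):
        assert pwm_scan("ACG", _consensus_motif("ACGTACGT")) == []

    def test_scores_match_naive_scorer(self):
        rng = np.random.default_rng(53)
        for _ in range(5):
            consensus = "".join("ACGT"[b] for b in rng.integers(0, 4, size=8))
            counts = rng.integers(0, 30, size=(4, 8)).astype(float)
            counts[:, 0] += 1  # no empty columns
            counts[:, 1:] += (counts[:, 1:].sum(axis=0) == 0) * 1.0
            motif = MotifMatrix("M", "TF", counts)
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=300))
            seq = seq[:50] + consensus + seq[58:]
            expected = _naive_log_odds_scores(seq, motif)
            lo = motif.log_odds()
            from secrc.motifs import _encode, _scores_one_strand
            got = _scores_one_strand(_encode(seq), lo)
            finite = [i for i, e in enumerate(expected) if e != float("-inf")]
            for i in finite:
                assert got[i] == pytest.approx(expected[i], abs=1e-9)


class TestNetworkAndCliques:
    def _net(self, edges, nodes=None):
        g = nx.DiGraph()
        if nodes:
            g.add_nodes_from(nodes)
        for i, j, w in edges:
            g.add_edge(i, j, weight=w)
        return TFNetwork("s", g)

    def test_planted_motif_produces_single_edge(self):
        genome = {"chr1": "T" * 200 + "ACGTACGTACGT" + "T" * 200}
        motifs = {
            "A": [_consensus_motif("ACGTACGTACGT")],
            "B": [_consensus_motif("CCCCCCGGGGGG")],
        }
        constituents = {
            "A": [GenomicRegion("chr1", 0, 100)],
            "B": [GenomicRegion("chr1", 150, 300)],
        }
        net = build_tf_network("s", constituents, genome, motifs)
        assert list(net.graph.edges) == [("A", "B")]

    def test_tf_without_motif_excluded(self):
        genome = {"chr1": "A" * 100}
        net = build_tf_network(
            "s", {"A": [GenomicRegion("chr1", 0, 50)]}, genome, {})
        assert net.nodes == []

    def test_three_tf_full_clique(self):
        tfs = ["A", "B", "C"]
        edges = [(i, j, 1.0) for i in tfs for j in tfs]
        cliques = find_crc_cliques(self._net(edges))
        assert len(cliques) == 1
        assert cliques[0].tf_set == ("A", "B", "C")

    def test_hegemonic_driver_excluded_from_all_cliques(self):
        # driver D: out-edges to everyone, no in-edges, no self-loop
        tfs = ["A", "B", "C"]
        edges = [(i, j, 1.0) for i in tfs for j in tfs]
        edges += [("D", t, 5.0) for t in tfs]
        cliques = find_crc_cliques(self._net(edges))
        assert cliques and all("D" not in c.tf_set for c in cliques)

    def test_matches_exhaustive_subset_enumeration(self):
        rng = np.random.default_rng(59)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            tfs = [f"T{i}" for i in range(n)]
            p = rng.uniform(0.2, 0.8)
            edges = [(a, b, float(rng.integers(1, 5)))
                     for a in tfs for b in tfs if rng.random() < p]
            net = self._net(edges, nodes=tfs)
            got = {c.tf_set for c in find_crc_cliques(net, top_k=10_000)}

            def ok(subset):
                return all(net.graph.has_edge(i, j)
                           for i in subset for j in subset)

            valid = [frozenset(s)
                     for r in range(1, n + 1)
                     for s in itertools.combinations(tfs, r) if ok(s)]
            maximal = {
                tuple(sorted(s)) for s in valid
                if not any(s < t for t in valid)
            }
            assert got == maximal
            for c in find_crc_cliques(net, top_k=10_000):
                assert validate_clique(net, c)

    def test_clique_ranking_is_deterministic(self):
        edges = [(i, j, 1.0) for i in "AB" for j in "AB"]
        edges += [(i, j, 3.0) for i in "CD" for j in "CD"]
        cliques = find_crc_cliques(self._net(edges))
        assert [c.tf_set for c in cliques] == [("C", "D"), ("A", "B")]
        assert [c.rank for c in cliques] == [1, 2]


class TestMembershipAndSpecificity:
    def test_membership_from_any_topk_clique(self):
        cliques = {
            "s1": [CRCClique(("A", "B"), 2.0, 1), CRCClique(("C",), 1.0, 10)],
            "s2": [],
        }
        m = crc_membership(cliques)
        assert bool(m.loc["C", "s1"]) is True
        assert bool(m.loc["A", "s2"]) is False
        # column sums equal independently recomputed union sizes
        for s, cl in cliques.items():
            union = set().union(*[c.tf_set for c in cl]) if cl else set()
            assert m[s].sum() == len(union)

    def test_specificity_thresholds(self):
        m = pd.DataFrame(
            {"c1": [True, True], "c2": [True, False],
             "k1": [False, True], "k2": [False, True], "k3": [False, True]},
            index=["GOOD", "BAD"])
        res = {r.tf: r for r in specificity_filter(
            m, ["c1", "c2"], ["k1", "k2", "k3"])}
        assert res["GOOD"].is_candidate  # 100% cases, 0% controls
        assert not res["BAD"].is_candidate  # present in 100% of controls

    def test_just_below_case_threshold_not_candidate(self):
        cases = [f"c{i}" for i in range(100)]
        m = pd.DataFrame(
            {**{c: [i < 49] for i, c in enumerate(cases)}, "k1": [False]},
            index=["TF"])
        res = specificity_filter(m, cases, ["k1"])
        assert res[0].case_fraction == pytest.approx(0.49)
        assert not res[0].is_candidate

    def test_overlapping_groups_rejected(self):
        m = pd.DataFrame({"a": [True]}, index=["TF"])
        with pytest.raises(ValueError, match="overlap"):
            specificity_filter(m, ["a"], ["a"])

    def test_fractions_match_direct_recount(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            tfs = [f"T{i}" for i in range(5)]
            cases = [f"c{i}" for i in range(6)]
            controls = [f"k{i}" for i in range(4)]
            m = pd.DataFrame(
                rng.random((5, 10)) < 0.5,
                index=tfs, columns=cases + controls)
            for r in specificity_filter(m, cases, controls):
                cf = m.loc[r.tf, cases].sum() / 6
                kf = m.loc[r.tf, controls].sum() / 4
                assert r.case_fraction == pytest.approx(cf)
                assert r.control_fraction == pytest.approx(kf)
                assert r.is_candidate == (cf >= 0.5 and kf < 0.3)
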