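"""Super-enhancer calling: stitching, scoring, tangent cutoff, consensus, PCA."""

import numpy as np
import pytest

from secrc.io import GenomicRegion, RegionSet, SignalTrack
from secrc.superenhancers import (
    ConsensusMatrix,
    StitchedRegion,
    build_consensus,
    call_superenhancers,
    normalize_profile,
    pca_profiles,
    score_regions,
    se_rank_curve,
    stitch_peaks,
    tangent_cutoff,
)


def _regions(spans, chrom="chr1"):
    return [GenomicRegion(chrom, s, e) for s, e in spans]


def _stitch_oracle(peaks, distance):
    """Naive O(n^2) transitive gap-merge partition."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            a, b = peaks[i], peaks[j]
            if a.chrom == b.chrom and \
                    max(a.start, b.start) - min(a.end, b.end) <= distance:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add((peaks[i].chrom, peaks[i].start, peaks[i].end))
    return {frozenset(g) for g in groups.values()}


class TestStitching:
    def test_two_peaks_within_distance_merge(self):
        peaks = RegionSet(_regions([(0, 1000), (5000, 6000)]))
        out = stitch_peaks(peaks, 12_500)
        assert len(out) == 1
        assert (out[0].region.start, out[0].region.end) == (0, 6000)
        assert len(out[0].constituents) == 2

    def test_distant_peaks_stay_separate(self):
        peaks = RegionSet(_regions([(0, 1000), (21_000, 22_000)]))
        assert len(stitch_peaks(peaks, 12_500)) == 2

    def test_tss_exclusion_drops_contained_peaks(self):
        peaks = RegionSet(_regions([(0, 1000), (5000, 6000)]))
        excl = RegionSet(_regions([(4900, 6100)]))
        out = stitch_peaks(peaks, 12_500, tss_exclusion=excl)
        assert len(out) == 1 and len(out[0].constituents) == 1

    def test_matches_quadratic_oracle_on_random_peaks(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            peaks = []
            for _ in range(200):
                start = int(rng.integers(0, 500_000))
                peaks.append(GenomicRegion(
                    f"chr{rng.integers(1, 3)}", start,
                    start + int(rng.integers(100, 3000))))
            distance = int(rng.integers(0, 20_000))
            result = stitch_peaks(RegionSet(peaks), distance)
            observed = {
                frozenset((c.chrom, c.start, c.end) for c in sr.constituents)
                for sr in result
            }
            assert observed == _stitch_oracle(peaks, distance)

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        peaks = []
        for _ in range(300):
            s = int(rng.integers(0, 200_000))
            peaks.append(GenomicRegion("chr1", s, s + int(rng.integers(50, 2000))))
        out = stitch_peaks(RegionSet(peaks), 5_000)
        assert sum(len(sr.constituents) for sr in out) == len(peaks)
        for sr in out:
            assert sr.region.start == min(c.start for c in sr.constituents)
            assert sr.region.end == max(c.end for c in sr.constituents)


class TestScoring:
    def test_flat_treatment_no_control(self):
        sr = StitchedRegion(GenomicRegion("chr1", 0, 10),
                            [GenomicRegion("chr1", 0, 10)])
        track = SignalTrack([(GenomicRegion("chr1", 0, 10), 3.0)])
        assert score_regions([sr], track)[0].net_signal == pytest.approx(30.0)

    def test_control_subtraction_floored_at_zero(self):
        sr = StitchedRegion(GenomicRegion("chr1", 0, 10),
                            [GenomicRegion("chr1", 0, 10)])
        treat = SignalTrack([(GenomicRegion("chr1", 0, 10), 2.0)])
        ctrl = SignalTrack([(GenomicRegion("chr1", 0, 10), 5.0)])
        assert score_regions([sr], treat, ctrl)[0].net_signal == 0.0

    def test_matches_per_base_summation_oracle(self):
        rng = np.random.default_rng(5)
        n_bases = 5_000
        treat_per_base = np.zeros(n_bases)
        ctrl_per_base = np.zeros(n_bases)
        treat_iv, ctrl_iv = [], []
        pos = 0
        while pos < n_bases - 10:
            width = int(rng.integers(5, 200))
            end = min(pos + width, n_bases)
            tv = float(rng.uniform(0, 10))
            cv = float(rng.uniform(0, 4))
            treat_iv.append((GenomicRegion("chr1", pos, end), tv))
            ctrl_iv.append((GenomicRegion("chr1", pos, end), cv))
            treat_per_base[pos:end] = tv
            ctrl_per_base[pos:end] = cv
            pos = end + int(rng.integers(0, 50))
        treat, ctrl = SignalTrack(treat_iv), SignalTrack(ctrl_iv)
        for _ in range(50):
            s = int(rng.integers(0, n_bases - 100))
            e = s + int(rng.integers(10, 100))
            sr = StitchedRegion(GenomicRegion("chr1", s, e),
                                [GenomicRegion("chr1", s, e)])
            expected = max(0.0, treat_per_base[s:e].sum() - ctrl_per_base[s:e].sum())
            got = score_regions([sr], treat, ctrl)[0].net_signal
            assert got == pytest.approx(expected, abs=1e-9)


def _cutoff_oracle(signals):
    """Brute-force scan of the scaled-slope definition over all ranks."""
    s = np.sort(np.asarray(signals, float))
    n = s.size
    lo, hi = s[0], s[-1]
    if hi <= lo:
        return hi
    x = np.arange(n) / (n - 1)
    y = (s - lo) / (hi - lo)
    for i in range(n):
        if i == 0:
            slope = (y[1] - y[0]) / (x[1] - x[0])
        elif i == n - 1:
            slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
        else:
            slope = (y[i + 1] - y[i - 1]) / (x[i + 1] - x[i - 1])
        if slope > 1:
            return float(s[i])
    return float(s[-1])


class TestTangentCutoff:
    def test_single_outlier_is_only_se(self):
        signals = [0.0, 1.0, 2.0, 3.0, 100.0]
        srs = [StitchedRegion(GenomicRegion("chr1", i * 10, i * 10 + 5),
                              [GenomicRegion("chr1", i * 10, i * 10 + 5)], s)
               for i, s in enumerate(signals)]
        profile = call_superenhancers(srs)
        assert [r.net_signal for r in profile.superenhancers()] == [100.0]
        assert profile.cutoff_signal == _cutoff_oracle(signals)

    def test_flat_curve_yields_no_superenhancers(self):
        srs = [StitchedRegion(GenomicRegion("chr1", i * 10, i * 10 + 5),
                              [GenomicRegion("chr1", i * 10, i * 10 + 5)], 7.0)
               for i in range(10)]
        assert call_superenhancers(srs).n_superenhancers() == 0

    def test_insufficient_regions(self):
        sr = StitchedRegion(GenomicRegion("chr1", 0, 5),
                            [GenomicRegion("chr1", 0, 5)], 1.0)
        with pytest.raises(ValueError, match="insufficient regions"):
            call_superenhancers([sr])

    def test_hockey_stick_elbow_within_one_rank(self):
        # piecewise-linear scaled curve: slope 0.2 below the elbow at rank
        # 950 (of 1000), then a steep linear rise to 1 — the analytic
        # slope-1 crossing sits at the planted elbow
        n, elbow = 1000, 950
        x = np.arange(n) / (n - 1)
        y = np.where(
            np.arange(n) < elbow,
            0.2 * x / x[elbow - 1],
            0.2 + 0.8 * (x - x[elbow - 1]) / (1 - x[elbow - 1]),
        )
        signals = y * 1000.0
        _, rank = tangent_cutoff(signals)
        assert abs(rank - elbow) <= 1

    def test_matches_brute_force_on_random_curves(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            signals = np.sort(rng.lognormal(2.0, 1.5, size=int(rng.integers(5, 500))))
            cutoff, _ = tangent_cutoff(signals)
            assert cutoff == pytest.approx(_cutoff_oracle(signals))

    def test_se_partition_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(10)
        signals = rng.lognormal(2.0, 1.0, size=100)
        srs = [StitchedRegion(GenomicRegion("chr1", i * 100, i * 100 + 50),
                              [GenomicRegion("chr1", i * 100, i * 100 + 50)], s)
               for i, s in enumerate(signals)]
        profile = call_superenhancers(srs)
        assert len(profile.se_flags) == len(profile.regions)
        for sr, flag in zip(profile.regions, profile.se_flags):
            assert flag == (sr.net_signal > profile.cutoff_signal)


class TestNormalize:
    def _profile(self, signals):
        srs = [StitchedRegion(GenomicRegion("chr1", i * 100, i * 100 + 50),
                              [GenomicRegion("chr1", i * 100, i * 100 + 50)], s)
               for i, s in enumerate(signals)]
        return call_superenhancers(srs)

    def test_intensities_are_fraction_of_max(self):
        profile = normalize_profile(self._profile([50.0, 200.0]))
        assert profile.normalized_intensity == pytest.approx([0.25, 1.0])

    def test_top_n_truncation_demotes_excess_ses(self):
        signals = [1.0] * 5 + list(np.linspace(100, 700, 600))
        profile = normalize_profile(self._profile(signals), top_n=500)
        assert profile.n_superenhancers() == 500
        # the demoted SEs are the lowest-signal ones
        kept = [r.net_signal for r, f in zip(profile.regions, profile.se_flags) if f]
        assert min(kept) >= max(
            r.net_signal for r, f in zip(profile.regions, profile.se_flags)
            if not f and r.net_signal > profile.cutoff_signal
        )

    def test_idempotent(self):
        once = normalize_profile(self._profile([0.0, 5.0, 9.0, 300.0]), top_n=2)
        twice = normalize_profile(once, top_n=2)
        assert twice.normalized_intensity == once.normalized_intensity
        assert twice.se_flags == once.se_flags


def _consensus_oracle(entries, min_overlap):
    """Transitive closure over pairwise of-smaller overlap >= threshold."""
    from secrc.io import overlap_fraction

    n = len(entries)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if overlap_fraction(entries[i], entries[j], "of_smaller") >= min_overlap:
                adj[i][j] = True
    groups = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        groups.append(frozenset(comp))
    return sorted(groups, key=lambda g: min(g))


class TestConsensus:
    def _profile_from_ses(self, sample, spans):
        # high-signal spans (the SEs) over a floor of low dummy regions,
        # so the tangent cutoff lands between the two blocks
        srs = [StitchedRegion(GenomicRegion("chr1", s, e),
                              [GenomicRegion("chr1", s, e)], float(100 + i))
               for i, (s, e) in enumerate(spans)]
        srs += [StitchedRegion(GenomicRegion("chr2", i * 10, i * 10 + 5),
                               [GenomicRegion("chr2", i * 10, i * 10 + 5)], 0.001)
                for i in range(3)]
        profile = call_superenhancers(srs, sample_id=sample)
        return normalize_profile(profile)

    def test_identical_se_in_two_samples(self):
        p1 = self._profile_from_ses("s1", [(1000, 3000)])
        p2 = self._profile_from_ses("s2", [(1000, 3000)])
        m = build_consensus([p1, p2])
        assert len(m.consensus_regions) == 1
        assert (m.values > 0).all()

    def test_disjoint_ses_stay_separate(self):
        p1 = self._profile_from_ses("s1", [(1000, 3000)])
        p2 = self._profile_from_ses("s2", [(50_000, 52_000)])
        m = build_consensus([p1, p2])
        assert len(m.consensus_regions) == 2
        assert ((m.values == 0).sum(axis=1) == 1).all()

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            profiles, flat = [], []
            for s in range(3):
                spans = []
                for _ in range(int(rng.integers(1, 8))):
                    start = int(rng.integers(0, 50_000))
                    spans.append((start, start + int(rng.integers(500, 5000))))
                spans = sorted(set(spans))
                profiles.append(self._profile_from_ses(f"s{s}", spans))
            for p in profiles:
                flat.extend(sr.region for sr in p.superenhancers())
            m = build_consensus(profiles, 0.5)
            oracle_groups = _consensus_oracle(flat, 0.5)
            assert len(m.consensus_regions) == len(oracle_groups)

    def test_values_equal_contributing_intensity(self):
        p1 = self._profile_from_ses("s1", [(1000, 3000), (9000, 12_000)])
        m = build_consensus([p1])
        lookup = {(sr.region.start, sr.region.end): x
                  for sr, x in p1.se_intensities()}
        for region, value in zip(m.consensus_regions, m.values[:, 0]):
            assert value == pytest.approx(lookup[(region.start, region.end)])


class TestPCA:
    def test_identical_samples_have_identical_coordinates(self):
        values = np.tile(np.array([[0.5], [0.2], [0.9]]), (1, 2))
        m = ConsensusMatrix(_regions([(0, 10), (20, 30), (40, 50)]),
                            ["a", "b"], values)
        scores, _ = pca_profiles(m, 1)
        assert scores[0] == pytest.approx(scores[1])

    def test_two_planted_groups_linearly_separable_on_pc1(self):
        rng = np.random.default_rng(33)
        n_regions, n_per_group = 100, 5
        values = np.zeros((n_regions, 2 * n_per_group))
        values[:50, :n_per_group] = rng.uniform(0.5, 1.0, (50, n_per_group))
        values[50:, n_per_group:] = rng.uniform(0.5, 1.0, (50, n_per_group))
        m = ConsensusMatrix(
            _regions([(i * 100, i * 100 + 50) for i in range(n_regions)]),
            [f"s{i}" for i in range(2 * n_per_group)], values)
        scores, evr = pca_profiles(m, 2)
        g1, g2 = scores[:n_per_group, 0], scores[n_per_group:, 0]
        assert max(g1) < min(g2) or max(g2) < min(g1)
        assert evr.sum() <= 1.0 + 1e-9

    def test_too_many_components_rejected(self):
        m = ConsensusMatrix(_regions([(0, 10)]), ["a", "b"],
                            np.array([[0.1, 0.9]]))
        with pytest.raises(ValueError):
            pca_profiles(m, 2)


class TestRankCurve:
    def test_group_means_sorted_ascending(self):
        m = ConsensusMatrix(
            _regions([(0, 10), (20, 30)]), ["a", "b"],
            np.array([[0.2, 0.4], [0.8, 0.6]]))
        _, curve = se_rank_curve(m)
        assert curve == pytest.approx([0.3, 0.7])
        assert np.all(np.diff(curve) >= 0)

    def test_single_sample_returns_own_sorted_intensities(self):
        m = ConsensusMatrix(
            _regions([(0, 10), (20, 30), (40, 50)]), ["a"],
            np.array([[0.9], [0.1], [0.5]]))
        _, curve = se_rank_curve(m, ["a"])
        assert curve == pytest.approx([0.1, 0.5, 0.9])
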