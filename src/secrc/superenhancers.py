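"""ROSE-style super-enhancer calling and cross-sample consensus.

The procedure mirrors the rank-ordering-of-super-enhancers (ROSE)
geometry: H3K27ac peaks within a stitching distance are merged into
stitched regions, each scored by input-subtracted signal, regions are
ranked by signal, and the super-enhancer cutoff is the point where the
slope of the min-max-scaled rank/signal curve first exceeds 1 (the
tangent-of-slope-one rule). Per-sample signals are then normalized by the
sample maximum, super-enhancers are merged across samples into a
consensus matrix, and sample structure is summarized by PCA.

Defaults follow ROSE: 12,500 bp stitching, optional TSS exclusion of
+/-2,500 bp, and retention of the top 500 super-enhancers per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    GenomicRegion,
    RegionSet,
    SignalTrack,
    overlap_fraction,
    overlap_length,
)

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_EXCLUSION = 2_500
DEFAULT_TOP_N_SE = 500


@dataclass
class StitchedRegion:
    """A merged cluster of peaks with its net (input-subtracted) signal."""

    region: GenomicRegion
    constituents: list[GenomicRegion]
    net_signal: float = 0.0

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError("stitched region needs >= 1 constituent")


@dataclass
class RankedProfile:
    """One sample's stitched regions ranked ascending by net signal."""

    sample_id: str
    regions: list[StitchedRegion]
    cutoff_signal: float
    se_flags: list[bool]
    normalized_intensity: list[float] = field(default_factory=list)

    def superenhancers(self) -> list[StitchedRegion]:
        return [r for r, f in zip(self.regions, self.se_flags) if f]

    def n_superenhancers(self) -> int:
        return sum(self.se_flags)

    def se_intensities(self) -> list[tuple[StitchedRegion, float]]:
        return [
            (r, x)
            for r, f, x in zip(self.regions, self.se_flags, self.normalized_intensity)
            if f
        ]


@dataclass
class ConsensusMatrix:
    """Merged super-enhancer regions x samples, normalized intensity."""

    consensus_regions: list[GenomicRegion]
    samples: list[str]
    values: np.ndarray  # regions x samples, in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.consensus_regions), len(self.samples)):
            raise ValueError("consensus matrix shape mismatch")


def stitch_peaks(
    peaks: RegionSet,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: RegionSet | None = None,
) -> list[StitchedRegion]:
    """Merge same-chromosome peaks whose gap is <= ``stitch_distance``.

    Peaks falling fully inside a TSS-exclusion region are dropped before
    stitching. The result is a partition of the retained peaks.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    retained = list(peaks)
    if tss_exclusion is not None and len(tss_exclusion):
        excl = list(tss_exclusion)
        retained = [
            p for p in retained
            if not any(
                e.chrom == p.chrom and e.start <= p.start and p.end <= e.end
                for e in excl
            )
        ]
    retained.sort(key=GenomicRegion.sort_key)
    out: list[StitchedRegion] = []
    current: list[GenomicRegion] = []
    for peak in retained:
        if current and peak.chrom == current[-1].chrom and \
                peak.start - max(c.end for c in current) <= stitch_distance:
            current.append(peak)
        else:
            if current:
                out.append(_finish_stitch(current))
            current = [peak]
    if current:
        out.append(_finish_stitch(current))
    return out


def _finish_stitch(constituents: list[GenomicRegion]) -> StitchedRegion:
    start = min(c.start for c in constituents)
    end = max(c.end for c in constituents)
    region = GenomicRegion(constituents[0].chrom, start, end)
    return StitchedRegion(region, list(constituents))


def score_regions(
    stitched: list[StitchedRegion],
    treatment: SignalTrack,
    control: SignalTrack | None = None,
) -> list[StitchedRegion]:
    """Attach net signal: treatment minus control coverage, floored at 0.

    Negative net enrichment after input subtraction is noise, hence the
    floor.
    """
    out = []
    for sr in stitched:
        signal = treatment.sum_over(sr.region)
        if control is not None:
            signal -= control.sum_over(sr.region)
        out.append(StitchedRegion(sr.region, sr.constituents, max(0.0, signal)))
    return out


def tangent_cutoff(signals: np.ndarray) -> tuple[float, int | None]:
    """Slope-1 cutoff on the min-max-scaled ascending rank/signal curve.

    Returns ``(cutoff_signal, cutoff_rank)`` where ``cutoff_rank`` indexes
    the ascending sorted signals, or ``(max_signal, None)`` when the slope
    never exceeds 1 (e.g. a flat curve), in which case nothing lies above
    the cutoff. Discrete slope by central difference, one-sided at the
    ends; the first crossing (scanning ascending) wins.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = s.size
    if n < 2:
        raise ValueError("insufficient regions")
    lo, hi = float(s[0]), float(s[-1])
    if hi <= lo:
        return hi, None
    x = np.arange(n) / (n - 1)
    y = (s - lo) / (hi - lo)
    slope = np.gradient(y, x)
    above = np.flatnonzero(slope > 1.0)
    if above.size == 0:
        return hi, None
    k = int(above[0])
    return float(s[k]), k


def call_superenhancers(scored: list[StitchedRegion],
                        sample_id: str = "") -> RankedProfile:
    """Partition scored regions into super-enhancers and typical enhancers.

    Regions with net signal strictly above the tangent cutoff are
    super-enhancers; ties at the cutoff stay typical enhancers.
    """
    if len(scored) < 2:
        raise ValueError("insufficient regions (need >= 2 scored regions)")
    signals = np.array([r.net_signal for r in scored], dtype=float)
    if not np.all(np.isfinite(signals)):
        raise ValueError("non-finite net signal")
    cutoff, _ = tangent_cutoff(signals)
    order = np.argsort(signals, kind="stable")
    regions = [scored[i] for i in order]
    flags = [r.net_signal > cutoff for r in regions]
    return RankedProfile(sample_id, regions, cutoff, flags)


def normalize_profile(profile: RankedProfile,
                      top_n: int = DEFAULT_TOP_N_SE) -> RankedProfile:
    """Normalize by the sample maximum and keep only the top-n SEs.

    ``normalized_intensity = net_signal / max(net_signal)``; super-
    enhancers beyond the top ``top_n`` by signal are demoted to typical
    enhancers. Idempotent.
    """
    signals = np.array([r.net_signal for r in profile.regions], dtype=float)
    max_signal = float(signals.max()) if signals.size else 0.0
    if max_signal <= 0:
        import logging
        logging.getLogger(__name__).warning(
            "sample %s: maximum net signal is 0; all intensities set to 0",
            profile.sample_id,
        )
        intensities = [0.0] * len(profile.regions)
    else:
        intensities = list(signals / max_signal)
    flags = list(profile.se_flags)
    n_se = sum(flags)
    if n_se > top_n:
        # regions are ascending by signal: demote the lowest-signal SEs
        to_demote = n_se - top_n
        for i, f in enumerate(flags):
            if to_demote == 0:
                break
            if f:
                flags[i] = False
                to_demote -= 1
    return RankedProfile(
        profile.sample_id, profile.regions, profile.cutoff_signal, flags,
        intensities,
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_consensus(
    profiles: list[RankedProfile],
    min_overlap: float = 0.5,
    mode: str = "of_smaller",
) -> ConsensusMatrix:
    """Merge SEs across samples (transitively) into consensus regions.

    Two SEs merge when their overlap fraction is >= ``min_overlap`` under
    ``mode`` (``of_smaller``: of the smaller region, the default; or
    ``reciprocal``: of both regions). The consensus region is the union
    span of its group; each matrix cell holds the sample's normalized
    intensity of its best-overlapping SE in the group, else 0.
    """
    if not profiles:
        raise ValueError("need >= 1 profile")
    if mode not in ("of_smaller", "reciprocal"):
        raise ValueError(f"unknown consensus overlap mode {mode!r}")
    entries: list[tuple[GenomicRegion, int, float]] = []  # region, sample idx, intensity
    samples = [p.sample_id for p in profiles]
    for j, profile in enumerate(profiles):
        if not profile.normalized_intensity:
            raise ValueError(
                f"profile {profile.sample_id} not normalized; call "
                "normalize_profile first"
            )
        for sr, intensity in profile.se_intensities():
            entries.append((sr.region, j, intensity))
    if not entries:
        return ConsensusMatrix([], samples, np.zeros((0, len(samples))))
    order = sorted(range(len(entries)), key=lambda i: entries[i][0].sort_key())
    uf = _UnionFind(len(entries))
    active: list[int] = []
    for i in order:
        ri = entries[i][0]
        active = [
            k for k in active
            if entries[k][0].chrom == ri.chrom and entries[k][0].end > ri.start
        ]
        for k in active:
            if _linked(ri, entries[k][0], min_overlap, mode):
                uf.union(i, k)
        active.append(i)
    groups: dict[int, list[int]] = {}
    for i in range(len(entries)):
        groups.setdefault(uf.find(i), []).append(i)
    consensus: list[tuple[GenomicRegion, dict[int, float]]] = []
    for members in groups.values():
        regions = [entries[i][0] for i in members]
        span = GenomicRegion(
            regions[0].chrom,
            min(r.start for r in regions),
            max(r.end for r in regions),
        )
        best: dict[int, tuple[int, float]] = {}  # sample -> (overlap, intensity)
        for i in members:
            region, j, intensity = entries[i]
            ov = overlap_length(region, span)
            if j not in best or ov > best[j][0]:
                best[j] = (ov, intensity)
        consensus.append((span, {j: v for j, (_, v) in best.items()}))
    consensus.sort(key=lambda t: t[0].sort_key())
    values = np.zeros((len(consensus), len(samples)))
    for i, (_, per_sample) in enumerate(consensus):
        for j, v in per_sample.items():
            values[i, j] = v
    return ConsensusMatrix([c[0] for c in consensus], samples, values)


def _linked(a: GenomicRegion, b: GenomicRegion, min_overlap: float,
            mode: str) -> bool:
    if mode == "of_smaller":
        return overlap_fraction(a, b, "of_smaller") >= min_overlap
    return (
        overlap_fraction(a, b, "of_a") >= min_overlap
        and overlap_fraction(b, a, "of_a") >= min_overlap
    )


def pca_profiles(matrix: ConsensusMatrix, n_components: int = 2):
    """Mean-centered PCA of samples over consensus-SE intensities.

    Returns ``(scores, explained_variance_ratio)`` with ``scores`` of
    shape samples x components. Deterministic up to sign; the sign of each
    component is fixed so that its largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA

    X = matrix.values.T  # samples x regions
    n_samples, n_regions = X.shape
    if n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    if n_components > min(n_samples, n_regions):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, regions)="
            f"{min(n_samples, n_regions)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for k in range(n_components):
        lead = np.argmax(np.abs(loadings[k]))
        if loadings[k, lead] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    return scores, pca.explained_variance_ratio_


def se_rank_curve(matrix: ConsensusMatrix,
                  samples: list[str] | None = None):
    """Rank consensus regions ascending by cross-sample mean intensity.

    ``samples`` restricts the mean to one group (e.g. the case samples).
    Returns ``(ordered_regions, ascending_mean_signal)``.
    """
    if samples is None:
        cols = list(range(len(matrix.samples)))
    else:
        missing = set(samples) - set(matrix.samples)
        if missing:
            raise ValueError(f"unknown samples {sorted(missing)}")
        cols = [matrix.samples.index(s) for s in samples]
    if not cols:
        raise ValueError("no samples selected")
    means = matrix.values[:, cols].mean(axis=1)
    order = np.argsort(means, kind="stable")
    return [matrix.consensus_regions[i] for i in order], means[order]
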