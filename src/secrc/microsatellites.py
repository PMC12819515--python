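"""Tandem-repeat (microsatellite) detection and enrichment statistics.

The agnostic scan enumerates every possible short tandem-repeat class —
all 4-mers required to repeat >= 4 times and all 3-mers required to
repeat >= 5 times — up to rotation (GGAA, GAAG, AAGG and AGGA describe
the same repeat tract) and excluding homopolymers (an AAAA x 4 run is a
poly-A tract, not a period-4 microsatellite). GGAA microsatellites, the
binding substrate that EWSR1::ETS fusion oncoproteins convert into
neo-enhancers, are the special case with >= 4 consecutive copies.

Hits are maximal period-k tracts: intervals where ``seq[i] == seq[i+k]``
throughout, long enough to contain the required number of tandem unit
copies. A 7-copy run is a single hit with ``n_repeats = 7``, never four
overlapping hits. Ambiguous bases (N) break runs.

Detection is implemented as a vectorized self-offset equality scan, which
is exactly equivalent to taking, for every rotation of the unit, all
maximal regex matches of ``(rotation){min_repeats,}`` and merging
overlapping intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import GenomicRegion, RegionSet

DEFAULT_K_SPECS: tuple[tuple[int, int], ...] = ((4, 4), (3, 5))
GGAA_UNIT = "GGAA"
GGAA_MIN_REPEATS = 4

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def canonical_rotation(unit: str) -> str:
    """Lexicographically minimal rotation — the class representative."""
    return min(rotations(unit))


def is_homopolymer(unit: str) -> bool:
    return len(set(unit)) == 1


@dataclass(frozen=True)
class RepeatClass:
    """A rotational equivalence class of tandem-repeat units."""

    unit: str
    min_repeats: int

    def __post_init__(self) -> None:
        if is_homopolymer(self.unit):
            raise ValueError(f"homopolymer unit {self.unit!r} is not a repeat class")
        if set(self.unit) - set("ACGT"):
            raise ValueError(f"unit {self.unit!r} has non-ACGT characters")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def canonical_unit(self) -> str:
        return canonical_rotation(self.unit)

    @property
    def rc_partner(self) -> str:
        """Canonical unit of the reverse-complement class."""
        return canonical_rotation(reverse_complement(self.unit))


@dataclass(frozen=True)
class MicrosatelliteHit:
    """A maximal tandem run of one repeat class."""

    region: GenomicRegion
    repeat_class: RepeatClass
    n_repeats: int


@dataclass
class MsatRegionStats:
    """Per-region microsatellite counts for one sample and region class."""

    sample_id: str
    label: str  # "SE" or "enhancer"
    counts: list[int]
    normalized: list[float]  # hits per kb: raw x 1000 / region length

    @property
    def mean_normalized(self) -> float:
        return float(np.mean(self.normalized)) if self.normalized else 0.0


def enumerate_repeat_classes(
    k_specs: Sequence[tuple[int, int]] = DEFAULT_K_SPECS,
) -> list[RepeatClass]:
    """One class per rotational necklace of each unit length, no homopolymers.

    For the default specs this yields 66 4-mer classes and 20 3-mer
    classes (70 and 24 necklaces minus the 4 homopolymers each).
    """
    import itertools

    out: list[RepeatClass] = []
    for k, min_repeats in k_specs:
        seen: set[str] = set()
        for combo in itertools.product("ACGT", repeat=k):
            unit = "".join(combo)
            if is_homopolymer(unit):
                continue
            canon = canonical_rotation(unit)
            if canon not in seen:
                seen.add(canon)
                out.append(RepeatClass(canon, min_repeats))
    return out


def ggaa_classes(mode: str = "rotation+rc") -> list[RepeatClass]:
    """The GGAA repeat class, optionally with its reverse complement (TTCC)."""
    fwd = RepeatClass(canonical_rotation(GGAA_UNIT), GGAA_MIN_REPEATS)
    if mode == "literal":
        return [fwd]
    if mode == "rotation+rc":
        rc = RepeatClass(canonical_rotation(reverse_complement(GGAA_UNIT)),
                         GGAA_MIN_REPEATS)
        return [fwd, rc]
    raise ValueError(f"unknown ggaa mode {mode!r}")


def _period_tracts(sequence: str, k: int) -> Iterable[tuple[int, int]]:
    """Maximal intervals of period k (N breaks them), any length >= k+1."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    if arr.size <= k:
        return
    valid = (
        (arr == ord("A")) | (arr == ord("C"))
        | (arr == ord("G")) | (arr == ord("T"))
    )
    eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
    padded = np.concatenate(([False], eq, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive, in eq coordinates
    for s, e in zip(starts, ends):
        yield int(s), int(e) + k  # tract interval [s, e + k)


def scan_sequence(
    sequence: str,
    classes: Sequence[RepeatClass],
    chrom: str = "seq",
    offset: int = 0,
) -> list[MicrosatelliteHit]:
    """All maximal tandem runs of any of ``classes`` in ``sequence``.

    Coordinates are reported on ``chrom`` shifted by ``offset`` so callers
    can scan extracted region sequences and keep genomic positions.
    """
    sequence = sequence.upper()
    by_k: dict[int, dict[str, RepeatClass]] = {}
    for cls in classes:
        by_k.setdefault(cls.unit_length, {})[cls.canonical_unit] = cls
    hits: list[MicrosatelliteHit] = []
    for k, canon_map in by_k.items():
        for s, e in _period_tracts(sequence, k):
            if (e - s) // k < 2:
                continue
            unit = sequence[s:s + k]
            cls = canon_map.get(canonical_rotation(unit))
            if cls is None or (e - s) // k < cls.min_repeats:
                continue
            # report the maximal whole-unit coverage of the tract: for a
            # unit with primitive period p < k (e.g. CGCG) the run of
            # whole units can start at any offset < p, and the best
            # offset may cover up to p-1 trailing bases more than offset 0
            L = e - s
            p = len(set(rotations(unit)))
            end = s + max(
                o + ((L - o) // k) * k
                for o in range(p)
                if (L - o) // k >= cls.min_repeats
            )
            n_rep = (end - s) // k
            region = GenomicRegion(
                chrom, offset + s, offset + end,
                name=cls.canonical_unit, score=float(n_rep),
            )
            hits.append(MicrosatelliteHit(region, cls, n_rep))
    hits.sort(key=lambda h: (h.region.start, h.region.end, h.repeat_class.canonical_unit))
    return hits


def find_repeats(
    sequence: str,
    repeat_class: RepeatClass,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MicrosatelliteHit]:
    """Maximal runs of one repeat class (any rotation of its unit)."""
    return scan_sequence(sequence, [repeat_class], chrom=chrom, offset=offset)


def has_tandem_run(sequence: str, unit: str = GGAA_UNIT,
                   min_repeats: int = GGAA_MIN_REPEATS,
                   mode: str = "rotation+rc") -> bool:
    """Does the sequence contain >= ``min_repeats`` consecutive unit copies?

    ``literal`` mode checks tandem copies of the unit exactly as given;
    ``rotation+rc`` also accepts any rotation and the reverse complement
    (GGAA elements occur on both strands of the reference).
    """
    sequence = sequence.upper()
    units = [unit] if mode == "literal" else None
    if units is None:
        if mode != "rotation+rc":
            raise ValueError(f"unknown mode {mode!r}")
        units = rotations(unit) + rotations(reverse_complement(unit))
    return any(u * min_repeats in sequence for u in units)


# ---------------------------------------------------------------------------
# genome access


def fetch_sequence(genome: Mapping[str, object], region: GenomicRegion) -> str:
    """Extract a region's sequence from a pyfaidx Fasta or a plain dict."""
    if region.chrom not in genome:
        raise KeyError(f"chromosome {region.chrom!r} not in genome")
    record = genome[region.chrom]
    if region.end > len(record):
        raise ValueError(
            f"region {region} extends beyond chromosome end ({len(record)} bp)"
        )
    return str(record[region.start:region.end]).upper()


def count_msats_in_regions(
    regions: RegionSet,
    genome: Mapping[str, object],
    classes: Sequence[RepeatClass],
    label: str = "SE",
) -> MsatRegionStats:
    """Per-region raw and per-kb-normalized microsatellite hit counts.

    The normalized count is ``raw x 1000 / region_length`` (hits per kb),
    the size normalization behind the per-sample means compared between
    super-enhancers and typical enhancers.
    """
    counts: list[int] = []
    normalized: list[float] = []
    for region in regions:
        seq = fetch_sequence(genome, region)
        n = len(scan_sequence(seq, classes, chrom=region.chrom,
                              offset=region.start))
        counts.append(n)
        normalized.append(n * 1000.0 / region.length)
    return MsatRegionStats(regions.sample_id, label, counts, normalized)


def fraction_with_msat(
    regions: RegionSet,
    genome: Mapping[str, object],
    classes: Sequence[RepeatClass],
) -> float:
    """Percent of regions containing at least one microsatellite hit."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    n_hit = 0
    for region in regions:
        seq = fetch_sequence(genome, region)
        if scan_sequence(seq, classes):
            n_hit += 1
    return 100.0 * n_hit / len(regions)


def flag_msat_peaks(
    ets_peaks: RegionSet,
    genome: Mapping[str, object],
    mode: str = "rotation+rc",
) -> list[bool]:
    """Flag ETS fusion-TF peaks containing >= 4 consecutive GGAA copies."""
    return [
        has_tandem_run(fetch_sequence(genome, peak), GGAA_UNIT,
                       GGAA_MIN_REPEATS, mode=mode)
        for peak in ets_peaks
    ]


def paired_enrichment_test(
    se_means: Sequence[float],
    enhancer_means: Sequence[float],
) -> tuple[float, float, int]:
    """Two-sided paired Wilcoxon signed-rank, SE vs enhancer per sample.

    Pairs are matched by sample; zero differences are dropped before
    ranking (Wilcoxon's original treatment). Returns
    ``(statistic, p_value, n_usable_pairs)``; fewer than 5 usable pairs is
    an error.
    """
    if len(se_means) != len(enhancer_means):
        raise ValueError("paired samples must have equal length")
    diffs = np.asarray(se_means, dtype=float) - np.asarray(enhancer_means, dtype=float)
    usable = diffs[diffs != 0]
    if usable.size < 5:
        raise ValueError(
            f"insufficient pairs: {usable.size} non-zero differences (need >= 5)"
        )
    res = stats.wilcoxon(usable, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), int(usable.size)
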