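"""Synthetic epigenomic study generator with a planted ground truth.

The generator emulates the data model of a two-entity ChIP-seq panel:

* a small random genome (2 x 1 Mb by default) carrying planted GGAA
  microsatellites at ~10x density inside case super-enhancer loci
  relative to background;
* per-sample H3K27ac peak calls and piecewise-constant signal tracks in
  which case samples share 20 high-signal stitched SE clusters and
  control samples carry SEs at disjoint loci, plus scattered typical
  enhancers;
* a fully interconnected 3-TF core regulatory circuit planted in case
  SEs only (every ordered pair, including self, has a motif occurrence),
  and a "hegemonic" driver TF whose GGAA-repeat motif occurs in the CRC
  TFs' SEs while its own locus carries no SE and no incoming motif — the
  out-edges-only configuration that can never join a clique;
* fusion-TF (ETS) peaks sitting on planted microsatellites in case
  samples only;
* chromatin loops forming promoter-enhancer chains that reach an
  mSat-bound anchor at configured hop distances (1..5, plus one TF at 6,
  which is invisible at the default depth cap), and decoy loops between
  unannotated anchors;
* an expression matrix (case-specific CRC TFs and driver) and a CRISPR
  dependency table in which the driver is the top dependency.

Every output is a plain-text standard format, and a JSON truth manifest
records each planted feature so any intermediate of the analysis can be
recomputed by brute force. Generation is deterministic: a fixed config
(including seed) yields byte-identical files.

The signal model is piecewise-constant coverage (peak heights are
lognormal; SE constituents ~10x typical-enhancer height) rather than
read-level simulation — super-enhancer calling consumes coverage, so
read simulation would add nothing testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import GenomicRegion, Loop, write_bedpe
from .microsatellites import (
    GGAA_UNIT,
    canonical_rotation,
    is_homopolymer,
    reverse_complement,
)
from .motifs import MotifMatrix, write_jaspar

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-truth dataset."""

    seed: int = 42
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_case: int = 10
    n_control: int = 10
    n_genes: int = 60
    n_tfs: int = 12
    n_se_per_sample: int = 20
    # microsatellite planting: per-kb rate in case SEs is 10x background
    bg_msat_per_kb: float = 0.1
    se_msat_per_kb: float = 1.0
    # chain planting: TF index (1-based) -> hop distance of the mSat anchor
    loop_hops: dict[str, int] = field(default_factory=lambda: {
        "TF01": 1, "TF02": 2, "TF03": 3, "TF04": 4, "TF05": 5, "TF06": 6,
    })
    n_decoy_loops: int = 30
    # noise
    peak_jitter_sd: float = 50.0
    expr_noise_sd: float = 0.5
    # signal model (log-space): SE constituents ~10x enhancer height
    se_peak_log_height: float = 3.0   # ~ e^3 = 20
    enh_peak_log_height: float = 0.7  # ~ e^0.7 = 2
    peak_log_height_sd: float = 0.25
    n_scatter_enhancers: int = 20  # capped by the scatter-zone grid
    # expression means (log2 scale)
    expr_high: float = 8.0
    expr_low: float = 0.3
    expr_mid: float = 5.0
    expr_baseline: float = 4.0
    # planted circuit
    crc_tfs: tuple[str, ...] = ("TF01", "TF02", "TF03")
    driver_tf: str = "TF12"
    lineage: str = "case"

    def __post_init__(self) -> None:
        if self.driver_tf in self.crc_tfs:
            raise ValueError("driver TF cannot be a CRC TF")

    def tf_names(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tfs)]

    def gene_names(self) -> list[str]:
        tfs = self.tf_names()
        others = [f"GENE{i + 1:02d}" for i in range(self.n_tfs, self.n_genes)]
        return tfs + others

    def case_samples(self) -> list[str]:
        return [f"case{i + 1:02d}" for i in range(self.n_case)]

    def control_samples(self) -> list[str]:
        return [f"ctrl{i + 1:02d}" for i in range(self.n_control)]


# ---------------------------------------------------------------------------
# deterministic genomic layout


@dataclass
class _Locus:
    chrom: str
    start: int  # SE cluster footprint start
    gene: str
    is_case: bool

    WIDTH = 10_000  # 4 constituent peaks at 2.5 kb pitch

    @property
    def end(self) -> int:
        return self.start + self.WIDTH

    @property
    def tss(self) -> int:
        return self.start + 200

    def constituents(self) -> list[tuple[int, int]]:
        return [(self.start + k * 2_500, self.start + k * 2_500 + 1_200)
                for k in range(4)]


class _Layout:
    """Deterministic positions of loci, genes, anchors and zones.

    Each chromosome is partitioned into a case territory [0, 500 kb), a
    control territory [500, 800 kb), a scattered-enhancer zone
    [800, 895 kb) and a decoy-loop zone [900, 990 kb).
    """

    CASE_PITCH = 45_000
    CASE_BASE = 50_000
    CTRL_PITCH = 28_000
    CTRL_BASE = 510_000
    SCATTER = (805_000, 985_000)
    # scatter peaks sit on an 18-kb grid so they never stitch together
    SCATTER_PITCH = 18_000
    DECOY = (900_000, 990_000)
    ANCHOR_OFFSET = 12_000  # first chain anchor, relative to the TSS
    ANCHOR_PITCH = 3_000
    ANCHOR_WIDTH = 1_000

    def __init__(self, cfg: SyntheticConfig):
        self.cfg = cfg
        if cfg.chrom_length < 1_000_000:
            raise ValueError("chrom_length must be >= 1 Mb for the layout")
        self.chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
        genes = cfg.gene_names()
        tfs = cfg.tf_names()
        non_tf = [g for g in genes if g not in tfs]
        n_loci = cfg.n_se_per_sample
        # case SE loci: CRC TFs first, then other TFs (minus the driver),
        # then non-TF genes
        case_gene_order = [t for t in tfs if t != cfg.driver_tf]
        case_gene_order += non_tf
        self.case_loci: list[_Locus] = []
        for i in range(n_loci):
            chrom = self.chroms[i % len(self.chroms)]
            start = self.CASE_BASE + (i // len(self.chroms)) * self.CASE_PITCH
            if start + _Locus.WIDTH + 35_000 > 500_000:
                raise ValueError("too many case SE loci for the territory")
            self.case_loci.append(_Locus(chrom, start, case_gene_order[i], True))
        self.control_loci: list[_Locus] = []
        ctrl_genes = [g for g in non_tf if g not in
                      {l.gene for l in self.case_loci}]
        for i in range(n_loci):
            chrom = self.chroms[i % len(self.chroms)]
            start = self.CTRL_BASE + (i // len(self.chroms)) * self.CTRL_PITCH
            if start + _Locus.WIDTH > 800_000:
                raise ValueError("too many control SE loci for the territory")
            self.control_loci.append(_Locus(chrom, start, ctrl_genes[i], False))
        # driver TSS: in case territory, far from any SE locus
        self.driver_tss = (self.chroms[0], 20_000)
        # remaining genes: spread through the scatter zone, 3 kb apart
        placed = {l.gene for l in self.case_loci + self.control_loci}
        placed.add(cfg.driver_tf)
        self.extra_tss: list[tuple[str, int, str]] = []
        leftover = [g for g in genes if g not in placed]
        for i, gene in enumerate(leftover):
            chrom = self.chroms[i % len(self.chroms)]
            pos = self.SCATTER[0] + 1_000 + (i // len(self.chroms)) * 3_000
            self.extra_tss.append((chrom, pos, gene))

    def locus_for_gene(self, gene: str) -> _Locus | None:
        for locus in self.case_loci + self.control_loci:
            if locus.gene == gene:
                return locus
        return None

    def gene_models(self) -> list[tuple[str, str, int, bool]]:
        """(gene, chrom, tss_pos, is_tf) for every gene."""
        tfs = set(self.cfg.tf_names())
        out = []
        for locus in self.case_loci + self.control_loci:
            out.append((locus.gene, locus.chrom, locus.tss, locus.gene in tfs))
        out.append((self.cfg.driver_tf, self.driver_tss[0], self.driver_tss[1], True))
        for chrom, pos, gene in self.extra_tss:
            out.append((gene, chrom, pos, gene in tfs))
        return out

    def chain_anchors(self, tf: str) -> list[tuple[str, int, int]]:
        """Anchor intervals A1..Ah for a TF's planted chain (h = hop)."""
        locus = self.locus_for_gene(tf)
        hop = self.cfg.loop_hops[tf]
        out = []
        for j in range(1, hop + 1):
            start = locus.tss + self.ANCHOR_OFFSET + (j - 1) * self.ANCHOR_PITCH
            out.append((locus.chrom, start, start + self.ANCHOR_WIDTH))
        return out


# ---------------------------------------------------------------------------
# genome with planted repeats and motifs


class _Planter:
    """Writes features into mutable chromosome arrays, avoiding collisions."""

    def __init__(self, sequences: dict[str, np.ndarray], rng: np.random.Generator):
        self.seq = sequences
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sequences}

    def _collides(self, chrom: str, start: int, end: int, margin: int = 10) -> bool:
        return any(s - margin < end and start < e + margin
                   for s, e in self.occupied[chrom])

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))

    def write(self, chrom: str, start: int, text: str) -> None:
        arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
        self.seq[chrom][start:start + arr.size] = arr
        self.reserve(chrom, start, start + arr.size)

    def plant_tandem(self, chrom: str, start: int, unit: str, n_rep: int) -> None:
        """Write a tandem run and break periodicity at both flanks."""
        k = len(unit)
        run = unit * n_rep
        self.write(chrom, start, run)
        end = start + k * n_rep
        seq = self.seq[chrom]
        if start >= 1 and seq[start - 1] == seq[start + k - 1]:
            seq[start - 1] = _other_base(seq[start + k - 1])
        if end < seq.size and seq[end] == seq[end - k]:
            seq[end] = _other_base(seq[end - k])

    def random_spot(self, chrom: str, lo: int, hi: int, width: int,
                    max_tries: int = 200) -> int:
        for _ in range(max_tries):
            start = int(self.rng.integers(lo, hi - width))
            if not self._collides(chrom, start, start + width):
                return start
        raise RuntimeError(
            f"could not place a {width}-bp feature in {chrom}:{lo}-{hi} "
            f"after {max_tries} tries"
        )


def _other_base(value: int) -> int:
    for b in _BASES:
        if b != value:
            return int(b)
    raise AssertionError


def _random_unit(rng: np.random.Generator, k: int) -> str:
    while True:
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
        if not is_homopolymer(unit):
            return unit


def make_motifs(cfg: SyntheticConfig,
                rng: np.random.Generator | None = None) -> dict[str, MotifMatrix]:
    """One sharp 12-bp matrix per TF; the driver's is a GGAA-repeat motif."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    motifs: dict[str, MotifMatrix] = {}
    used: set[str] = set()
    for i, tf in enumerate(cfg.tf_names()):
        if tf == cfg.driver_tf:
            consensus = GGAA_UNIT * 3
        else:
            while True:
                consensus = "".join(
                    "ACGT"[b] for b in rng.integers(0, 4, size=12))
                if consensus not in used and reverse_complement(consensus) not in used \
                        and GGAA_UNIT * 2 not in consensus:
                    break
            used.add(consensus)
        counts = np.full((4, len(consensus)), 0.0)
        for j, base in enumerate(consensus):
            counts["ACGT".index(base), j] = 100.0
        motifs[tf] = MotifMatrix(f"SYN{i + 1:04d}", tf, counts)
    return motifs


def make_genome(cfg: SyntheticConfig):
    """Random genome with planted repeats and motif occurrences.

    Returns ``(sequences, records)`` where ``sequences`` maps chromosome
    name to str and ``records`` is the planted-feature part of the truth
    manifest (microsatellites, motif occurrences).
    """
    layout = _Layout(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    seqs = {
        chrom: _BASES[rng.integers(0, 4, size=cfg.chrom_length)].copy()
        for chrom in layout.chroms
    }
    planter = _Planter(seqs, rng)
    motifs = make_motifs(cfg)
    msat_records: list[dict] = []
    motif_records: list[dict] = []

    # 1) CRC wiring: for every ordered (source, target) pair over the CRC
    #    TFs (self included) plant the source's consensus inside one of
    #    the target's SE constituent peak footprints.
    for target in cfg.crc_tfs:
        locus = layout.locus_for_gene(target)
        for s_idx, source in enumerate(cfg.crc_tfs):
            c_start, c_end = locus.constituents()[s_idx]
            consensus = motifs[source].consensus()
            pos = (c_start + c_end) // 2 - len(consensus) // 2
            planter.write(locus.chrom, pos, consensus)
            motif_records.append({
                "source": source, "target": target,
                "chrom": locus.chrom, "start": pos,
                "end": pos + len(consensus),
            })

    # 2) microsatellites inside case SE loci (high density)
    for locus in layout.case_loci:
        n_runs = int(rng.poisson(cfg.se_msat_per_kb * _Locus.WIDTH / 1000.0))
        for _ in range(n_runs):
            n_rep = int(rng.integers(4, 13))
            width = 4 * n_rep
            start = planter.random_spot(locus.chrom, locus.start,
                                        locus.end - width, width)
            planter.plant_tandem(locus.chrom, start, GGAA_UNIT, n_rep)
            msat_records.append({
                "chrom": locus.chrom, "start": start, "end": start + width,
                "unit": canonical_rotation(GGAA_UNIT), "n_repeats": n_rep,
                "context": "case_se", "gene": locus.gene,
            })

    # 3) mSat anchors terminating the planted promoter-enhancer chains
    for tf in cfg.loop_hops:
        chrom, a_start, a_end = layout.chain_anchors(tf)[-1]
        n_rep = 6
        start = (a_start + a_end) // 2 - 2 * n_rep
        planter.plant_tandem(chrom, start, GGAA_UNIT, n_rep)
        msat_records.append({
            "chrom": chrom, "start": start, "end": start + 4 * n_rep,
            "unit": canonical_rotation(GGAA_UNIT), "n_repeats": n_rep,
            "context": "anchor", "gene": tf,
        })

    # 4) sparse background repeats everywhere outside case SE loci:
    #    mostly GGAA, some random 4-mer and 3-mer classes
    total_kb = cfg.n_chroms * cfg.chrom_length / 1000.0
    n_bg = int(rng.poisson(cfg.bg_msat_per_kb * total_kb))
    case_spans = {(l.chrom, l.start, l.end + 35_000) for l in layout.case_loci}
    for _ in range(n_bg):
        chrom = layout.chroms[int(rng.integers(0, len(layout.chroms)))]
        u = rng.random()
        if u < 0.7:
            unit, n_rep = GGAA_UNIT, int(rng.integers(4, 9))
        elif u < 0.9:
            unit, n_rep = _random_unit(rng, 4), int(rng.integers(4, 9))
        else:
            unit, n_rep = _random_unit(rng, 3), int(rng.integers(5, 10))
        width = len(unit) * n_rep
        for _ in range(50):
            start = int(rng.integers(1_000, cfg.chrom_length - width - 1_000))
            if any(c == chrom and s <= start < e for c, s, e in case_spans):
                continue
            if not planter._collides(chrom, start, start + width):
                break
        else:
            continue
        planter.plant_tandem(chrom, start, unit, n_rep)
        msat_records.append({
            "chrom": chrom, "start": start, "end": start + width,
            "unit": canonical_rotation(unit), "n_repeats": n_rep,
            "context": "background", "gene": None,
        })

    sequences = {c: arr.tobytes().decode("ascii") for c, arr in seqs.items()}
    return sequences, {"msats": msat_records, "motif_occurrences": motif_records}


# ---------------------------------------------------------------------------
# per-sample ChIP landscapes


def _jitter(rng: np.random.Generator, sd: float) -> int:
    return int(round(rng.normal(0.0, sd))) if sd > 0 else 0


def make_chip_samples(cfg: SyntheticConfig, msat_records: list[dict] | None = None):
    """Per-sample H3K27ac peaks/signal and case-only ETS peak calls.

    Returns a dict: sample -> {"peaks": [(chrom, start, end, height)],
    "ets": [(chrom, start, end)]} with peaks sorted. Case samples share
    the case SE loci (plus their chain-anchor peaks); controls use the
    disjoint control loci; both get scattered typical enhancers. ETS
    peaks sit on the planted case-SE and anchor microsatellites
    (``msat_records`` from :func:`make_genome`; regenerated when absent).
    """
    layout = _Layout(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    if msat_records is None:
        _, records = make_genome(cfg)
        msat_records = records["msats"]
    case_msats = [m for m in msat_records if m["context"] in ("case_se", "anchor")]

    samples: dict[str, dict] = {}
    for group, names in (("case", cfg.case_samples()),
                         ("control", cfg.control_samples())):
        loci = layout.case_loci if group == "case" else layout.control_loci
        for name in names:
            peaks: list[tuple[str, int, int, float]] = []
            for locus in loci:
                for c_start, c_end in locus.constituents():
                    s = max(0, c_start + _jitter(rng, cfg.peak_jitter_sd))
                    e = c_end + _jitter(rng, cfg.peak_jitter_sd)
                    height = float(np.exp(rng.normal(
                        cfg.se_peak_log_height, cfg.peak_log_height_sd)))
                    peaks.append((locus.chrom, s, max(e, s + 200), height))
            if group == "case":
                for tf in cfg.loop_hops:
                    for chrom, a_start, a_end in layout.chain_anchors(tf):
                        s = max(0, a_start + _jitter(rng, cfg.peak_jitter_sd))
                        e = a_end + _jitter(rng, cfg.peak_jitter_sd)
                        height = float(np.exp(rng.normal(
                            cfg.enh_peak_log_height, cfg.peak_log_height_sd)))
                        peaks.append((chrom, s, max(e, s + 200), height))
            # scattered typical enhancers on a sparse grid: slot pitch
            # exceeds the stitch distance, so each stays a singleton
            zone_lo, zone_hi = layout.SCATTER
            slots = []
            for chrom in layout.chroms:
                pos = zone_lo
                while pos + layout.SCATTER_PITCH <= zone_hi:
                    slots.append((chrom, pos))
                    pos += layout.SCATTER_PITCH
            for chrom, slot in slots[:cfg.n_scatter_enhancers]:
                width = int(rng.integers(800, 1_400))
                start = slot + int(rng.integers(0, 2_000))
                height = float(np.exp(rng.normal(
                    cfg.enh_peak_log_height, cfg.peak_log_height_sd)))
                peaks.append((chrom, start, start + width, height))
            peaks.sort()
            ets = []
            if group == "case":
                for m in case_msats:
                    center = (m["start"] + m["end"]) // 2
                    ets.append((m["chrom"], center - 200, center + 200))
                ets.sort()
            samples[name] = {"group": group, "peaks": peaks, "ets": ets}
    return samples


def make_loops(cfg: SyntheticConfig):
    """Per-case-sample loop lists realizing the configured hop distances."""
    layout = _Layout(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    loops_by_sample: dict[str, list[Loop]] = {}
    for name in cfg.case_samples():
        loops: list[Loop] = []
        for tf in cfg.loop_hops:
            locus = layout.locus_for_gene(tf)
            promoter = GenomicRegion(locus.chrom, locus.tss - 1_000,
                                     locus.tss + 1_000)
            prev = promoter
            for chrom, a_start, a_end in layout.chain_anchors(tf):
                anchor = GenomicRegion(chrom, a_start, a_end)
                loops.append(Loop(prev, anchor, count=5.0))
                prev = anchor
        decoy_lo, decoy_hi = layout.DECOY
        for _ in range(cfg.n_decoy_loops):
            chrom = layout.chroms[int(rng.integers(0, len(layout.chroms)))]
            a = int(rng.integers(decoy_lo, decoy_hi - 2_000))
            b = int(rng.integers(decoy_lo, decoy_hi - 2_000))
            if abs(a - b) < 2_000:
                continue
            loops.append(Loop(GenomicRegion(chrom, a, a + 1_000),
                              GenomicRegion(chrom, b, b + 1_000), count=1.0))
        loops_by_sample[name] = loops
    return loops_by_sample


def make_expression_and_dependency(cfg: SyntheticConfig):
    """Expression matrix and dependency table consistent with the truth.

    CRC TFs and the driver are high in cases and low in controls; the
    driver carries the most negative dependency T-statistic; CRC TFs are
    mildly negative; a handful of planted non-TF genes are negative with
    and without SE association.
    """
    import pandas as pd

    layout = _Layout(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    genes = cfg.gene_names()
    samples = cfg.case_samples() + cfg.control_samples()
    groups = {s: ("case" if s.startswith("case") else "control")
              for s in samples}
    specific = set(cfg.crc_tfs) | {cfg.driver_tf}
    se_genes = {l.gene for l in layout.case_loci}
    values = np.zeros((len(genes), len(samples)))
    for i, gene in enumerate(genes):
        for j, sample in enumerate(samples):
            if gene in specific:
                mean = cfg.expr_high if groups[sample] == "case" else cfg.expr_low
            elif gene in se_genes or any(l.gene == gene for l in layout.control_loci):
                mean = cfg.expr_mid
            elif gene.startswith("TF"):
                mean = cfg.expr_mid
            else:
                mean = cfg.expr_baseline
            values[i, j] = mean + rng.normal(0.0, cfg.expr_noise_sd)
    expr = pd.DataFrame(values, index=genes, columns=samples)

    non_tf_se = [g for g in se_genes if not g.startswith("TF")]
    dep_se_assoc = sorted(non_tf_se)[:5]           # negative, SE-associated
    any_locus_gene = se_genes | {l.gene for l in layout.control_loci}
    pool = [g for g in genes if g not in any_locus_gene
            and g not in specific and not g.startswith("TF")]
    dep_no_se = sorted(pool)[:5]                   # negative, not SE-associated
    rows = []

    def add(gene: str, t: float, effect: float, p: float,
            lineage: str | None = None) -> None:
        rows.append({"gene": gene, "lineage": lineage or cfg.lineage,
                     "gene_effect": effect, "t_statistic": t, "adj_p": p})

    add(cfg.driver_tf, -12.0, -2.5, 1e-30)
    for k, tf in enumerate(cfg.crc_tfs):
        add(tf, -3.0 - 0.2 * k, -0.8 - 0.1 * k, 1e-6)
    for k, g in enumerate(dep_se_assoc):
        add(g, -2.0 - 0.1 * k, -0.6, 1e-4)
    for k, g in enumerate(dep_no_se):
        add(g, -1.5 - 0.1 * k, -0.5, 1e-3)
    positives = [g for g in genes if g not in {r["gene"] for r in rows}][:20]
    for k, g in enumerate(positives):
        add(g, 0.5 + 0.1 * k, 0.1, 0.5)
    # a second lineage so lineage filtering is non-trivial
    add("GENE55", -4.0, -1.0, 1e-5, lineage="other")
    dependency = pd.DataFrame(rows)
    truth = {
        "case_specific_genes": sorted(specific),
        "dependency_negative": sorted({r["gene"] for r in rows
                                       if r["lineage"] == cfg.lineage
                                       and r["t_statistic"] < 0}),
        "dependency_se_associated": sorted(set(cfg.crc_tfs) | set(dep_se_assoc)
                                           | ({cfg.driver_tf} & se_genes)),
        "dependency_not_se_associated": sorted({cfg.driver_tf} | set(dep_no_se)),
    }
    return expr, groups, dependency, truth


# ---------------------------------------------------------------------------
# dataset assembly


def generate_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write the full study to ``out_dir`` and return the truth manifest."""
    out = Path(out_dir)
    for sub in ("peaks", "signal", "ets", "loops"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    layout = _Layout(cfg)

    sequences, genome_truth = make_genome(cfg)
    with open(out / "genome.fa", "w") as fh:
        for chrom in layout.chroms:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    gene_rows = layout.gene_models()
    with open(out / "genes.bed", "w") as fh:
        for gene, chrom, pos, _is_tf in sorted(gene_rows, key=lambda r: (r[1], r[2])):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{gene}\t0\t+\n")
    with open(out / "tf_list.txt", "w") as fh:
        for tf in cfg.tf_names():
            fh.write(tf + "\n")

    motifs = make_motifs(cfg)
    write_jaspar(list(motifs.values()), out / "motifs.jaspar")

    samples = make_chip_samples(cfg, genome_truth["msats"])
    sheet_rows = []
    for name, payload in samples.items():
        peak_path = f"peaks/{name}.narrowPeak"
        signal_path = f"signal/{name}.bedGraph"
        with open(out / peak_path, "w") as fh:
            for i, (chrom, s, e, h) in enumerate(payload["peaks"]):
                fh.write(f"{chrom}\t{s}\t{e}\tpeak{i}\t{min(1000, int(h * 10))}"
                         f"\t.\t{h:.3f}\t-1\t-1\t{(e - s) // 2}\n")
        with open(out / signal_path, "w") as fh:
            for chrom, s, e, h in payload["peaks"]:
                fh.write(f"{chrom}\t{s}\t{e}\t{h:.4f}\n")
        ets_path = ""
        if payload["ets"]:
            ets_path = f"ets/{name}.narrowPeak"
            with open(out / ets_path, "w") as fh:
                for i, (chrom, s, e) in enumerate(payload["ets"]):
                    fh.write(f"{chrom}\t{s}\t{e}\tets{i}\t0\t.\t0\t-1\t-1\t"
                             f"{(e - s) // 2}\n")
        sheet_rows.append({
            "sample_id": name, "group": payload["group"],
            "peaks": peak_path, "signal": signal_path,
            "control_signal": "", "ets_peaks": ets_path, "loops": "",
        })

    loops_by_sample = make_loops(cfg)
    for name, loops in loops_by_sample.items():
        loop_path = f"loops/{name}.bedpe"
        write_bedpe(loops, out / loop_path)
        for row in sheet_rows:
            if row["sample_id"] == name:
                row["loops"] = loop_path

    expr, groups, dependency, dep_truth = make_expression_and_dependency(cfg)
    expr.round(4).to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    dependency.to_csv(out / "dependency.csv", index=False)

    with open(out / "sample_sheet.tsv", "w") as fh:
        cols = ["sample_id", "group", "peaks", "signal", "control_signal",
                "ets_peaks", "loops"]
        fh.write("\t".join(cols) + "\n")
        for row in sorted(sheet_rows, key=lambda r: r["sample_id"]):
            fh.write("\t".join(row[c] for c in cols) + "\n")

    manifest = {
        "config": asdict(cfg),
        "case_samples": cfg.case_samples(),
        "control_samples": cfg.control_samples(),
        "crc_tfs": list(cfg.crc_tfs),
        "driver_tf": cfg.driver_tf,
        "loop_hops": dict(cfg.loop_hops),
        "se_loci": [
            {"chrom": l.chrom, "start": l.start, "end": l.end,
             "gene": l.gene, "is_case": l.is_case}
            for l in layout.case_loci + layout.control_loci
        ],
        **genome_truth,
        **dep_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# lightweight enrichment simulation (power / type-I studies)


def simulate_enrichment_pair(
    rng: np.random.Generator,
    n_samples: int = 10,
    n_se: int = 10,
    se_len: int = 2_000,
    n_enh: int = 50,
    enh_len: int = 1_000,
    bg_per_kb: float = 0.3,
    se_multiplier: float = 10.0,
) -> tuple[list[float], list[float]]:
    """Per-sample SE and enhancer mean mSat densities from planted sequences.

    Each region is an i.i.d. random sequence carrying Poisson-many planted
    GGAA runs at the region-class rate (``bg_per_kb`` for enhancers,
    ``bg_per_kb * se_multiplier`` for SEs; a multiplier of 1 is the null).
    Counting runs through the real scanner, so the whole statistics path
    is exercised.
    """
    from .microsatellites import ggaa_classes, scan_sequence

    classes = ggaa_classes("rotation+rc")
    se_means, enh_means = [], []
    for _ in range(n_samples):
        for which, (n_reg, length, rate), sink in (
            ("se", (n_se, se_len, bg_per_kb * se_multiplier), se_means),
            ("enh", (n_enh, enh_len, bg_per_kb), enh_means),
        ):
            densities = []
            for _ in range(n_reg):
                seq = _BASES[rng.integers(0, 4, size=length)].copy()
                n_runs = int(rng.poisson(rate * length / 1000.0))
                placed: list[tuple[int, int]] = []
                for _ in range(n_runs):
                    n_rep = int(rng.integers(4, 9))
                    width = 4 * n_rep
                    for _ in range(30):
                        s = int(rng.integers(0, length - width))
                        if all(s + width + 8 <= a or b + 8 <= s for a, b in placed):
                            placed.append((s, s + width))
                            run = np.frombuffer((GGAA_UNIT * n_rep).encode(),
                                                dtype=np.uint8)
                            seq[s:s + width] = run
                            break
                text = seq.tobytes().decode("ascii")
                densities.append(
                    len(scan_sequence(text, classes)) * 1000.0 / length)
            sink.append(float(np.mean(densities)))
    return se_means, enh_means
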